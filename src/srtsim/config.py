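"""Experiment configuration: YAML-backed, schema-validated, reproducible.

One config plus one master seed determines the entire pipeline output:
corpus synthesis, word draws, listener responses and condition order.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .corpus import Corpus, CorpusConfig, build_corpus
from .listener import ListenerProfile
from .staircase import Listener, StaircaseParams
from .stimulus import CONDITION_LABELS

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid or malformed experiment configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CorpusSection(_Strict):
    sample_rate: int = 22050
    rms_constant: float = 0.05
    duration_min_s: float = 0.3
    duration_max_s: float = 0.5
    cue_word_index: int = 0

    def to_corpus_config(self) -> CorpusConfig:
        return CorpusConfig(
            sample_rate=self.sample_rate,
            rms_constant=self.rms_constant,
            duration_range=(self.duration_min_s, self.duration_max_s),
            cue_word_index=self.cue_word_index,
        )


class StaircaseSection(_Strict):
    initial_snr_db: float = 10.0
    step_initial_db: float = 4.0
    step_final_db: float = 2.0
    reversals_to_reduce: int = 2
    max_trials: int = 20
    reversals_required: int = 6
    srt_reversals: int = 6
    snr_low_db: float = -60.0
    snr_high_db: float = 40.0

    def to_params(self) -> StaircaseParams:
        return StaircaseParams(
            initial_snr_db=self.initial_snr_db,
            step_initial_db=self.step_initial_db,
            step_final_db=self.step_final_db,
            reversals_to_reduce=self.reversals_to_reduce,
            max_trials=self.max_trials,
            reversals_required=self.reversals_required,
            srt_reversals=self.srt_reversals,
            snr_bounds_db=(self.snr_low_db, self.snr_high_db),
        )


class ListenerSection(_Strict):
    """Population from which per-listener thresholds are drawn."""

    n_listeners: int = 10
    threshold_db: float = -10.0  # population mean per-keyword midpoint
    threshold_sd_db: float = 2.0  # between-listener spread
    reversed_benefit_db: float = 6.0  # threshold improvement with reversed maskers
    slope_db: float = 2.0
    guess: float = 0.1
    lapse: float = 0.0


class ExperimentConfig(_Strict):
    """Top-level config: corpus, staircase, listeners, conditions, seed."""

    corpus: CorpusSection = CorpusSection()
    staircase: StaircaseSection = StaircaseSection()
    listeners: ListenerSection = ListenerSection()
    conditions: list[str] = list(CONDITION_LABELS)
    reversal_states: list[Literal["forward", "reversed"]] = ["forward", "reversed"]
    master_seed: int = 0
    runs_per_condition_min: int = 2
    runs_per_condition_max: int = 3

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        bad = [c for c in self.conditions if c not in CONDITION_LABELS]
        if bad:
            raise ValueError(f"unknown condition labels {bad}; valid: {CONDITION_LABELS}")
        if not 1 <= self.runs_per_condition_min <= self.runs_per_condition_max:
            raise ValueError("runs_per_condition bounds must satisfy 1 <= min <= max")
        return self

    def condition_cells(self) -> list[tuple[str, bool]]:
        return [
            (label, state == "reversed")
            for label in self.conditions
            for state in self.reversal_states
        ]

    def build_corpus(self) -> Corpus:
        return build_corpus(self.corpus.to_corpus_config(), self.master_seed)

    def build_listeners(self, rng: np.random.Generator) -> list[Listener]:
        """Draw the simulated listener panel from the population settings."""
        ls = self.listeners
        panel = []
        for i in range(ls.n_listeners):
            base = ls.threshold_db + rng.normal(0.0, ls.threshold_sd_db)
            profiles = {}
            for label, rev in self.condition_cells():
                theta = base - (ls.reversed_benefit_db if rev else 0.0)
                profiles[(label, rev)] = ListenerProfile(
                    threshold_db=theta, slope_db=ls.slope_db,
                    guess=ls.guess, lapse=ls.lapse,
                )
            panel.append(Listener(listener_id=f"L{i + 1:02d}", profiles=profiles))
        return panel


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; defaults filled in."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    """Serialize a config back to YAML (lossless round trip)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
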