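"""Adaptive 1-up/1-down SRT staircase and experiment simulation.

The staircase tracks the SNR at which both keywords are reported
correctly on 50% of trials: a correct keyword pair lowers the SNR, an
incorrect one raises it.  The step is 4 dB until two reversals have
occurred and 2 dB thereafter.  A run lasts exactly 20 trials; it is
valid only if it contains at least six reversals, and its SRT is the
mean SNR of the last six reversals.  Two to three valid runs are
averaged per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .listener import ListenerProfile, p_both
from .stimulus import (
    CONDITION_LABELS,
    MaskerCondition,
    condition,
    draw_masker_specs,
    draw_target_spec,
)

__all__ = [
    "StaircaseParams",
    "Trial",
    "StaircaseRun",
    "ConditionResult",
    "ConvergenceError",
    "run_staircase",
    "measure_srt",
    "Listener",
    "ExperimentResult",
    "simulate_experiment",
]

Responder = Callable[[float], bool]


class ConvergenceError(RuntimeError):
    """Raised when the required number of valid runs cannot be collected."""


@dataclass(frozen=True)
class StaircaseParams:
    initial_snr_db: float = 10.0
    step_initial_db: float = 4.0
    step_final_db: float = 2.0
    reversals_to_reduce: int = 2
    max_trials: int = 20
    reversals_required: int = 6
    srt_reversals: int = 6
    snr_bounds_db: tuple[float, float] = (-60.0, 40.0)

    def __post_init__(self) -> None:
        if self.step_final_db > self.step_initial_db:
            raise ValueError("step_final_db must not exceed step_initial_db")
        if self.srt_reversals > self.reversals_required:
            raise ValueError("srt_reversals must not exceed reversals_required")
        lo, hi = self.snr_bounds_db
        if not lo <= self.initial_snr_db <= hi:
            raise ValueError("snr_bounds_db must contain initial_snr_db")


@dataclass(frozen=True)
class Trial:
    index: int  # 1-based
    snr_db: float
    correct: bool
    step_after_db: float
    is_reversal: bool
    clamped: bool = False  # the commanded next SNR hit a bound


@dataclass(frozen=True)
class StaircaseRun:
    trials: tuple[Trial, ...]
    reversal_snrs_db: tuple[float, ...]
    valid: bool
    srt_db: float | None  # defined only when valid
    clamped: bool = False  # any trial's commanded SNR was clamped

    @property
    def snr_sequence(self) -> list[float]:
        return [t.snr_db for t in self.trials]


def run_staircase(
    responder: Responder,
    params: StaircaseParams | None = None,
) -> StaircaseRun:
    """Run one adaptive track against a responder.

    A reversal is logged at the trial whose response flips the commanded
    direction of SNR change; the reversal SNR is the SNR presented at
    that trial.  The reduced step applies to every step commanded after
    the second reversal has been logged.  Degenerate responders produce
    invalid runs, never errors.
    """
    params = params or StaircaseParams()
    lo, hi = params.snr_bounds_db
    snr = params.initial_snr_db
    prev_dir: int | None = None
    reversal_snrs: list[float] = []
    trials: list[Trial] = []
    any_clamped = False

    for index in range(1, params.max_trials + 1):
        correct = bool(responder(snr))
        direction = -1 if correct else +1
        is_reversal = prev_dir is not None and direction != prev_dir
        if is_reversal:
            reversal_snrs.append(snr)
        step = (
            params.step_final_db
            if len(reversal_snrs) >= params.reversals_to_reduce
            else params.step_initial_db
        )
        next_snr = snr + direction * step
        clamped = not lo <= next_snr <= hi
        next_snr = min(max(next_snr, lo), hi)
        any_clamped = any_clamped or clamped
        trials.append(Trial(index, snr, correct, step, is_reversal, clamped))
        prev_dir = direction
        snr = next_snr

    valid = len(reversal_snrs) >= params.reversals_required
    srt = (
        float(np.mean(reversal_snrs[-params.srt_reversals:])) if valid else None
    )
    return StaircaseRun(
        trials=tuple(trials),
        reversal_snrs_db=tuple(reversal_snrs),
        valid=valid,
        srt_db=srt,
        clamped=any_clamped,
    )


@dataclass(frozen=True)
class ConditionResult:
    """Per-condition SRT: the mean over valid runs."""

    condition: str | None
    reversed: bool
    run_srts_db: tuple[float, ...]
    srt_db: float
    n_discarded: int
    runs: tuple[StaircaseRun, ...] = field(default=(), repr=False)


def measure_srt(
    responder_factory: Callable[[np.random.Generator], Responder],
    params: StaircaseParams,
    n_runs: int,
    rng: np.random.Generator,
    max_attempts: int = 20,
    condition_label: str | None = None,
    reversed: bool = False,
) -> ConditionResult:
    """Collect ``n_runs`` valid staircase runs and average their SRTs.

    Invalid runs (fewer than the required reversals within the trial
    budget) are discarded and rerun, as in the testing protocol.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    valid_runs: list[StaircaseRun] = []
    n_discarded = 0
    for _ in range(max_attempts):
        run = run_staircase(responder_factory(rng), params)
        if run.valid:
            valid_runs.append(run)
            if len(valid_runs) == n_runs:
                break
        else:
            n_discarded += 1
    else:
        raise ConvergenceError(
            f"only {len(valid_runs)}/{n_runs} valid runs in {max_attempts} attempts"
        )
    srts = tuple(r.srt_db for r in valid_runs)
    return ConditionResult(
        condition=condition_label,
        reversed=reversed,
        run_srts_db=srts,
        srt_db=float(np.mean(srts)),
        n_discarded=n_discarded,
        runs=tuple(valid_runs),
    )


@dataclass(frozen=True)
class Listener:
    """A simulated participant: one psychometric profile per condition."""

    listener_id: str
    profiles: dict[tuple[str, bool], ListenerProfile]  # (label, reversed) -> profile

    def profile_for(self, label: str, reversed: bool) -> ListenerProfile:
        try:
            return self.profiles[(label, reversed)]
        except KeyError:
            raise KeyError(
                f"listener {self.listener_id!r} has no profile for "
                f"({label!r}, reversed={reversed})"
            ) from None


@dataclass(frozen=True)
class ExperimentResult:
    """Tidy outputs of a simulated experiment."""

    trials: pd.DataFrame  # listener, condition, reversed, run, trial, snr_db, correct, is_reversal
    summary: pd.DataFrame  # listener, condition, reversed, srt_db, n_runs, n_discarded


def _stimulus_drawing_responder(
    corpus: Corpus,
    cond: MaskerCondition,
    profile: ListenerProfile,
    rng: np.random.Generator,
) -> Responder:
    """Responder that draws fresh word selections every trial.

    The simulated response depends on SNR through the psychometric
    function; the per-trial target and masker word draws reproduce the
    protocol's trial-to-trial stimulus variability and keep the word
    streams part of the seeded state.
    """

    def respond(snr_db: float) -> bool:
        tspec = draw_target_spec(corpus, rng)
        draw_masker_specs(corpus, tspec, cond.masker_talkers, rng, reversed=cond.reversed)
        return bool(rng.random() < p_both(snr_db, profile))

    return respond


def simulate_experiment(
    corpus: Corpus,
    conditions: Sequence[tuple[str, bool]],
    listeners: Sequence[Listener],
    params: StaircaseParams | None = None,
    rng: np.random.Generator | None = None,
    runs_per_condition: tuple[int, int] = (2, 3),
    max_attempts: int = 20,
) -> ExperimentResult:
    """Simulate the full experiment: listeners x conditions x reversal.

    Condition order is randomized per listener; two to three valid runs
    (drawn uniformly from ``runs_per_condition``) are collected per
    cell; fresh word selections are drawn for every trial.  Fully
    reproducible from the passed generator.
    """
    params = params or StaircaseParams()
    rng = rng if rng is not None else np.random.default_rng()
    for label, _ in conditions:
        if label not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {label!r}")

    trial_rows = []
    summary_rows = []
    for listener in listeners:
        order = [conditions[i] for i in rng.permutation(len(conditions))]
        for label, rev in order:
            profile = listener.profile_for(label, rev)
            n_runs = int(rng.integers(runs_per_condition[0], runs_per_condition[1] + 1))

            def factory(r: np.random.Generator, _label=label, _rev=rev, _p=profile):
                cond = condition(_label, corpus, reversed=_rev, rng=r)
                return _stimulus_drawing_responder(corpus, cond, _p, r)

            result = measure_srt(
                factory, params, n_runs, rng,
                max_attempts=max_attempts, condition_label=label, reversed=rev,
            )
            summary_rows.append(
                {
                    "listener": listener.listener_id,
                    "condition": label,
                    "reversed": rev,
                    "srt_db": result.srt_db,
                    "n_runs": len(result.run_srts_db),
                    "n_discarded": result.n_discarded,
                }
            )
            for run_idx, run in enumerate(result.runs, start=1):
                for t in run.trials:
                    trial_rows.append(
                        {
                            "listener": listener.listener_id,
                            "condition": label,
                            "reversed": rev,
                            "run": run_idx,
                            "trial": t.index,
                            "snr_db": t.snr_db,
                            "correct": t.correct,
                            "is_reversal": t.is_reversal,
                        }
                    )

    trials = pd.DataFrame(trial_rows)
    summary = pd.DataFrame(summary_rows).sort_values(
        ["listener", "condition", "reversed"], ignore_index=True
    )
    return ExperimentResult(trials=trials, summary=summary)
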