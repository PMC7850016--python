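"""Simulated listeners with logistic psychometric functions.

A listener's probability of reporting one keyword correctly at a given
SNR follows a logistic function with a guess floor (closed-set task
with 10 response alternatives per category) and an optional lapse rate.
The tracked event — both keywords correct — assumes keyword
independence, so its probability is the square of the per-keyword
probability and its chance floor is 0.01.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus
from .glimpse import GlimpseParams, mean_glimpse_snr_batch
from .stimulus import MaskerCondition

__all__ = [
    "ListenerProfile",
    "p_keyword",
    "p_both",
    "snr_at_p_both",
    "respond",
    "GlimpseCoupling",
    "glimpse_linked_profile",
    "save_profiles",
    "load_profiles",
]


@dataclass(frozen=True)
class ListenerProfile:
    """Psychometric parameters of one simulated listener in one condition.

    ``threshold_db`` is the midpoint of the per-keyword logistic;
    ``slope_db`` its spread (dB per logistic unit); ``guess`` and
    ``lapse`` are per-keyword floor and ceiling deficits.
    """

    threshold_db: float
    slope_db: float = 2.0
    guess: float = 0.1  # 10 response alternatives per category
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.guess < 1:
            raise ValueError(f"guess must be in [0, 1), got {self.guess}")
        if not 0 <= self.lapse < 1:
            raise ValueError(f"lapse must be in [0, 1), got {self.lapse}")
        if self.guess + self.lapse >= 1:
            raise ValueError("guess + lapse must be < 1")
        if self.slope_db <= 0:
            raise ValueError(f"slope_db must be positive, got {self.slope_db}")


def p_keyword(snr_db: float, profile: ListenerProfile) -> float:
    """Probability of one keyword correct at the given SNR."""
    z = (snr_db - profile.threshold_db) / profile.slope_db
    # numerically stable logistic for extreme z
    if z >= 0:
        sigma = 1.0 / (1.0 + math.exp(-z))
    else:
        e = math.exp(z)
        sigma = e / (1.0 + e)
    return profile.guess + (1.0 - profile.guess - profile.lapse) * sigma


def p_both(snr_db: float, profile: ListenerProfile) -> float:
    """Probability that both keywords are correct (independence model)."""
    return p_keyword(snr_db, profile) ** 2


def snr_at_p_both(profile: ListenerProfile, p: float) -> float:
    """The unique SNR at which P(both keywords correct) equals ``p``.

    Solved in closed form by inverting the squared logistic; this is
    the analytic ground truth an adaptive track at ``p`` should
    recover.
    """
    floor = profile.guess**2
    ceiling = (1.0 - profile.lapse) ** 2
    if not floor < p < ceiling:
        raise ValueError(
            f"p={p} outside attainable range ({floor}, {ceiling}) for this profile"
        )
    pk = math.sqrt(p)
    sigma = (pk - profile.guess) / (1.0 - profile.guess - profile.lapse)
    return profile.threshold_db + profile.slope_db * math.log(sigma / (1.0 - sigma))


def respond(snr_db: float, profile: ListenerProfile, rng: np.random.Generator) -> bool:
    """Bernoulli keyword-pair response at the given SNR."""
    return bool(rng.random() < p_both(snr_db, profile))


@dataclass(frozen=True)
class GlimpseCoupling:
    """Links a listener's threshold to a condition's glimpsing SNR.

    theta = baseline_db - gain * (mean glimpsing SNR at the reference
    mixing SNR, averaged over seeded trials).  An illustrative device
    for producing condition-dependent listeners; not fitted to human
    data.
    """

    baseline_db: float = -10.0
    gain: float = 1.0
    reference_snr_db: float = 0.0
    n_trials: int = 20


def glimpse_linked_profile(
    corpus: Corpus,
    cond: MaskerCondition,
    coupling: GlimpseCoupling,
    rng: np.random.Generator,
    params: GlimpseParams | None = None,
    slope_db: float = 2.0,
    guess: float = 0.1,
    lapse: float = 0.0,
) -> ListenerProfile:
    """Build a listener whose threshold tracks the condition's glimpsing SNR."""
    if coupling.gain == 0:
        theta = coupling.baseline_db
    else:
        g_snr = mean_glimpse_snr_batch(
            corpus, cond, coupling.reference_snr_db, coupling.n_trials, rng, params
        )
        theta = coupling.baseline_db - coupling.gain * g_snr
    return ListenerProfile(threshold_db=theta, slope_db=slope_db, guess=guess, lapse=lapse)


def save_profiles(profiles: dict[str, ListenerProfile], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: asdict(v) for k, v in profiles.items()}, indent=2)
    )


def load_profiles(path: str | Path) -> dict[str, ListenerProfile]:
    raw = json.loads(Path(path).read_text())
    return {k: ListenerProfile(**v) for k, v in raw.items()}
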