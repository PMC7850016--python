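"""Glimpsing analysis: sliding long-term RMS envelopes and glimpse SNR.

The target and the combined maskers are tracked separately with a
300-ms sliding RMS window hopped every 20 ms — the smoothing of a
volume-unit (VU) meter.  A frame is a "glimpse" when the target's
windowed RMS strictly exceeds the combined maskers'.  The mean
glimpsing SNR averages the framewise dB ratio over glimpsed frames and
is an index of energetic masking: higher values mean more of the target
is audible above the masker mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus
from .stimulus import MaskerCondition, SentenceAudio, build_trial

__all__ = [
    "GlimpseParams",
    "GlimpseProfile",
    "sliding_rms",
    "glimpse_profile",
    "mean_glimpse_snr_for_trial",
    "mean_glimpse_snr_batch",
]


@dataclass(frozen=True)
class GlimpseParams:
    """Sliding-window settings: 300-ms window, 20-ms hop by default."""

    window: float = 0.300  # seconds
    hop: float = 0.020  # seconds

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window:
            raise ValueError(f"need 0 < hop <= window, got hop={self.hop}, window={self.window}")

    def window_samples(self, sample_rate: int) -> int:
        return int(round(self.window * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop * sample_rate))


@dataclass(frozen=True)
class GlimpseProfile:
    """Framewise target/masker envelopes, glimpse mask and summary stats."""

    frame_times: np.ndarray  # seconds; window start times
    target_rms: np.ndarray
    masker_rms: np.ndarray
    glimpse_mask: np.ndarray  # boolean
    glimpse_proportion: float
    mean_glimpse_snr_db: float | None  # None when no frame is glimpsed

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def sliding_rms(wave: np.ndarray, sample_rate: int, params: GlimpseParams) -> np.ndarray:
    """Per-frame RMS over left-aligned full windows.

    Frame ``i`` covers samples ``[i*H, i*H + W)``; only full windows are
    used, giving ``floor((L - W) / H) + 1`` frames for a signal of
    length ``L``.
    """
    wave = np.asarray(wave, dtype=np.float64)
    W = params.window_samples(sample_rate)
    H = params.hop_samples(sample_rate)
    L = len(wave)
    if L < W:
        raise ValueError(f"signal length {L} shorter than one window ({W} samples)")
    n_frames = (L - W) // H + 1
    # Cumulative sum of squares gives each window's energy in O(L).
    csum = np.concatenate([[0.0], np.cumsum(wave**2)])
    starts = np.arange(n_frames) * H
    energies = csum[starts + W] - csum[starts]
    return np.sqrt(energies / W)


def glimpse_profile(
    target: SentenceAudio | np.ndarray,
    masker_sum: np.ndarray,
    params: GlimpseParams | None = None,
    sample_rate: int | None = None,
) -> GlimpseProfile:
    """Compute the glimpse profile of a target against summed maskers.

    ``mean_glimpse_snr_db`` is the mean over glimpsed frames of
    ``20*log10(target_rms / masker_rms)``, or ``None`` when no frame is
    glimpsed.  Ties are not glimpses: the target must strictly exceed
    the combined maskers.
    """
    params = params or GlimpseParams()
    if isinstance(target, SentenceAudio):
        sr = target.sample_rate
        twave = target.samples
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required when target is a bare waveform")
        sr = sample_rate
        twave = np.asarray(target, dtype=np.float64)
    mwave = np.asarray(masker_sum, dtype=np.float64)
    if len(mwave) != len(twave):
        raise ValueError(f"length mismatch: target {len(twave)}, masker {len(mwave)}")

    t_rms = sliding_rms(twave, sr, params)
    m_rms = sliding_rms(mwave, sr, params)
    mask = t_rms > m_rms
    proportion = float(np.mean(mask))
    if mask.any():
        with np.errstate(divide="ignore"):
            snr = 20.0 * np.log10(t_rms[mask] / m_rms[mask])
        mean_snr = float(np.mean(snr))
    else:
        mean_snr = None
    H = params.hop_samples(sr)
    frame_times = np.arange(len(t_rms)) * H / sr
    return GlimpseProfile(
        frame_times=frame_times,
        target_rms=t_rms,
        masker_rms=m_rms,
        glimpse_mask=mask,
        glimpse_proportion=proportion,
        mean_glimpse_snr_db=mean_snr,
    )


def mean_glimpse_snr_for_trial(
    corpus: Corpus,
    cond: MaskerCondition,
    snr_db: float,
    params: GlimpseParams | None = None,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Mean glimpsing SNR of one freshly drawn trial at the stated SNR."""
    rng = rng if rng is not None else np.random.default_rng()
    trial = build_trial(corpus, cond, snr_db, rng)
    profile = glimpse_profile(
        trial.target_component, trial.masker_component, params, trial.sample_rate
    )
    return profile.mean_glimpse_snr_db


def mean_glimpse_snr_batch(
    corpus: Corpus,
    cond: MaskerCondition,
    snr_db: float,
    n_trials: int,
    rng: np.random.Generator,
    params: GlimpseParams | None = None,
) -> float:
    """Average the mean glimpsing SNR over seeded trials (None excluded)."""
    values = []
    for _ in range(n_trials):
        v = mean_glimpse_snr_for_trial(corpus, cond, snr_db, params, rng)
        if v is not None:
            values.append(v)
    if not values:
        raise ValueError("no glimpsed frames in any trial")
    return float(np.mean(values))
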