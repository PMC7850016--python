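"""Synthetic matrix-sentence corpus.

Generates a deterministic, fully parametric stand-in for a sung/spoken
matrix corpus: 5 talkers x 5 word categories x 10 monosyllabic words.
Each word token is a harmonic complex at the talker's fundamental
frequency, shaped by word-specific resonance peaks and an asymmetric
amplitude envelope (fast attack, gradual decay) that mimics a stressed
natural monosyllable.  All tokens are normalized to one long-term RMS
amplitude, and every token is reproducible in isolation from a master
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "CATEGORIES",
    "TalkerSpec",
    "SynthParams",
    "WordToken",
    "Corpus",
    "CorpusConfig",
    "build_default_talkers",
    "stable_seed",
    "synthesize_word",
    "resynthesize",
    "build_corpus",
    "save_corpus",
    "load_corpus",
]

#: Fixed category order of the matrix sentence.
CATEGORIES: tuple[str, ...] = ("Name", "Verb", "Number", "Color", "Object")


@dataclass(frozen=True)
class TalkerSpec:
    """One talker: identity, sex, mean fundamental frequency and role."""

    talker_id: str
    sex: str  # "male" | "female"
    mean_f0: float  # Hz
    role: str  # "target" | "masker"

    def __post_init__(self) -> None:
        if self.mean_f0 <= 0:
            raise ValueError(f"mean_f0 must be positive, got {self.mean_f0}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.role not in ("target", "masker"):
            raise ValueError(f"unknown role {self.role!r}")


def build_default_talkers() -> list[TalkerSpec]:
    """The default five-talker panel.

    One male target (mean F0 106 Hz), two male maskers (97 and 128 Hz)
    and two female maskers (157 and 190 Hz).
    """
    return [
        TalkerSpec("T", "male", 106.0, "target"),
        TalkerSpec("M1", "male", 97.0, "masker"),
        TalkerSpec("M2", "male", 128.0, "masker"),
        TalkerSpec("F1", "female", 157.0, "masker"),
        TalkerSpec("F2", "female", 190.0, "masker"),
    ]


@dataclass(frozen=True)
class SynthParams:
    """Parameters that fully determine a token's waveform at any duration.

    Kept on the token so a word can be resynthesized at a new duration
    with its pitch parameters untouched (pitch-preserving time scaling
    by construction).
    """

    f0: float  # Hz, after per-word jitter
    harmonic_amps: tuple[float, ...]  # relative amplitude per harmonic
    harmonic_phases: tuple[float, ...]  # radians
    decay_end: float  # envelope amplitude at word end, relative to peak
    ramp_s: float  # raised-cosine attack/release duration, seconds


@dataclass(frozen=True)
class WordToken:
    """A synthesized (or loaded) monosyllabic word."""

    samples: np.ndarray
    sample_rate: int
    talker: TalkerSpec
    category: str
    word_index: int
    duration: float  # seconds
    rms: float  # linear amplitude, equals the corpus constant
    params: SynthParams | None = None  # None for externally loaded audio

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        self.samples.setflags(write=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CorpusConfig:
    """Tunable corpus-generation settings."""

    sample_rate: int = 22050
    rms_constant: float = 0.05  # linear full-scale; headroom for 1+4 voices
    duration_range: tuple[float, float] = (0.3, 0.5)  # seconds
    talker_duration_jitter: float = 0.10  # +/- fraction, per talker
    f0_jitter: float = 0.03  # +/- fraction, per word
    n_words: int = 10
    cue_word_index: int = 0
    max_harmonics: int = 20
    max_harmonic_hz: float = 5000.0
    n_resonances: int = 3
    decay_end_range: tuple[float, float] = (0.25, 0.40)
    ramp_s: float = 0.010

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("duration_range must be positive and ordered")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.rms_constant <= 0:
            raise ValueError("rms_constant must be positive")


@dataclass(frozen=True)
class Corpus:
    """The full token set: 5 talkers x 5 categories x n_words words."""

    talkers: tuple[TalkerSpec, ...]
    tokens: Mapping[tuple[str, str, int], WordToken]  # (talker_id, category, index)
    cue_word_index: int
    sample_rate: int
    rms_constant: float
    config: CorpusConfig = field(default=CorpusConfig())
    master_seed: int | None = None

    @property
    def target_talker(self) -> TalkerSpec:
        (t,) = [t for t in self.talkers if t.role == "target"]
        return t

    @property
    def masker_talkers(self) -> list[TalkerSpec]:
        return [t for t in self.talkers if t.role == "masker"]

    def token(self, talker: TalkerSpec | str, category: str, word_index: int) -> WordToken:
        tid = talker.talker_id if isinstance(talker, TalkerSpec) else talker
        try:
            return self.tokens[(tid, category, word_index)]
        except KeyError:
            raise KeyError(
                f"corpus integrity error: no token for talker={tid!r}, "
                f"category={category!r}, word_index={word_index}"
            ) from None


def stable_seed(*parts: object) -> int:
    """Derive a reproducible 31-bit seed from arbitrary hashable parts.

    Uses SHA-256 so the derivation is stable across processes and Python
    versions (unlike the built-in ``hash``).
    """
    msg = "\x1f".join(repr(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(msg).digest()[:4], "big") % (2**31)


def _synthesize(params: SynthParams, n_samples: int, sample_rate: int,
                rms_constant: float) -> np.ndarray:
    """Render a waveform of exactly ``n_samples`` from synthesis parameters."""
    t = np.arange(n_samples) / sample_rate
    wave = np.zeros(n_samples)
    for k, (a, phi) in enumerate(zip(params.harmonic_amps, params.harmonic_phases), start=1):
        wave += a * np.sin(2 * np.pi * k * params.f0 * t + phi)

    # Asymmetric envelope: raised-cosine attack, exponential decay toward
    # decay_end at the word's end, raised-cosine release.
    dur = n_samples / sample_rate
    env = np.exp(np.log(params.decay_end) * t / dur)
    n_ramp = min(int(round(params.ramp_s * sample_rate)), n_samples // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= ramp
        env[-n_ramp:] *= ramp[::-1]
    wave *= env

    rms = np.sqrt(np.mean(wave**2))
    if rms == 0:
        raise ValueError("degenerate synthesis: zero-energy waveform")
    return wave * (rms_constant / rms)


def _draw_params(talker: TalkerSpec, seed: int, config: CorpusConfig) -> SynthParams:
    rng = np.random.default_rng(seed)
    f0 = talker.mean_f0 * (1 + rng.uniform(-config.f0_jitter, config.f0_jitter))
    n_harm = min(config.max_harmonics, int(config.max_harmonic_hz // f0))
    n_harm = max(n_harm, 1)

    # Formant-like resonance peaks shaping the harmonic amplitudes, on a
    # 1/k spectral tilt typical of voiced speech.
    centers = rng.uniform(300.0, 3200.0, size=config.n_resonances)
    widths = rng.uniform(80.0, 400.0, size=config.n_resonances)
    gains = rng.uniform(0.5, 1.0, size=config.n_resonances)
    freqs = f0 * np.arange(1, n_harm + 1)
    shape = np.full(n_harm, 0.05)
    for c, w, g in zip(centers, widths, gains):
        shape += g * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    amps = shape / np.arange(1, n_harm + 1)

    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    decay_end = rng.uniform(*config.decay_end_range)
    return SynthParams(
        f0=f0,
        harmonic_amps=tuple(amps),
        harmonic_phases=tuple(phases),
        decay_end=decay_end,
        ramp_s=config.ramp_s,
    )


def synthesize_word(
    talker: TalkerSpec,
    category: str,
    word_index: int,
    duration: float,
    sample_rate: int,
    seed: int,
    config: CorpusConfig | None = None,
) -> WordToken:
    """Synthesize one word token; deterministic in all arguments.

    The token is a voiced harmonic complex at the talker's (jittered)
    fundamental, RMS-normalized to the corpus constant.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if not 0 <= word_index <= 9:
        raise ValueError(f"word_index must be in 0..9, got {word_index}")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    config = config or CorpusConfig(sample_rate=sample_rate)

    params = _draw_params(talker, seed, config)
    n = int(round(duration * sample_rate))
    samples = _synthesize(params, n, sample_rate, config.rms_constant)
    return WordToken(
        samples=samples,
        sample_rate=sample_rate,
        talker=talker,
        category=category,
        word_index=word_index,
        duration=duration,
        rms=config.rms_constant,
        params=params,
    )


def resynthesize(token: WordToken, n_samples: int) -> WordToken:
    """Re-render a parametric token at a new length, pitch unchanged.

    Raises ``ValueError`` for tokens without synthesis parameters
    (externally loaded audio cannot be time-scaled here).
    """
    if token.params is None:
        raise ValueError(
            "unsupported operation: token has no synthesis parameters; "
            "configure an external time-scaler for loaded audio"
        )
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    samples = _synthesize(token.params, n_samples, token.sample_rate, token.rms)
    return replace(
        token,
        samples=samples,
        duration=n_samples / token.sample_rate,
    )


def build_corpus(
    config: CorpusConfig | None = None,
    master_seed: int = 0,
    talkers: list[TalkerSpec] | None = None,
) -> Corpus:
    """Build the full deterministic corpus from a master seed.

    Word durations are drawn once per (category, word) and shared across
    talkers up to a seeded per-talker jitter, so the word slots of
    different talkers are of similar duration.  Per-token seeds are
    derived from the master seed so any single token can be regenerated
    in isolation.
    """
    config = config or CorpusConfig()
    talkers = talkers if talkers is not None else build_default_talkers()

    lo, hi = config.duration_range
    tokens: dict[tuple[str, str, int], WordToken] = {}
    for category in CATEGORIES:
        for idx in range(config.n_words):
            dur_rng = np.random.default_rng(stable_seed(master_seed, "dur", category, idx))
            base_dur = dur_rng.uniform(lo, hi)
            for talker in talkers:
                jit_rng = np.random.default_rng(
                    stable_seed(master_seed, "durjit", talker.talker_id, category, idx)
                )
                j = config.talker_duration_jitter
                dur = base_dur * (1 + jit_rng.uniform(-j, j))
                seed = stable_seed(master_seed, talker.talker_id, category, idx)
                tokens[(talker.talker_id, category, idx)] = synthesize_word(
                    talker, category, idx, dur, config.sample_rate, seed, config
                )

    return Corpus(
        talkers=tuple(talkers),
        tokens=tokens,
        cue_word_index=config.cue_word_index,
        sample_rate=config.sample_rate,
        rms_constant=config.rms_constant,
        config=config,
        master_seed=master_seed,
    )


def save_corpus(corpus: Corpus, directory: str | Path) -> None:
    """Export the corpus as ``<talker>/<category>_<index>.wav`` + manifest."""
    from .io import write_wav

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (tid, category, idx), token in sorted(corpus.tokens.items()):
        tdir = directory / tid
        tdir.mkdir(exist_ok=True)
        write_wav(tdir / f"{category}_{idx}.wav", token.samples, token.sample_rate)
    manifest = {
        "talkers": [
            {"talker_id": t.talker_id, "sex": t.sex, "mean_f0": t.mean_f0, "role": t.role}
            for t in corpus.talkers
        ],
        "cue_word_index": corpus.cue_word_index,
        "sample_rate": corpus.sample_rate,
        "rms_constant": corpus.rms_constant,
        "categories": list(CATEGORIES),
        "n_words": corpus.config.n_words,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_corpus(directory: str | Path) -> Corpus:
    """Load a corpus from a WAV directory + manifest (real or synthetic).

    Loaded tokens carry no synthesis parameters; duration matching of
    loaded audio requires an external time-scaler.
    """
    from .io import read_wav

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    talkers = [TalkerSpec(**t) for t in manifest["talkers"]]
    sr = manifest["sample_rate"]
    tokens: dict[tuple[str, str, int], WordToken] = {}
    for talker in talkers:
        for category in manifest["categories"]:
            for idx in range(manifest["n_words"]):
                samples, file_sr = read_wav(directory / talker.talker_id / f"{category}_{idx}.wav")
                if file_sr != sr:
                    raise ValueError(
                        f"sample-rate mismatch in {talker.talker_id}/{category}_{idx}.wav: "
                        f"{file_sr} != manifest {sr}"
                    )
                tokens[(talker.talker_id, category, idx)] = WordToken(
                    samples=samples,
                    sample_rate=sr,
                    talker=talker,
                    category=category,
                    word_index=idx,
                    duration=len(samples) / sr,
                    rms=float(np.sqrt(np.mean(samples**2))),
                    params=None,
                )
    config = CorpusConfig(
        sample_rate=sr,
        rms_constant=manifest["rms_constant"],
        n_words=manifest["n_words"],
        cue_word_index=manifest["cue_word_index"],
    )
    return Corpus(
        talkers=tuple(talkers),
        tokens=tokens,
        cue_word_index=manifest["cue_word_index"],
        sample_rate=sr,
        rms_constant=manifest["rms_constant"],
        config=config,
    )
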