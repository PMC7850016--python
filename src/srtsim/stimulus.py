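"""Sentence assembly and SNR-controlled trial mixing.

A target sentence concatenates one word from each of the five
categories, with the Name slot fixed to the cue word.  Masker sentences
draw words that collide neither with the target nor with each other
within any category.  Maskers may be per-word time-reversed, are
duration-matched to the target by pitch-preserving resynthesis, and the
mixture is scaled to a commanded long-term SNR and overall RMS level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .corpus import CATEGORIES, Corpus, TalkerSpec, WordToken, resynthesize

__all__ = [
    "CONDITION_LABELS",
    "SentenceSpec",
    "SentenceAudio",
    "MaskerCondition",
    "TrialStimulus",
    "draw_target_spec",
    "draw_masker_specs",
    "assemble_sentence",
    "match_duration",
    "mix_trial",
    "condition",
]

#: Valid target-masker condition labels. After the leading T (the male
#: target), S marks a same-sex (male) masker and D a different-sex
#: (female) masker.
CONDITION_LABELS: tuple[str, ...] = ("TD", "TS", "TDD", "TSS", "TSD", "TSSDD")


@dataclass(frozen=True)
class SentenceSpec:
    """Word selection for one sentence: one index per category, in order."""

    talker: TalkerSpec
    word_indices: tuple[int, ...]  # (Name, Verb, Number, Color, Object)
    reversed: bool = False

    def __post_init__(self) -> None:
        if len(self.word_indices) != len(CATEGORIES):
            raise ValueError(
                f"need {len(CATEGORIES)} word indices, got {len(self.word_indices)}"
            )


@dataclass(frozen=True)
class SentenceAudio:
    """Five concatenated word tokens with recorded word boundaries."""

    samples: np.ndarray
    sample_rate: int
    boundaries: tuple[tuple[int, int], ...]  # 0-based, half-open [start, end)
    spec: SentenceSpec
    tokens: tuple[WordToken, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        self.samples.setflags(write=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class MaskerCondition:
    """One target-masker configuration: label, masker voices, reversal."""

    label: str
    masker_talkers: tuple[TalkerSpec, ...]
    reversed: bool = False

    @property
    def n_maskers(self) -> int:
        return len(self.masker_talkers)


@dataclass(frozen=True)
class TrialStimulus:
    """A mixed trial: target plus scaled maskers at a stated SNR and level."""

    mixture: np.ndarray
    target: SentenceAudio
    maskers: tuple[SentenceAudio, ...]
    snr_db: float
    level_rms: float
    keywords: tuple[int, int]  # (Number index, Color index) of the target
    masker_scale: float  # applied to the summed maskers before mixing
    level_scale: float  # applied to the whole mixture afterwards

    @property
    def sample_rate(self) -> int:
        return self.target.sample_rate

    @property
    def target_component(self) -> np.ndarray:
        """The target's contribution to the final mixture."""
        return self.level_scale * self.target.samples

    @property
    def masker_component(self) -> np.ndarray:
        """The summed maskers' contribution to the final mixture."""
        msum = np.sum([m.samples for m in self.maskers], axis=0)
        return self.level_scale * self.masker_scale * msum


def draw_target_spec(corpus: Corpus, rng: np.random.Generator) -> SentenceSpec:
    """Draw a target sentence: cue Name, remaining categories uniform."""
    n = corpus.config.n_words
    indices = [corpus.cue_word_index]
    indices += [int(rng.integers(n)) for _ in CATEGORIES[1:]]
    return SentenceSpec(corpus.target_talker, tuple(indices), reversed=False)


def draw_masker_specs(
    corpus: Corpus,
    target_spec: SentenceSpec,
    masker_talkers: Sequence[TalkerSpec],
    rng: np.random.Generator,
    reversed: bool = False,
) -> list[SentenceSpec]:
    """Draw masker sentences with per-category word exclusion.

    In every category the masker indices are drawn sequentially without
    replacement from the words not used by the target nor by previously
    drawn maskers, so target and all maskers are pairwise distinct
    within each category.
    """
    n = corpus.config.n_words
    if len(masker_talkers) + 1 > n:
        raise ValueError("not enough words per category for exclusive selection")
    used: list[set[int]] = [{target_spec.word_indices[c]} for c in range(len(CATEGORIES))]
    specs = []
    for talker in masker_talkers:
        indices = []
        for c in range(len(CATEGORIES)):
            available = sorted(set(range(n)) - used[c])
            pick = int(available[rng.integers(len(available))])
            used[c].add(pick)
            indices.append(pick)
        specs.append(SentenceSpec(talker, tuple(indices), reversed=reversed))
    return specs


def assemble_sentence(corpus: Corpus, spec: SentenceSpec) -> SentenceAudio:
    """Concatenate the five word tokens in category order.

    If the spec is reversed, each word's samples are reversed in time
    individually before concatenation; the word order is unchanged.
    """
    tokens = tuple(
        corpus.token(spec.talker, category, idx)
        for category, idx in zip(CATEGORIES, spec.word_indices)
    )
    pieces = []
    boundaries = []
    pos = 0
    for token in tokens:
        samples = token.samples[::-1] if spec.reversed else token.samples
        pieces.append(samples)
        boundaries.append((pos, pos + len(samples)))
        pos += len(samples)
    return SentenceAudio(
        samples=np.concatenate(pieces),
        sample_rate=corpus.sample_rate,
        boundaries=tuple(boundaries),
        spec=spec,
        tokens=tokens,
    )


def match_duration(masker: SentenceAudio, target_duration: float) -> SentenceAudio:
    """Uniformly time-scale a masker sentence to the target duration.

    Every word is resynthesized with its duration scaled by the global
    ratio and its pitch parameters unchanged, so the operation is
    pitch-preserving by construction.  Word boundaries are rescaled by
    cumulative rounding so the output length equals
    ``round(target_duration * sample_rate)`` exactly.
    """
    if not masker.tokens or any(t.params is None for t in masker.tokens):
        raise ValueError(
            "unsupported operation: duration matching requires parametric "
            "tokens or a configured external time-scaler"
        )
    sr = masker.sample_rate
    ratio = target_duration / masker.total_duration
    if ratio == 1.0 and int(round(target_duration * sr)) == masker.n_samples:
        return masker

    durations = np.array([t.n_samples / sr for t in masker.tokens])
    ends = np.round(np.cumsum(durations * ratio) * sr).astype(int)
    starts = np.concatenate([[0], ends[:-1]])

    pieces = []
    new_tokens = []
    for token, s, e in zip(masker.tokens, starts, ends):
        new_tok = resynthesize(token, int(e - s))
        samples = new_tok.samples[::-1] if masker.spec.reversed else new_tok.samples
        pieces.append(samples)
        new_tokens.append(new_tok)
    return SentenceAudio(
        samples=np.concatenate(pieces),
        sample_rate=sr,
        boundaries=tuple(zip(starts.tolist(), ends.tolist())),
        spec=masker.spec,
        tokens=tuple(new_tokens),
    )


def mix_trial(
    target: SentenceAudio,
    maskers: Sequence[SentenceAudio],
    snr_db: float,
    level_rms: float,
) -> TrialStimulus:
    """Mix target and maskers at a commanded long-term SNR and level.

    The maskers are summed sample-wise; the sum is scaled so the
    target-to-summed-masker RMS ratio equals ``snr_db``; the whole
    mixture is then scaled to a long-term RMS of ``level_rms``.
    """
    if not maskers:
        raise ValueError("at least one masker required")
    for m in maskers:
        if m.n_samples != target.n_samples:
            raise ValueError(
                f"masker length {m.n_samples} != target length {target.n_samples}; "
                "duration-match maskers first"
            )
    msum = np.sum([m.samples for m in maskers], axis=0)
    msum_rms = float(np.sqrt(np.mean(msum**2)))
    if msum_rms == 0:
        raise ValueError("degenerate input: zero-energy masker sum")
    target_rms = target.rms
    masker_scale = target_rms / (msum_rms * 10 ** (snr_db / 20))
    mixture = target.samples + masker_scale * msum
    mix_rms = float(np.sqrt(np.mean(mixture**2)))
    level_scale = level_rms / mix_rms
    mixture = level_scale * mixture

    spec = target.spec
    keywords = (
        spec.word_indices[CATEGORIES.index("Number")],
        spec.word_indices[CATEGORIES.index("Color")],
    )
    return TrialStimulus(
        mixture=mixture,
        target=target,
        maskers=tuple(maskers),
        snr_db=snr_db,
        level_rms=level_rms,
        keywords=keywords,
        masker_scale=masker_scale,
        level_scale=level_scale,
    )


def condition(
    label: str,
    corpus: Corpus,
    reversed: bool = False,
    rng: np.random.Generator | None = None,
) -> MaskerCondition:
    """Resolve a condition label to concrete masker talkers.

    Two-masker-per-sex labels (TSS, TDD, TSSDD) use both available
    talkers of the required sex.  Single-slot labels (TS, TD, TSD) pick
    one of the two same-sex masker talkers uniformly — fixed for the
    lifetime of the returned condition, as within one test run.
    """
    if label not in CONDITION_LABELS:
        raise ValueError(f"unknown condition label {label!r}; valid: {CONDITION_LABELS}")
    males = [t for t in corpus.masker_talkers if t.sex == "male"]
    females = [t for t in corpus.masker_talkers if t.sex == "female"]

    def pick(pool: list[TalkerSpec]) -> TalkerSpec:
        if rng is None:
            return pool[0]
        return pool[int(rng.integers(len(pool)))]

    slots = label[1:]  # masker slots after the target T
    talkers: list[TalkerSpec] = []
    if slots == "S":
        talkers = [pick(males)]
    elif slots == "D":
        talkers = [pick(females)]
    elif slots == "SS":
        talkers = list(males)
    elif slots == "DD":
        talkers = list(females)
    elif slots == "SD":
        talkers = [pick(males), pick(females)]
    elif slots == "SSDD":
        talkers = list(males) + list(females)
    return MaskerCondition(label=label, masker_talkers=tuple(talkers), reversed=reversed)


def build_trial(
    corpus: Corpus,
    cond: MaskerCondition,
    snr_db: float,
    rng: np.random.Generator,
    level_rms: float | None = None,
) -> TrialStimulus:
    """Draw fresh word selections and render one complete mixed trial."""
    level = level_rms if level_rms is not None else corpus.rms_constant
    tspec = draw_target_spec(corpus, rng)
    mspecs = draw_masker_specs(corpus, tspec, cond.masker_talkers, rng, reversed=cond.reversed)
    target = assemble_sentence(corpus, tspec)
    maskers = [
        match_duration(assemble_sentence(corpus, spec), target.total_duration)
        for spec in mspecs
    ]
    return mix_trial(target, maskers, snr_db, level)
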