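"""Sentence assembly, word exclusion, duration matching, SNR mixing."""

import numpy as np
import pytest

from srtsim import (
    CATEGORIES,
    CONDITION_LABELS,
    assemble_sentence,
    build_trial,
    condition,
    draw_masker_specs,
    draw_target_spec,
    match_duration,
    mix_trial,
)
from srtsim.stimulus import SentenceSpec


def _measured_snr_db(trial):
    t = trial.target_component
    m = trial.masker_component
    return 20 * np.log10(np.sqrt(np.mean(t**2)) / np.sqrt(np.mean(m**2)))


class TestDrawSpecs:
    def test_target_name_is_cue_word(self, corpus, rng):
        for _ in range(50):
            spec = draw_target_spec(corpus, rng)
            assert spec.word_indices[0] == corpus.cue_word_index
            assert not spec.reversed

    def test_target_draw_uniformity(self, corpus):
        """Each Number index appears ~uniformly over many draws."""
        rng = np.random.default_rng(7)
        counts = np.zeros(10)
        n = 10_000
        num_pos = CATEGORIES.index("Number")
        for _ in range(n):
            counts[draw_target_spec(corpus, rng).word_indices[num_pos]] += 1
        sd = np.sqrt(n * 0.1 * 0.9)
        assert np.all(np.abs(counts - n / 10) < 4 * sd)

    def test_target_draw_deterministic(self, corpus):
        a = draw_target_spec(corpus, np.random.default_rng(5))
        b = draw_target_spec(corpus, np.random.default_rng(5))
        assert a.word_indices == b.word_indices

    @pytest.mark.parametrize("n_maskers", [1, 2, 4])
    def test_masker_exclusion_per_category(self, corpus, rng, n_maskers):
        """Target and all maskers use pairwise-distinct words per category."""
        talkers = corpus.masker_talkers[:n_maskers] if n_maskers < 4 else corpus.masker_talkers
        for _ in range(200):
            tspec = draw_target_spec(corpus, rng)
            mspecs = draw_masker_specs(corpus, tspec, talkers, rng)
            for c in range(len(CATEGORIES)):
                indices = [tspec.word_indices[c]] + [m.word_indices[c] for m in mspecs]
                assert len(set(indices)) == len(indices)

    def test_masker_name_never_cue_word(self, corpus, rng):
        for _ in range(200):
            tspec = draw_target_spec(corpus, rng)
            mspecs = draw_masker_specs(corpus, tspec, corpus.masker_talkers, rng)
            for m in mspecs:
                assert m.word_indices[0] != corpus.cue_word_index


class TestAssembleSentence:
    def test_boundaries_tile_waveform(self, corpus, rng):
        sent = assemble_sentence(corpus, draw_target_spec(corpus, rng))
        assert sent.boundaries[0][0] == 0
        assert sent.boundaries[-1][1] == sent.n_samples
        for (s0, e0), (s1, e1) in zip(sent.boundaries, sent.boundaries[1:]):
            assert e0 == s1

    def test_duration_is_sum_of_word_durations(self, corpus, rng):
        spec = draw_target_spec(corpus, rng)
        sent = assemble_sentence(corpus, spec)
        total = sum(
            corpus.token(spec.talker, c, i).n_samples
            for c, i in zip(CATEGORIES, spec.word_indices)
        )
        assert sent.n_samples == total

    def test_reversal_is_per_word_involution(self, corpus, rng):
        """Reversing each word twice restores the forward waveform exactly."""
        from dataclasses import replace

        spec = draw_target_spec(corpus, rng)
        fwd = assemble_sentence(corpus, spec)
        rev = assemble_sentence(corpus, replace(spec, reversed=True))
        assert not np.array_equal(fwd.samples, rev.samples)
        unrev = np.concatenate([rev.samples[s:e][::-1] for s, e in rev.boundaries])
        np.testing.assert_array_equal(fwd.samples, unrev)

    def test_reversal_preserves_rms_and_length(self, corpus, rng):
        from dataclasses import replace

        spec = draw_target_spec(corpus, rng)
        fwd = assemble_sentence(corpus, spec)
        rev = assemble_sentence(corpus, replace(spec, reversed=True))
        assert fwd.n_samples == rev.n_samples
        assert fwd.rms == pytest.approx(rev.rms, rel=1e-12)

    def test_missing_token_raises(self, corpus):
        spec = SentenceSpec(corpus.target_talker, (0, 1, 2, 3, 4))
        bad = SentenceSpec(corpus.target_talker.__class__("X", "male", 100.0, "masker"),
                           (0, 1, 2, 3, 4))
        assemble_sentence(corpus, spec)  # sanity: valid spec works
        with pytest.raises(KeyError, match="integrity"):
            assemble_sentence(corpus, bad)


class TestMatchDuration:
    def test_identity_ratio(self, corpus, rng):
        sent = assemble_sentence(corpus, draw_target_spec(corpus, rng))
        out = match_duration(sent, sent.total_duration)
        np.testing.assert_array_equal(out.samples, sent.samples)

    def test_output_length_exact(self, corpus, rng):
        tspec = draw_target_spec(corpus, rng)
        mspec = draw_masker_specs(corpus, tspec, corpus.masker_talkers[:1], rng)[0]
        target = assemble_sentence(corpus, tspec)
        masker = assemble_sentence(corpus, mspec)
        out = match_duration(masker, target.total_duration)
        assert out.n_samples == target.n_samples

    def test_pitch_preserved(self, corpus, rng):
        """Each word's dominant F0 is unchanged by duration matching."""
        tspec = draw_target_spec(corpus, rng)
        mspec = draw_masker_specs(corpus, tspec, corpus.masker_talkers[:1], rng)[0]
        target = assemble_sentence(corpus, tspec)
        masker = assemble_sentence(corpus, mspec)
        out = match_duration(masker, target.total_duration)
        sr = corpus.sample_rate

        def peak_f0(samples):
            spec = np.abs(np.fft.rfft(samples, n=8 * len(samples)))
            freqs = np.fft.rfftfreq(8 * len(samples), 1 / sr)
            lo = freqs > 50
            return freqs[lo][np.argmax(spec[lo])]

        for (s0, e0), (s1, e1) in zip(masker.boundaries, out.boundaries):
            f_before = peak_f0(masker.samples[s0:e0])
            f_after = peak_f0(out.samples[s1:e1])
            assert abs(f_after - f_before) / f_before < 0.01

    def test_reversed_masker_stays_reversed(self, corpus, rng):
        """Duration matching preserves per-word reversal (reversal first)."""
        tspec = draw_target_spec(corpus, rng)
        mspec = draw_masker_specs(corpus, tspec, corpus.masker_talkers[:1], rng,
                                  reversed=True)[0]
        target = assemble_sentence(corpus, tspec)
        masker = assemble_sentence(corpus, mspec)
        out = match_duration(masker, target.total_duration)
        assert out.spec.reversed
        # un-reversing each word must give the forward-assembled, matched sentence
        from dataclasses import replace

        fwd = assemble_sentence(corpus, replace(mspec, reversed=False))
        fwd_matched = match_duration(fwd, target.total_duration)
        unrev = np.concatenate([out.samples[s:e][::-1] for s, e in out.boundaries])
        np.testing.assert_array_equal(unrev, fwd_matched.samples)


class TestMixTrial:
    @pytest.mark.parametrize("snr_db", [-30.0, -10.0, 0.0, 10.0])
    @pytest.mark.parametrize("n_maskers", [1, 2, 4])
    def test_commanded_snr_is_measured_snr(self, corpus, rng, snr_db, n_maskers):
        talkers = corpus.masker_talkers[:n_maskers] if n_maskers < 4 else corpus.masker_talkers
        tspec = draw_target_spec(corpus, rng)
        mspecs = draw_masker_specs(corpus, tspec, talkers, rng)
        target = assemble_sentence(corpus, tspec)
        maskers = [match_duration(assemble_sentence(corpus, s), target.total_duration)
                   for s in mspecs]
        trial = mix_trial(target, maskers, snr_db, level_rms=0.05)
        assert _measured_snr_db(trial) == pytest.approx(snr_db, abs=0.01)

    def test_overall_level(self, corpus, rng):
        trial = build_trial(corpus, condition("TSD", corpus, rng=rng), 5.0, rng)
        mix_rms = np.sqrt(np.mean(trial.mixture**2))
        assert mix_rms == pytest.approx(trial.level_rms, rel=1e-4)

    def test_mixture_is_linear_combination(self, corpus, rng):
        trial = build_trial(corpus, condition("TDD", corpus, rng=rng), 0.0, rng)
        residual = trial.mixture - (trial.target_component + trial.masker_component)
        assert np.max(np.abs(residual)) < 1e-10

    def test_snr_zero_means_equal_rms(self, corpus, rng):
        trial = build_trial(corpus, condition("TD", corpus, rng=rng), 0.0, rng)
        t_rms = np.sqrt(np.mean(trial.target_component**2))
        m_rms = np.sqrt(np.mean(trial.masker_component**2))
        assert t_rms / m_rms == pytest.approx(1.0, rel=1e-9)

    def test_equal_masker_contribution(self, corpus, rng):
        """Before SNR scaling, each masker sentence has equal long-term RMS."""
        trial = build_trial(corpus, condition("TSSDD", corpus, rng=rng), 0.0, rng)
        rmss = [m.rms for m in trial.maskers]
        assert max(rmss) / min(rmss) - 1 < 1e-3

    def test_zero_energy_masker_rejected(self, corpus, rng):
        from dataclasses import replace

        tspec = draw_target_spec(corpus, rng)
        target = assemble_sentence(corpus, tspec)
        silent = replace(target, samples=np.zeros(target.n_samples))
        with pytest.raises(ValueError, match="degenerate"):
            mix_trial(target, [silent], 0.0, 0.05)


class TestCondition:
    @pytest.mark.parametrize(
        "label, n, sexes",
        [
            ("TD", 1, {"female": 1}),
            ("TS", 1, {"male": 1}),
            ("TDD", 2, {"female": 2}),
            ("TSS", 2, {"male": 2}),
            ("TSD", 2, {"male": 1, "female": 1}),
            ("TSSDD", 4, {"male": 2, "female": 2}),
        ],
    )
    def test_label_composition(self, corpus, rng, label, n, sexes):
        cond = condition(label, corpus, rng=rng)
        assert cond.n_maskers == n
        got = {}
        for t in cond.masker_talkers:
            got[t.sex] = got.get(t.sex, 0) + 1
        assert got == sexes
        assert all(t.role == "masker" for t in cond.masker_talkers)

    def test_two_masker_labels_use_both_talkers(self, corpus, rng):
        tss = condition("TSS", corpus, rng=rng)
        assert len({t.talker_id for t in tss.masker_talkers}) == 2
        tssdd = condition("TSSDD", corpus, rng=rng)
        assert len({t.talker_id for t in tssdd.masker_talkers}) == 4

    def test_unknown_label_rejected(self, corpus):
        with pytest.raises(ValueError, match="unknown condition"):
            condition("TDS", corpus)

    def test_single_slot_talker_varies_across_runs(self, corpus):
        rng = np.random.default_rng(3)
        ids = {condition("TS", corpus, rng=rng).masker_talkers[0].talker_id
               for _ in range(50)}
        assert len(ids) == 2


def test_word_exclusion_audit_all_conditions(corpus):
    """No within-category word collisions across many trials, any condition."""
    rng = np.random.default_rng(11)
    for label in CONDITION_LABELS:
        cond = condition(label, corpus, rng=rng)
        for _ in range(200):
            tspec = draw_target_spec(corpus, rng)
            mspecs = draw_masker_specs(corpus, tspec, cond.masker_talkers, rng)
            for c in range(len(CATEGORIES)):
                indices = [tspec.word_indices[c]] + [m.word_indices[c] for m in mspecs]
                assert len(set(indices)) == len(indices)
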