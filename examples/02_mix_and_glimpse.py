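"""Mix a speech-on-speech trial and run the glimpsing analysis.

A trial pairs a target sentence (Name fixed to the cue word) with
masker sentences whose words never collide with the target's within a
category.  The maskers are duration-matched to the target and the mix
is set to a commanded SNR.  The glimpsing analysis then asks: in how
many 300-ms frames does the target's RMS exceed the combined maskers',
and by how much?  Time-reversing the masker words leaves their spectra
and long-term level untouched but exposes more of the target.
"""

import numpy as np

from srtsim import build_corpus, build_trial, condition, glimpse_profile

corpus = build_corpus(master_seed=1)

for reversed_ in (False, True):
    rng = np.random.default_rng(7)  # same words for a paired comparison
    cond = condition("TSS", corpus, reversed=reversed_, rng=rng)
    trial = build_trial(corpus, cond, snr_db=0.0, rng=rng)

    t, m = trial.target_component, trial.masker_component
    measured = 20 * np.log10(np.sqrt(np.mean(t**2)) / np.sqrt(np.mean(m**2)))
    profile = glimpse_profile(t, m, sample_rate=trial.sample_rate)

    tag = "time-reversed" if reversed_ else "time-forward "
    print(f"TSS, {tag} maskers: commanded SNR 0.0 dB, measured {measured:+.4f} dB")
    print(f"  glimpse proportion {profile.glimpse_proportion:.3f}, "
          f"mean glimpsing SNR {profile.mean_glimpse_snr_db:+.2f} dB")

print("\nHigher mean glimpsing SNR with reversed maskers = less energetic")
print("masking: where the target rises above the masker mixture it does so by")
print("a larger margin, even though the long-term SNR is identical.")
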