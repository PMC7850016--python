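"""Measure an SRT adaptively from a simulated listener.

The 1-up/1-down staircase starts at +10 dB SNR, moves 4 dB until two
reversals have occurred and 2 dB after, runs 20 trials, and scores the
SRT as the mean SNR of the last six reversals.  It converges on the
SNR where the listener gets both keywords right half the time, which
is known in closed form for a logistic listener.
"""

import numpy as np

from srtsim import (
    ListenerProfile,
    StaircaseParams,
    measure_srt,
    p_both,
    snr_at_p_both,
)

profile = ListenerProfile(threshold_db=-12.0, slope_db=2.0, guess=0.1)
truth = snr_at_p_both(profile, 0.5)
print(f"simulated listener: per-keyword midpoint {profile.threshold_db} dB, "
      f"slope {profile.slope_db} dB, guess {profile.guess}")
print(f"analytic 50%-correct-both SNR: {truth:+.2f} dB\n")


def factory(rng):
    return lambda snr: bool(rng.random() < p_both(snr, profile))


result = measure_srt(factory, StaircaseParams(), n_runs=3,
                     rng=np.random.default_rng(11))
for i, run in enumerate(result.runs, 1):
    snrs = " ".join(f"{t.snr_db:+.0f}" for t in run.trials)
    print(f"run {i}: SNRs {snrs}")
    print(f"        {len(run.reversal_snrs_db)} reversals, SRT {run.srt_db:+.2f} dB")
print(f"\nSRT averaged over {len(result.run_srts_db)} valid runs: "
      f"{result.srt_db:+.2f} dB (truth {truth:+.2f} dB, "
      f"{result.n_discarded} discarded runs)")
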