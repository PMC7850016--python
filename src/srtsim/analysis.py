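"""Derived masking contrasts and SNR/TMR accounting.

Masking release (MR) due to masker intelligibility is the SRT
difference between time-forward and time-reversed maskers; MR due to
sex cues is the same-sex minus different-sex SRT; the multi-masker
penalty (MMP) is the SRT worsening when the number of maskers doubles.
SNR is measured against the summed maskers, TMR against each masker
individually, so each doubling of equal-level maskers adds exactly
10*log10(2) ~ 3.01 dB to the penalty under TMR accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContrastResult",
    "SEX_CUE_PAIRS",
    "MMP_PAIRS",
    "TALKER_GROUPS",
    "N_MASKERS",
    "mr_intelligibility",
    "mr_sex_cue",
    "multi_masker_penalty",
    "snr_to_tmr",
    "summarize",
]

#: (same-sex condition, different-sex condition) pairs for the sex-cue MR.
SEX_CUE_PAIRS: tuple[tuple[str, str], ...] = (("TS", "TD"), ("TSS", "TDD"), ("TSS", "TSD"))

#: (more-maskers condition, fewer-maskers condition) doubling pairs.
MMP_PAIRS: tuple[tuple[str, str], ...] = (("TDD", "TD"), ("TSS", "TS"), ("TSSDD", "TSD"))

#: Condition groupings by number of competing masker talkers.
TALKER_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("TS", "TD"),
    2: ("TDD", "TSD", "TSS"),
    4: ("TSSDD",),
}

#: Number of masker voices per condition label.
N_MASKERS: dict[str, int] = {
    "TD": 1, "TS": 1, "TDD": 2, "TSS": 2, "TSD": 2, "TSSDD": 4,
}


@dataclass(frozen=True)
class ContrastResult:
    """One oriented SRT difference between two conditions."""

    name: str
    value_db: float
    operands: tuple[tuple[str, float], tuple[str, float]]  # ((label, srt), (label, srt))


def mr_intelligibility(srt_forward_db: float, srt_reversed_db: float) -> float:
    """MR due to masker intelligibility: forward minus reversed SRT.

    Positive when time-reversing the maskers (removing their
    intelligibility) helps the listener.
    """
    return srt_forward_db - srt_reversed_db


def mr_sex_cue(srt_same_sex_db: float, srt_diff_sex_db: float) -> float:
    """MR due to target-masker sex differences: same-sex minus different-sex SRT."""
    return srt_same_sex_db - srt_diff_sex_db


def multi_masker_penalty(srt_more_db: float, srt_fewer_db: float) -> float:
    """Penalty for doubling the maskers: more-maskers minus fewer-maskers SRT."""
    return srt_more_db - srt_fewer_db


def snr_to_tmr(snr_db: float, n_maskers: int) -> float:
    """Convert SNR (vs summed maskers) to TMR (vs each masker).

    Summing n equal-RMS mutually incoherent maskers raises the combined
    power by a factor n, so TMR = SNR + 10*log10(n).
    """
    if n_maskers < 1:
        raise ValueError(f"n_maskers must be >= 1, got {n_maskers}")
    return snr_db + 10.0 * math.log10(n_maskers)


def _condition_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, reversed) mean SRT and SE across listeners."""
    rows = []
    for (label, rev), grp in summary.groupby(["condition", "reversed"]):
        srts = grp["srt_db"].to_numpy(dtype=float)
        rows.append(
            {
                "condition": label,
                "reversed": rev,
                "mean_srt_db": float(np.mean(srts)),
                "se_db": float(np.std(srts, ddof=1) / np.sqrt(len(srts)))
                if len(srts) > 1
                else float("nan"),
                "n_listeners": len(srts),
            }
        )
    return pd.DataFrame(rows).sort_values(["condition", "reversed"], ignore_index=True)


def summarize(summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate a per-listener SRT table into means and all contrasts.

    Input columns: listener, condition, reversed, srt_db.  Returns a
    dict with:

    - ``conditions``: per-(condition, reversed) mean SRT +/- SE;
    - ``groups``: mean SRT by number of masker talkers (1 = TS/TD mean,
      2 = TDD/TSD/TSS mean, 4 = TSSDD) per reversal state;
    - ``contrasts``: all MR and MMP families; MMP in both SNR and TMR
      accounting.

    With a single listener the SE is NaN, never fabricated.
    """
    required = {"listener", "condition", "reversed", "srt_db"}
    if not required <= set(summary.columns):
        raise ValueError(f"summary table must have columns {sorted(required)}")
    present = set(zip(summary["condition"], summary["reversed"]))
    expected = {(c, r) for c in N_MASKERS for r in (False, True)}
    missing = expected - present
    if missing:
        raise ValueError(f"incomplete design: missing condition cells {sorted(missing)}")

    cond_means = _condition_means(summary)
    mean_of = {
        (row.condition, row.reversed): row.mean_srt_db for row in cond_means.itertuples()
    }

    group_rows = []
    for n_talkers, labels in TALKER_GROUPS.items():
        for rev in (False, True):
            group_rows.append(
                {
                    "n_talkers": n_talkers,
                    "reversed": rev,
                    "mean_srt_db": float(np.mean([mean_of[(l, rev)] for l in labels])),
                }
            )
    groups = pd.DataFrame(group_rows)

    contrast_rows = []

    def add(name, family, a_label, a_srt, b_label, b_srt, value):
        contrast_rows.append(
            {
                "name": name,
                "family": family,
                "first": a_label,
                "first_srt_db": a_srt,
                "second": b_label,
                "second_srt_db": b_srt,
                "value_db": value,
            }
        )

    for label in N_MASKERS:
        fwd, rev = mean_of[(label, False)], mean_of[(label, True)]
        add(
            f"MR_intelligibility_{label}", "mr_intelligibility",
            f"{label}|forward", fwd, f"{label}|reversed", rev,
            mr_intelligibility(fwd, rev),
        )
    for rev in (False, True):
        tag = "reversed" if rev else "forward"
        for same, diff in SEX_CUE_PAIRS:
            s, d = mean_of[(same, rev)], mean_of[(diff, rev)]
            add(
                f"MR_sexcue_{same}_vs_{diff}_{tag}", "mr_sex_cue",
                same, s, diff, d, mr_sex_cue(s, d),
            )
        for more, fewer in MMP_PAIRS:
            m, f = mean_of[(more, rev)], mean_of[(fewer, rev)]
            mmp_snr = multi_masker_penalty(m, f)
            add(
                f"MMP_{more}_vs_{fewer}_{tag}", "mmp_snr",
                more, m, fewer, f, mmp_snr,
            )
            # TMR accounting: each SRT re-expressed relative to a single
            # masker before differencing.
            mmp_tmr = multi_masker_penalty(
                snr_to_tmr(m, N_MASKERS[more]), snr_to_tmr(f, N_MASKERS[fewer])
            )
            add(
                f"MMP_TMR_{more}_vs_{fewer}_{tag}", "mmp_tmr",
                more, m, fewer, f, mmp_tmr,
            )

    contrasts = pd.DataFrame(contrast_rows)
    return {"conditions": cond_means, "groups": groups, "contrasts": contrasts}
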