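"""VLP-fraction enrichment of scaffolds from short-read count tables.

For each scaffold the relative abundance in a VLP fraction is compared
with its abundance in the total-community DNA of the same donor via the
ratio r = a_vlp / a_total. Across the scaffolds of one donor x fraction
the ratios are standardised to Z-scores and scaffolds more than two
standard deviations above the mean are flagged as VLP-overrepresented.
A one-sample Kolmogorov-Smirnov test against a moment-fitted normal is
provided as a diagnostic for the normality assumption behind the Z cut
(with the usual caveat that fitting the moments makes the asymptotic
p-value approximate, as in the Lilliefors setting).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["relative_abundance", "enrichment_z", "ks_normality"]


def relative_abundance(counts, total_reads: int):
    """Per-scaffold read count divided by the sample's total read count."""
    counts = np.asarray(counts, dtype=float)
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if counts.sum() > total_reads:
        raise ValueError("scaffold counts exceed total_reads")
    return counts / float(total_reads)


def enrichment_z(
    vlp_counts,
    total_counts,
    vlp_total_reads: int,
    total_total_reads: int,
    scaffold_ids=None,
    *,
    pseudocount: float = 0.5,
    log_ratio: bool = False,
) -> pd.DataFrame:
    """Per-scaffold VLP/total abundance ratios, Z-scores and +2 SD flags.

    Zero counts receive ``pseudocount`` reads so every ratio is finite.
    With ``log_ratio`` the Z-scores are computed on log10 ratios instead
    of raw ratios (diagnostic switch; the default follows the raw-ratio
    convention). Returns columns
    ``scaffold_id, a_vlp, a_total, ratio, z, flagged``.
    """
    vlp = np.asarray(vlp_counts, dtype=float)
    tot = np.asarray(total_counts, dtype=float)
    if vlp.shape != tot.shape:
        raise ValueError("count vectors differ in length")
    if np.count_nonzero(tot) < 3:
        raise ValueError("need >= 3 scaffolds with nonzero total-community counts")
    if scaffold_ids is None:
        scaffold_ids = [f"s{i}" for i in range(vlp.size)]

    vlp_p = np.where(vlp == 0, pseudocount, vlp)
    tot_p = np.where(tot == 0, pseudocount, tot)
    a_vlp = vlp_p / float(vlp_total_reads)
    a_total = tot_p / float(total_total_reads)
    ratio = a_vlp / a_total
    x = np.log10(ratio) if log_ratio else ratio
    sd = x.std(ddof=1)
    z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    return pd.DataFrame(
        {
            "scaffold_id": scaffold_ids,
            "a_vlp": vlp / float(vlp_total_reads),
            "a_total": tot / float(total_total_reads),
            "ratio": ratio,
            "z": z,
            "flagged": z > 2.0,
        }
    )


def ks_normality(ratios):
    """One-sample KS test of the ratios against a moment-fitted normal.

    Returns ``(D, p)`` with the asymptotic p-value. Requires n >= 8 and a
    non-degenerate sample.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 8:
        raise ValueError("ks_normality requires n >= 8")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) ratios")
    res = stats.kstest(r, "norm", args=(r.mean(), sd), mode="asymp")
    return float(res.statistic), float(res.pvalue)
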