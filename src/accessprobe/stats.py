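"""Chaperone-dependency classification and enrichment statistics.

An sRNA is called Hfq-dependent when any of its probed regions shows a
significant paired difference in normalized accessibility between the
wild-type and hfq-null strains (two-tailed paired t-test, replicate-paired,
strict p < alpha).  The extremes-enrichment comparison uses the N−1 χ² test
(Pearson χ² scaled by (N−1)/N) on the 2×2 table of extreme / non-extreme
accessibility counts in two region groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegionComparison",
    "paired_t_test",
    "compare_regions",
    "classify_hfq",
    "n1_chi2_extremes",
    "diff_skew",
    "benjamini_hochberg",
]


@dataclass
class RegionComparison:
    """Paired accessibility comparison of one region between two strains."""

    region: str
    t: float
    dof: int
    p: float
    difference: float  # mean(A) - mean(B)
    degenerate: bool = False


def paired_t_test(a, b) -> tuple[float, int, float]:
    """Two-tailed paired t-test on replicate vectors a and b.

    Degenerate cases are defined rather than erroring: zero-variance
    differences give (0, dof, 1) when the mean difference is zero and
    (inf-signed t, dof, 0) when it is not.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = a - b
    dof = n - 1
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, dof, 1.0
        return math.copysign(math.inf, mean), dof, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), dof, float(p)


def compare_regions(a: pd.DataFrame, b: pd.DataFrame) -> list[RegionComparison]:
    """Per-region paired tests between two strains' accessibility tables.

    Each table has columns ``region``, ``replicate``, ``raw`` (normalized
    per-replicate accessibility); replicates are paired by label.  Regions
    with fewer than 2 shared replicates are skipped.
    """
    out = []
    for region in sorted(set(a["region"]) & set(b["region"])):
        xa = a[a["region"] == region].set_index("replicate")["raw"]
        xb = b[b["region"] == region].set_index("replicate")["raw"]
        shared = sorted(set(xa.index) & set(xb.index))
        va = xa.loc[shared].to_numpy(dtype=float)
        vb = xb.loc[shared].to_numpy(dtype=float)
        keep = ~(np.isnan(va) | np.isnan(vb))
        va, vb = va[keep], vb[keep]
        if va.size < 2:
            continue
        t, dof, p = paired_t_test(va, vb)
        sd = (va - vb).std(ddof=1)
        out.append(RegionComparison(
            region=region, t=t, dof=dof, p=p,
            difference=float(va.mean() - vb.mean()),
            degenerate=(sd == 0),
        ))
    return out


def classify_hfq(comparisons: list[RegionComparison], alpha: float = 0.05) -> str | None:
    """'dependent' iff any region's p < alpha (strict); None if untestable."""
    if not comparisons:
        return None
    return "dependent" if any(c.p < alpha for c in comparisons) else "independent"


def n1_chi2_extremes(group1, group2, lo: float = 0.125, hi: float = 0.875):
    """N−1 χ² test for enrichment of accessibility extremes.

    A value is extreme iff it is < lo or > hi (strict).  Builds the 2×2
    extreme/non-extreme table for the two groups and returns
    ``(chi2_n1, p, (prop1, prop2))`` with
    ``chi2_n1 = Pearson chi2 * (N-1)/N`` and p from χ²(1).
    An empty margin (e.g. no extremes anywhere) leaves the statistic
    undefined: returns (nan, nan, props).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    e1 = int(np.sum((g1 < lo) | (g1 > hi)))
    e2 = int(np.sum((g2 < lo) | (g2 > hi)))
    table = np.array([[e1, g1.size - e1], [e2, g2.size - e2]], dtype=float)
    props = (e1 / g1.size, e2 / g2.size)
    N = table.sum()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan, props
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / N
    pearson = float(((table - expected) ** 2 / expected).sum())
    chi2_n1 = pearson * (N - 1) / N
    p = float(sps.chi2.sf(chi2_n1, df=1))
    return chi2_n1, p, props


def diff_skew(comparisons: list[RegionComparison], alpha: float | None = None) -> dict:
    """Descriptive summary of accessibility differences (strain A − strain B).

    Pass alpha to restrict to significant comparisons first.
    """
    if alpha is not None:
        comparisons = [c for c in comparisons if c.p < alpha]
    diffs = np.array([c.difference for c in comparisons], dtype=float)
    if diffs.size == 0:
        return {"n": 0, "mean": math.nan, "median": math.nan, "share_positive": math.nan}
    return {
        "n": int(diffs.size),
        "mean": float(diffs.mean()),
        "median": float(np.median(diffs)),
        "share_positive": float(np.mean(diffs > 0)),
    }


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; the default workflow reports raw p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
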