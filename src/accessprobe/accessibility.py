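"""Relative accessibility from transcript-length histograms.

A probe's transcript-length distribution summarizes how often hybridization
anti-terminated transcription.  The pipeline is:

1. weighted-average transcript length per probe (replicate, strain);
2. subtract a baseline — the minimum reporter transcript size — flooring
   negatives at zero;
3. *overexpression mode*: accessibility = adjusted induced / adjusted
   uninduced weighted average (one construct, two induction states);
   *native mode*: per-molecule, per-replicate min-max normalization of the
   adjusted lengths to a raw accessibility in [0, 1];
4. reported accessibility = replicate mean, min-max renormalized within the
   molecule; standard errors of the raw replicates are propagated through
   the second normalization as a linear map (divided by the mean range).

Baselines default to 85 nt (overexpression) and 164 nt (native); ``auto``
uses the minimum observed weighted-average length in the run.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "weighted_average_length",
    "overexpression_accessibility",
    "native_raw_accessibility",
    "reported_accessibility",
    "native_accessibility_table",
    "OVEREXPRESSION_BASELINE",
    "NATIVE_BASELINE",
]

logger = logging.getLogger(__name__)

OVEREXPRESSION_BASELINE = 85.0  # nt, minimum overexpression-reporter transcript
NATIVE_BASELINE = 164.0  # nt, native-mode adjustment


def weighted_average_length(hist: dict) -> float:
    """Count-weighted mean transcript length of one histogram entry.

    Returns NaN (logged) for an empty histogram rather than 0 — a probe with
    no reads is missing, not short.
    """
    total = sum(hist.values())
    if total <= 0:
        logger.warning("empty length histogram: weighted average undefined")
        return math.nan
    return sum(length * count for length, count in hist.items()) / total


def _adjust(wa: float, baseline: float) -> float:
    return max(0.0, wa - baseline)


def overexpression_accessibility(
    wa_induced: float, wa_uninduced: float, baseline: float = OVEREXPRESSION_BASELINE
) -> float:
    """Induced / uninduced ratio of baseline-adjusted weighted lengths.

    Adjusted values are floored at 0; a non-positive denominator yields NaN
    (logged).
    """
    if math.isnan(wa_induced) or math.isnan(wa_uninduced):
        return math.nan
    num = _adjust(wa_induced, baseline)
    den = _adjust(wa_uninduced, baseline)
    if den <= 0:
        logger.warning("uninduced weighted average at or below baseline; ratio undefined")
        return math.nan
    return num / den


def native_raw_accessibility(adjusted: pd.Series | np.ndarray | dict, baseline_applied: bool = True):
    """Min-max normalize adjusted lengths within one molecule/replicate group.

    A degenerate group (max == min, e.g. a single region) maps everything to
    0.5 with a warning.  NaNs pass through.
    """
    if isinstance(adjusted, dict):
        keys = list(adjusted)
        vals = np.array([adjusted[k] for k in keys], dtype=float)
    else:
        keys = None
        vals = np.asarray(adjusted, dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        out = vals
    else:
        lo, hi = finite.min(), finite.max()
        if hi == lo:
            warnings.warn("degenerate accessibility group (max == min); values set to 0.5",
                          stacklevel=2)
            out = np.where(np.isnan(vals), np.nan, 0.5)
        else:
            out = (vals - lo) / (hi - lo)
    if keys is not None:
        return dict(zip(keys, out))
    return out


def reported_accessibility(raw: pd.DataFrame):
    """Replicate means, second normalization, and propagated SEs.

    ``raw`` has one row per (region, replicate) with columns ``region`` and
    ``raw``.  Returns a DataFrame indexed by region with columns
    ``mean_raw``, ``reported``, ``se``, ``n``.  The SE is the sample SE of
    the raw replicates scaled by 1 / (max mean - min mean), treating the
    normalization anchors as constants.
    """
    grouped = raw.groupby("region")["raw"]
    means = grouped.mean()
    n = grouped.count()
    sd = grouped.std(ddof=1)
    se = sd / np.sqrt(n)
    span = means.max() - means.min()
    if span == 0 or np.isnan(span):
        warnings.warn("degenerate second normalization (all region means equal)", stacklevel=2)
        reported = pd.Series(0.5, index=means.index)
        se_scaled = se * np.nan
    else:
        reported = (means - means.min()) / span
        se_scaled = se / span
    return pd.DataFrame(
        {"mean_raw": means, "reported": reported, "se": se_scaled, "n": n}
    )


def native_accessibility_table(
    hists_by_key: dict,
    region_to_ta: dict,
    baseline: float | str = NATIVE_BASELINE,
) -> pd.DataFrame:
    """Full native-mode pipeline over many probes, replicates and strains.

    Parameters
    ----------
    hists_by_key:
        ``{(region_id, strain, replicate): {length: count}}``.
    region_to_ta:
        region id -> molecule (sRNA) id; normalization groups are
        (molecule, strain, replicate).
    baseline:
        nt, or ``"auto"`` for the minimum observed weighted-average length
        across the run.

    Returns a tidy table with columns ta, region, strain, replicate, wa,
    adjusted, raw, reported, se.
    """
    rows = []
    for (region, strain, rep), hist in hists_by_key.items():
        wa = weighted_average_length(hist)
        rows.append({"ta": region_to_ta[region], "region": region,
                     "strain": strain, "replicate": rep, "wa": wa})
    df = pd.DataFrame(rows)
    if baseline == "auto":
        baseline = float(np.nanmin(df["wa"].values))
    df["adjusted"] = np.maximum(0.0, df["wa"] - float(baseline))

    df["raw"] = np.nan
    for _, idx in df.groupby(["ta", "strain", "replicate"]).groups.items():
        vals = df.loc[idx, "adjusted"].to_numpy()
        if np.isfinite(vals).sum() < 2:
            warnings.warn("accessibility group with < 2 regions; degenerate normalization",
                          stacklevel=2)
        df.loc[idx, "raw"] = native_raw_accessibility(vals)

    df["reported"] = np.nan
    df["se"] = np.nan
    for (_ta, _strain), idx in df.groupby(["ta", "strain"]).groups.items():
        sub = df.loc[idx, ["region", "raw"]]
        rep = reported_accessibility(sub)
        df.loc[idx, "reported"] = rep.loc[df.loc[idx, "region"], "reported"].to_numpy()
        df.loc[idx, "se"] = rep.loc[df.loc[idx, "region"], "se"].to_numpy()
    return df
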