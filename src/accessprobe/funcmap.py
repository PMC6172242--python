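"""Functional-region calling and prediction filtering.

Mapped sRNA:mRNA binding sites cluster at extreme (very high or very low)
accessibility and sit toward the sRNA's 5' or 3' ends.  This module turns
those two signatures into a caller for likely functional regions, uses the
called regions to filter externally computed sRNA:mRNA interaction
predictions (keep a prediction iff its sRNA interval overlaps a called
region by >= 5 nt), and categorizes / tallies in vitro validation outcomes.

The YUNR (pyrimidine-U-N-purine) tetramer, characteristic of antisense
RNA:RNA recognition loops, breaks ties when window accessibilities cluster
mid-scale.  Its match p-value comes from exact enumeration: 16 of the 256
4-mers match, so a perfect match has p = 1/16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FunctionalRegion",
    "PredictionRecord",
    "yunr_scan",
    "YUNR_MATCH_P",
    "select_functional_regions",
    "interface_informed_filter",
    "read_prediction_csv",
    "categorize_and_ppv",
    "tally_validation",
]

YUNR_MATCH_P = 1.0 / 16.0  # 16/256 4-mers match [CU] U [ACGU] [AG]

_POSITIVE_BINDING = {"yes", "weak"}


@dataclass(frozen=True)
class FunctionalRegion:
    """A called likely-functional region on an sRNA."""

    region_id: str
    start: int
    end: int
    accessibility: float
    flags: frozenset = field(default_factory=frozenset)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class PredictionRecord:
    """One ranked computational sRNA:mRNA interaction prediction.

    mRNA coordinates are relative to the start codon (+1 = first codon
    nucleotide; negative values are 5'-UTR).
    """

    srna_id: str
    mrna_id: str
    rank: int
    energy: float
    srna_start: int
    srna_end: int
    mrna_start: int
    mrna_end: int


def yunr_scan(seq: str):
    """All YUNR motif matches in an RNA sequence.

    Returns ``(matches, sequence_p)``: 1-based match start positions and the
    probability of >= 1 match in a random sequence of the same length under
    a uniform background, ``1 - (1 - 1/16)**m`` over the m scanned
    positions.  Sequences shorter than 4 nt have no matches.
    """
    s = seq.upper().replace("T", "U")
    matches = []
    m = max(0, len(s) - 3)
    for i in range(m):
        w = s[i : i + 4]
        if w[0] in "CU" and w[1] == "U" and w[3] in "AG":
            matches.append(i + 1)
    seq_p = 1.0 - (1.0 - YUNR_MATCH_P) ** m if m else math.nan
    return matches, seq_p


def select_functional_regions(
    profile: pd.DataFrame,
    L: int,
    window_frac: float = 0.2,
    hi: float = 0.75,
    lo: float = 0.25,
    max_n: int = 3,
    extended_frac: float = 0.4,
    yunr_alpha: float = YUNR_MATCH_P,
) -> list[FunctionalRegion]:
    """Call up to ``max_n`` likely functional regions from an accessibility profile.

    ``profile`` has columns region, start, end, accessibility (and sequence,
    needed only on the tie-break path).  A candidate must start or end
    within the 5' window [1, window_frac*L] or the 3' window
    [(1-window_frac)*L, L] and be extreme (accessibility > hi or < lo).
    When no 3'-window candidate qualifies, the 5' search widens to
    ``extended_frac``.  If every window candidate clusters mid-scale
    (none outside [lo, hi]), the tie-break picks the 5'-most extreme region
    in the 5' half that contains a YUNR motif with match p <= yunr_alpha.
    """
    if profile.empty:
        raise ValueError("empty accessibility profile")
    five_end = int(window_frac * L)
    three_start = L - int(window_frac * L) + 1

    def in_window(row, lo_bound, hi_bound):
        return (lo_bound <= row.start <= hi_bound) or (lo_bound <= row.end <= hi_bound)

    def extreme(acc):
        return acc > hi or acc < lo

    rows = list(profile.itertuples())
    cand = []
    three_prime_hits = False
    for r in rows:
        w5 = in_window(r, 1, five_end)
        w3 = in_window(r, three_start, L)
        if not (w5 or w3):
            continue
        if not extreme(r.accessibility):
            continue
        if w3:
            three_prime_hits = True
        flags = set()
        flags.add("extreme_high" if r.accessibility > hi else "extreme_low")
        if w5:
            flags.add("window_5prime")
        if w3:
            flags.add("window_3prime")
        cand.append((r, flags))

    if not three_prime_hits and extended_frac > window_frac:
        ext_end = int(extended_frac * L)
        chosen = {r.region for r, _ in cand}
        for r in rows:
            if r.region in chosen or not in_window(r, 1, ext_end):
                continue
            if extreme(r.accessibility):
                cand.append((r, {"extreme_high" if r.accessibility > hi else "extreme_low",
                                 "window_5prime"}))

    if cand:
        cand.sort(key=lambda item: (-abs(item[0].accessibility - 0.5), item[0].start))
        return [
            FunctionalRegion(str(r.region), int(r.start), int(r.end),
                             float(r.accessibility), frozenset(flags))
            for r, flags in cand[:max_n]
        ]

    # Mid-accessibility clustering: no extreme window candidate. Tie-break on
    # the YUNR motif among extreme regions in the 5' half.
    half = [r for r in rows if r.start <= L / 2 and extreme(r.accessibility)]
    half.sort(key=lambda r: r.start)
    for r in half:
        seq = getattr(r, "sequence", None)
        if seq is None:
            raise ValueError("YUNR tie-break requires a 'sequence' column in the profile")
        matches, _ = yunr_scan(str(seq))
        if matches and YUNR_MATCH_P <= yunr_alpha:
            flags = frozenset({"yunr_tiebreak",
                               "extreme_high" if r.accessibility > hi else "extreme_low"})
            return [FunctionalRegion(str(r.region), int(r.start), int(r.end),
                                     float(r.accessibility), flags)]
    return []


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def interface_informed_filter(
    preds: list[PredictionRecord],
    regions: list[FunctionalRegion],
    min_overlap: int = 5,
) -> list[PredictionRecord]:
    """Predictions whose sRNA interval overlaps any called region by >= min_overlap nt."""
    return [
        p for p in preds
        if any(_overlap((p.srna_start, p.srna_end), r.interval) >= min_overlap for r in regions)
    ]


_COLUMN_ALIASES = {
    "srna_id": ("srna_id", "id2", "query", "srna"),
    "mrna_id": ("mrna_id", "id1", "target", "mrna"),
    "rank": ("rank",),
    "energy": ("energy", "e", "mfe"),
    "srna_start": ("srna_start", "start2", "qstart"),
    "srna_end": ("srna_end", "end2", "qend"),
    "mrna_start": ("mrna_start", "start1", "tstart"),
    "mrna_end": ("mrna_end", "end1", "tend"),
}


def read_prediction_csv(path, sep: str = None) -> list[PredictionRecord]:
    """Load a ranked interaction-prediction table (header aliases accepted).

    Recognizes both this package's column names and common prediction-tool
    exports (id1/start1/end1 for the target mRNA, id2/start2/end2 for the
    query sRNA, E for energy); separator is sniffed between ',' and ';'.
    """
    df = pd.read_csv(path, sep=sep, engine="python") if sep else pd.read_csv(
        path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            if key == "rank":
                continue  # rank may be implicit (row order)
            raise ValueError(f"prediction table missing column for {key!r} "
                             f"(accepted: {aliases})")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        rank = int(d[resolved["rank"]]) if "rank" in resolved else i
        out.append(PredictionRecord(
            srna_id=str(d[resolved["srna_id"]]), mrna_id=str(d[resolved["mrna_id"]]),
            rank=rank, energy=float(d[resolved["energy"]]),
            srna_start=int(d[resolved["srna_start"]]), srna_end=int(d[resolved["srna_end"]]),
            mrna_start=int(d[resolved["mrna_start"]]), mrna_end=int(d[resolved["mrna_end"]]),
        ))
    return out


def categorize_and_ppv(
    preds: list[PredictionRecord],
    informed: list[PredictionRecord],
    outcomes: dict[str, str],
    top_n: int = 5,
):
    """Categorize tested candidates and compute per-category PPV.

    ``outcomes`` maps tested mRNA id -> binding call in {yes, weak, no};
    weak counts as positive.  Categories: ``Both`` (informed and rank <=
    top_n), ``INTERFACE`` (informed only), ``Top-ranked`` (rank <= top_n
    only).  Returns ``(rows, ppv)`` where rows is a DataFrame (mrna, rank,
    category, binding) and ppv maps each category (plus the
    ``interface_informed`` and ``top_ranked`` unions) to confirmed/tested.
    """
    by_mrna = {p.mrna_id: p for p in preds}
    unknown = set(outcomes) - set(by_mrna)
    if unknown:
        raise ValueError(f"outcomes supplied for unknown mRNAs: {sorted(unknown)}")
    informed_ids = {p.mrna_id for p in informed}
    rows = []
    for mrna, binding in outcomes.items():
        if binding not in _POSITIVE_BINDING | {"no"}:
            raise ValueError(f"binding call must be yes/weak/no, got {binding!r}")
        p = by_mrna[mrna]
        is_informed = mrna in informed_ids
        is_top = p.rank <= top_n
        if is_informed and is_top:
            category = "Both"
        elif is_informed:
            category = "INTERFACE"
        elif is_top:
            category = "Top-ranked"
        else:
            category = "Neither"
        rows.append({"mrna": mrna, "rank": p.rank, "category": category, "binding": binding})
    rows = pd.DataFrame(rows).sort_values("rank", ignore_index=True)

    def ppv(mask):
        sub = rows[mask]
        if sub.empty:
            return math.nan
        return float(sub["binding"].isin(_POSITIVE_BINDING).mean())

    ppvs = {
        "INTERFACE": ppv(rows["category"] == "INTERFACE"),
        "Top-ranked": ppv(rows["category"] == "Top-ranked"),
        "Both": ppv(rows["category"] == "Both"),
        "interface_informed": ppv(rows["category"].isin(["INTERFACE", "Both"])),
        "top_ranked": ppv(rows["category"].isin(["Top-ranked", "Both"])),
    }
    return rows, ppvs


def tally_validation(rows: pd.DataFrame) -> dict:
    """Totals over a validation benchmark table.

    ``rows`` has columns srna, mrna, rank, category, binding.  Confirmed
    means binding in {yes, weak}.  Returns counts overall and the maximum
    confirmed rank per sRNA.
    """
    required = {"srna", "mrna", "rank", "category", "binding"}
    if rows.empty:
        return {"confirmed": 0, "interface_only": 0, "top_only": 0, "both": 0,
                "max_confirmed_rank": {}}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"benchmark table missing columns {sorted(missing)}")
    binding = rows["binding"].str.strip().str.lower()
    confirmed = binding.isin(_POSITIVE_BINDING)
    cat = rows["category"].str.strip()
    out = {
        "confirmed": int(confirmed.sum()),
        "interface_only": int((confirmed & (cat == "INTERFACE")).sum()),
        "top_only": int((confirmed & (cat == "Top-ranked")).sum()),
        "both": int((confirmed & (cat == "Both")).sum()),
        "max_confirmed_rank": {
            str(s): int(sub.loc[confirmed[sub.index], "rank"].max())
            for s, sub in rows.groupby("srna")
            if confirmed[sub.index].any()
        },
    }
    return out
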