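"""Paired-read processing for anti-termination reporter transcripts.

Each reporter transcript carries its antisense probe as a 5' barcode, so a
read pair identifies (R1) which target region was probed and (R2) where
transcription terminated.  This module builds per-probe reference
transcripts, assigns read pairs to probes with the pipeline's filtering
rules, and aggregates transcript-length histograms:

* R1 must match a reference exactly from the transcript start (error-free,
  TSS-anchored prefix match), on exactly one reference (multi-mapped reads
  are discarded), and must overlap at least 7 nt of that probe's antisense
  segment;
* the surviving R1 is joined to its R2 by read id, and R2 is exact-matched
  within the same reference to fix the transcription end site;
* transcript length = end position - TSS position + 1.

Externally mapped reads enter through :func:`load_mapped_bed` (BED6, 0-based
half-open) under the same filtering contract.  All internal coordinates and
TSV outputs are 1-based closed.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .thermo import reverse_complement

__all__ = [
    "ScaffoldConfig",
    "ProbeRecord",
    "RunLog",
    "build_reference_library",
    "process_read_pairs",
    "length_histograms",
    "load_mapped_bed",
    "read_fastq_pairs",
    "write_histogram_tsv",
    "read_histogram_tsv",
]

MIN_PROBE_OVERLAP = 7  # R1 must cover >= 7 nt of the antisense segment

_RNA_TO_DNA = str.maketrans("U", "T")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _dna(seq: str) -> str:
    return seq.upper().translate(_RNA_TO_DNA)


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScaffoldConfig:
    """Fixed reporter elements downstream of the probe (5'->3' order).

    The reference transcript for a probe is
    ``leader + asRNA + rse + rbs + es + rer`` with the TSS at position 1.
    Sequences are stored as DNA (reads are DNA-space).
    """

    rse: str
    rbs: str
    es: str
    rer: str
    leader: str = ""

    def __post_init__(self):
        for name in ("rse", "rbs", "es", "rer", "leader"):
            object.__setattr__(self, name, _dna(getattr(self, name)))
        for name in ("rse", "rbs", "es", "rer"):
            if not getattr(self, name):
                raise ValueError(f"scaffold element {name!r} must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "ScaffoldConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**{k: cfg[k] for k in ("rse", "rbs", "es", "rer") } ,
                   leader=cfg.get("leader", ""))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"leader": self.leader, "rse": self.rse, "rbs": self.rbs,
                 "es": self.es, "rer": self.rer}, fh)


@dataclass(frozen=True)
class ProbeRecord:
    """One probe and its reporter reference transcript."""

    probe_id: str
    as_seq: str  # antisense probe, DNA-space
    ta_id: str
    target_start: int
    target_end: int
    reference: str
    tss: int = 1  # 1-based position of the transcript start in the reference

    @property
    def probe_span(self) -> tuple[int, int]:
        """1-based closed interval of the antisense segment in the reference."""
        idx = self.reference.index(self.as_seq)
        return (idx + 1, idx + len(self.as_seq))

    @property
    def length(self) -> int:
        return len(self.reference)


@dataclass
class RunLog:
    """Read-conservation accounting for one processing run."""

    total_pairs: int = 0
    retained: int = 0
    discarded_short_overlap: int = 0
    discarded_multimapped: int = 0
    discarded_unassigned: int = 0
    discarded_orphan_r2: int = 0
    discarded_ambiguous_r2: int = 0
    discarded_unknown_reference: int = 0
    discarded_end_before_tss: int = 0
    notes: list = field(default_factory=list)

    def conserved(self) -> bool:
        discarded = (
            self.discarded_short_overlap + self.discarded_multimapped
            + self.discarded_unassigned + self.discarded_orphan_r2
            + self.discarded_ambiguous_r2 + self.discarded_unknown_reference
            + self.discarded_end_before_tss
        )
        return self.total_pairs == self.retained + discarded

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def build_reference_library(probes, scaffold: ScaffoldConfig) -> list[ProbeRecord]:
    """One reference transcript per probe row.

    ``probes`` is a DataFrame (or records) with columns
    probe_id, probe_seq, ta_id, start, end.  The probe sequence must occur
    exactly once within its own reference; duplicate probe ids are rejected.
    """
    if isinstance(probes, pd.DataFrame):
        rows = probes.to_dict("records")
    else:
        rows = list(probes)
    records = []
    seen = set()
    for row in rows:
        pid = str(row["probe_id"])
        if pid in seen:
            raise ValueError(f"duplicate probe id {pid!r}")
        seen.add(pid)
        as_seq = _dna(str(row["probe_seq"]))
        ref = scaffold.leader + as_seq + scaffold.rse + scaffold.rbs + scaffold.es + scaffold.rer
        if ref.count(as_seq) != 1:
            raise ValueError(
                f"probe {pid!r} sequence occurs {ref.count(as_seq)} times in its reference"
            )
        records.append(
            ProbeRecord(
                probe_id=pid, as_seq=as_seq, ta_id=str(row["ta_id"]),
                target_start=int(row["start"]), target_end=int(row["end"]),
                reference=ref,
            )
        )
    return records


def _assign_r1(r1: str, references: list[ProbeRecord]):
    """Return (probe_id, reason) for one R1 sequence.

    reason is None on success, else one of 'multimapped', 'unassigned',
    'short_overlap'.
    """
    hits = [rec for rec in references if rec.reference.startswith(r1)]
    if len(hits) > 1:
        return None, "multimapped"
    if not hits:
        return None, "unassigned"
    rec = hits[0]
    ps, pe = rec.probe_span
    overlap = min(len(r1), pe) - ps + 1
    if overlap < MIN_PROBE_OVERLAP:
        return None, "short_overlap"
    return rec.probe_id, None


def _locate_end(r2: str, rec: ProbeRecord):
    """Transcript end position from R2 (reverse-strand read), or (None, reason)."""
    frag = _revcomp_dna(r2)
    first = rec.reference.find(frag)
    if first < 0:
        return None, "unknown_reference"
    if rec.reference.find(frag, first + 1) >= 0:
        return None, "ambiguous_r2"
    return first + len(frag), None  # 1-based inclusive end


def process_read_pairs(pairs, references: list[ProbeRecord]):
    """Assign read pairs to (probe, transcript end position).

    ``pairs`` yields ``(read_id, r1_seq, r2_seq)``.  Returns
    ``(assignments, log)`` where assignments is a list of
    ``(read_id, probe_id, end_position)``.  Error-free reads recur, so
    per-sequence decisions are memoized.
    """
    log = RunLog()
    by_id = {rec.probe_id: rec for rec in references}
    r1_cache: dict[str, tuple] = {}
    r2_cache: dict[tuple[str, str], tuple] = {}
    assignments = []
    for read_id, r1, r2 in pairs:
        log.total_pairs += 1
        r1 = _dna(r1)
        r2 = _dna(r2)
        if r1 not in r1_cache:
            r1_cache[r1] = _assign_r1(r1, references)
        pid, reason = r1_cache[r1]
        if reason == "multimapped":
            log.discarded_multimapped += 1
            continue
        if reason == "unassigned":
            log.discarded_unassigned += 1
            continue
        if reason == "short_overlap":
            log.discarded_short_overlap += 1
            continue
        key = (pid, r2)
        if key not in r2_cache:
            r2_cache[key] = _locate_end(r2, by_id[pid])
        end, r2_reason = r2_cache[key]
        if r2_reason == "unknown_reference":
            log.discarded_orphan_r2 += 1
            continue
        if r2_reason == "ambiguous_r2":
            log.discarded_ambiguous_r2 += 1
            continue
        assignments.append((read_id, pid, end))
        log.retained += 1
    return assignments, log


def length_histograms(assignments, references: list[ProbeRecord], log: RunLog | None = None):
    """Aggregate transcript lengths per probe: {probe_id: {length: count}}.

    length = end position - TSS position + 1; reads ending before the TSS are
    dropped (and logged when a log is supplied).
    """
    by_id = {rec.probe_id: rec for rec in references}
    hists: dict[str, Counter] = defaultdict(Counter)
    for _read_id, pid, end in assignments:
        rec = by_id[pid]
        length = end - rec.tss + 1
        if length < 1:
            if log is not None:
                log.discarded_end_before_tss += 1
                log.retained -= 1
            continue
        hists[pid][length] += 1
    return {pid: dict(cnt) for pid, cnt in hists.items()}


def load_mapped_bed(bed_path, references: list[ProbeRecord], pairing):
    """Assignments from externally mapped reads (BED6) plus an R1/R2 pairing table.

    BED intervals are 0-based half-open on the reference transcripts, read
    ids in the name field; ``pairing`` is a DataFrame or TSV path with
    columns r1_id, r2_id.  The same filtering contract as
    :func:`process_read_pairs` applies, computed on intervals: probe overlap
    >= 7 nt for R1, multi-mapped ids dropped, R2 fixes the end position.
    """
    if not isinstance(pairing, pd.DataFrame):
        pairing = pd.read_csv(pairing, sep="\t", dtype=str)
    by_id = {rec.probe_id: rec for rec in references}
    intervals: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    log = RunLog()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{bed_path}:{lineno}: expected BED6, got {len(fields)} fields")
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if end_i <= start_i:
                raise ValueError(f"{bed_path}:{lineno}: empty or inverted interval")
            # 0-based half-open -> 1-based closed
            intervals[name].append((chrom, start_i + 1, end_i))

    assignments = []
    for _, row in pairing.iterrows():
        r1_id, r2_id = str(row["r1_id"]), str(row["r2_id"])
        log.total_pairs += 1
        r1_hits = intervals.get(r1_id, [])
        r2_hits = intervals.get(r2_id, [])
        if len(r1_hits) > 1:
            log.discarded_multimapped += 1
            continue
        if not r1_hits:
            log.discarded_unassigned += 1
            continue
        chrom, s1, e1 = r1_hits[0]
        rec = by_id.get(chrom)
        if rec is None:
            log.discarded_unknown_reference += 1
            continue
        ps, pe = rec.probe_span
        overlap = min(e1, pe) - max(s1, ps) + 1
        if overlap < MIN_PROBE_OVERLAP:
            log.discarded_short_overlap += 1
            continue
        if len(r2_hits) > 1:
            log.discarded_ambiguous_r2 += 1
            continue
        if not r2_hits or r2_hits[0][0] != chrom:
            log.discarded_orphan_r2 += 1
            continue
        assignments.append((r1_id, rec.probe_id, r2_hits[0][2]))
        log.retained += 1
    return assignments, log


def read_fastq_pairs(r1_path, r2_path):
    """Yield (read_id, r1_seq, r2_seq) from paired FASTQ files (same order)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(r1_path) as fh1, open(r2_path) as fh2:
        for (t1, s1, _q1), (t2, s2, _q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True
        ):
            id1 = t1.split()[0].removesuffix("/1")
            id2 = t2.split()[0].removesuffix("/2")
            if id1 != id2:
                raise ValueError(f"unpaired FASTQ records: {id1!r} vs {id2!r}")
            yield id1, s1, s2


def write_histogram_tsv(hists: dict, path) -> None:
    rows = [
        {"probe_id": pid, "length": length, "count": count}
        for pid, cnt in sorted(hists.items())
        for length, count in sorted(cnt.items())
    ]
    pd.DataFrame(rows, columns=["probe_id", "length", "count"]).to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "length": int, "count": int})
    out: dict[str, dict[int, int]] = defaultdict(dict)
    for row in df.itertuples():
        out[row.probe_id][int(row.length)] = int(row.count)
    return dict(out)


def save_reference_fasta(references: list[ProbeRecord], path) -> None:
    """Write reference transcripts as FASTA (e.g. for an external mapper)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(r.reference), id=r.probe_id, description="") for r in references]
    seqio_write(recs, Path(path), "fasta")
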