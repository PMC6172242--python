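"""Ground-truth-labeled synthetic reporter datasets.

Emulates what the wet experiment produces so every downstream module is
testable offline: per-probe transcript-length mixtures over the three
termination landmarks of the reporter (~80 nt, within the leader-peptide
element; ~140 nt, at the end of the Rho-utilization terminator; ~200 nt,
read-through into the elongation reporter), replicate noise, and a second
strain with planted per-region accessibility shifts.

For a region of true accessibility ``a`` each read terminates at the
read-through landmark with probability ``a`` and otherwise at the short or
mid landmark with split ``rho : 1 - rho``; lengths are jittered by a rounded
Normal(0, sd) and truncated to [1, reference length].  What this emulates —
and what it deliberately does not (sequencing errors are off by default,
quality scores are uniform, transcript abundance is equal across probes) —
is documented in docs/methods.md.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import readproc
from .readproc import ProbeRecord, ScaffoldConfig, _revcomp_dna
from .thermo import reverse_complement

__all__ = [
    "SimConfig",
    "SimBundle",
    "default_scaffold",
    "simulate_true_accessibilities",
    "simulate_histograms",
    "emit_paired_fastq",
    "make_fixture_bundle",
    "simulate_bundle",
]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def default_scaffold(seed: int = 947) -> ScaffoldConfig:
    """Synthetic stand-in reporter scaffold (fixed by seed).

    Element lengths are sized so the three termination landmarks fall where
    they do on the real reporter: with a ~12 nt probe the leader-peptide
    element spans ~45-155 nt and the read-through landmark (200 nt) lies
    inside the elongation reporter.  The sequences themselves are synthetic.
    """
    rng = np.random.default_rng(seed)
    return ScaffoldConfig(
        rse=_random_dna(rng, 21),
        rbs="TTAAGGAGGTGA",
        es=_random_dna(rng, 110),
        rer=_random_dna(rng, 130),
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    landmarks are transcript lengths (nt) of the three termination modes;
    ``rho`` is the short:mid split among terminated reads; ``noise_sd`` is
    per-replicate accessibility jitter; ``hfq_deltas`` maps region ids to
    accessibility shifts applied in the second (hfq-null-like) strain.
    """

    n_probes: int = 50
    probe_len: int = 12
    ta_length: int = 200
    landmarks: tuple = (80, 140, 200)
    jitter_sd: float = 3.0
    rho: float = 0.7
    reads_per_probe: int = 10_000
    replicates: int = 3
    beta_params: tuple = (2.0, 2.0)
    noise_sd: float = 0.02
    hfq_deltas: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if list(self.landmarks) != sorted(set(self.landmarks)):
            raise ValueError("landmarks must be strictly increasing")
        if self.reads_per_probe < 1:
            raise ValueError("reads_per_probe must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class SimBundle:
    """In-memory synthetic dataset with ground truth."""

    config: SimConfig
    ta_id: str
    ta_seq: str
    probes: pd.DataFrame  # probe_id, ta_id, start, end, probe_seq
    references: list
    truth: dict  # strain -> {probe_id: true accessibility}
    hists: dict  # (probe_id, strain, replicate) -> {length: count}


def simulate_true_accessibilities(n_regions: int, alpha: float = 2.0, beta: float = 2.0,
                                  seed: int | None = None) -> np.ndarray:
    """Seeded true accessibility coefficients, Beta(alpha, beta) in [0, 1]."""
    if n_regions < 1:
        raise ValueError("need n_regions >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be > 0")
    return np.random.default_rng(seed).beta(alpha, beta, size=n_regions)


def simulate_histograms(truth: float, ref_length: int, config: SimConfig,
                        rng: np.random.Generator) -> dict:
    """One probe/replicate transcript-length histogram.

    Reads terminate at the read-through landmark with probability ``truth``,
    else at the short (rho) or mid (1-rho) landmark; lengths get rounded
    Normal(0, jitter_sd) jitter truncated to [1, ref_length].
    """
    if not 0 <= truth <= 1:
        raise ValueError("truth must be in [0, 1]")
    short, mid, full = config.landmarks
    probs = [(1 - truth) * config.rho, (1 - truth) * (1 - config.rho), truth]
    counts = rng.multinomial(config.reads_per_probe, probs)
    hist: dict[int, int] = {}
    for landmark, k in zip((short, mid, full), counts):
        if k == 0:
            continue
        if config.jitter_sd > 0:
            lengths = landmark + np.rint(rng.normal(0.0, config.jitter_sd, size=k)).astype(int)
        else:
            lengths = np.full(k, landmark, dtype=int)
        np.clip(lengths, 1, ref_length, out=lengths)
        for length, c in zip(*np.unique(lengths, return_counts=True)):
            hist[int(length)] = hist.get(int(length), 0) + int(c)
    return hist


def _tile_probes(ta_id: str, ta_seq: str, n_probes: int, probe_len: int,
                 scaffold: ScaffoldConfig) -> pd.DataFrame:
    """Evenly spaced probe windows; windows whose probe sequence collides
    with the scaffold (would not be unique in its reference) are nudged."""
    L = len(ta_seq)
    scaffold_body = scaffold.rse + scaffold.rbs + scaffold.es + scaffold.rer
    if n_probes == 1:
        starts = [1]
    else:
        starts = [1 + round(i * (L - probe_len) / (n_probes - 1)) for i in range(n_probes)]
    rows = []
    for i, start in enumerate(starts):
        for start_try in range(start, 0, -1):
            region = ta_seq[start_try - 1 : start_try - 1 + probe_len]
            probe = _revcomp_dna(region)
            if probe not in scaffold_body:
                start = start_try
                break
        rows.append({"probe_id": f"{ta_id}_r{i + 1:03d}", "ta_id": ta_id,
                     "start": start, "end": start + probe_len - 1, "probe_seq": probe})
    return pd.DataFrame(rows)


def simulate_bundle(config: SimConfig, scaffold: ScaffoldConfig | None = None) -> SimBundle:
    """Full synthetic dataset: one taRNA, tiled probes, two strains, replicates."""
    rng = np.random.default_rng(config.seed)
    scaffold = scaffold or default_scaffold()
    ta_id = "srna1"
    ta_seq = _random_dna(rng, config.ta_length)
    probes = _tile_probes(ta_id, ta_seq, config.n_probes, config.probe_len, scaffold)
    references = readproc.build_reference_library(probes, scaffold)
    by_id = {r.probe_id: r for r in references}

    base = simulate_true_accessibilities(
        config.n_probes, *config.beta_params, seed=int(rng.integers(2**31)))
    truth_parent = dict(zip(probes["probe_id"], base))
    truth_mutant = {
        pid: float(np.clip(a + config.hfq_deltas.get(pid, 0.0), 0.0, 1.0))
        for pid, a in truth_parent.items()
    }
    truth = {"parent": truth_parent, "dhfq": truth_mutant}

    hists = {}
    for strain, tmap in truth.items():
        for rep in range(1, config.replicates + 1):
            for pid, a in tmap.items():
                a_rep = float(np.clip(a + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
                hists[(pid, strain, rep)] = simulate_histograms(
                    a_rep, by_id[pid].length, config, rng)
    return SimBundle(config=config, ta_id=ta_id, ta_seq=ta_seq, probes=probes,
                     references=references, truth=truth, hists=hists)


def emit_paired_fastq(hists: dict, references: list, r1_path, r2_path,
                      read_len: int = 75) -> int:
    """Write error-free read pairs reproducing the given histograms.

    R1 is the first min(read_len, L) nt of each simulated transcript, R2 the
    reverse complement of the last min(read_len, L) nt; ids are shared and
    qualities uniform.  ``hists`` maps probe_id -> {length: count}.
    Returns the number of pairs written.
    """
    by_id = {r.probe_id: r for r in references}
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pid in sorted(hists):
            ref = by_id[pid].reference
            for length in sorted(hists[pid]):
                transcript = ref[:length]
                r1 = transcript[:read_len]
                r2 = _revcomp_dna(transcript[-read_len:])
                q1 = "I" * len(r1)
                q2 = "I" * len(r2)
                for _ in range(hists[pid][length]):
                    n += 1
                    rid = f"read{n:08d}"
                    f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
                    f2.write(f"@{rid}/2\n{r2}\n+\n{q2}\n")
    return n


def _predictions_frame(bundle: SimBundle, rng: np.random.Generator,
                       n_predictions: int = 20) -> pd.DataFrame:
    """Synthetic ranked prediction table with planted functional overlaps.

    The first few predictions overlap the most accessible probe regions by
    exactly 5 nt (the filter's inclusive boundary); the rest are random.
    """
    L = len(bundle.ta_seq)
    parent = bundle.truth["parent"]
    top = sorted(parent, key=parent.get, reverse=True)[:3]
    spans = {pid: (int(row.start), int(row.end))
             for pid, row in zip(bundle.probes["probe_id"], bundle.probes.itertuples())}
    rows = []
    for rank in range(1, n_predictions + 1):
        if rank <= len(top):
            s, e = spans[top[rank - 1]]
            start2 = min(max(1, e - 4), L - 8)  # 5-nt overlap with the region end
            end2 = min(L, start2 + 8)
        else:
            start2 = int(rng.integers(1, max(2, L - 12)))
            end2 = min(L, start2 + int(rng.integers(8, 14)))
        rows.append({
            "rank": rank, "id1": f"mRNA{rank:03d}",
            "start1": int(rng.integers(-60, 40)), "end1": 0,
            "id2": bundle.ta_id, "start2": start2, "end2": end2,
            "E": float(np.round(-16 + 0.12 * rank + rng.normal(0, 0.3), 2)),
        })
        rows[-1]["end1"] = rows[-1]["start1"] + (end2 - start2)
    return pd.DataFrame(rows)


def make_fixture_bundle(config: SimConfig, outdir, force: bool = False,
                        scaffold: ScaffoldConfig | None = None,
                        write_fastq: bool = True) -> SimBundle:
    """Write a complete fixture directory (FASTA/TSV/FASTQ/CSV/YAML).

    Refuses an existing non-empty output directory unless ``force``.
    Identical configs (same seed) produce byte-identical bundles.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scaffold = scaffold or default_scaffold()
    bundle = simulate_bundle(config, scaffold)
    rng = np.random.default_rng(config.seed + 1)

    with open(outdir / "taRNA.fa", "w") as fh:
        fh.write(f">{bundle.ta_id}\n{bundle.ta_seq}\n")
    bundle.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    scaffold.to_yaml(outdir / "scaffold.yaml")
    pd.DataFrame(
        [{"probe_id": pid, "strain": strain, "true_accessibility": a}
         for strain, tmap in bundle.truth.items() for pid, a in tmap.items()]
    ).to_csv(outdir / "truth.csv", index=False)
    _predictions_frame(bundle, rng).to_csv(outdir / "predictions.csv", index=False)

    if write_fastq:
        for strain in bundle.truth:
            for rep in range(1, config.replicates + 1):
                per_probe = {pid: bundle.hists[(pid, strain, rep)]
                             for pid in bundle.probes["probe_id"]}
                emit_paired_fastq(
                    per_probe, bundle.references,
                    outdir / f"{strain}_rep{rep}_R1.fastq",
                    outdir / f"{strain}_rep{rep}_R2.fastq",
                )
    return bundle
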