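"""From sequencing reads to regional accessibility.

Simulates a small probed RNA (known ground truth), writes paired FASTQ,
re-processes the reads into transcript-length histograms, and computes
reported accessibilities — then compares them with the planted truth.
"""

import tempfile
import warnings
from pathlib import Path

from scipy.stats import spearmanr

from accessprobe import accessibility, readproc, simdata

cfg = simdata.SimConfig(n_probes=12, ta_length=140, reads_per_probe=2000,
                        replicates=3, seed=5)
bundle = simdata.simulate_bundle(cfg)

workdir = Path(tempfile.mkdtemp())
hists = {}
for rep in range(1, cfg.replicates + 1):
    per_probe = {pid: bundle.hists[(pid, "parent", rep)]
                 for pid in bundle.probes["probe_id"]}
    r1, r2 = workdir / f"rep{rep}_R1.fq", workdir / f"rep{rep}_R2.fq"
    simdata.emit_paired_fastq(per_probe, bundle.references, r1, r2)
    assignments, log = readproc.process_read_pairs(
        readproc.read_fastq_pairs(r1, r2), bundle.references)
    print(f"replicate {rep}: retained {log.retained}/{log.total_pairs} read pairs")
    hists.update({(pid, "parent", rep): h for pid, h in
                  readproc.length_histograms(assignments, bundle.references, log).items()})

region_to_ta = {pid: bundle.ta_id for pid in bundle.probes["probe_id"]}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = accessibility.native_accessibility_table(hists, region_to_ta, baseline=85.0)

reported = table.groupby("region")["reported"].first()
truth = bundle.truth["parent"]
print("\nregion            truth  reported")
for pid in reported.index:
    print(f"{pid:<16} {truth[pid]:6.2f}   {reported[pid]:6.2f}")
rho = spearmanr([truth[r] for r in reported.index], reported.values).statistic
print(f"\nSpearman(truth, reported) = {rho:.3f} — the reported 0-1 scale "
      "recovers the planted accessibility ranking.")
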