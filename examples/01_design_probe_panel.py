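"""Design an antisense probe panel for one small RNA.

Scores every 9-16 nt window of a toy RNA with the hybridization-efficacy
model (nu), converts the scores into knowledge-gradient values, and selects
a covering panel with the greedy weighted set cover.
"""

import numpy as np

from accessprobe import design, thermo

ta = thermo.NucleotideSequence(
    "GGGAAACCCAAAGGGAAACCCAAAUUUCCCAAAGGGAAAUUU", id="toy_srna")

regions = design.enumerate_candidate_regions(ta, min_len=9, max_len=16)
scores = design.score_regions(regions, ta)
nu = np.array([s.nu for s in scores])
print(f"{len(regions)} candidate windows on {ta.id} (L={len(ta)})")
print(f"nu range: {nu.min():.1f} .. {nu.max():.1f} "
      "(higher = more hybridization-favorable)")

# belief means from min-max-normalized nu; unit prior variance, unit noise
mu = (nu - nu.min()) / (nu.max() - nu.min())
v = design.kg_values(design.KnowledgeState(mu, np.ones_like(mu), 1.0))
panel = design.greedy_set_cover(regions, v, lam=1.0, L=len(ta))

print(f"\nselected {len(panel.selected)} probes covering [1,{len(ta)}]:")
for k in panel.selected:
    r = regions[k]
    print(f"  [{r.start:>2},{r.end:>2}]  probe {r.probe_seq}  "
          f"nu={nu[k]:7.1f}  v_k={v[k]:.4f}")
print("\neach line is one probe: its target interval, antisense sequence, "
      "biophysical score and value of measuring it.")
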