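# Methods

This note documents the models implemented in `accessprobe`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data generator does and does not emulate.

## Folding engine (`accessprobe.thermo`)

The structure space is the set of nested (pseudoknot-free) pairings over
Watson-Crick (GC, AU) and wobble (GU) pairs with hairpin loops of at least
`min_hairpin_loop = 3` unpaired nucleotides. The energy of a structure is
the sum of its pair energies (defaults GC −3.0, AU −2.0, GU −1.0 kcal/mol);
there are no stacking, loop or dangle terms. This model is intentionally
minimal: every ensemble quantity can be verified to ~1e−15 relative against
exhaustive enumeration (`enumerate_structures`, guarded at n ≤ 18), which is
the package's primary correctness oracle. The engine is a registry
(`thermo.BACKENDS`) so a full nearest-neighbour backend can replace the
builtin physics without changing any caller; absolute energies and hence
absolute `nu` values are model-dependent by construction, and only relative
comparisons within one engine are meaningful.

Partition functions use O(n³) inside recursions. Pair probabilities use an
outside pass that conditions each pair on its innermost enclosing pair; the
enclosing sum is evaluated as a vector-matrix-vector product per pair, which
is O(n⁴) arithmetic but vectorized, entirely adequate at sRNA scale
(n ≤ a few hundred). For n > 200 the recursion is rescaled per nucleotide by
the MFE density (equivalent to log-space scaling) to keep Z in float range;
below that threshold the plain recursion is exact in double precision.

Derived quantities:

* `theta_bar` — summed unpaired probability over a region, from
  `1 − Σ_j P(i, j)`.
* `dG_tf = −RT ln(Z_constrained / Z)` with all region nucleotides barred
  from pairing. The constrained ensemble is a subset of the full one, so
  `dG_tf ≥ 0`, and it is monotone non-decreasing as the region grows.
* `dG_asT` — the probe is by construction the exact reverse complement of
  its region, so the duplex energy is the plain per-pair sum; inputs that
  are not exact reverse complements are rejected rather than aligned.
* `dG_asF` — minimum free energy over the probe's structure space (≤ 0).
  Probe lengths outside the 9-26 nt design range warn but do not error, so
  off-design candidates can still be scored.

`RT` defaults to 0.616 kcal/mol (37 °C). DNA input (T) is normalized to U.

## Panel selection (`accessprobe.design`)

Candidate regions are all windows of length 9-16 nt (or a seeded random
sample). The selection objective is a weighted set cover,
`max Σ v_k x_k − λ Σ x_k` subject to full coverage of `[1, L]`, solved with
the greedy rule `argmin_k (λ − v_k)/|[i_k, j_k] \ C|`. Decisions taken where
the design was open:

* **Knowledge-gradient values.** The original sparse-linear belief update is
  not recoverable; the package uses the standard independent-normal
  knowledge-gradient closed form and, equivalently everywhere, accepts
  caller-supplied value vectors. The closed form is cross-checked in tests
  against a Monte-Carlo estimate of the expected posterior-maximum gain.
* **Tie-breaking** in the argmin: smallest start index, then shortest
  region. Fully covered candidates (zero marginal gain) leave the pool each
  iteration; division by zero cannot occur.
* **λ defaults to 1.0** and is exposed everywhere. With values normalized
  to [0, 1], λ = 1 keeps every α non-negative and penalizes panel size;
  values above λ flip α negative and let high-value regions be picked ahead
  of coverage efficiency, which is the intended semantics of the objective.
* Greedy set cover is an approximation: on small instances tests verify
  feasibility and compare the greedy objective against the exhaustive
  optimum as a bound, not an equality.
* The global "top fraction of ranked regions" filter is a separate post-hoc
  operation (`top_fraction`, default 1.5%).

Baselines for benchmarking: *exploration* draws seeded random fixed-length
12-mers until covered; *exploitation* runs the same greedy cover on min-max
normalized `nu` with no knowledge-gradient step. `experimental_effort` is
the gap between the molecule's best true accessibility and the best among
the selected regions, min-max rescaled across the compared algorithms.

## Read processing (`accessprobe.readproc`)

Reference transcripts are `leader + probe + RSE + RBS + ES + RER` with the
transcription start at position 1; the probe must occur exactly once in its
reference. The built-in matcher is exact (mismatches disallowed): R1 must be
a TSS-anchored prefix of exactly one reference (reads matching more than one
are discarded as multi-mapped) and must cover at least 7 nt of the probe
segment, inclusive. R2 is exact-matched within the assigned reference; an
ambiguous (multiply occurring) or unmatched R2 drops the pair. Transcript
length is `end − TSS + 1`. Every dropped pair is counted in a run log whose
categories sum to the input count (a tested conservation invariant).

Mismatch-tolerant alignment is out of scope: synthetic reads are error-free
by default, and an optional substitution rate in the generator exists to
document (not to overcome) this limitation. Externally mapped reads enter
via BED6 (0-based half-open, converted to the 1-based closed internal
convention) plus an R1/R2 pairing table, under the same filtering contract.
Because error-free reads collapse to few unique sequences, assignment
decisions are memoized by sequence; this is purely an optimization.

## Accessibility (`accessprobe.accessibility`)

Weighted-average length → baseline adjustment → normalization. Defaults:
85 nt baseline in overexpression mode and 164 nt in native mode, with
`baseline="auto"` using the minimum observed weighted average for workflows
where the appropriate floor is dataset-specific. Adjusted lengths are
floored at 0 (reads shorter than the baseline carry no anti-termination
signal). Probes with zero reads yield a missing value, never 0. Degenerate
normalization groups (max = min, e.g. a single region) map to 0.5 with a
warning. Standard errors are sample SEs of the raw replicate values scaled
by the reciprocal of the replicate-mean range — the second normalization is
treated as a fixed linear map, so SEs are approximate when the min/max
anchor regions are themselves noisy. Because of the per-molecule min-max,
reported accessibilities are comparable within a molecule, not across
molecules, and are invariant to uniform length shifts (the baseline cancels).

## Statistics (`accessprobe.stats`)

Paired two-tailed t-tests are implemented explicitly so degenerate cases are
defined: zero-variance differences give (t=0, p=1) at zero mean and a
flagged (±inf, p=0) otherwise; the regular path agrees with
`scipy.stats.ttest_rel` to 1e−10 in tests. An sRNA is Hfq-dependent iff any
region's p is strictly below α = 0.05. No multiple-testing correction is
applied by default (per-region p-values are reported as-is); an optional
Benjamini-Hochberg flag exists in the CLI. The extremes test classifies a
value as extreme iff it is strictly below 0.125 or strictly above 0.875
(a 0.25/0.75 preset serves functional-region calling) and computes
`χ²_{N−1} = Pearson χ² × (N−1)/N` with p from χ²(1); Pearson χ² comes from
`scipy.stats.chi2_contingency` without continuity correction.

## Functional regions and prediction filtering (`accessprobe.funcmap`)

A region is a candidate iff it starts or ends within the 5' or 3' end
window (20% of the molecule each) *and* its reported accessibility is
extreme (> 0.75 or < 0.25). Up to three regions are kept, ranked by distance
from 0.5 and then by 5'-most start. If no 3'-window candidate exists the 5'
window widens to 40%. "Mid-accessibility clustering" is operationalized as:
no window candidate is outside [0.25, 0.75]; the tie-break then selects the
5'-most extreme region in the 5' half containing a YUNR motif.

The YUNR (pyrimidine-U-N-purine) scan uses exact enumeration: 16 of the 256
4-mers match, so a perfect match has p = 1/16 = 0.0625 and the probability
of at least one match in m scanned positions is `1 − (15/16)^m`. Note that
under exact enumeration no match can reach p < 0.05 — a 4-position motif
with two 2-letter classes simply cannot be rarer than 1/16 against a uniform
background — so the tie-break's significance threshold defaults to 1/16
(i.e., an exact match qualifies) and is exposed as a parameter. Motif-tool
p-values computed from log-odds scores against a trained background are not
reproduced.

Predictions are kept iff their sRNA interaction interval overlaps a called
region by ≥ 5 nt (inclusive). Tested candidates partition into
`Both` / `INTERFACE` / `Top-ranked` (top-group size default 5, configurable
up to the "top 5-7" used in practice); weak binding counts as positive in
PPV and tallies. The bundled benchmark table
(`accessprobe/data/emsa_benchmark.csv`) transcribes published in vitro
binding outcomes for three sRNAs and is used as a fixed input.

## Synthetic data (`accessprobe.simdata`)

The generator emulates the reporter's three-peak transcript-length
signature: termination at ~80 nt (within the leader-peptide element),
~140 nt (end of the Rho-utilization site) or ~200 nt (read-through into the
elongation reporter). For true accessibility `a`, a read terminates at the
read-through landmark with probability `a`, otherwise at the short or mid
landmark with split ρ = 0.7 : 0.3. The split is fixed once as a plausible
value (the real peak ratio is not quantified) and configurable. Lengths get
rounded Normal(0, 3 nt) jitter truncated to [1, reference length]. True
accessibilities are Beta(2, 2) draws; replicates jitter the truth by
Normal(0, 0.02). The second strain applies planted per-region accessibility
deltas (clipped to [0, 1]). The scaffold sequences are synthetic stand-ins
(fixed by seed) whose element lengths place the landmarks correctly; probe
windows that would collide with the scaffold sequence are nudged to keep
every probe unique in its reference.

What the generator does **not** emulate: sequencing errors and quality
variation (reads are error-free, so the exact matcher retains 100% of
them — real data loses reads at every filter), transcript-abundance
differences between probes, cross-hybridization between probes and
off-target RNAs, and any sequence-dependence of termination. Passing the
recovery benchmarks therefore demonstrates that the quantification pipeline
inverts the generative model faithfully — not that the biological readout
is noise-free.

## Problem sizes and determinism

The recovery benchmark uses 50 probes × 10⁴ reads × 3 replicates × 2
strains (3 × 10⁶ read pairs end to end) with shifts of +0.4 planted on the
ten least-accessible regions; enumeration-oracle checks use 200 random
sequences of length ≤ 15; the greedy cover is stress-tested on 1000 random
instances of ≤ 12 candidates. All stochastic steps take explicit seeds and
seeded runs are bit-reproducible; `scripts/acceptance.py --seed N` threads
one seed through every source of randomness.

## Known limitations

* The builtin energy model ignores stacking; absolute ΔG and `nu` values do
  not match nearest-neighbour engines (rankings within a molecule are the
  meaningful output).
* The O(n⁴)-arithmetic outside pass and per-region constrained partition
  functions make exhaustive scoring of very long RNAs (n ≫ 500) slow;
  candidate sampling (`mode="random"`) is the intended path there.
* SE propagation treats normalization anchors as constants.
* The independent-normal knowledge gradient ignores belief correlations
  between overlapping regions that a sparse-linear belief model would
  capture; the two coincide only for disjoint regions.
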