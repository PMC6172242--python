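"""Antisense probe panel design.

Scores candidate target regions with the biophysical hybridization-efficacy
model

    nu = theta_bar * (dG_tf - dG_asT) + dG_asF

where ``theta_bar`` is the summed per-nucleotide unpaired probability of the
region, ``dG_tf`` the cost of opening the target region, ``dG_asT`` the
probe:target duplex energy and ``dG_asF`` the probe self-folding MFE — and
selects a probe panel by a batch knowledge-gradient weighted set cover:

    max  sum_k v_k x_k - lambda * sum_k x_k
    s.t. union of selected [i_k, j_k] = [1, L]

solved greedily: repeatedly pick argmin_k alpha_k with
``alpha_k = (lambda - v_k) / |[i_k, j_k] \\ C|`` over candidates with nonzero
marginal coverage.  Knowledge-gradient values come from the independent-
normal closed form; externally computed value vectors are accepted anywhere
``v`` is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import thermo
from .thermo import EnergyModel, NucleotideSequence, as_sequence, reverse_complement

__all__ = [
    "CandidateRegion",
    "HybridizationScore",
    "KnowledgeState",
    "CoverDesign",
    "enumerate_candidate_regions",
    "hybridization_score",
    "score_regions",
    "kg_value",
    "kg_values",
    "greedy_set_cover",
    "baseline_design",
    "experimental_effort",
    "rescale_efforts",
    "top_fraction",
]


class CoverageError(RuntimeError):
    """The candidate set cannot cover [1, L]."""


@dataclass(frozen=True)
class CandidateRegion:
    """One candidate target window [start, end] (1-based closed) on a taRNA."""

    ta_id: str
    start: int
    end: int
    region_seq: str
    probe_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class HybridizationScore:
    nu: float
    theta_bar: float
    dG_tf: float
    dG_asT: float
    dG_asF: float


@dataclass
class KnowledgeState:
    """Independent-normal belief over per-region accessibility.

    mu/sigma2 are the belief mean and variance per region; sigma2_eps is the
    measurement noise variance of one probing experiment.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    sigma2_eps: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same shape")
        if np.any(self.sigma2 < 0):
            raise ValueError("belief variances must be >= 0")
        if not self.sigma2_eps > 0:
            raise ValueError("measurement noise variance must be > 0")


@dataclass
class CoverDesign:
    """Result of a coverage selection: indices, covered set, and the alpha trace."""

    selected: list[int]
    covered: set[int]
    L: int
    lam: float
    alpha_trace: list[dict[int, float]] = field(default_factory=list)
    regions: list | None = None  # candidate pool the indices refer to

    @property
    def full_coverage(self) -> bool:
        return self.covered == set(range(1, self.L + 1))


def enumerate_candidate_regions(
    ta,
    min_len: int = 9,
    max_len: int = 16,
    mode: str = "exhaustive",
    sample_size: int | None = None,
    seed: int | None = None,
) -> list[CandidateRegion]:
    """All (or a seeded random sample of) windows of length min_len..max_len.

    ``mode='random'`` draws ``sample_size`` windows without replacement; a
    sample size exceeding the window count is capped with a warning.
    """
    ta = as_sequence(ta)
    L = len(ta)
    if L < min_len:
        raise ValueError(f"taRNA length {L} < min_len {min_len}")
    windows = []
    for w in range(min_len, min(max_len, L) + 1):
        for start in range(1, L - w + 2):
            windows.append((start, start + w - 1))
    if mode == "random":
        if sample_size is None:
            raise ValueError("random mode requires sample_size")
        if sample_size > len(windows):
            warnings.warn(
                f"sample_size {sample_size} exceeds {len(windows)} windows; capped",
                stacklevel=2,
            )
            sample_size = len(windows)
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(windows), size=sample_size, replace=False)
        windows = [windows[i] for i in sorted(idx)]
    elif mode != "exhaustive":
        raise ValueError(f"mode must be 'exhaustive' or 'random', got {mode!r}")
    out = []
    for start, end in windows:
        region = ta.residues[start - 1 : end]
        out.append(
            CandidateRegion(
                ta_id=ta.id, start=start, end=end,
                region_seq=region, probe_seq=reverse_complement(region),
            )
        )
    return out


def hybridization_score(
    region: CandidateRegion,
    ta,
    model: EnergyModel | None = None,
    ensemble: thermo.FoldEnsemble | None = None,
) -> HybridizationScore:
    """Hybridization efficacy nu of one candidate region.

    Pass ``ensemble`` (the taRNA fold ensemble) to avoid recomputing the
    partition function for every window of the same molecule.
    """
    ta = as_sequence(ta)
    model = model or EnergyModel()
    if ensemble is None:
        ensemble = thermo.pair_probabilities(ta, model)
    theta = float(thermo.unpaired_profile(ensemble, region.start, region.end).sum())
    dG_tf = thermo.opening_energy(ta, region.start, region.end, model)
    dG_asT = thermo.duplex_energy(region.probe_seq, region.region_seq, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scoring mode tolerates off-design lengths
        dG_asF = thermo.probe_folding_energy(region.probe_seq, model)
    nu = theta * (dG_tf - dG_asT) + dG_asF
    return HybridizationScore(nu=nu, theta_bar=theta, dG_tf=dG_tf, dG_asT=dG_asT, dG_asF=dG_asF)


def score_regions(regions, ta, model: EnergyModel | None = None) -> list[HybridizationScore]:
    """Score many windows of one taRNA, sharing a single fold ensemble."""
    ta = as_sequence(ta)
    model = model or EnergyModel()
    ens = thermo.pair_probabilities(ta, model)
    return [hybridization_score(r, ta, model, ensemble=ens) for r in regions]


def kg_values(state: KnowledgeState) -> np.ndarray:
    """Knowledge-gradient value of measuring each region once.

    Independent-normal closed form:
    sigma_tilde_k = sigma2_k / sqrt(sigma2_k + sigma2_eps),
    zeta_k = -|mu_k - max_{j != k} mu_j| / sigma_tilde_k,
    v_k = sigma_tilde_k * (zeta_k * Phi(zeta_k) + phi(zeta_k)).
    v_k = 0 where sigma_tilde_k = 0.
    """
    n = state.mu.size
    if n < 2:
        raise ValueError("knowledge gradient needs at least 2 regions")
    sig = state.sigma2 / np.sqrt(state.sigma2 + state.sigma2_eps)
    # max of the others: top value unless k is itself the unique argmax
    order = np.argsort(state.mu)
    best, second = state.mu[order[-1]], state.mu[order[-2]]
    other_max = np.where(state.mu == best, second, best)
    # when several regions tie at the max, each still sees a rival at `best`
    if np.sum(state.mu == best) > 1:
        other_max = np.full(n, best)
    v = np.zeros(n)
    nz = sig > 0
    zeta = -np.abs(state.mu[nz] - other_max[nz]) / sig[nz]
    v[nz] = sig[nz] * (zeta * norm.cdf(zeta) + norm.pdf(zeta))
    return v


def kg_value(state: KnowledgeState, k: int) -> float:
    """v_k for a single region (see :func:`kg_values`)."""
    return float(kg_values(state)[k])


def greedy_set_cover(regions, v, lam: float = 1.0, L: int | None = None) -> CoverDesign:
    """Greedy solution of the weighted set cover with per-region values v.

    At each step computes ``alpha_k = (lam - v_k) / |[i_k, j_k] \\ C|`` over
    unselected regions with nonzero marginal coverage and selects the argmin;
    ties break to the smallest start index, then the shortest region.
    """
    intervals = [r.interval if isinstance(r, CandidateRegion) else tuple(r) for r in regions]
    v = np.asarray(v, dtype=float)
    if len(intervals) != v.size:
        raise ValueError("regions and v must align")
    if L is None:
        L = max(e for _, e in intervals)
    universe = set(range(1, L + 1))
    reachable = set()
    for s, e in intervals:
        reachable.update(range(s, e + 1))
    if not universe <= reachable:
        missing = sorted(universe - reachable)
        raise CoverageError(f"candidates cannot cover nucleotides {missing}")

    covered: set[int] = set()
    selected: list[int] = []
    trace: list[dict[int, float]] = []
    while covered != universe:
        alphas: dict[int, float] = {}
        for k, (s, e) in enumerate(intervals):
            if k in selected:
                continue
            gain = len(set(range(s, e + 1)) - covered)
            if gain == 0:
                continue  # fully covered: dropped from the candidate pool
            alphas[k] = (lam - v[k]) / gain
        if not alphas:  # unreachable given the feasibility check above
            raise CoverageError("no candidate adds coverage")
        k_star = min(
            alphas,
            key=lambda k: (alphas[k], intervals[k][0], intervals[k][1] - intervals[k][0]),
        )
        trace.append(alphas)
        selected.append(k_star)
        s, e = intervals[k_star]
        covered.update(range(s, e + 1))
    return CoverDesign(selected=selected, covered=covered, L=L, lam=lam,
                       alpha_trace=trace, regions=list(regions))


def baseline_design(ta, mode: str, lam: float = 1.0, probe_len: int = 12,
                    min_len: int = 9, max_len: int = 16,
                    seed: int | None = None, model: EnergyModel | None = None) -> CoverDesign:
    """Naive comparison designs.

    ``exploration`` draws random fixed-length (12 nt) windows until [1, L] is
    covered; ``exploitation`` runs the greedy cover on min-max-normalized
    biophysical scores with no knowledge-gradient step.
    """
    ta = as_sequence(ta)
    L = len(ta)
    if mode == "exploration":
        rng = np.random.default_rng(seed)
        starts = rng.permutation(L - probe_len + 1) + 1
        covered: set[int] = set()
        chosen = []
        intervals = []
        for s in starts:
            s = int(s)
            iv = set(range(s, s + probe_len))
            if not iv - covered:
                continue
            covered |= iv
            chosen.append(len(intervals))
            intervals.append((s, s + probe_len - 1))
            if covered == set(range(1, L + 1)):
                break
        if covered != set(range(1, L + 1)):
            raise CoverageError(f"random {probe_len}-mers cannot cover [1,{L}]")
        regions = [
            CandidateRegion(ta.id, s, e, ta.residues[s - 1 : e],
                            reverse_complement(ta.residues[s - 1 : e]))
            for s, e in intervals
        ]
        return CoverDesign(selected=chosen, covered=covered, L=L, lam=0.0,
                           alpha_trace=[{k: 0.0} for k in chosen], regions=regions)
    if mode == "exploitation":
        regions = enumerate_candidate_regions(ta, min_len, max_len)
        scores = score_regions(regions, ta, model)
        nu = np.array([s.nu for s in scores])
        rng = nu.max() - nu.min()
        v = (nu - nu.min()) / rng if rng > 0 else np.zeros_like(nu)
        design = greedy_set_cover(regions, v, lam=lam, L=L)
        return design
    raise ValueError(f"mode must be 'exploration' or 'exploitation', got {mode!r}")


def experimental_effort(selected_truth, all_truth) -> float:
    """Raw experimental effort of one design on one molecule.

    ``max(all_truth) - max(selected_truth)``: how far the best probed region
    falls short of the molecule's truly most accessible region (0 when the
    optimum was probed).
    """
    selected_truth = np.asarray(selected_truth, dtype=float)
    all_truth = np.asarray(all_truth, dtype=float)
    if selected_truth.size == 0:
        raise ValueError("empty selection")
    return float(all_truth.max() - selected_truth.max())


def rescale_efforts(efforts: dict[str, float]) -> dict[str, float]:
    """Min-max rescale per-algorithm efforts to [0, 1] for comparison."""
    vals = np.array(list(efforts.values()), dtype=float)
    span = vals.max() - vals.min()
    if span == 0:
        return {k: 0.0 for k in efforts}
    return {k: float((x - vals.min()) / span) for k, x in zip(efforts, vals)}


def top_fraction(values, fraction: float = 0.015) -> np.ndarray:
    """Indices of the top `fraction` of a global value ranking (>= 1 kept)."""
    values = np.asarray(values, dtype=float)
    n_keep = max(1, int(round(fraction * values.size)))
    return np.argsort(values)[::-1][:n_keep]
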