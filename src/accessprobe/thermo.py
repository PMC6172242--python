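"""Nucleic-acid folding thermodynamics for antisense probe design.

This module supplies every free-energy and probability term consumed by the
hybridization-efficacy score: per-nucleotide unpaired probabilities from a
McCaskill-style partition function, the cost of forcing a target region open,
the probe:target duplex energy, and the probe self-folding minimum free
energy.

The energy model is deliberately simple — additive per-pair energies
(GC/AU/GU), a minimum hairpin loop, no stacking or loop terms — so that every
quantity can be verified against exhaustive structure enumeration on short
sequences (:func:`enumerate_structures`).  The engine is pluggable: a
nearest-neighbour backend can be registered under a name and selected via
``thermo.backend`` without any API change (see :data:`BACKENDS`).

Structure space: nested (pseudoknot-free) sets of Watson-Crick + GU pairs
with hairpin loops of at least ``min_hairpin_loop`` unpaired nucleotides.
Coordinates in the public API are 1-based closed intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NucleotideSequence",
    "EnergyModel",
    "FoldEnsemble",
    "pair_probabilities",
    "unpaired_profile",
    "duplex_energy",
    "opening_energy",
    "probe_folding_energy",
    "enumerate_structures",
    "reverse_complement",
    "BACKENDS",
    "get_backend",
]

_VALID = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Canonical pairs; both orientations are filled in EnergyModel.__post_init__.
_DEFAULT_PAIR_ENERGY = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}


class SequenceError(ValueError):
    """Input sequence violates the RNA alphabet or length contract."""


class IntervalError(ValueError):
    """A 1-based closed interval falls outside the sequence bounds."""


def _normalize(residues: str) -> str:
    s = residues.strip().upper().replace("T", "U")
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise SequenceError(f"invalid residues {sorted(bad)} (alphabet ACGU/T)")
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence over {A,C,G,U}; DNA T is normalized to U on input."""

    residues: str
    id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", _normalize(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def subsequence(self, start: int, end: int, id: str | None = None) -> "NucleotideSequence":
        """1-based closed subinterval as a new sequence."""
        _check_interval(len(self), start, end)
        return NucleotideSequence(self.residues[start - 1 : end], id or f"{self.id}[{start},{end}]")


def as_sequence(seq) -> NucleotideSequence:
    return seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(str(seq))


def reverse_complement(seq) -> str:
    s = _normalize(str(seq))
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class EnergyModel:
    """Additive per-pair RNA energy model.

    Parameters
    ----------
    pair_energy:
        kcal/mol per formed pair, keyed by unordered pair type. Defaults
        GC −3.0, AU −2.0, GU −1.0.
    min_hairpin_loop:
        minimum unpaired nucleotides enclosed by a hairpin-closing pair.
    RT:
        gas constant times temperature, kcal/mol (0.616 ≈ 37 °C).
    """

    pair_energy: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_ENERGY))
    min_hairpin_loop: int = 3
    RT: float = 0.616

    def __post_init__(self):
        table = {}
        for (a, b), e in self.pair_energy.items():
            if not math.isfinite(e) or e > 0:
                raise ValueError(f"pair energy for {a}{b} must be finite and <= 0, got {e}")
            table[(a, b)] = e
            table[(b, a)] = e
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        if not self.RT > 0:
            raise ValueError("RT must be > 0")
        object.__setattr__(self, "pair_energy", table)

    def energy(self, a: str, b: str) -> float | None:
        """Energy of pairing bases a:b, or None if they cannot pair."""
        return self.pair_energy.get((a, b))


@dataclass
class FoldEnsemble:
    """Equilibrium ensemble summary for one sequence.

    ``Z`` counts the empty structure, so ``Z >= 1`` and
    ``ensemble_dG = -RT ln Z <= 0``.  ``unpaired_prob[i] = 1 - sum_j
    pair_prob[i, j]``.
    """

    sequence: NucleotideSequence
    model: EnergyModel
    Z: float
    ensemble_dG: float
    pair_prob: np.ndarray
    unpaired_prob: np.ndarray


def _check_interval(n: int, start: int, end: int) -> None:
    if not (1 <= start <= end <= n):
        raise IntervalError(f"interval [{start},{end}] outside [1,{n}]")


def _weight_matrix(s: str, model: EnergyModel, forbidden=()) -> np.ndarray:
    """Boltzmann weight of pair (i,j) (0-based), honoring the loop constraint.

    Positions in ``forbidden`` (0-based) are barred from pairing.
    """
    n = len(s)
    W = np.zeros((n, n))
    blocked = set(forbidden)
    for i in range(n):
        if i in blocked:
            continue
        for j in range(i + model.min_hairpin_loop + 1, n):
            if j in blocked:
                continue
            e = model.energy(s[i], s[j])
            if e is not None:
                W[i, j] = math.exp(-e / model.RT)
    return W


def _inside(W: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Inside recursion.

    Returns Q with 1-based indexing: ``Q[i, j]`` is the (scaled) partition
    function of closed interval [i, j]; empty intervals (j < i) are 1.
    With ``scale = s``, each nucleotide carries weight 1/s and each pair
    w/s², so ``Q[1, n] = Z / s**n`` — used to keep large-n recursions in
    float range (log-space equivalent).
    """
    n = W.shape[0]
    u = 1.0 / scale
    Q = np.ones((n + 2, n + 1))
    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            # j unpaired, plus j paired to k in [i, j)
            acc = Q[i, j - 1] * u
            ks = np.arange(i, j)
            w = W[ks - 1, j - 1] * (u * u)
            nz = w > 0
            if nz.any():
                ks = ks[nz]
                acc += float(np.dot(Q[i, ks - 1] * w[nz], Q[ks + 1, j - 1]))
            Q[i, j] = acc
    return Q


def _pick_scale(s: str, model: EnergyModel) -> float:
    # Linear-domain recursion overflows once Z ~ e^709; rescale per
    # nucleotide by the MFE density so both Z and the unstructured state
    # stay representable for sRNA-scale inputs.
    n = len(s)
    if n <= 200:
        return 1.0
    mfe = _mfe(s, model)
    return math.exp(-mfe / (model.RT * n) / 2.0)


def _mfe(s: str, model: EnergyModel) -> float:
    n = len(s)
    M = np.zeros((n + 2, n + 1))
    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            best = M[i, j - 1]
            for k in range(i, j):
                e = model.energy(s[k - 1], s[j - 1])
                if e is not None and j - k - 1 >= model.min_hairpin_loop:
                    cand = M[i, k - 1] + e + M[k + 1, j - 1]
                    if cand < best:
                        best = cand
                M[i, j] = best
    return float(M[1, n])


def pair_probabilities(seq, model: EnergyModel | None = None) -> FoldEnsemble:
    """Equilibrium pair probabilities by inside/outside recursions.

    O(n³) inside; the outside pass conditions each pair on its innermost
    enclosing pair, which factorizes exactly under the additive pair-energy
    model.
    """
    seq = as_sequence(seq)
    model = model or EnergyModel()
    s = seq.residues
    n = len(s)
    scale = _pick_scale(s, model)
    W = _weight_matrix(s, model)
    Q = _inside(W, scale)
    Z_scaled = Q[1, n]
    logZ = math.log(Z_scaled) + n * math.log(scale)

    u = 1.0 / scale
    Ws = W * (u * u)
    # Qb[i, j] (1-based): scaled partition over structures on [i, j] with i:j paired
    Qb = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if Ws[i - 1, j - 1] > 0:
                Qb[i, j] = Ws[i - 1, j - 1] * Q[i + 1, j - 1]

    # Outside: Qout[i, j] = weight of everything outside pair (i, j),
    # either fully exterior or directly inside an enclosing pair (h, l).
    P = np.zeros((n, n))
    Qout = np.zeros((n + 1, n + 1))
    for span in range(n, 1, -1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            if Qb[i, j] == 0:
                continue
            out = Q[1, i - 1] * Q[j + 1, n]
            if i > 1 and j < n:
                # sum over enclosing pairs h < i, l > j
                hs = np.arange(1, i)
                ls = np.arange(j + 1, n + 1)
                M = Qout[np.ix_(hs, ls)] * Ws[np.ix_(hs - 1, ls - 1)]
                if M.any():
                    qleft = Q[hs + 1, i - 1]
                    qright = Q[j + 1, ls - 1]
                    out += float(qleft @ M @ qright)
            Qout[i, j] = out
            P[i - 1, j - 1] = Qb[i, j] * out / Z_scaled
    P = P + P.T
    unpaired = 1.0 - P.sum(axis=1)
    np.clip(unpaired, 0.0, 1.0, out=unpaired)
    return FoldEnsemble(
        sequence=seq,
        model=model,
        Z=math.exp(logZ) if logZ < 700 else math.inf,
        ensemble_dG=-model.RT * logZ,
        pair_prob=P,
        unpaired_prob=unpaired,
    )


def unpaired_profile(ens: FoldEnsemble, start: int, end: int) -> np.ndarray:
    """Unpaired probabilities restricted to 1-based closed [start, end]."""
    _check_interval(len(ens.sequence), start, end)
    return ens.unpaired_prob[start - 1 : end].copy()


def duplex_energy(probe, target_region, model: EnergyModel | None = None) -> float:
    """ΔG of the perfect probe:target duplex (ΔG_asT), kcal/mol.

    The probe must be the exact reverse complement of the target region —
    that is how the reporter probes are designed — so the duplex energy is
    the plain sum of per-pair energies over the full length.
    """
    probe = as_sequence(probe)
    target_region = as_sequence(target_region)
    model = model or EnergyModel()
    if probe.residues != reverse_complement(target_region.residues):
        raise SequenceError("probe is not the exact reverse complement of the target region")
    total = 0.0
    for a, b in zip(probe.residues, reversed(target_region.residues)):
        e = model.energy(a, b)
        if e is None:  # unreachable for a true reverse complement
            raise SequenceError(f"non-pairing duplex column {a}:{b}")
        total += e
    return total


def opening_energy(seq, start: int, end: int, model: EnergyModel | None = None) -> float:
    """Free-energy cost ΔG_tf >= 0 of forcing [start, end] fully unpaired.

    ΔG_tf = -RT ln(Z_constrained / Z), where the constrained ensemble
    contains only structures in which every nucleotide of the interval is
    unpaired.
    """
    seq = as_sequence(seq)
    model = model or EnergyModel()
    s = seq.residues
    n = len(s)
    _check_interval(n, start, end)
    scale = _pick_scale(s, model)
    Z = _inside(_weight_matrix(s, model), scale)[1, n]
    Zc = _inside(_weight_matrix(s, model, forbidden=range(start - 1, end)), scale)[1, n]
    return max(0.0, -model.RT * (math.log(Zc) - math.log(Z)))


def probe_folding_energy(probe, model: EnergyModel | None = None) -> float:
    """Minimum free energy of probe self-structure (ΔG_asF <= 0).

    Probes are designed at 9-26 nt; other lengths are accepted with a
    warning so the library can score off-design candidates.
    """
    probe = as_sequence(probe)
    model = model or EnergyModel()
    if not 9 <= len(probe) <= 26:
        warnings.warn(
            f"probe length {len(probe)} outside the 9-26 nt design range",
            stacklevel=2,
        )
    return _mfe(probe.residues, model)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (testing only; small n)
# ---------------------------------------------------------------------------

_ORACLE_MAX_N = 18


def enumerate_structures(seq, model: EnergyModel | None = None):
    """Exhaustively enumerate all nested structures of a short sequence.

    Returns ``(structures, Z, pair_prob, unpaired_prob, mfe)`` where
    ``structures`` is a list of ``(pairs, energy)`` with ``pairs`` a tuple of
    1-based (i, j) pairs.  Exact Boltzmann sums; refuses n > 18.
    """
    seq = as_sequence(seq)
    model = model or EnergyModel()
    s = seq.residues
    n = len(s)
    if n > _ORACLE_MAX_N:
        raise ValueError(f"enumeration oracle limited to n <= {_ORACLE_MAX_N}, got {n}")

    memo: dict[tuple[int, int], list[tuple[tuple, float]]] = {}

    def rec(i: int, j: int):
        # all structures on 0-based closed [i, j] as (pairs, energy)
        if j - i + 1 <= model.min_hairpin_loop:
            return [((), 0.0)]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [(p, e) for p, e in rec(i, j - 1)]
        for k in range(i, j - model.min_hairpin_loop):
            e_pair = model.energy(s[k], s[j])
            if e_pair is None:
                continue
            for pl, el in rec(i, k - 1) if k > i else [((), 0.0)]:
                for pr, er in rec(k + 1, j - 1):
                    out.append((pl + ((k + 1, j + 1),) + pr, el + e_pair + er))
        memo[key] = out
        return out

    structures = rec(0, n - 1) if n else [((), 0.0)]
    weights = np.array([math.exp(-e / model.RT) for _, e in structures])
    Z = float(weights.sum())
    P = np.zeros((n, n))
    for (pairs, _), w in zip(structures, weights):
        for i, j in pairs:
            P[i - 1, j - 1] += w
    P /= Z
    P = P + P.T
    unpaired = 1.0 - P.sum(axis=1)
    mfe = min(e for _, e in structures)
    return structures, Z, P, unpaired, mfe


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

BACKENDS: dict[str, object] = {"builtin": pair_probabilities}
"""Registered folding backends, keyed by the ``thermo.backend`` config value.

A backend is a callable ``(seq, model) -> FoldEnsemble``; register a
nearest-neighbour engine here to swap the physics without touching callers.
"""


def get_backend(name: str = "builtin"):
    try:
        return BACKENDS[name]
    except KeyError:
        raise KeyError(f"unknown thermo backend {name!r}; registered: {sorted(BACKENDS)}") from None
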