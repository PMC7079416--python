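"""RNA secondary-structure prediction backends.

Two backends produce the quantities the structure features need — the
minimum free energy (MFE), one MFE structure in dot-bracket notation, and
the base-pair probability matrix of the Boltzmann ensemble:

``simple``
    A self-contained Nussinov/McCaskill-style dynamic program under a
    deliberately minimal energy model: every admissible pair (Watson-Crick
    plus G·U wobble) contributes -1, unpaired bases contribute 0, hairpin
    loops span at least three unpaired bases, no pseudoknots, and the
    Boltzmann factor is exp(-E) at unit temperature.  Every number it
    produces can be checked exactly against :func:`exhaustive_oracle`,
    which enumerates all secondary structures of a short sequence.

``turner``
    An adapter around the ViennaRNA library (nearest-neighbour
    thermodynamic parameters at 37 °C), for runs that should mirror
    RNAfold-derived statistics on real pre-miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldResult",
    "FoldingError",
    "BackendUnavailableError",
    "fold",
    "builtin_fold",
    "turner_fold",
    "exhaustive_oracle",
]

#: pairs admitted by the built-in model (Watson-Crick + wobble)
ALLOWED_PAIRS = frozenset(
    {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
)

#: minimal number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN_LOOP = 3

#: energy of one pair in the built-in model (arbitrary units)
PAIR_ENERGY = -1.0

RNA_ALPHABET = frozenset("ACGU")


class FoldingError(ValueError):
    """Invalid input to a folding routine."""


class BackendUnavailableError(RuntimeError):
    """The requested folding backend cannot run in this environment."""


@dataclass(frozen=True)
class FoldResult:
    """Secondary-structure summary of one sequence.

    Attributes
    ----------
    mfe:
        Minimum free energy; ``<= 0`` because the open chain scores 0 and
        is always admissible.  kcal/mol for the ``turner`` backend,
        dimensionless pair counts (times -1) for ``simple``.
    structure:
        Dot-bracket string of one MFE structure, same length as the
        sequence.
    bpp:
        Symmetric ``L x L`` matrix of Boltzmann pair probabilities.
    """

    mfe: float
    structure: str
    bpp: np.ndarray = field(repr=False)

    @property
    def n_pairs(self) -> int:
        """Number of base pairs in the MFE structure."""
        return self.structure.count("(")


def _check_sequence(seq: str) -> str:
    if not seq:
        raise FoldingError("cannot fold an empty sequence")
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise FoldingError(
            f"sequence contains characters outside A/C/G/U: {sorted(bad)}"
        )
    return seq


def _pairable_matrix(seq: str) -> np.ndarray:
    """Boolean matrix: True where (i, j) may pair (loop constraint included)."""
    n = len(seq)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if (seq[i], seq[j]) in ALLOWED_PAIRS:
                pairable[i, j] = True
    return pairable


# ---------------------------------------------------------------------------
# built-in backend
# ---------------------------------------------------------------------------

def _mfe_matrix(pairable: np.ndarray) -> np.ndarray:
    """Interval DP for the minimum energy under the built-in model.

    E[i, j] = min( E[i+1, j],
                   min_k pairable(i,k): PAIR_ENERGY + E[i+1, k-1] + E[k+1, j] )
    """
    n = pairable.shape[0]
    # E[i, j+1] holds the optimum over seq[i..j]; the padding row/column
    # makes empty intervals read as 0 without branching.
    E = np.zeros((n + 1, n + 1))
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j + 1]
            ks = np.nonzero(pairable[i, : j + 1])[0]
            if ks.size:
                cand = PAIR_ENERGY + E[i + 1, ks] + E[ks + 1, j + 1]
                m = cand.min()
                if m < best:
                    best = m
            E[i, j + 1] = best
    return E


def _traceback(E: np.ndarray, pairable: np.ndarray) -> list[tuple[int, int]]:
    """Recover one MFE structure; co-optimal ties resolved by preferring the
    pair with the smallest 5' index, then the smallest 3' index."""
    n = pairable.shape[0]

    def get(i: int, j: int) -> float:
        return E[i, j + 1] if i <= j else 0.0

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = get(i, j)
        if target == 0.0 and not pairable[i : j + 1, i : j + 1].any():
            continue
        paired = False
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not pairable[i, k]:
                continue
            if PAIR_ENERGY + get(i + 1, k - 1) + get(k + 1, j) == target:
                pairs.append((i, k))
                # push right segment first so the left is traced first
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def _partition_inside(pairable: np.ndarray) -> np.ndarray:
    """Inside partition function Z[i, j+1] over seq[i..j], empty interval = 1."""
    n = pairable.shape[0]
    w = math.exp(-PAIR_ENERGY)  # Boltzmann weight of one pair
    # Z[i, j+1] covers seq[i..j]; untouched cells stay 1 = empty interval.
    Z = np.ones((n + 2, n + 2))
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            total = Z[i + 1, j + 1]
            ks = np.nonzero(pairable[i, : j + 1])[0]
            if ks.size:
                total += w * float(Z[i + 1, ks] @ Z[ks + 1, j + 1])
            Z[i, j + 1] = total
    return Z


def _pair_probabilities(pairable: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Exact Boltzmann pair probabilities via an outside recursion.

    Zhat[i, j] sums the weights of all structures on the positions outside
    [i, j] that are compatible with (i, j) being paired; the innermost pair
    enclosing (i, j), if any, splits the exterior into independent
    intervals, giving

        Zhat[i,j] = Z[0,i-1] * Z[j+1,n-1]
                  + w * sum_{k<i, l>j pairable} Z[k+1,i-1] * Z[j+1,l-1] * Zhat[k,l]

    evaluated from the widest (i, j) inward.  p_ij = w * Z[i+1,j-1] * Zhat[i,j] / Z.
    """
    n = pairable.shape[0]
    w = math.exp(-PAIR_ENERGY)
    Ztot = Z[0, n]
    bpp = np.zeros((n, n))
    # widest pairs first: Zhat(i, j) only consults strictly enclosing pairs
    spans = sorted(np.argwhere(pairable).tolist(), key=lambda ij: ij[0] - ij[1])
    weighted = np.zeros((n, n))  # pairable * Zhat, filled as we go
    for i, j in spans:
        ext = Z[0, i] * Z[j + 1, n]
        if i > 0 and j < n - 1:
            # contraction over all enclosing pairable (k, l):
            # left[k] = Z over (k, i), right[l] = Z over (j, l) interiors
            ext += w * Z[1 : i + 1, i] @ weighted[:i, j + 1 :] @ Z[j + 1, j + 1 : n]
        weighted[i, j] = ext
        p = w * Z[i + 1, j] * ext / Ztot
        bpp[i, j] = p
        bpp[j, i] = p
    return bpp


def builtin_fold(seq: str) -> FoldResult:
    """Fold under the built-in pair-counting model (backend id ``simple``).

    MFE and traceback by interval dynamic programming; pair probabilities
    by the exact inside/outside partition-function recursion at unit
    temperature.  Deterministic, dependency-free, and exactly verifiable by
    :func:`exhaustive_oracle` on short sequences.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    pairable = _pairable_matrix(seq)
    if not pairable.any():
        return FoldResult(0.0, "." * n, np.zeros((n, n)))
    E = _mfe_matrix(pairable)
    pairs = _traceback(E, pairable)
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    Z = _partition_inside(pairable)
    bpp = _pair_probabilities(pairable, Z)
    return FoldResult(float(E[0, n]), "".join(structure), bpp)


# ---------------------------------------------------------------------------
# thermodynamic backend
# ---------------------------------------------------------------------------

def turner_fold(seq: str) -> FoldResult:
    """Fold with ViennaRNA nearest-neighbour parameters (backend id ``turner``).

    Uses default ViennaRNA model settings (37 °C, current Turner parameter
    set).  Requires the ``RNA`` Python bindings.
    """
    seq = _check_sequence(seq)
    try:
        import RNA  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise BackendUnavailableError(
            "the 'turner' backend needs the ViennaRNA Python bindings; "
            "install them with: pip install ViennaRNA"
        ) from exc
    fc = RNA.fold_compound(seq)
    structure, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    fc.pf()
    n = len(seq)
    upper = np.asarray(fc.bpp())[1:, 1:]  # ViennaRNA is 1-based, upper triangular
    bpp = upper + upper.T
    return FoldResult(float(mfe), structure, bpp)


_BACKENDS = {"simple": builtin_fold, "turner": turner_fold}


def fold(seq: str, backend: str = "simple") -> FoldResult:
    """Fold ``seq`` with the named backend (``simple`` or ``turner``)."""
    try:
        impl = _BACKENDS[backend]
    except KeyError:
        raise FoldingError(
            f"unknown folding backend {backend!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return impl(seq)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def exhaustive_oracle(seq: str, max_len: int = 26) -> FoldResult:
    """Exact fold of a short sequence by enumerating every structure.

    Enumerates all pseudoknot-free structures respecting the hairpin-loop
    constraint, under the same energy model as :func:`builtin_fold`, and
    returns the exact MFE, one MFE structure (ties broken toward the
    lexicographically smallest sorted pair list, which matches the DP
    traceback preference for small 5' then 3' indices), and exact Boltzmann
    pair probabilities.  Intended as an independent oracle for tests; cost
    grows exponentially with length.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    if n > max_len:
        raise FoldingError(
            f"sequence of length {n} exceeds the oracle limit of {max_len}"
        )
    pairable = _pairable_matrix(seq)

    cache: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def enum(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if i >= j:
            return [()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not pairable[i, k]:
                continue
            for inner in enum(i + 1, k - 1):
                for outer in enum(k + 1, j):
                    out.append(((i, k),) + inner + outer)
        cache[key] = out
        return out

    structures = enum(0, n - 1)
    w = math.exp(-PAIR_ENERGY)
    Z = 0.0
    pair_weight = np.zeros((n, n))
    best_energy = 0.0
    best_pairs: tuple[tuple[int, int], ...] = ()
    for pairs in structures:
        e = PAIR_ENERGY * len(pairs)
        key = tuple(sorted(pairs))
        if e < best_energy or (e == best_energy and key < tuple(sorted(best_pairs))):
            best_energy = e
            best_pairs = pairs
        weight = w ** len(pairs)
        Z += weight
        for i, j in pairs:
            pair_weight[i, j] += weight
    bpp = pair_weight / Z
    bpp = bpp + bpp.T
    structure = ["."] * n
    for i, j in best_pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(best_energy, "".join(structure), bpp)
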