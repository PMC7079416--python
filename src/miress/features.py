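"""The 38-feature vector describing one pre-miRNA / mature-miRNA record.

The vector concatenates three blocks:

* 14 legacy sequence/structure features: base contents (U/C/G) of the
  pre-miRNA, the mature region(s) and the non-mature remainder, the three
  region lengths, the minimum free energy (MFE) and its per-length variant
  (nMFE), and a three-valued cleavage-site class encoding whether the 5'
  base of every / some / no mature product is U.
* 18 dinucleotide frequencies: the nine A-free pairs SZ with S, Z in
  {U, C, G}, counted over all overlapping windows, separately for the
  pre-miRNA and for the mature sequence.
* 6 partition-function statistics of the pre-miRNA: base-pairing
  propensity P, Shannon entropy of the pair probabilities Q, expected
  base-pair distance D — each already divided by the sequence length —
  plus their divided-once-more variants nP, nQ, nD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import MiRNARecord
from .folding import FoldResult, fold

__all__ = [
    "FEATURE_NAMES",
    "DINUCLEOTIDES",
    "FeatureVector",
    "FeatureError",
    "base_content",
    "dinucleotide_frequencies",
    "locate_mature",
    "locate_all_matures",
    "non_mature_region",
    "cleavage_site_class",
    "structure_features",
    "extract_features",
]


class FeatureError(ValueError):
    """Invalid input to a feature computation."""


#: the nine tracked dinucleotides (A-free), row-major over (U, C, G)
DINUCLEOTIDES = ("UU", "UC", "UG", "CU", "CC", "CG", "GU", "GC", "GG")

#: canonical order of the 38 features
FEATURE_NAMES: tuple[str, ...] = (
    "pre_U",
    "pre_C",
    "pre_G",
    "mat_len",
    "mat_U",
    "mat_C",
    "mat_G",
    "nonmat_len",
    "nonmat_U",
    "nonmat_C",
    "nonmat_G",
    "MFE",
    "nMFE",
    "cleavage_class",
    *(f"pre_{d}" for d in DINUCLEOTIDES),
    *(f"mat_{d}" for d in DINUCLEOTIDES),
    "P",
    "nP",
    "Q",
    "nQ",
    "D",
    "nD",
)

#: identity required for an inexact mature placement
MATURE_MIN_IDENTITY = 0.9


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric description of one record.

    ``values`` follows :data:`FEATURE_NAMES`; ``label`` is the essentiality
    class (1 essential, 0 non-essential) when known.
    """

    id: str
    values: np.ndarray
    label: int | None = None

    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(FEATURE_NAMES),):
            raise FeatureError(
                f"{self.id}: expected {len(FEATURE_NAMES)} feature values, "
                f"got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise FeatureError(f"{self.id}: non-finite feature values")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def base_content(seq: str, base: str) -> float:
    """Fraction of positions in ``seq`` equal to ``base``."""
    if not seq:
        raise FeatureError("base content of an empty sequence is undefined")
    if base not in {"U", "C", "G", "A"}:
        raise FeatureError(f"unknown base {base!r}")
    return seq.count(base) / len(seq)


def dinucleotide_frequencies(seq: str) -> dict[str, float]:
    """Frequencies of the nine A-free dinucleotides in ``seq``.

    Every overlapping window of length 2 counts toward the denominator
    ``len(seq) - 1``, including windows containing A; only the nine
    {U, C, G} x {U, C, G} pairs are reported.
    """
    if len(seq) < 2:
        raise FeatureError("dinucleotide frequencies need a sequence of length >= 2")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    denom = len(seq) - 1
    return {d: c / denom for d, c in counts.items()}


def locate_mature(pre_seq: str, mature_seq: str) -> tuple[int, int]:
    """Locate one mature product within its precursor (0-based, half-open).

    Exact leftmost substring match first; failing that, the leftmost
    ungapped window with the highest identity, accepted only at >= 0.9.
    """
    if not pre_seq or not mature_seq:
        raise FeatureError("cannot locate an empty sequence")
    if len(mature_seq) > len(pre_seq):
        raise FeatureError("mature sequence longer than precursor")
    pos = pre_seq.find(mature_seq)
    if pos >= 0:
        return pos, pos + len(mature_seq)
    m = len(mature_seq)
    best_pos, best_id = 0, -1.0
    for start in range(len(pre_seq) - m + 1):
        window = pre_seq[start : start + m]
        ident = sum(a == b for a, b in zip(window, mature_seq)) / m
        if ident > best_id:
            best_pos, best_id = start, ident
    if best_id < MATURE_MIN_IDENTITY:
        raise FeatureError(
            f"best ungapped identity {best_id:.3f} below {MATURE_MIN_IDENTITY}"
        )
    return best_pos, best_pos + m


def locate_all_matures(record: MiRNARecord) -> list[tuple[int, int]]:
    """Locate every annotated mature; intervals must not overlap."""
    intervals: list[tuple[int, int]] = []
    for mat_id, mat_seq in record.matures:
        try:
            intervals.append(locate_mature(record.pre_seq, mat_seq))
        except FeatureError as exc:
            raise FeatureError(f"{record.id}/{mat_id}: {exc}") from None
    ordered = sorted(intervals)
    for (a0, a1), (b0, _) in zip(ordered, ordered[1:]):
        if b0 < a1:
            raise FeatureError(f"{record.id}: mature intervals overlap")
    return intervals


def non_mature_region(pre_seq: str, mature_intervals: Sequence[tuple[int, int]]) -> str:
    """Concatenation (5' to 3') of precursor positions outside all matures."""
    covered = np.zeros(len(pre_seq), dtype=bool)
    for start, end in mature_intervals:
        if not (0 <= start <= end <= len(pre_seq)):
            raise FeatureError(f"interval [{start}, {end}) outside precursor")
        covered[start:end] = True
    return "".join(b for b, c in zip(pre_seq, covered) if not c)


def cleavage_site_class(record: MiRNARecord) -> int:
    """Three-valued class of the mature 5'-terminal bases.

    1 if every mature of the precursor starts with U, -1 if none does,
    0 otherwise.  The 5' end of the mature is where Drosha/Dicer cleave.
    """
    if not record.matures:
        raise FeatureError(f"{record.id}: no mature annotated")
    first = [seq[0] for _, seq in record.matures]
    if all(b == "U" for b in first):
        return 1
    if all(b != "U" for b in first):
        return -1
    return 0


def structure_features(
    fold_result: FoldResult, length: int
) -> tuple[float, float, float, float, float, float, float, float]:
    """(MFE, nMFE, P, nP, Q, nQ, D, nD) from one fold of a length-L precursor.

    P = pairs in the MFE structure / L; Q = -(1/L) sum p_ij log2 p_ij over
    i < j with p_ij > 0; D = (1/L) sum p_ij (1 - p_ij) over i < j.  The
    n-variants divide once more by L.
    """
    if len(fold_result.structure) != length:
        raise FeatureError(
            f"fold is for length {len(fold_result.structure)}, record has {length}"
        )
    L = length
    mfe = fold_result.mfe
    P = fold_result.n_pairs / L
    iu = np.triu_indices(L, k=1)
    p = fold_result.bpp[iu]
    nz = p[p > 0]
    Q = float(-(nz * np.log2(nz)).sum() / L) if nz.size else 0.0
    D = float((p * (1.0 - p)).sum() / L)
    return (mfe, mfe / L, P, P / L, Q, Q / L, D, D / L)


def _contents(seq: str) -> tuple[float, float, float]:
    if not seq:
        return (0.0, 0.0, 0.0)
    return tuple(base_content(seq, b) for b in ("U", "C", "G"))  # type: ignore[return-value]


def extract_features(record: MiRNARecord, backend: str = "simple") -> FeatureVector:
    """Compute the full 38-feature vector for one record.

    Mature-derived features use the 5'-to-3' concatenation of all annotated
    matures; the non-mature block uses the remaining precursor positions.
    """
    if "N" in record.pre_seq or any("N" in m for _, m in record.matures):
        raise FeatureError(f"{record.id}: ambiguous base N; record excluded")
    try:
        intervals = locate_all_matures(record)
        order = np.argsort([s for s, _ in intervals])
        mat_seq = "".join(record.pre_seq[intervals[i][0] : intervals[i][1]] for i in order)
        nonmat_seq = non_mature_region(record.pre_seq, intervals)
        fr = fold(record.pre_seq, backend=backend)
        mfe, nmfe, P, nP, Q, nQ, D, nD = structure_features(fr, len(record.pre_seq))
        pre_dinuc = dinucleotide_frequencies(record.pre_seq)
        mat_dinuc = dinucleotide_frequencies(mat_seq)
        values = [
            *_contents(record.pre_seq),
            float(len(mat_seq)),
            *_contents(mat_seq),
            float(len(nonmat_seq)),
            *_contents(nonmat_seq),
            mfe,
            nmfe,
            float(cleavage_site_class(record)),
            *(pre_dinuc[d] for d in DINUCLEOTIDES),
            *(mat_dinuc[d] for d in DINUCLEOTIDES),
            P,
            nP,
            Q,
            nQ,
            D,
            nD,
        ]
    except FeatureError:
        raise
    except Exception as exc:  # attach the record id to backend errors
        raise FeatureError(f"{record.id}: {exc}") from exc
    return FeatureVector(id=record.id, values=np.array(values), label=record.label)
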