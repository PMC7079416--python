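"""Reading and writing the formats the pipeline touches.

FASTA in/out goes through Biopython; label tables and feature tables
through pandas.  Sequences are normalised to the RNA alphabet on read
(uppercase, T -> U), so downstream code only ever sees A/C/G/U (plus N,
which excludes a record from feature extraction).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MiRNARecord",
    "DataError",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "assemble_dataset",
    "write_feature_table",
    "read_feature_table",
    "table_to_arrays",
]

VALID_INPUT = frozenset("ACGUN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class MiRNARecord:
    """One pre-miRNA with its annotated mature product(s).

    ``pre_seq`` and every mature sequence are RNA-alphabet strings; every
    mature must be locatable within the precursor.  ``label`` is 1 for
    essential, 0 for non-essential, None when unknown.
    """

    id: str
    pre_seq: str
    matures: list[tuple[str, str]] = field(default_factory=list)
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.pre_seq:
            raise DataError(f"{self.id}: empty precursor sequence")
        if self.matures:
            longest = max(len(seq) for _, seq in self.matures)
            if longest > len(self.pre_seq):
                raise DataError(f"{self.id}: mature longer than precursor")
        if self.label is not None and self.label not in (0, 1):
            raise DataError(f"{self.id}: label must be 0 or 1, got {self.label!r}")


def _normalise(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - VALID_INPUT
    if bad:
        raise DataError(
            f"record {record_id!r}: characters outside A/C/G/U/T/N: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file into (id, sequence) pairs.

    Sequences are uppercased and DNA-style T is converted to U; order is
    preserved.  An empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise DataError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
    out: list[tuple[str, str]] = []
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out.append((rec.id, _normalise(str(rec.seq), rec.id)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column id/label table (TSV or CSV, header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] != 2:
        raise DataError(f"{path}: expected exactly 2 columns, found {df.shape[1]}")
    # drop a header row (non-numeric second field, e.g. "label")
    try:
        int(df.iloc[0, 1].strip())
    except ValueError:
        df = df.iloc[1:]
        if df.empty:
            raise DataError(f"{path}: no label rows") from None
    labels: dict[str, int] = {}
    for _, (rid, raw) in df.iterrows():
        rid = rid.strip()
        raw = raw.strip()
        if raw not in {"0", "1"}:
            raise DataError(f"{path}: label for {rid!r} must be 0 or 1, got {raw!r}")
        if rid in labels:
            raise DataError(f"{path}: duplicate id {rid!r}")
        labels[rid] = int(raw)
    return labels


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    """Write an id -> label map as a two-column TSV."""
    with Path(path).open("w") as handle:
        for rid, lab in labels.items():
            handle.write(f"{rid}\t{lab}\n")


_ARM_SUFFIX = re.compile(r"(-5p|-3p|\*)$", re.IGNORECASE)


def _stem(name: str) -> str:
    """Matching stem of a miRNA name: lowercase, arm suffix and the
    mir/miR token collapsed (miRBase names the hairpin mir and the mature
    miR)."""
    s = _ARM_SUFFIX.sub("", name.strip().lower())
    return s.replace("mir-", "").replace("mir", "", 1) if "mir" in s else s


def assemble_dataset(
    pre_records: Sequence[tuple[str, str]],
    mature_records: Sequence[tuple[str, str]],
    labels: Mapping[str, int] | None = None,
) -> list[MiRNARecord]:
    """Join precursor and mature sequences into labelled records.

    A mature is attached to a precursor by exact id equality first, then by
    case-insensitive stem match (arm suffixes -5p/-3p/* and the mir/miR
    token stripped).  Precursors without any mature are dropped with a
    warning; unmatched matures are reported the same way.
    """
    if not pre_records:
        raise DataError("no precursor records given")
    by_exact: dict[str, list[tuple[str, str]]] = {rid: [] for rid, _ in pre_records}
    by_stem: dict[str, list[str]] = {}
    by_copy_stem: dict[str, list[str]] = {}
    for rid, _ in pre_records:
        stem = _stem(rid)
        by_stem.setdefault(stem, []).append(rid)
        # hairpin copies (e.g. the -1 of mir-1a-1) share their matures
        copy_stripped = re.sub(r"-\d+$", "", stem)
        if copy_stripped != stem:
            by_copy_stem.setdefault(copy_stripped, []).append(rid)

    unmatched: list[str] = []
    for mid, mseq in mature_records:
        stem = _stem(mid)
        hits = [mid] if mid in by_exact else by_stem.get(stem) or by_copy_stem.get(stem, [])
        if hits:
            for rid in hits:
                by_exact[rid].append((mid, mseq))
        else:
            unmatched.append(mid)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} mature sequence(s) matched no precursor: "
            f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}"
        )

    out: list[MiRNARecord] = []
    dropped: list[str] = []
    for rid, seq in pre_records:
        matures = by_exact[rid]
        if not matures:
            dropped.append(rid)
            continue
        label = labels.get(rid) if labels else None
        out.append(MiRNARecord(id=rid, pre_seq=seq, matures=matures, label=label))
    if dropped:
        warnings.warn(
            f"{len(dropped)} precursor(s) had no mature and were dropped: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not out:
        raise DataError("no records could be assembled from the inputs")
    return out


def write_feature_table(vectors: Sequence, path: str | Path) -> None:
    """Write feature vectors as a TSV: id, the 38 features, optional label.

    Values survive a write/read round trip at 12 significant digits.
    """
    from .features import FEATURE_NAMES  # local import to avoid a cycle

    rows = []
    has_labels = any(v.label is not None for v in vectors)
    for v in vectors:
        if v.values.shape != (len(FEATURE_NAMES),):
            raise DataError(f"{v.id}: inconsistent feature vector length")
        row = {"id": v.id, **dict(zip(FEATURE_NAMES, v.values))}
        if has_labels:
            row["label"] = v.label
        rows.append(row)
    columns = ["id", *FEATURE_NAMES] + (["label"] if has_labels else [])
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    from .features import FEATURE_NAMES

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing[:3]}...")
    return df


def table_to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None, list[str], list[str]]:
    """Split a feature table into (X, y, feature_names, ids); y is None
    when the table carries no label column."""
    from .features import FEATURE_NAMES

    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
    return X, y, list(FEATURE_NAMES), df["id"].astype(str).tolist()
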