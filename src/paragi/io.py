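"""Readers and writers for the tab-separated interchange formats.

All on-disk formats are plain TSV:

- counts: header row, first column = array id, remaining columns = integer
  read counts per sample;
- annotation: columns ``array_id, gene1, gene2, control_class`` (blank
  ``gene2`` marks a single-knockout construct);
- gene sets: one symbol per line;
- reference SL pairs: two gene columns;
- percent-identity table: ``gene_a, gene_b, pct_identity_ab,
  pct_identity_ba`` (directional values averaged at load);
- scores: long format, one row per (pair, screen), columns as in
  :data:`paragi.core.SCORE_COLUMNS`. The missing-value marker is the
  empty string.
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    SCORE_COLUMNS,
    ControlClass,
    CountMatrix,
    GIScoreTable,
    LibraryAnnotation,
    PairKey,
    ReferenceSets,
)

__all__ = [
    "read_counts",
    "read_annotation",
    "read_gene_set",
    "read_sl_pairs",
    "read_reference_sets",
    "read_identity_table",
    "read_expression",
    "write_scores",
    "read_scores",
    "write_counts",
    "write_annotation",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def read_counts(path: str | PathLike, t0_name: str) -> CountMatrix:
    """Read a raw read-count TSV and validate it into a :class:`CountMatrix`.

    Counts must be non-negative integers; violations are hard errors naming
    the offending row and column. Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate array id {dup!r}")
    out = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-integer count {df.loc[row, col]!r} at "
                f"array {row!r}, sample {col!r}")
        if (numeric < 0).any():
            row = df.index[numeric < 0][0]
            raise ValueError(
                f"{path}: negative count {df.loc[row, col]} at "
                f"array {row!r}, sample {col!r}")
        out[col] = numeric.astype(np.int64)
    counts = pd.DataFrame(out, index=df.index)
    counts.index.name = None  # in-memory matrices carry no index label
    return CountMatrix(counts=counts, t0_sample=t0_name)


def write_counts(cm: CountMatrix, path: str | PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="array_id")


def read_annotation(path: str | PathLike) -> LibraryAnnotation:
    """Read a library annotation TSV.

    Expected columns: ``array_id, gene1, gene2, control_class``; a blank
    ``gene2`` marks a single-knockout array. ``construct_class`` is inferred
    from the number of non-blank targets. A pair of identical genes or an
    unknown control token is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"array_id", "gene1", "gene2", "control_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns "
                         f"{sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        ctrl = row["control_class"] or "none"
        try:
            ControlClass(ctrl)
        except ValueError:
            raise ValueError(
                f"{path}: unknown control_class {ctrl!r} for array "
                f"{row['array_id']!r}") from None
        g2 = row["gene2"].strip() or None
        if g2 is not None and g2 == row["gene1"].strip():
            raise ValueError(
                f"{path}: array {row['array_id']!r} pairs gene "
                f"{g2!r} with itself")
        records.append((row["array_id"], row["gene1"].strip(), g2, ctrl))
    return LibraryAnnotation.from_records(records)


def write_annotation(ann: LibraryAnnotation, path: str | PathLike) -> None:
    df = ann.table.reset_index()
    df = df[["array_id", "gene1", "gene2", "control_class"]].copy()
    df["gene2"] = df["gene2"].fillna("")
    df["control_class"] = [ControlClass(c).value
                           for c in df["control_class"]]
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | PathLike) -> frozenset[str]:
    """Read a gene set: one symbol per line, blanks ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_sl_pairs(path: str | PathLike) -> frozenset[PairKey]:
    """Read a two-column TSV of reference synthetic-lethal gene pairs.

    A header line whose first field is ``gene_a`` or ``gene1`` is skipped.
    """
    pairs: set[PairKey] = set()
    with open(path) as fh:
        for n, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if n == 0 and fields[0].lower() in {"gene_a", "gene1"}:
                continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: line {n + 1}: expected two gene "
                                 f"columns, got {line!r}")
            pairs.add(PairKey.of(fields[0], fields[1]))
    return frozenset(pairs)


def read_reference_sets(
    essential_path: str | PathLike,
    nonessential_path: str | PathLike,
    sl_pairs_path: str | PathLike | None = None,
) -> ReferenceSets:
    return ReferenceSets(
        essential_genes=read_gene_set(essential_path),
        nonessential_genes=read_gene_set(nonessential_path),
        reference_sl_pairs=(read_sl_pairs(sl_pairs_path)
                            if sl_pairs_path is not None else frozenset()),
    )


def read_identity_table(path: str | PathLike) -> dict[PairKey, float]:
    """Read paralog percent-sequence-identity, averaging the two directions.

    Expected columns ``gene_a, gene_b, pct_identity_ab, pct_identity_ba``.
    Because alignment identity is asymmetric (it is computed relative to
    each sequence's length), the two directional values are averaged into
    one number per unordered pair. Values must lie in [0, 100].
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "pct_identity_ab", "pct_identity_ba"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: identity table missing columns "
                         f"{sorted(missing)}")
    acc: dict[PairKey, list[float]] = {}
    for _, row in df.iterrows():
        mean_id = (float(row["pct_identity_ab"])
                   + float(row["pct_identity_ba"])) / 2.0
        if not 0.0 <= mean_id <= 100.0:
            raise ValueError(
                f"{path}: identity {mean_id} outside [0, 100] for pair "
                f"({row['gene_a']}, {row['gene_b']})")
        acc.setdefault(PairKey.of(row["gene_a"], row["gene_b"]),
                       []).append(mean_id)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def read_expression(path: str | PathLike) -> pd.DataFrame:
    """Read a gene x cell-line expression matrix (log2 TPM), genes as rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene {dup!r} in expression "
                         f"matrix")
    return df.astype(float)


def write_scores(table: GIScoreTable, path: str | PathLike) -> None:
    """Write a score table as long-format TSV.

    One row per (pair, screen); missing scores are written as the empty
    string. Floats are rendered with 12 significant digits so the table
    round-trips losslessly through :func:`read_scores`.
    """
    df = table.data.copy()
    for c in ("hit_dlfc", "hit_zdlfc", "hit_rdlfc"):
        df[c] = df[c].map({True: "True", False: "False"})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              na_rep="")


def read_scores(path: str | PathLike) -> GIScoreTable:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str,
                                            "screen": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: score table missing columns {missing}")
    for c in ("hit_dlfc", "hit_zdlfc", "hit_rdlfc"):
        df[c] = df[c].map({"True": True, "False": False, True: True,
                           False: False})
    return GIScoreTable(df)
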