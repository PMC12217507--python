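"""Shared domain types for paralog genetic-interaction scoring.

The data model mirrors a multiplex CRISPR knockout screen: a read-count
matrix per screen (arrays x samples, one T0 column), a library annotation
mapping each array to its target gene or gene pair, reference gene sets
used as controls, and a long-format score table holding the three
interaction scores (dLFC, ZdLFC, RdLFC) per pair per screen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PairKey",
    "ConstructClass",
    "ControlClass",
    "CountMatrix",
    "LibraryAnnotation",
    "ReferenceSets",
    "GIScoreTable",
    "HitThresholds",
    "SCORE_COLUMNS",
]


class PairKey(NamedTuple):
    """Order-invariant identifier for a gene pair.

    ``gene_a`` always sorts before ``gene_b``, so (A, B) and (B, A) map to
    the same key. Construct via :meth:`of` to enforce the canonical order.
    """

    gene_a: str
    gene_b: str

    @classmethod
    def of(cls, a: str, b: str) -> "PairKey":
        if a == b:
            raise ValueError(f"self-pair is not a valid gene pair: {a!r}")
        return cls(a, b) if a < b else cls(b, a)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene_a}|{self.gene_b}"


class ConstructClass(str, Enum):
    SINGLE = "single"
    PAIR = "pair"


class ControlClass(str, Enum):
    ESSENTIAL = "essential_ctrl"
    NONESSENTIAL = "nonessential_ctrl"
    NONE = "none"


@dataclass
class CountMatrix:
    """Raw (or normalized) read counts for one screen.

    Parameters
    ----------
    counts
        arrays x samples matrix; index = array ids, columns = sample ids.
        Integer reads for raw data; floats allowed after normalization.
    t0_sample
        Name of the reference (T0) column. All remaining columns are
        endpoint samples.
    """

    counts: pd.DataFrame
    t0_sample: str

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate array id: {dup!r}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if self.t0_sample not in self.counts.columns:
            raise ValueError(f"t0 sample {self.t0_sample!r} not among samples "
                             f"{list(self.counts.columns)}")
        if self.counts.shape[1] < 2:
            raise ValueError("count matrix needs at least one endpoint sample "
                             "besides T0")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("count matrix contains non-finite values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count {vals[i, j]} at array {idx[i]!r}, "
                f"sample {self.counts.columns[j]!r}")

    @property
    def array_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def endpoint_samples(self) -> list[str]:
        return [s for s in self.counts.columns if s != self.t0_sample]


@dataclass
class LibraryAnnotation:
    """Maps each array id to its target gene(s) and control status.

    ``table`` is indexed by array id with columns ``gene1``, ``gene2``
    (None for single constructs), ``construct_class`` and ``control_class``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene1", "gene2", "construct_class", "control_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate array id in annotation: {dup!r}")
        for aid, row in self.table.iterrows():
            cc = row["construct_class"]
            if cc == ConstructClass.PAIR:
                if not row["gene2"] or row["gene2"] == row["gene1"]:
                    raise ValueError(
                        f"array {aid!r}: pair construct must target two "
                        f"distinct genes")
            elif cc == ConstructClass.SINGLE:
                if row["gene2"]:
                    raise ValueError(
                        f"array {aid!r}: single construct with two targets")
            else:
                raise ValueError(f"array {aid!r}: bad construct_class {cc!r}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str | None, str]],
    ) -> "LibraryAnnotation":
        """Build from (array_id, gene1, gene2_or_None, control_class) rows.

        ``construct_class`` is inferred from the number of targets.
        """
        rows = []
        for aid, g1, g2, ctrl in records:
            g2 = g2 or None
            cc = ConstructClass.PAIR if g2 else ConstructClass.SINGLE
            rows.append((aid, g1, g2, cc, ControlClass(ctrl)))
        df = pd.DataFrame(
            rows, columns=["array_id", "gene1", "gene2", "construct_class",
                           "control_class"],
        ).set_index("array_id")
        return cls(df)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, array_id: str) -> bool:
        return array_id in self.table.index

    def target_key(self, array_id: str) -> tuple[str, ...]:
        """Canonical target-set key: ``(gene,)`` or sorted ``(a, b)``."""
        row = self.table.loc[array_id]
        if row["construct_class"] == ConstructClass.PAIR:
            return tuple(PairKey.of(row["gene1"], row["gene2"]))
        return (row["gene1"],)

    def target_keys(self) -> pd.Series:
        """Target-set key per array, aligned with the annotation index."""
        return pd.Series(
            [self.target_key(a) for a in self.table.index],
            index=self.table.index, name="target_key",
        )

    def pairs(self) -> set[PairKey]:
        """All distinct gene pairs targeted by pair constructs."""
        mask = self.table["construct_class"] == ConstructClass.PAIR
        return {
            PairKey.of(g1, g2)
            for g1, g2 in zip(self.table.loc[mask, "gene1"],
                              self.table.loc[mask, "gene2"])
        }

    def single_arrays(self, control: ControlClass | None = None) -> list[str]:
        mask = self.table["construct_class"] == ConstructClass.SINGLE
        if control is not None:
            mask &= self.table["control_class"] == control
        return list(self.table.index[mask])

    def validate_against(self, cm: CountMatrix) -> None:
        """Every array in a count matrix must be annotated."""
        unknown = set(cm.array_ids) - set(self.table.index)
        if unknown:
            raise ValueError(
                f"{len(unknown)} array id(s) in counts missing from "
                f"annotation, e.g. {sorted(unknown)[:3]}")


@dataclass(frozen=True)
class ReferenceSets:
    """Reference gene sets: essential / nonessential QC controls and the
    positive-control synthetic-lethal pairs used by RdLFC rescaling."""

    essential_genes: frozenset[str] = frozenset()
    nonessential_genes: frozenset[str] = frozenset()
    reference_sl_pairs: frozenset[PairKey] = frozenset()

    def __post_init__(self) -> None:
        both = self.essential_genes & self.nonessential_genes
        if both:
            raise ValueError(
                f"genes in both essential and nonessential sets: "
                f"{sorted(both)[:5]}")
        object.__setattr__(
            self, "essential_genes", frozenset(self.essential_genes))
        object.__setattr__(
            self, "nonessential_genes", frozenset(self.nonessential_genes))
        object.__setattr__(
            self, "reference_sl_pairs",
            frozenset(PairKey.of(*p) for p in self.reference_sl_pairs))


@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling cutoffs. All are strict upper bounds: a hit requires the
    score to fall strictly below the cut.

    Defaults follow the published screen analysis: raw method dLFC < -1
    with pair LFC < -1; Z method ZdLFC < -2 with ZLFC < -2; rescaled
    method RdLFC < -0.7 with ZLFC < -2.
    """

    dlfc_cut: float = -1.0
    lfc_cut: float = -1.0
    zdlfc_cut: float = -2.0
    zlfc_cut: float = -2.0
    rdlfc_cut: float = -0.7


#: Column order of the long-format score table (one row per pair per screen).
SCORE_COLUMNS = [
    "gene_a", "gene_b", "screen",
    "observed_lfc", "expected_lfc", "dlfc", "zlfc", "zdlfc", "rdlfc",
    "hit_dlfc", "hit_zdlfc", "hit_rdlfc",
]

_FLOAT_COLS = ["observed_lfc", "expected_lfc", "dlfc", "zlfc", "zdlfc",
               "rdlfc"]
_HIT_COLS = ["hit_dlfc", "hit_zdlfc", "hit_rdlfc"]


@dataclass
class GIScoreTable:
    """Per-pair, per-screen genetic-interaction scores in long format.

    Invariants: ``dlfc = observed_lfc - expected_lfc`` wherever both are
    present; ``zdlfc`` is an affine transform of ``dlfc`` per screen;
    ``rdlfc`` is populated only when a reference SL set was supplied.
    Missing scores are NaN; hit flags are nullable booleans.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        self.data = self.data[SCORE_COLUMNS].reset_index(drop=True)
        for c in _FLOAT_COLS:
            self.data[c] = self.data[c].astype(float)
        for c in _HIT_COLS:
            self.data[c] = self.data[c].astype("boolean")

    @classmethod
    def empty(cls) -> "GIScoreTable":
        return cls(pd.DataFrame(columns=SCORE_COLUMNS))

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[pd.Series]:  # pragma: no cover
        return (row for _, row in self.data.iterrows())

    @property
    def screens(self) -> list[str]:
        return list(dict.fromkeys(self.data["screen"]))

    @property
    def pair_keys(self) -> pd.Series:
        return pd.Series(
            [PairKey(a, b) for a, b in zip(self.data["gene_a"],
                                           self.data["gene_b"])],
            index=self.data.index,
        )

    def for_screen(self, screen: str) -> pd.DataFrame:
        return self.data[self.data["screen"] == screen]

    def scoreable_pairs(self, screen: str,
                        column: str = "dlfc") -> set[PairKey]:
        """Pairs with a finite score of the given kind in this screen."""
        sub = self.for_screen(screen)
        ok = np.isfinite(sub[column].to_numpy(dtype=float))
        return {PairKey(a, b)
                for a, b in zip(sub.loc[ok, "gene_a"], sub.loc[ok, "gene_b"])}

    def copy(self) -> "GIScoreTable":
        return GIScoreTable(self.data.copy())


def as_pair_keys(pairs: Iterable[tuple[str, str]]) -> set[PairKey]:
    """Canonicalize arbitrary (a, b) tuples into a set of PairKeys."""
    return {PairKey.of(a, b) for a, b in pairs}
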