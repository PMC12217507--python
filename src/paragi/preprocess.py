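"""Raw counts -> log2 fold changes and screen quality control.

The preprocessing chain per screen is: add a pseudocount to every array in
every sample, depth-normalize each sample to a fixed total read count,
take log2 of endpoint over T0 per array (averaging replicate endpoints at
the LFC level), then aggregate arrays to their exact target set (a single
gene, or a canonical gene pair) by the arithmetic mean.

Screen quality is summarized by Cohen's D between the single-knockout
LFC distributions of nonessential and essential control genes:

    D = (mean LFC_nonessential - mean LFC_essential) / pooled sd

with the pooled standard deviation using sample (n-1) variances. A larger
D means cleaner separation of the control distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ControlClass, CountMatrix, LibraryAnnotation, ReferenceSets

__all__ = [
    "normalize_counts",
    "guide_lfc",
    "aggregate_gene_lfc",
    "FoldChangeTable",
    "QCReport",
    "qc_cohens_d",
    "pooled_cohens_d",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_DEPTH",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 5
DEFAULT_DEPTH = 1e7


@dataclass
class FoldChangeTable:
    """Guide-level and target-level LFCs across one or more screens.

    ``guide`` is arrays x screens; ``gene`` is target-set keys x screens,
    where a key is ``(gene,)`` for singles and the canonically ordered
    ``(gene_a, gene_b)`` for pairs. Every ``gene`` value is the arithmetic
    mean of the guide values of the arrays targeting exactly that set.
    """

    guide: pd.DataFrame
    gene: pd.DataFrame | None = None

    @property
    def screens(self) -> list[str]:
        return list(self.guide.columns)

    def gene_value(self, target: tuple[str, ...], screen: str) -> float:
        """Aggregated LFC for one exact target set in one screen.

        Ragged tuple keys sit in an object index, which pandas label
        indexing mishandles; this goes through a plain dict instead.
        """
        if self.gene is None:
            raise ValueError("gene-level LFCs not aggregated yet")
        d = self.gene[screen].to_dict()
        if target not in d:
            raise KeyError(f"no LFC for target set {target!r} in "
                           f"screen {screen!r}")
        return float(d[target])


def normalize_counts(
    cm: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    depth: float = DEFAULT_DEPTH,
) -> pd.DataFrame:
    """Pseudocount and depth-normalize a count matrix.

    Each sample column s becomes ``depth * (n_is + pc) / sum_i (n_is + pc)``
    so every column sums to ``depth`` exactly (to floating tolerance).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = cm.counts.astype(float) + pseudocount
    colsums = shifted.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(
            f"sample {zero.index[0]!r} has zero total reads after "
            f"pseudocount {pseudocount}; cannot depth-normalize")
    return shifted.div(colsums, axis=1) * depth


def guide_lfc(norm: pd.DataFrame, t0_sample: str) -> pd.Series:
    """Guide-level log2 fold change of endpoint(s) versus T0 for one screen.

    With several endpoint columns the per-endpoint LFCs are averaged per
    array, keeping each replicate's own depth normalization.
    """
    if t0_sample not in norm.columns:
        raise ValueError(f"t0 sample {t0_sample!r} not in normalized matrix")
    endpoints = [c for c in norm.columns if c != t0_sample]
    if not endpoints:
        raise ValueError("no endpoint sample to compare against T0")
    t0 = norm[t0_sample]
    if (t0 <= 0).any():
        bad = t0.index[t0 <= 0][0]
        raise ValueError(
            f"non-positive T0 abundance for array {bad!r}; use a positive "
            f"pseudocount")
    lfcs = pd.DataFrame(
        {e: np.log2(norm[e] / t0) for e in endpoints})
    return lfcs.mean(axis=1)


def aggregate_gene_lfc(
    fct: FoldChangeTable, ann: LibraryAnnotation
) -> FoldChangeTable:
    """Average guide-level LFCs over arrays sharing an exact target set.

    Single-gene arrays and pair arrays never mix: the key for a single
    array is ``(gene,)`` and for a pair array the canonical two-gene tuple,
    so a single-gene LFC for gene A excludes pair arrays containing A.
    Target sets with no arrays are simply absent from the output.
    """
    unknown = set(fct.guide.index) - set(ann.table.index)
    if unknown:
        raise ValueError(
            f"{len(unknown)} array(s) in fold-change table missing from "
            f"annotation, e.g. {sorted(unknown)[:3]}")
    keys = [ann.target_key(a) for a in fct.guide.index]
    gene = fct.guide.groupby(pd.Index(keys, name="target", tupleize_cols=False)).mean()
    return FoldChangeTable(guide=fct.guide, gene=gene)


def pooled_cohens_d(group1: np.ndarray, group2: np.ndarray) -> float | None:
    """Cohen's D = (mean1 - mean2) / pooled sd, sample-variance convention.

    Returns None (undefined) when either group has < 2 values or the
    pooled standard deviation is zero.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    x1 = x1[np.isfinite(x1)]
    x2 = x2[np.isfinite(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        return None
    s1, s2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return None
    return float((x1.mean() - x2.mean()) / pooled)


@dataclass
class QCReport:
    """Per-screen screen-quality summary from control singles.

    ``cohens_d[screen]`` is None when undefined (too few controls or zero
    pooled sd), in which case the screen also appears in ``undefined``.
    """

    cohens_d: dict[str, float | None]
    n_essential_ctrl: int
    n_nonessential_ctrl: int
    level: str = "gene"
    undefined: set[str] = field(default_factory=set)


def _control_values(
    fct: FoldChangeTable,
    ann: LibraryAnnotation,
    refs: ReferenceSets,
    control: ControlClass,
    level: str,
) -> pd.DataFrame:
    """LFC rows for one control group, at guide or gene level."""
    flagged = ann.single_arrays(control)
    if flagged:
        arrays = [a for a in flagged if a in fct.guide.index]
        genes = sorted({ann.target_key(a)[0] for a in arrays})
    else:
        # fall back to reference-set membership among single-gene targets
        ref_genes = (refs.essential_genes
                     if control == ControlClass.ESSENTIAL
                     else refs.nonessential_genes)
        arrays = [a for a in ann.single_arrays()
                  if a in fct.guide.index and ann.target_key(a)[0] in ref_genes]
        genes = sorted({ann.target_key(a)[0] for a in arrays})
    if level == "guide":
        return fct.guide.loc[arrays]
    if fct.gene is None:
        raise ValueError("gene-level QC requires aggregated LFCs; run "
                         "aggregate_gene_lfc first or use level='guide'")
    keys = [(g,) for g in genes if (g,) in fct.gene.index]
    return fct.gene.loc[keys]


def qc_cohens_d(
    fct: FoldChangeTable,
    ann: LibraryAnnotation,
    refs: ReferenceSets,
    level: str = "gene",
) -> QCReport:
    """Screen QC: Cohen's D between nonessential- and essential-control LFCs.

    ``level`` selects guide-level or gene-level control values (default
    gene-level). Requires at least two values per group per screen; a
    degenerate pooled sd yields an undefined flag rather than a number.
    """
    if level not in ("gene", "guide"):
        raise ValueError(f"level must be 'gene' or 'guide', got {level!r}")
    ess = _control_values(fct, ann, refs, ControlClass.ESSENTIAL, level)
    non = _control_values(fct, ann, refs, ControlClass.NONESSENTIAL, level)
    report = QCReport(cohens_d={}, n_essential_ctrl=len(ess),
                      n_nonessential_ctrl=len(non), level=level)
    for screen in fct.guide.columns:
        d = pooled_cohens_d(non[screen].to_numpy(), ess[screen].to_numpy())
        report.cohens_d[screen] = d
        if d is None:
            report.undefined.add(screen)
            logger.warning("Cohen's D undefined for screen %s "
                           "(degenerate controls)", screen)
    return report
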