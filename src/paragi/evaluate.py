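"""Cross-screen consistency of hit sets and secondary evaluations.

With no accepted gold standard for paralog synthetic lethality, scoring
methods are compared by how reproducible their hit calls are across
screens of different cell lines: the Jaccard coefficient
|A∩B| / |A∪B| over every unordered pair of screens, summarized by its
median. Secondary views: how many screens each hit recurs in, the median
paralog percent sequence identity per recurrence stratum, the Cohen's D
between strata, and an expression-based plausibility check (fraction of
cell lines in which both genes of a pair are expressed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import PairKey
from .preprocess import pooled_cohens_d

__all__ = [
    "jaccard",
    "consistency",
    "ConsistencyReport",
    "identity_by_frequency",
    "stratum_effect_size",
    "expressed_fraction",
]

logger = logging.getLogger(__name__)


def jaccard(a: set, b: set) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; defined as 0 for two empty sets
    (with a warning, since the ratio is formally 0/0)."""
    union = len(a | b)
    if union == 0:
        logger.warning("jaccard of two empty sets; returning 0 by "
                       "convention")
        return 0.0
    return len(a & b) / union


@dataclass
class ConsistencyReport:
    """Cross-screen hit consistency.

    ``pairwise_jaccard`` maps each unordered screen pair to its Jaccard
    coefficient; ``median_jaccard`` is the median over those (midpoint of
    the two central values for even counts). ``pair_frequency`` counts, for
    every pair in the union of hit sets, the number of screens calling it;
    ``overlap_counts[k]`` is the number of pairs hit in exactly k screens,
    a partition of that union.
    """

    pairwise_jaccard: dict[tuple[str, str], float]
    median_jaccard: float
    pair_frequency: dict[PairKey, int]
    overlap_counts: dict[int, int]
    n_screens: int

    def pairs_hit_in(self, k: int) -> set[PairKey]:
        return {p for p, n in self.pair_frequency.items() if n == k}


def consistency(
    hit_sets: Mapping[str, set[PairKey]],
    universes: Mapping[str, set[PairKey]] | None = None,
) -> ConsistencyReport:
    """Pairwise Jaccard coefficients and recurrence counts over screens.

    When ``universes`` is given (the scoreable pairs per screen), each
    pairwise comparison is restricted to pairs scoreable in *both* screens,
    mirroring an analysis restricted to the library intersection; the
    recurrence counts are likewise computed over pairs scoreable in every
    screen.
    """
    screens = list(hit_sets)
    if len(screens) < 2:
        raise ValueError("consistency requires at least 2 screens")
    pairwise: dict[tuple[str, str], float] = {}
    for s1, s2 in itertools.combinations(screens, 2):
        a, b = set(hit_sets[s1]), set(hit_sets[s2])
        if universes is not None:
            common = set(universes[s1]) & set(universes[s2])
            a, b = a & common, b & common
        pairwise[(s1, s2)] = jaccard(a, b)
    median = float(np.median(list(pairwise.values())))
    sets = {s: set(hit_sets[s]) for s in screens}
    if universes is not None:
        everywhere = set.intersection(*(set(universes[s]) for s in screens))
        sets = {s: h & everywhere for s, h in sets.items()}
    freq: dict[PairKey, int] = {}
    for h in sets.values():
        for p in h:
            freq[p] = freq.get(p, 0) + 1
    overlap = {k: sum(1 for n in freq.values() if n == k)
               for k in range(1, len(screens) + 1)}
    return ConsistencyReport(
        pairwise_jaccard=pairwise, median_jaccard=median,
        pair_frequency=freq, overlap_counts=overlap, n_screens=len(screens))


def identity_by_frequency(
    report: ConsistencyReport,
    ids: Mapping[PairKey, float],
) -> dict[int, float]:
    """Median percent sequence identity of hits per recurrence stratum.

    Pairs absent from the identity table are skipped (logged). Strata with
    no annotated pair are omitted from the result.
    """
    out: dict[int, float] = {}
    n_missing = 0
    for k in range(1, report.n_screens + 1):
        vals = []
        for p in report.pairs_hit_in(k):
            if p in ids:
                vals.append(ids[p])
            else:
                n_missing += 1
        if vals:
            out[k] = float(np.median(vals))
    if n_missing:
        logger.info("%d hit pair(s) lacked a sequence-identity annotation "
                    "and were skipped", n_missing)
    return out


def stratum_effect_size(
    ids_k1: Iterable[float],
    ids_k2: Iterable[float],
) -> float | None:
    """Cohen's D between two identity strata: (mean2 - mean1) / pooled sd.

    Returns None when either stratum has fewer than two values or the
    pooled sd is zero (undefined). Swapping the strata negates the sign.
    """
    return pooled_cohens_d(np.asarray(list(ids_k2), dtype=float),
                           np.asarray(list(ids_k1), dtype=float))


def expressed_fraction(
    pairs: Iterable[PairKey],
    expr: pd.DataFrame,
    cut: float = 2.0,
) -> dict[PairKey, float]:
    """Fraction of cell lines in which BOTH genes of a pair are expressed.

    ``expr`` is a gene x cell-line matrix of log2 TPM; a gene is expressed
    in a cell line when its value strictly exceeds ``cut`` (default
    log2 TPM > 2). Pairs with a gene missing from the matrix are skipped
    and reported.
    """
    out: dict[PairKey, float] = {}
    skipped = []
    above = expr > cut
    for p in sorted({PairKey.of(*q) for q in pairs}):
        if p.gene_a not in expr.index or p.gene_b not in expr.index:
            skipped.append(p)
            continue
        both = above.loc[p.gene_a] & above.loc[p.gene_b]
        out[p] = float(both.mean())
    if skipped:
        logger.info("%d pair(s) had a gene missing from the expression "
                    "matrix and were skipped, e.g. %s", len(skipped),
                    skipped[:3])
    return out
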