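"""End-to-end orchestration: counts -> LFCs -> null models -> scores -> hits.

This is the programmatic entry point tying the stages together, the
equivalent of a screen-analysis driver script. :func:`score_screens` works
on in-memory objects; :func:`run_pipeline` is the file-based counterpart
that reads the TSV inputs, writes the long-format score table, the fitted
model parameters and a :class:`RunManifest` capturing every effective
parameter, input digest and seed, so any run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import io as pio
from .core import (
    CountMatrix,
    GIScoreTable,
    HitThresholds,
    LibraryAnnotation,
    PairKey,
    ReferenceSets,
)
from .evaluate import ConsistencyReport, consistency
from .models import (
    MixtureModel,
    NullModel,
    fit_dlfc_null,
    fit_lfc_mixture,
    write_models,
)
from .preprocess import (
    DEFAULT_DEPTH,
    DEFAULT_PSEUDOCOUNT,
    FoldChangeTable,
    QCReport,
    aggregate_gene_lfc,
    guide_lfc,
    normalize_counts,
    qc_cohens_d,
)
from .scoring import (
    call_hits,
    compute_dlfc,
    compute_rdlfc,
    compute_zdlfc,
    compute_zlfc,
    flag_hits,
)

__all__ = [
    "ScreenScoreResult",
    "score_screens",
    "common_pairs",
    "method_consistency",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_METHOD_COLUMN = {"dlfc": "dlfc", "zdlfc": "zdlfc", "rdlfc": "rdlfc"}


@dataclass
class ScreenScoreResult:
    """Everything one scoring run produces.

    Hit calls are re-derivable from ``table`` and ``thresholds``; the
    fitted per-screen models are kept because the Z-scores are
    uninterpretable without them.
    """

    table: GIScoreTable
    fold_changes: FoldChangeTable
    mixtures: dict[str, MixtureModel]
    nulls: dict[str, NullModel]
    qc: QCReport | None
    thresholds: HitThresholds
    pairs: list[PairKey]

    @property
    def screens(self) -> list[str]:
        return self.table.screens

    def hit_sets(self, method: str = "zdlfc") -> dict[str, set[PairKey]]:
        return call_hits(self.table, self.thresholds, method)

    def universes(self, method: str = "zdlfc") -> dict[str, set[PairKey]]:
        """Scoreable pairs per screen for a method (its hit universe)."""
        col = _METHOD_COLUMN[method]
        return {s: self.table.scoreable_pairs(s, col) for s in self.screens}


def common_pairs(gene_lfc: pd.DataFrame) -> set[PairKey]:
    """Pairs scoreable in every screen: the pair row and both single-gene
    rows exist with finite values in all columns."""
    finite = gene_lfc.notna().all(axis=1)
    keys = set(gene_lfc.index[finite])
    out = set()
    for key in keys:
        if len(key) == 2 and (key[0],) in keys and (key[1],) in keys:
            out.add(PairKey(*key))
    return out


def score_screens(
    counts: Mapping[str, CountMatrix],
    annotation: LibraryAnnotation,
    references: ReferenceSets | None = None,
    thresholds: HitThresholds = HitThresholds(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    depth: float = DEFAULT_DEPTH,
    seed: int = 0,
    pairs: set[PairKey] | None = None,
) -> ScreenScoreResult:
    """Score genetic interactions across one or more screens.

    Per screen: depth-normalize counts, compute guide LFCs (replicate
    endpoints averaged), aggregate to target sets, fit the two-component
    LFC mixture on all guide LFCs (seeded ``seed + screen index``), fit
    the Tukey-trimmed dLFC null on the scored pair set, then fill dLFC,
    ZLFC, ZdLFC and (when reference SL pairs are supplied) RdLFC, and
    flag hits at ``thresholds``.

    ``pairs`` defaults to the pairs scoreable in *every* screen, mirroring
    an analysis restricted to the library intersection.
    """
    if not counts:
        raise ValueError("no screens supplied")
    guide_cols = {}
    for screen, cm in counts.items():
        annotation.validate_against(cm)
        norm = normalize_counts(cm, pseudocount=pseudocount, depth=depth)
        guide_cols[screen] = guide_lfc(norm, cm.t0_sample)
    guide_df = pd.DataFrame(guide_cols)
    fct = aggregate_gene_lfc(FoldChangeTable(guide=guide_df), annotation)

    qc: QCReport | None = None
    refs = references or ReferenceSets()
    try:
        qc = qc_cohens_d(fct, annotation, refs)
    except ValueError:
        logger.info("screen QC skipped (no usable control singles)")

    if pairs is None:
        pairs = common_pairs(fct.gene)
        logger.info("scoring %d pairs common to all %d screens",
                    len(pairs), len(counts))
    else:
        pairs = {PairKey.of(*p) for p in pairs}

    table = compute_dlfc(fct.gene, pairs)

    mixtures: dict[str, MixtureModel] = {}
    nulls: dict[str, NullModel] = {}
    for j, screen in enumerate(table.screens):
        mixtures[screen] = fit_lfc_mixture(
            guide_df[screen].dropna(), seed=seed + j)
        nulls[screen] = fit_dlfc_null(
            table.for_screen(screen)["dlfc"].dropna())
        logger.info(
            "screen %s: LFC null mu=%.3f sd=%.3f w=%.3f; dLFC null "
            "mu=%.3f sd=%.3f (n=%d)", screen,
            mixtures[screen].null_mean, mixtures[screen].null_sd,
            mixtures[screen].weights[mixtures[screen].null_component],
            nulls[screen].mu, nulls[screen].sigma, nulls[screen].n_used)

    table = compute_zlfc(table, mixtures)
    table = compute_zdlfc(table, nulls)
    if refs.reference_sl_pairs:
        table = compute_rdlfc(table, nulls, refs)
    table = flag_hits(table, thresholds)

    return ScreenScoreResult(
        table=table, fold_changes=fct, mixtures=mixtures, nulls=nulls,
        qc=qc, thresholds=thresholds, pairs=sorted(pairs))


def method_consistency(
    result: ScreenScoreResult,
    method: str = "zdlfc",
) -> ConsistencyReport:
    """Cross-screen consistency of a method's hit sets, with each pairwise
    comparison restricted to pairs scoreable in both screens."""
    return consistency(result.hit_sets(method), result.universes(method))


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    parameters: dict
    inputs: dict[str, str]
    version: str = __version__
    seed: int | None = None

    def write(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def digest(path: str | PathLike) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()


def run_pipeline(
    counts_paths: Mapping[str, str | PathLike],
    annotation_path: str | PathLike,
    out_dir: str | PathLike,
    t0_name: str = "T0",
    essential_path: str | PathLike | None = None,
    nonessential_path: str | PathLike | None = None,
    sl_pairs_path: str | PathLike | None = None,
    thresholds: HitThresholds = HitThresholds(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    depth: float = DEFAULT_DEPTH,
    seed: int = 0,
) -> ScreenScoreResult:
    """File-based pipeline: read TSVs, score, write outputs + manifest.

    Writes ``scores.tsv`` (long format), ``lfc_mixtures.json`` and
    ``dlfc_nulls.json`` (fitted null parameters per screen), ``qc.tsv``
    (Cohen's D per screen, when computable) and ``manifest.json`` into
    ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {s: pio.read_counts(p, t0_name)
              for s, p in counts_paths.items()}
    annotation = pio.read_annotation(annotation_path)
    refs = None
    if essential_path and nonessential_path:
        refs = pio.read_reference_sets(essential_path, nonessential_path,
                                       sl_pairs_path)
    elif sl_pairs_path:
        refs = ReferenceSets(reference_sl_pairs=pio.read_sl_pairs(
            sl_pairs_path))
    result = score_screens(counts, annotation, references=refs,
                           thresholds=thresholds, pseudocount=pseudocount,
                           depth=depth, seed=seed)
    pio.write_scores(result.table, out / "scores.tsv")
    write_models(result.mixtures, out / "lfc_mixtures.json")
    write_models(result.nulls, out / "dlfc_nulls.json")
    if result.qc is not None:
        pd.DataFrame({
            "screen": list(result.qc.cohens_d),
            "cohens_d": [result.qc.cohens_d[s] for s in result.qc.cohens_d],
        }).to_csv(out / "qc.tsv", sep="\t", index=False,
                  float_format="%.6g", na_rep="NA")

    input_files = {str(p): RunManifest.digest(p)
                   for p in list(counts_paths.values())
                   + [annotation_path]
                   + [p for p in (essential_path, nonessential_path,
                                  sl_pairs_path) if p]}
    manifest = RunManifest(
        command="run_pipeline",
        parameters={
            "counts": {s: str(p) for s, p in counts_paths.items()},
            "annotation": str(annotation_path),
            "t0_name": t0_name,
            "thresholds": dataclasses.asdict(thresholds),
            "pseudocount": pseudocount,
            "depth": depth,
            "seed": seed,
        },
        inputs=input_files,
        seed=seed,
    )
    manifest.write(out / "manifest.json")
    return result
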