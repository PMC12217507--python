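"""Synthetic multiplex paralog-screen generator with known ground truth.

Emulates the structure of a multi-cell-line combinatorial knockout
screen: single-knockout arrays for every gene (including 50 essential and
50 nonessential control genes), multi-guide pair arrays for a panel of
gene pairs, and negative-binomial sequencing counts for a T0 and an
endpoint sample per simulated cell line.

Fitness model (log2 scale): each essential gene carries a true single-KO
LFC; a pair's true observed LFC is the sum of its members' single LFCs
plus its true interaction dLFC (additive expectation). Synthetic-lethal
pairs carry a negative dLFC in every screen ("common") or in a single
screen ("context-specific"). Each screen multiplies all true effects by a
screen-specific scale factor, reflecting how cell lines differ in growth
rate and editing efficiency, which in real data makes raw-LFC thresholds
screen-dependent.

All randomness descends from one root seed through
``numpy.random.SeedSequence`` spawning: child 0 drives library structure
and truth assignment, child 1 + j drives counts for screen j, so each
screen is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    ControlClass,
    CountMatrix,
    LibraryAnnotation,
    PairKey,
    ReferenceSets,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedScreens",
    "ScreenMetrics",
    "simulate_screens",
    "truth_metrics",
]

LABEL_SL_COMMON = "sl_common"
LABEL_SL_CONTEXT = "sl_context"
LABEL_NULL = "null"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated world.

    Defaults emulate the screens the scoring methods were designed for:
    ~1000 genes with 4-guide single arrays, 500 assayed pairs of which 10%
    are synthetic lethal with a planted dLFC of -2, essential single
    knockouts at LFC -2, 50 + 50 designated control genes, four screens at
    10M reads. ``dispersion`` is the negative-binomial size r
    (var = mu + mu^2 / r); ``math.inf`` gives Poisson counts.
    ``screen_scale_range`` bounds the per-screen multiplier applied to all
    true effect sizes (uniform draw per screen).
    """

    seed: int
    n_genes: int = 1000
    n_pairs: int = 500
    guides_per_construct: int = 4
    n_screens: int = 4
    frac_essential_singles: float = 0.15
    frac_sl_pairs: float = 0.10
    frac_context_specific: float = 0.2
    lfc_essential: float = -2.0
    dlfc_sl: float = -2.0
    guide_noise_sd: float = 0.3
    dispersion: float = 100.0
    depth: float = 1e7
    n_control_each: int = 50
    n_reference_sl: int = 13
    screen_scale_range: tuple[float, float] = (0.5, 1.5)
    t0_name: str = "T0"

    def __post_init__(self) -> None:
        for name in ("frac_essential_singles", "frac_sl_pairs",
                     "frac_context_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_pairs", "guides_per_construct",
                     "n_screens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.guide_noise_sd < 0:
            raise ValueError("guide_noise_sd must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be positive")
        n_ess = round(self.frac_essential_singles * self.n_genes)
        if n_ess < self.n_control_each:
            raise ValueError(
                f"need at least {self.n_control_each} essential genes for "
                f"controls; frac_essential_singles*n_genes = {n_ess}")
        if self.n_genes - n_ess < self.n_control_each:
            raise ValueError("too few nonessential genes for controls")
        lo, hi = self.screen_scale_range
        if not 0 < lo <= hi:
            raise ValueError("screen_scale_range must satisfy 0 < lo <= hi")


@dataclass
class GroundTruth:
    """Planted truth behind a simulated screen set.

    ``single_lfc``: gene x screen true single-knockout LFC.
    ``pair_dlfc``: PairKey x screen true interaction dLFC; a pair's true
    observed LFC is the sum of its members' single LFCs plus this value.
    """

    single_lfc: pd.DataFrame
    pair_dlfc: pd.DataFrame
    labels: dict[PairKey, str]
    active_screen: dict[PairKey, str]
    screen_scales: dict[str, float]

    @property
    def common_sl_pairs(self) -> set[PairKey]:
        return {p for p, l in self.labels.items() if l == LABEL_SL_COMMON}

    @property
    def context_sl_pairs(self) -> set[PairKey]:
        return {p for p, l in self.labels.items() if l == LABEL_SL_CONTEXT}

    @property
    def null_pairs(self) -> set[PairKey]:
        return {p for p, l in self.labels.items() if l == LABEL_NULL}

    def positives(self, screen: str) -> set[PairKey]:
        """True SL pairs in a screen: common pairs plus context pairs
        active there."""
        ctx = {p for p in self.context_sl_pairs
               if self.active_screen[p] == screen}
        return self.common_sl_pairs | ctx

    def negatives(self, screen: str) -> set[PairKey]:
        return set(self.labels) - self.positives(screen)


@dataclass
class SimulatedScreens:
    counts: dict[str, CountMatrix]
    annotation: LibraryAnnotation
    references: ReferenceSets
    truth: GroundTruth
    config: SimConfig

    @property
    def screens(self) -> list[str]:
        return list(self.counts)

    def write(self, outdir: str | PathLike) -> None:
        """Write counts, annotation, reference sets and ground truth as
        TSV/plain-text files under ``outdir``."""
        from . import io as pio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for screen, cm in self.counts.items():
            pio.write_counts(cm, out / f"counts_{screen}.tsv")
        pio.write_annotation(self.annotation, out / "annotation.tsv")
        for name, genes in [("essential", self.references.essential_genes),
                            ("nonessential",
                             self.references.nonessential_genes)]:
            (out / f"{name}_genes.txt").write_text(
                "".join(f"{g}\n" for g in sorted(genes)))
        with open(out / "reference_sl_pairs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for p in sorted(self.references.reference_sl_pairs):
                fh.write(f"{p.gene_a}\t{p.gene_b}\n")
        dl = self.truth.pair_dlfc
        pairs = list(dl.index)
        truth = pd.DataFrame({
            "gene_a": [p[0] for p in pairs],
            "gene_b": [p[1] for p in pairs],
            "label": [self.truth.labels[p] for p in pairs],
            "active_screen": [self.truth.active_screen.get(p, "")
                              for p in pairs],
        })
        for s in dl.columns:
            truth[f"true_dlfc_{s}"] = dl[s].to_numpy()
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             r: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size ``r``
    (var = mean + mean^2/r); Poisson in the r -> inf limit."""
    mean = np.asarray(mean, dtype=float)
    if math.isinf(r):
        return rng.poisson(mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_pairs(rng: np.random.Generator, pool: np.ndarray, n: int,
                  taken: set[PairKey]) -> list[PairKey]:
    out: list[PairKey] = []
    guard = 0
    while len(out) < n:
        a, b = pool[rng.choice(len(pool), size=2, replace=False)]
        pk = PairKey.of(str(a), str(b))
        if pk not in taken:
            taken.add(pk)
            out.append(pk)
        guard += 1
        if guard > 100 * n + 1000:
            raise ValueError("could not sample enough distinct pairs from "
                             "the gene pool")
    return out


def simulate_screens(cfg: SimConfig) -> SimulatedScreens:
    """Generate counts, annotation, reference sets and ground truth.

    Deterministic given ``cfg.seed``: the same configuration reproduces
    byte-identical counts. See the module docstring for the generative
    model.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(1 + cfg.n_screens)
    rng = np.random.default_rng(children[0])

    width = max(4, len(str(cfg.n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(cfg.n_genes)])
    order = rng.permutation(cfg.n_genes)
    n_ess = round(cfg.frac_essential_singles * cfg.n_genes)
    essential = genes[order[:n_ess]]
    nonessential = genes[order[n_ess:]]
    ess_ctrl = set(essential[:cfg.n_control_each])
    non_ctrl = set(nonessential[:cfg.n_control_each])
    ctrl_genes = ess_ctrl | non_ctrl

    screens = [f"screen{j + 1}" for j in range(cfg.n_screens)]
    lo, hi = cfg.screen_scale_range
    scales = rng.uniform(lo, hi, cfg.n_screens)
    scale_of = dict(zip(screens, scales))

    # --- true single-gene LFCs -------------------------------------------
    ess_mask = np.isin(genes, essential)
    single_lfc = pd.DataFrame(
        np.outer(np.where(ess_mask, cfg.lfc_essential, 0.0), scales),
        index=genes, columns=screens)

    # --- pair panel and true dLFCs ---------------------------------------
    n_sl = round(cfg.frac_sl_pairs * cfg.n_pairs)
    taken: set[PairKey] = set()
    sl_pool = np.array([g for g in nonessential if g not in ctrl_genes])
    sl_pairs = _sample_pairs(rng, sl_pool, n_sl, taken)
    null_pool = np.array([g for g in genes if g not in ctrl_genes])
    null_pairs = _sample_pairs(rng, null_pool, cfg.n_pairs - n_sl, taken)
    all_pairs = sl_pairs + null_pairs

    n_ctx = round(cfg.frac_context_specific * n_sl)
    ctx_idx = set(rng.choice(n_sl, size=n_ctx, replace=False).tolist()) \
        if n_ctx else set()
    labels: dict[PairKey, str] = {}
    active: dict[PairKey, str] = {}
    dlfc_rows = []
    for i, pk in enumerate(all_pairs):
        if i < n_sl and i in ctx_idx:
            labels[pk] = LABEL_SL_CONTEXT
            act = screens[int(rng.integers(cfg.n_screens))]
            active[pk] = act
            dlfc_rows.append([cfg.dlfc_sl * scale_of[s] if s == act else 0.0
                              for s in screens])
        elif i < n_sl:
            labels[pk] = LABEL_SL_COMMON
            dlfc_rows.append([cfg.dlfc_sl * scale_of[s] for s in screens])
        else:
            labels[pk] = LABEL_NULL
            dlfc_rows.append([0.0] * cfg.n_screens)
    pair_dlfc = pd.DataFrame(dlfc_rows, columns=screens,
                             index=pd.Index(all_pairs,
                                            tupleize_cols=False))

    # --- library annotation ----------------------------------------------
    records = []
    for g in genes:
        ctrl = (ControlClass.ESSENTIAL.value if g in ess_ctrl
                else ControlClass.NONESSENTIAL.value if g in non_ctrl
                else ControlClass.NONE.value)
        for k in range(cfg.guides_per_construct):
            records.append((f"{g}_g{k + 1}", g, None, ctrl))
    for pk in all_pairs:
        for k in range(cfg.guides_per_construct):
            records.append((f"{pk.gene_a}_{pk.gene_b}_g{k + 1}",
                            pk.gene_a, pk.gene_b, ControlClass.NONE.value))
    annotation = LibraryAnnotation.from_records(records)
    array_ids = list(annotation.table.index)
    n_arrays = len(array_ids)

    # true construct LFC per array per screen
    gene_pos = {g: i for i, g in enumerate(genes)}
    pair_pos = {pk: i for i, pk in enumerate(all_pairs)}
    single_vals = single_lfc.to_numpy()
    dlfc_vals = pair_dlfc.to_numpy()
    construct_lfc = np.empty((n_arrays, cfg.n_screens))
    row = 0
    for g in genes:
        v = single_vals[gene_pos[g]]
        for _ in range(cfg.guides_per_construct):
            construct_lfc[row] = v
            row += 1
    for pk in all_pairs:
        v = (single_vals[gene_pos[pk.gene_a]]
             + single_vals[gene_pos[pk.gene_b]]
             + dlfc_vals[pair_pos[pk]])
        for _ in range(cfg.guides_per_construct):
            construct_lfc[row] = v
            row += 1

    # --- counts per screen ------------------------------------------------
    counts: dict[str, CountMatrix] = {}
    mean0 = cfg.depth / n_arrays
    for j, screen in enumerate(screens):
        rng_j = np.random.default_rng(children[1 + j])
        t0 = _nb_draw(rng_j, np.full(n_arrays, mean0), cfg.dispersion)
        effect = construct_lfc[:, j].copy()
        if cfg.guide_noise_sd > 0:
            effect += rng_j.normal(0.0, cfg.guide_noise_sd, n_arrays)
        ep_mean = mean0 * np.exp2(effect)
        ep = _nb_draw(rng_j, ep_mean, cfg.dispersion)
        cols = {}
        for name, col in ((cfg.t0_name, t0), ("endpoint", ep)):
            total = col.sum()
            if total == 0:
                raise ValueError(f"simulated sample {name} in {screen} has "
                                 f"zero total reads; raise depth")
            cols[name] = np.rint(col * (cfg.depth / total)).astype(np.int64)
        counts[screen] = CountMatrix(
            counts=pd.DataFrame(cols, index=array_ids),
            t0_sample=cfg.t0_name)

    # --- reference sets ----------------------------------------------------
    common = [p for p in sl_pairs if labels[p] == LABEL_SL_COMMON]
    n_ref = min(cfg.n_reference_sl, len(common))
    ref_idx = rng.choice(len(common), size=n_ref, replace=False) \
        if n_ref else np.array([], dtype=int)
    references = ReferenceSets(
        essential_genes=frozenset(ess_ctrl),
        nonessential_genes=frozenset(non_ctrl),
        reference_sl_pairs=frozenset(common[i] for i in sorted(ref_idx)),
    )

    truth = GroundTruth(single_lfc=single_lfc, pair_dlfc=pair_dlfc,
                        labels=labels, active_screen=active,
                        screen_scales=scale_of)
    return SimulatedScreens(counts=counts, annotation=annotation,
                            references=references, truth=truth, config=cfg)


@dataclass
class ScreenMetrics:
    """Hit-calling accuracy against planted truth in one screen.

    ``precision`` is None (undefined) for an empty hit set;
    ``recall_context`` is None when the screen has no active
    context-specific positives. ``fpr`` is false positives over true
    negatives in this screen.
    """

    n_hits: int
    n_positives: int
    tp: int
    fp: int
    precision: float | None
    recall: float
    fpr: float
    recall_common: float
    recall_context: float | None


def truth_metrics(
    hits: Mapping[str, set[PairKey]],
    gt: GroundTruth,
) -> dict[str, ScreenMetrics]:
    """Precision/recall of hit sets against the planted truth, per screen.

    Context-specific SL pairs count as positives only in their active
    screen (and as negatives elsewhere).
    """
    out: dict[str, ScreenMetrics] = {}
    for screen, hs in hits.items():
        hs = {PairKey.of(*p) for p in hs}
        unknown = hs - set(gt.labels)
        if unknown:
            raise ValueError(
                f"screen {screen}: {len(unknown)} hit pair(s) absent from "
                f"ground truth, e.g. {sorted(unknown)[:3]}")
        pos = gt.positives(screen)
        neg = gt.negatives(screen)
        tp = len(hs & pos)
        fp = len(hs - pos)
        common = gt.common_sl_pairs
        ctx = pos - common
        out[screen] = ScreenMetrics(
            n_hits=len(hs), n_positives=len(pos), tp=tp, fp=fp,
            precision=(tp / len(hs)) if hs else None,
            recall=(tp / len(pos)) if pos else 0.0,
            fpr=(fp / len(neg)) if neg else 0.0,
            recall_common=(len(hs & common) / len(common)) if common else 0.0,
            recall_context=(len(hs & ctx) / len(ctx)) if ctx else None,
        )
    return out
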