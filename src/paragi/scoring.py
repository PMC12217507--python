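"""The three genetic-interaction scores and hit calling.

Under an additive (log-scale multiplicative) fitness model the expected
LFC of a pair knockout is the sum of the two single-knockout LFCs. The
residual

    dLFC = observed pair LFC - (LFC_A + LFC_B)

measures genetic interaction; strongly negative dLFC indicates synthetic
lethality. ZdLFC standardizes dLFC against the screen's trimmed Gaussian
null, and RdLFC rescales it so the null mean maps to 0 and the median
dLFC of a positive-control reference SL set maps to -1:

    RdLFC = (dLFC - mu_null) / (mu_null - median(dLFC of REF SL))

Hits are called with strict thresholds, always in conjunction with a
pair-essentiality condition (the dual knockout must itself drop out).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    SCORE_COLUMNS,
    GIScoreTable,
    HitThresholds,
    PairKey,
    ReferenceSets,
)
from .models import MixtureModel, NullModel, z_transform, z_transform_lfc

__all__ = [
    "compute_dlfc",
    "compute_zlfc",
    "compute_zdlfc",
    "compute_rdlfc",
    "call_hits",
    "flag_hits",
    "HIT_METHODS",
]

logger = logging.getLogger(__name__)

HIT_METHODS = ("dlfc", "zdlfc", "rdlfc")


def compute_dlfc(
    gene_lfc: pd.DataFrame,
    pairs: Iterable[PairKey],
) -> GIScoreTable:
    """Observed, expected and delta LFC for each pair in each screen.

    ``gene_lfc`` is the target-level LFC table (target-set tuples x
    screens). For a pair (A, B): expected = LFC_A + LFC_B from the
    single-gene rows, observed = the pair row, dlfc = observed - expected.
    Pairs missing any ingredient in a screen are emitted with NaN scores
    and the reason is logged.
    """
    pairs = sorted({PairKey.of(*p) for p in pairs})
    screens = list(gene_lfc.columns)
    # plain dicts: the target-set index holds ragged tuples, which pandas
    # label lookup handles poorly
    lut = {s: gene_lfc[s].to_dict() for s in screens}
    rows = []
    n_incomplete = 0
    nan = float("nan")
    for pk in pairs:
        for screen in screens:
            col = lut[screen]
            obs = float(col.get(tuple(pk), nan))
            la = float(col.get((pk.gene_a,), nan))
            lb = float(col.get((pk.gene_b,), nan))
            if np.isnan(obs) or np.isnan(la) or np.isnan(lb):
                n_incomplete += 1
                missing = [name for name, v in
                           [("pair", obs), (pk.gene_a, la), (pk.gene_b, lb)]
                           if np.isnan(v)]
                logger.debug("pair %s screen %s unscoreable (missing: %s)",
                             pk, screen, ", ".join(missing))
                expected = dlfc = np.nan
                obs = np.nan if np.isnan(obs) else obs
            else:
                expected = la + lb
                dlfc = obs - expected
            rows.append((pk.gene_a, pk.gene_b, screen, obs, expected, dlfc,
                         np.nan, np.nan, np.nan, pd.NA, pd.NA, pd.NA))
    if n_incomplete:
        logger.info("%d (pair, screen) combinations lacked a pair or "
                    "single-gene LFC and were left unscored", n_incomplete)
    return GIScoreTable(pd.DataFrame(rows, columns=SCORE_COLUMNS))


def compute_zlfc(
    table: GIScoreTable,
    mixtures: Mapping[str, MixtureModel],
) -> GIScoreTable:
    """Fill the ZLFC column: the pair's observed LFC standardized against
    the screen's higher-weight mixture component."""
    out = table.copy()
    for screen, sub in out.data.groupby("screen", sort=False):
        if screen not in mixtures:
            raise KeyError(f"no LFC mixture model for screen {screen!r}")
        out.data.loc[sub.index, "zlfc"] = z_transform_lfc(
            sub["observed_lfc"], mixtures[screen])
    return out


def compute_zdlfc(
    table: GIScoreTable,
    nulls: Mapping[str, NullModel],
) -> GIScoreTable:
    """Fill the ZdLFC column: dLFC standardized by the screen's trimmed
    Gaussian null. Monotone in dLFC within a screen."""
    out = table.copy()
    for screen, sub in out.data.groupby("screen", sort=False):
        if screen not in nulls:
            raise KeyError(f"no dLFC null model for screen {screen!r}")
        nm = nulls[screen]
        out.data.loc[sub.index, "zdlfc"] = z_transform(
            sub["dlfc"], nm.mu, nm.sigma)
    return out


def compute_rdlfc(
    table: GIScoreTable,
    nulls: Mapping[str, NullModel],
    refs: ReferenceSets,
) -> GIScoreTable:
    """Fill the RdLFC column using the positive-control reference SL pairs.

    Per screen: ``rdlfc = (dlfc - mu) / (mu - median(ref dlfcs))`` where
    the reference median is taken over this screen's observed dLFCs of
    the reference pairs. By construction rdlfc(mu) = 0 and rdlfc(reference
    median) = -1. Screens with no scored reference pair are left NaN with
    a warning; a reference median at or above mu makes the rescaling
    meaningless and is an error.
    """
    if not refs.reference_sl_pairs:
        raise ValueError("compute_rdlfc requires a non-empty reference SL "
                         "pair set")
    out = table.copy()
    keys = out.pair_keys
    is_ref = keys.isin(refs.reference_sl_pairs)
    for screen, sub in out.data.groupby("screen", sort=False):
        nm = nulls[screen]
        ref_dlfcs = sub.loc[is_ref[sub.index], "dlfc"].dropna()
        if ref_dlfcs.empty:
            logger.warning("screen %s: no reference SL pair has a dLFC; "
                           "RdLFC omitted for this screen", screen)
            continue
        med = float(ref_dlfcs.median())
        denom = nm.mu - med
        if denom <= 0:
            raise ValueError(
                f"screen {screen}: reference-set median dLFC ({med:.4g}) is "
                f"not below the null mean ({nm.mu:.4g}); rescaling "
                f"meaningless")
        out.data.loc[sub.index, "rdlfc"] = (sub["dlfc"] - nm.mu) / denom
    return out


def call_hits(
    table: GIScoreTable,
    th: HitThresholds = HitThresholds(),
    method: str = "zdlfc",
) -> dict[str, set[PairKey]]:
    """Call synthetic-lethal hits per screen for one scoring method.

    All comparisons are strict. Conditions per method:

    - ``dlfc``: dlfc < dlfc_cut AND observed pair LFC < lfc_cut
    - ``zdlfc``: zdlfc < zdlfc_cut AND zlfc < zlfc_cut
    - ``rdlfc``: rdlfc < rdlfc_cut AND zlfc < zlfc_cut

    Pairs with any missing ingredient score are never hits.
    """
    if method not in HIT_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of "
                         f"{HIT_METHODS}")
    df = table.data
    if method == "dlfc":
        mask = (df["dlfc"] < th.dlfc_cut) & (df["observed_lfc"] < th.lfc_cut)
    elif method == "zdlfc":
        mask = (df["zdlfc"] < th.zdlfc_cut) & (df["zlfc"] < th.zlfc_cut)
    else:
        mask = (df["rdlfc"] < th.rdlfc_cut) & (df["zlfc"] < th.zlfc_cut)
    mask = mask.fillna(False)
    hits: dict[str, set[PairKey]] = {s: set() for s in table.screens}
    for a, b, screen in zip(df.loc[mask, "gene_a"], df.loc[mask, "gene_b"],
                            df.loc[mask, "screen"]):
        hits[screen].add(PairKey(a, b))
    return hits


def flag_hits(
    table: GIScoreTable,
    th: HitThresholds = HitThresholds(),
) -> GIScoreTable:
    """Populate the hit_* flag columns for every method with scores present.

    A flag is True/False where the method's ingredient scores exist in a
    screen and left missing where the method was not computed at all
    (e.g. RdLFC without a reference set).
    """
    out = table.copy()
    df = out.data
    for method, score_col, flag_col in [
        ("dlfc", "dlfc", "hit_dlfc"),
        ("zdlfc", "zdlfc", "hit_zdlfc"),
        ("rdlfc", "rdlfc", "hit_rdlfc"),
    ]:
        if df[score_col].notna().any():
            hits = call_hits(out, th, method)
            keys = out.pair_keys
            flags = [
                (k in hits[s]) if np.isfinite(v) else pd.NA
                for k, s, v in zip(keys, df["screen"], df[score_col])
            ]
            df[flag_col] = pd.array(flags, dtype="boolean")
    return out
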