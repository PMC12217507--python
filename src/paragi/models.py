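"""Gaussian null models for Z-scoring screens.

Two nulls are fit per screen:

- **LFC mixture** — a two-component Gaussian mixture over all guide-level
  LFCs. The higher-weight component captures the majority of guides with
  no fitness effect and serves as the null for ZLFC: ``ZLFC = (LFC - mu) /
  sigma`` of that component. The lower-weight, lower-mean component
  absorbs the fitness-defect tail.
- **dLFC null** — a single Gaussian over the pair dLFC distribution after
  Tukey-fence outlier removal (drop values outside [Q1 - 1.5*IQR,
  Q3 + 1.5*IQR]). Its mean/sd standardize dLFC into ZdLFC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureModel",
    "NullModel",
    "ModelFitError",
    "fit_lfc_mixture",
    "z_transform",
    "z_transform_lfc",
    "fit_dlfc_null",
    "write_models",
    "read_models",
]


class ModelFitError(RuntimeError):
    """A null-model fit failed (degenerate data or no convergence)."""


@dataclass(frozen=True)
class MixtureModel:
    """Two-component Gaussian mixture over LFCs.

    ``null_component`` indexes the higher-weight component (ties broken
    toward the larger mean, since the no-effect majority sits near zero
    while the fitness-defect component lies below it).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    null_component: int
    seed: int | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.sds) <= 0:
            raise ValueError("mixture sds must be positive")
        w0, w1 = self.weights
        expect = (0 if w0 > w1 else 1 if w1 > w0
                  else int(self.means[1] >= self.means[0]))
        if self.null_component != expect:
            raise ValueError("null_component must be the higher-weight "
                             "(tie: larger-mean) component")

    @property
    def null_mean(self) -> float:
        return self.means[self.null_component]

    @property
    def null_sd(self) -> float:
        return self.sds[self.null_component]

    def to_dict(self) -> dict:
        return {
            "kind": "mixture",
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "null_component": self.null_component,
            "seed": self.seed,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(weights=tuple(d["weights"]), means=tuple(d["means"]),
                   sds=tuple(d["sds"]), null_component=d["null_component"],
                   seed=d.get("seed"), n_iter=d.get("n_iter"))


@dataclass(frozen=True)
class NullModel:
    """Outlier-trimmed single-Gaussian null for the dLFC distribution."""

    mu: float
    sigma: float
    n_used: int
    fences: tuple[float, float]
    n_total: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("null-model sigma must be positive")
        if self.fences[0] > self.fences[1]:
            raise ValueError("lower fence above upper fence")

    def to_dict(self) -> dict:
        return {"kind": "null", "mu": self.mu, "sigma": self.sigma,
                "n_used": self.n_used, "fences": list(self.fences),
                "n_total": self.n_total}

    @classmethod
    def from_dict(cls, d: dict) -> "NullModel":
        return cls(mu=d["mu"], sigma=d["sigma"], n_used=d["n_used"],
                   fences=tuple(d["fences"]), n_total=d.get("n_total"))


def fit_lfc_mixture(
    lfcs: np.ndarray | pd.Series,
    seed: int,
    min_points: int = 50,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """EM-fit a two-component Gaussian mixture to guide-level LFCs.

    Deterministic given ``seed`` and the data (k-means initialization with
    ``n_init`` restarts). The higher-weight component becomes the null.

    Raises
    ------
    ModelFitError
        If fewer than ``min_points`` finite values are supplied, the data
        are degenerate (zero variance), or EM does not converge within
        ``max_iter`` iterations.
    """
    x = np.asarray(lfcs, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_points:
        raise ModelFitError(
            f"need at least {min_points} finite LFCs to fit the mixture, "
            f"got {len(x)}")
    if np.std(x) == 0:
        raise ModelFitError("all LFC values identical; mixture variance "
                            "degenerate")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", tol=tol, max_iter=max_iter,
        n_init=n_init, init_params="kmeans", random_state=seed,
    ).fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise ModelFitError(
            f"EM did not converge within {max_iter} iterations "
            f"(last run used {gm.n_iter_})")
    weights = tuple(float(w) for w in gm.weights_)
    means = tuple(float(m) for m in gm.means_.ravel())
    sds = tuple(float(np.sqrt(c)) for c in gm.covariances_.ravel())
    w0, w1 = weights
    if w0 != w1:
        null = int(np.argmax(weights))
    else:  # exact tie: the no-effect majority has the larger mean
        null = int(means[1] >= means[0])
    return MixtureModel(weights=weights, means=means, sds=sds,
                        null_component=null, seed=seed,
                        n_iter=int(gm.n_iter_))


def z_transform(values, mu: float, sigma: float):
    """Standardize values against a Gaussian null: (x - mu) / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (values - mu) / sigma


def z_transform_lfc(values, mm: MixtureModel):
    """ZLFC: standardize LFCs against the mixture's null component.

    ``values`` may be a scalar, array, Series or DataFrame of LFCs at any
    level (guide arrays or aggregated genes/pairs); the shape is preserved.
    """
    return z_transform(values, mm.null_mean, mm.null_sd)


def fit_dlfc_null(
    dlfcs: np.ndarray | pd.Series,
    min_points: int = 20,
    quantile_method: str = "linear",
) -> NullModel:
    """Fit the ZdLFC null: Gaussian on dLFCs inside the Tukey fences.

    Q1 and Q3 are computed on the full finite dLFC vector (linear
    interpolation between order statistics by default); values outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are dropped; mu and sigma are the mean
    and sample (n-1) sd of the retained values.
    """
    x = np.asarray(dlfcs, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_points:
        raise ModelFitError(
            f"need at least {min_points} finite dLFCs to fit the null, "
            f"got {len(x)}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = x[(x >= lo) & (x <= hi)]
    if len(kept) < 2:
        raise ModelFitError("fewer than 2 dLFCs inside the Tukey fences")
    sigma = float(np.std(kept, ddof=1))
    if sigma == 0:
        raise ModelFitError(
            "retained dLFCs have zero variance (degenerate fences); "
            "cannot define a null sd")
    return NullModel(mu=float(np.mean(kept)), sigma=sigma,
                     n_used=int(len(kept)), fences=(float(lo), float(hi)),
                     n_total=int(len(x)))


def write_models(models: dict, path: str | PathLike) -> None:
    """Serialize fitted models (per screen) to a small JSON text file."""
    payload = {screen: m.to_dict() for screen, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_models(path: str | PathLike) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for screen, d in payload.items():
        cls = MixtureModel if d.get("kind") == "mixture" else NullModel
        out[screen] = cls.from_dict(d)
    return out
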