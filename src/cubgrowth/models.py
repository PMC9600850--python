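"""Box-Cox growth models: MMv1 (whole-sample background CUB), MMBC
(bias-corrected, per-gene backgrounds + GC term), and MMv2 (piecewise switch
on the consistency statistic Ψ at 0.6).

Model forms (response: minimum doubling time d in hours, Φ_λ the Box-Cox
transform):

    MMv1:  Φ_λ(d) ~ CUB̄_HE                      [+ OGT]
    MMBC:  Φ_λ(d) ~ (iCUB̄_All − iCUB̄_HE)/iCUB̄_All + |0.5 − GC|   [+ OGT]

MMv2 applies MMv1 when Ψ < 0.6 and MMBC otherwise: when community members
share codon preferences (low Ψ) the whole-sample background is a low-variance
estimate; when they do not, per-gene backgrounds remove the composition bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .codonstats import CubgrowthWarning

__all__ = [
    "PSI_SWITCH_THRESHOLD",
    "FeatureVector",
    "BoxCoxTransform",
    "GrowthModel",
    "GrowthPrediction",
    "boxcox",
    "inverse_boxcox",
    "fit_lambda",
    "fit_growth_model",
    "predict_mmv1",
    "predict_mmbc",
    "predict_mmv2",
    "cross_validate",
    "features_from_frame",
]

#: Ψ value at and above which MMv2 dispatches to the bias-corrected model
PSI_SWITCH_THRESHOLD = 0.6

#: clamp bounds (hours) for out-of-domain inverse Box-Cox predictions
MAX_DOUBLING_TIME_H = 100.0
MIN_DOUBLING_TIME_H = 1e-3

_MODE_PREDICTORS = {
    "mmv1": ("cub_he",),
    "mmbc": ("normalized_cub", "gc_deviation"),
}


@dataclass
class FeatureVector:
    """Codon-usage features of one genome or metagenome sample."""

    cub_he: float
    icub_all: float
    icub_he: float
    gc: float
    psi: float | None = None
    ogt: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must lie in [0, 1], got {self.gc}")
        if self.icub_all == 0:
            raise ValueError("icub_all is zero; normalized CUB undefined")

    @property
    def normalized_cub(self) -> float:
        """Ratio-normalized CUB, (iCUB̄_All − iCUB̄_HE)/iCUB̄_All."""
        return (self.icub_all - self.icub_he) / self.icub_all

    @property
    def gc_deviation(self) -> float:
        return abs(0.5 - self.gc)

    def predictor(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"feature {name!r} is missing")
        return float(value)


@dataclass(frozen=True)
class BoxCoxTransform:
    lam: float

    def forward(self, x: float | np.ndarray) -> float | np.ndarray:
        return boxcox(x, self.lam)

    def inverse(self, y: float | np.ndarray) -> float | np.ndarray:
        return inverse_boxcox(y, self.lam)


@dataclass
class GrowthModel:
    """A fitted Box-Cox linear growth model."""

    mode: str  # "mmv1" or "mmbc"
    lam: float
    intercept: float
    coefficients: dict[str, float]
    with_temperature: bool = False
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = list(_MODE_PREDICTORS[self.mode])
        if self.with_temperature:
            expected.append("ogt")
        if list(self.coefficients) != expected:
            raise ValueError(
                f"mode {self.mode!r} expects predictors {expected}, "
                f"got {list(self.coefficients)}"
            )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "with_temperature": self.with_temperature,
            "training_metadata": dict(self.training_metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthModel":
        return cls(
            mode=d["mode"],
            lam=float(d["lambda"]),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            with_temperature=bool(d.get("with_temperature", False)),
            training_metadata=dict(d.get("training_metadata", {})),
        )


@dataclass
class GrowthPrediction:
    doubling_time: float  # hours
    mode_used: str
    psi: float | None
    features: FeatureVector
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Box-Cox


def boxcox(x, lam: float):
    """Φ_λ(x) = (x^λ − 1)/λ, or ln x at λ = 0.  Requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0.0:
        out = np.log(x)
    else:
        out = (np.power(x, lam) - 1.0) / lam
    return float(out) if out.ndim == 0 else out


def inverse_boxcox(y, lam: float):
    """Exact algebraic inverse of the Box-Cox transform.

    For λ ≠ 0 the domain requires λ·y + 1 > 0; violations raise ValueError.
    """
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        out = np.exp(y)
    else:
        base = lam * y + 1.0
        if np.any(base <= 0):
            raise ValueError(
                f"inverse Box-Cox out of domain: lambda*y+1 = {base} <= 0"
            )
        out = np.power(base, 1.0 / lam)
    return float(out) if out.ndim == 0 else out


def fit_lambda(
    responses: Sequence[float],
    exog: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Profile-likelihood Box-Cox λ over a grid (−2..2, step 0.01).

    With ``exog`` the profile likelihood is that of the linear model
    (intercept prepended automatically), matching standard Box-Cox practice
    for regression; without it, the intercept-only model is used.
    """
    y = np.asarray(responses, dtype=float)
    if y.size < 10:
        raise ValueError("fit_lambda requires at least 10 responses")
    if np.any(y <= 0):
        raise ValueError("responses must be strictly positive")
    if np.allclose(y, y[0]):
        raise ValueError("constant response; lambda is unidentifiable")
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    n = y.size
    if exog is None:
        X = np.ones((n, 1))
    else:
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        X = np.column_stack([np.ones(n), exog])
    log_jac = np.sum(np.log(y))
    best_lam, best_llf = grid[0], -np.inf
    for lam in grid:
        z = boxcox(y, float(lam))
        resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        rss = float(resid @ resid)
        if rss <= 0:
            continue
        llf = -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_jac
        if llf > best_llf:
            best_llf, best_lam = llf, float(lam)
    return best_lam


# --------------------------------------------------------------------------
# fitting and prediction


def _design_matrix(
    features: Sequence[FeatureVector], mode: str, with_temperature: bool
) -> pd.DataFrame:
    names = list(_MODE_PREDICTORS[mode])
    if with_temperature:
        names.append("ogt")
    return pd.DataFrame(
        {name: [f.predictor(name) for f in features] for name in names}
    )


def fit_growth_model(
    features: Sequence[FeatureVector],
    doubling_times: Sequence[float],
    mode: str = "mmbc",
    with_temperature: bool = False,
) -> GrowthModel:
    """Fit Φ_λ(doubling time) by OLS on the mode's predictors.

    λ is fitted first by profile likelihood of the regression, then the
    transformed response is regressed on the predictors.
    """
    if mode not in _MODE_PREDICTORS:
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(doubling_times, dtype=float)
    X = _design_matrix(features, mode, with_temperature)
    if y.size != len(X):
        raise ValueError("features and responses differ in length")
    if y.size <= X.shape[1] + 1:
        raise ValueError("too few observations to fit the model")
    if np.any(y <= 0):
        raise ValueError("doubling times must be positive")
    lam = fit_lambda(y, exog=X.to_numpy())
    z = boxcox(y, lam)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(z, Xc).fit()
    params = res.params
    return GrowthModel(
        mode=mode,
        lam=lam,
        intercept=float(params["const"]),
        coefficients={name: float(params[name]) for name in X.columns},
        with_temperature=with_temperature,
        training_metadata={
            "n": int(y.size),
            "r_squared": float(res.rsquared),
            "response": "doubling_time_h",
        },
    )


def _predict(features: FeatureVector, model: GrowthModel) -> GrowthPrediction:
    if model.with_temperature and features.ogt is None:
        raise ValueError("model expects an optimal growth temperature (ogt)")
    lin = model.intercept + sum(
        coef * features.predictor(name)
        for name, coef in model.coefficients.items()
    )
    notes: list[str] = []
    try:
        d = inverse_boxcox(lin, model.lam)
    except ValueError:
        # out-of-domain extrapolation: the violated side corresponds to
        # d -> +inf (clamped to the ceiling) or d -> 0 (clamped to the floor)
        if model.lam < 0:
            d = MAX_DOUBLING_TIME_H
        else:
            d = MIN_DOUBLING_TIME_H
        msg = (
            f"inverse Box-Cox out of domain (linear predictor {lin:.4g}, "
            f"lambda {model.lam:.3g}); doubling time clamped to {d} h"
        )
        notes.append(msg)
        warnings.warn(msg, CubgrowthWarning, stacklevel=2)
    return GrowthPrediction(
        doubling_time=float(d),
        mode_used=model.mode,
        psi=features.psi,
        features=features,
        warnings=notes,
    )


def predict_mmv1(features: FeatureVector, model: GrowthModel) -> GrowthPrediction:
    """Predict doubling time with the original whole-sample-background model."""
    if model.mode != "mmv1":
        raise ValueError(f"predict_mmv1 requires an mmv1 model, got {model.mode!r}")
    return _predict(features, model)


def predict_mmbc(features: FeatureVector, model: GrowthModel) -> GrowthPrediction:
    """Predict doubling time with the bias-corrected (per-gene background) model."""
    if model.mode != "mmbc":
        raise ValueError(f"predict_mmbc requires an mmbc model, got {model.mode!r}")
    return _predict(features, model)


def predict_mmv2(
    features: FeatureVector, mmv1: GrowthModel, mmbc: GrowthModel
) -> GrowthPrediction:
    """Piecewise dispatch: MMv1 when Ψ < 0.6, MMBC otherwise (never a blend)."""
    if features.psi is None:
        raise ValueError("predict_mmv2 requires the consistency statistic psi")
    if mmv1.with_temperature != mmbc.with_temperature:
        raise ValueError("mmv1 and mmbc models disagree on the temperature flag")
    if features.psi < PSI_SWITCH_THRESHOLD:
        return predict_mmv1(features, mmv1)
    return predict_mmbc(features, mmbc)


# --------------------------------------------------------------------------
# cross-validation

_FEATURE_COLUMNS = ("cub_he", "icub_all", "icub_he", "gc", "psi")


def features_from_frame(table: pd.DataFrame) -> list[FeatureVector]:
    """Build FeatureVectors from a training table with feature columns."""
    feats = []
    for _, row in table.iterrows():
        feats.append(
            FeatureVector(
                cub_he=float(row["cub_he"]),
                icub_all=float(row["icub_all"]),
                icub_he=float(row["icub_he"]),
                gc=float(row["gc"]),
                psi=float(row["psi"]) if "psi" in table.columns else None,
                ogt=float(row["ogt_c"]) if "ogt_c" in table.columns else None,
            )
        )
    return feats


def cross_validate(
    table: pd.DataFrame,
    scheme: str = "random-kfold",
    mode: str = "mmbc",
    with_temperature: bool = False,
    k: int = 10,
    seed: int = 0,
    error_scale: str = "boxcox",
) -> pd.DataFrame:
    """Cross-validated MSE per fold.

    ``random-kfold`` uses k seeded folds; ``blocked-by-phylum`` uses the unique
    phylum labels as folds, controlling for phylogenetic structure.  MSE is
    reported on the Box-Cox (fitting) scale by default, or in hours.
    """
    n = len(table)
    rng = np.random.default_rng(seed)
    if scheme == "random-kfold":
        perm = rng.permutation(n)
        folds = [("fold%02d" % i, np.sort(perm[i::k])) for i in range(k)]
    elif scheme == "blocked-by-phylum":
        phyla = table["phylum"].astype(str).to_numpy()
        labels = sorted(set(phyla))
        if len(labels) < 2:
            raise ValueError("blocked cross-validation needs >= 2 phylum labels")
        folds = [(lab, np.flatnonzero(phyla == lab)) for lab in labels]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    feats_all = features_from_frame(table)
    y_all = table["doubling_time_h"].to_numpy(dtype=float)
    for name, test_idx in folds:
        if len(test_idx) < 2:
            warnings.warn(
                f"fold {name!r} has {len(test_idx)} point(s); skipped",
                CubgrowthWarning,
                stacklevel=2,
            )
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        model = fit_growth_model(
            [feats_all[i] for i in train_idx],
            y_all[train_idx],
            mode=mode,
            with_temperature=with_temperature,
        )
        preds = np.array(
            [_predict(feats_all[i], model).doubling_time for i in test_idx]
        )
        if error_scale == "boxcox":
            err = boxcox(preds, model.lam) - boxcox(y_all[test_idx], model.lam)
        elif error_scale == "hours":
            err = preds - y_all[test_idx]
        else:
            raise ValueError(f"unknown error scale {error_scale!r}")
        rows.append(
            {"fold": name, "n_test": int(len(test_idx)), "mse": float(np.mean(err**2))}
        )
    return pd.DataFrame(rows)
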