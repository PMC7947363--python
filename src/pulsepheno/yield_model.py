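"""Seed-yield prediction with LASSO regression.

Features and yield are z-score standardized within normalization groups
(each year x location, or each year for combined data): x_n = (x_r - m) / s.
An L1-penalized linear model (lasso, i.e. elastic-net weight alpha = 1) is
then fit with the penalty chosen to minimize cross-validated MSE over a
log-spaced path, the cross-validation repeated with re-randomized folds and
the MSE curves averaged.

Two evaluation protocols:

* plot mode — random 3:1 train/test split; within the training set five
  80/20 resamples tune the penalty; the tuned model is refit on the full
  training set and scored on the held-out quarter; the whole procedure runs
  for four independent iterations.
* cultivar mode — replicate-averaged entries are too few for a held-out
  quarter, so leave-one-out: each entry is predicted by a model tuned
  (five-fold CV) and fit on all the others, and test R^2 pools the held-out
  predictions.

Features with a nonzero coefficient in at least 75% of the fits are the
reported predictor set. Test R^2 is the squared Pearson correlation between
predicted and observed held-out yield; the 1 - SSE/SST form is computed and
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .trait_stats import pearson

__all__ = [
    "LassoConfig",
    "LassoFit",
    "ModelEvaluation",
    "normalize",
    "fit_lasso",
    "evaluate_plot_mode",
    "evaluate_cultivar_mode",
    "r2_corr",
    "r2_sse",
]


@dataclass
class LassoConfig:
    """Protocol parameters for lasso yield prediction."""

    alpha: float = 1.0  # elastic-net mixing: 1 = pure lasso
    mc_reps: int = 3  # repetitions of cross-validation (re-randomized folds)
    n_folds: int = 5
    n_iterations: int = 4  # independent 3:1 split iterations (plot mode)
    test_fraction: float = 0.25  # 3:1 train:test
    n_resamples: int = 5  # 80/20 tuning resamples within the training set
    resample_validation_fraction: float = 0.2
    selection_frequency_threshold: float = 0.75
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha != 1.0:
            raise ValueError("only the pure lasso (alpha = 1) is implemented")
        for name in ("mc_reps", "n_folds", "n_iterations", "n_resamples", "n_lambda"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.selection_frequency_threshold <= 1:
            raise ValueError("selection_frequency_threshold must be in (0, 1]")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def normalize(
    table: pd.DataFrame,
    columns: Sequence[str],
    group_cols: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score standardize ``columns`` within each normalization group.

    x_n = (x_r - m) / s with the sample (n-1) standard deviation. Returns the
    transformed table and a parameter table (group, feature, m, s) that makes
    the transform invertible. Raises if any feature has zero variance within
    a group, naming the feature.
    """
    out = table.copy()
    out[list(columns)] = out[list(columns)].astype(float)
    params = []
    if group_cols:
        groups = out.groupby(list(group_cols), sort=False)
    else:
        groups = [((), out)]
    for key, sub in groups:
        for col in columns:
            v = sub[col].to_numpy(dtype=float)
            m = float(np.nanmean(v))
            s = float(np.nanstd(v, ddof=1))
            if not np.isfinite(s) or s == 0.0:
                raise ValueError(
                    f"feature {col!r} has zero variance in group {key!r}; cannot normalize"
                )
            out.loc[sub.index, col] = (v - m) / s
            rec = {"feature": col, "m": m, "s": s}
            for gc, gv in zip(group_cols, key if isinstance(key, tuple) else (key,)):
                rec[gc] = gv
            params.append(rec)
    return out, pd.DataFrame(params)


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, min_ratio: float) -> np.ndarray:
    """Log-spaced penalty path from the null-model penalty downward.

    Penalties are in scikit-learn units (objective (1/2n)||y - Xw||^2 +
    lam ||w||_1), so lam_max = max |X_c^T y_c| / n for centred data.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xc.T @ yc)) / len(y))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def _path_val_mse(
    Xtr: np.ndarray, ytr: np.ndarray, Xva: np.ndarray, yva: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Validation MSE along the penalty path, fit on centred training data."""
    xm, ym = Xtr.mean(axis=0), ytr.mean()
    _, coefs, _ = _silent_path(Xtr - xm, ytr - ym, lams)
    pred = (Xva - xm) @ coefs + ym  # (n_val, n_lambda)
    return np.mean((pred - yva[:, None]) ** 2, axis=0)


def _silent_path(Xc: np.ndarray, yc: np.ndarray, lams: np.ndarray):
    # collinear VI features make the duality gap stall at tiny penalties;
    # the warm-started path is accurate enough for penalty selection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return lasso_path(Xc, yc, alphas=lams, max_iter=3000, tol=1e-6)


@dataclass
class LassoFit:
    """A lasso solution with its penalty path and CV curve."""

    coef: np.ndarray
    intercept: float
    lam: float
    lambdas: np.ndarray
    cv_mse: np.ndarray
    coef_path: np.ndarray  # (n_features, n_lambda) on the full data
    feature_names: list[str]

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)

    @property
    def selected_features(self) -> list[str]:
        return [self.feature_names[i] for i in self.support]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def _refit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    xm, ym = X.mean(axis=0), y.mean()
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=100000, tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X - xm, y - ym)
    coef = model.coef_.copy()
    return coef, float(ym - xm @ coef)


def fit_lasso(
    X,
    y,
    config: LassoConfig | None = None,
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> LassoFit:
    """Lasso with the penalty minimizing repeated k-fold cross-validated MSE.

    The penalty path has ``n_lambda`` log-spaced values from the smallest
    penalty yielding the null model down by ``lambda_min_ratio``. K-fold CV
    is repeated ``mc_reps`` times with re-randomized fold assignments and the
    per-fold validation MSE curves are averaged; the penalty at the minimum
    of the averaged curve is refit on the full data.
    """
    config = config or LassoConfig()
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = list(feature_names or [f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < config.n_folds:
        raise ValueError(f"need at least n_folds = {config.n_folds} observations, got {n}")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite cells are not allowed in the model matrix")
    if np.std(y) == 0.0:
        raise ValueError("response has zero variance")

    lams = _lambda_grid(X, y, config.n_lambda, config.lambda_min_ratio)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 61])
    )
    curves = []
    for _ in range(config.mc_reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, config.n_folds)
        for va in folds:
            tr = np.setdiff1d(perm, va, assume_unique=True)
            curves.append(_path_val_mse(X[tr], y[tr], X[va], y[va], lams))
    cv_mse = np.mean(curves, axis=0)
    lam = float(lams[int(np.argmin(cv_mse))])

    coef, intercept = _refit(X, y, lam)
    xm, ym = X.mean(axis=0), y.mean()
    _, coef_path, _ = _silent_path(X - xm, y - ym, lams)
    return LassoFit(
        coef=coef, intercept=intercept, lam=lam, lambdas=lams, cv_mse=cv_mse,
        coef_path=coef_path, feature_names=feature_names,
    )


def r2_corr(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    r, _, n = pearson(obs, pred)
    return float(r * r) if np.isfinite(r) else 0.0


def r2_sse(obs: np.ndarray, pred: np.ndarray) -> float:
    """1 - SSE/SST coefficient of determination (can be negative)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        return np.nan
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


@dataclass
class ModelEvaluation:
    """Outcome of a full evaluation protocol."""

    mode: str
    iterations: pd.DataFrame
    selection_frequency: pd.Series
    reported_features: list[str]
    config: LassoConfig
    predictions: pd.DataFrame | None = None
    fits: list[LassoFit] = field(default_factory=list)

    def summary(self) -> dict:
        """Headline numbers: mean train/test R^2 and reported feature count."""
        return {
            "mode": self.mode,
            "train_r2": float(self.iterations["train_r2"].mean()),
            "test_r2": float(self.iterations["test_r2"].mean()),
            "test_r2_sse": float(self.iterations["test_r2_sse"].mean()),
            "n_features": len(self.reported_features),
        }


def evaluate_plot_mode(X, y, config: LassoConfig | None = None) -> ModelEvaluation:
    """3:1 split protocol on plot-level data, four independent iterations.

    Per iteration: a seeded random 3:1 train/test split; per CV repetition,
    five 80/20 resamples of the training set give an averaged validation-MSE
    curve whose minimizing penalty is refit on the full training set (these
    iteration x repetition fits feed the selection-frequency tally); the
    penalty minimizing the curve averaged over all repetitions gives the
    iteration's final model, scored on the held-out test set.
    """
    config = config or LassoConfig()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    n_test = int(round(n * config.test_fraction))
    if n_test < 1 or n - n_test < max(config.n_folds, 2):
        raise ValueError(f"too few observations (n = {n}) for a {config.test_fraction:.0%} test split")

    tallies: dict[str, int] = {name: 0 for name in names}
    n_tally_fits = 0
    rows = []
    fits = []
    for it in range(config.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71, it]))
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X[train_idx], y[train_idx]
        n_tr = len(train_idx)
        n_val = max(1, int(round(n_tr * config.resample_validation_fraction)))
        lams = _lambda_grid(Xtr, ytr, config.n_lambda, config.lambda_min_ratio)

        rep_curves = []
        for rep in range(config.mc_reps):
            curves = []
            for s in range(config.n_resamples):
                p = rng.permutation(n_tr)
                va, tr = p[:n_val], p[n_val:]
                curves.append(_path_val_mse(Xtr[tr], ytr[tr], Xtr[va], ytr[va], lams))
            curve = np.mean(curves, axis=0)
            rep_curves.append(curve)
            lam_rep = float(lams[int(np.argmin(curve))])
            coef_rep, _ = _refit(Xtr, ytr, lam_rep)
            for i in np.flatnonzero(coef_rep != 0.0):
                tallies[names[i]] += 1
            n_tally_fits += 1

        cv_mse = np.mean(rep_curves, axis=0)
        lam = float(lams[int(np.argmin(cv_mse))])
        coef, intercept = _refit(Xtr, ytr, lam)
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coef_path, _ = _silent_path(Xtr - xm, ytr - ym, lams)
        fit = LassoFit(coef, intercept, lam, lams, cv_mse, coef_path, names)
        fits.append(fit)

        pred_tr = fit.predict(Xtr)
        pred_te = fit.predict(X[test_idx])
        rows.append(
            {
                "iteration": it,
                "lam": lam,
                "train_r2": r2_corr(ytr, pred_tr),
                "test_r2": r2_corr(y[test_idx], pred_te),
                "train_r2_sse": r2_sse(ytr, pred_tr),
                "test_r2_sse": r2_sse(y[test_idx], pred_te),
                "n_selected": int(np.count_nonzero(coef)),
                "selected": ",".join(fit.selected_features),
            }
        )

    freq = pd.Series({k: v / n_tally_fits for k, v in tallies.items()}, name="frequency")
    reported = [f for f in names if freq[f] >= config.selection_frequency_threshold]
    return ModelEvaluation(
        mode="plot",
        iterations=pd.DataFrame(rows),
        selection_frequency=freq,
        reported_features=reported,
        config=config,
        fits=fits,
    )


def evaluate_cultivar_mode(X, y, config: LassoConfig | None = None) -> ModelEvaluation:
    """Leave-one-out protocol on replicate-averaged (cultivar) data.

    Each instance is predicted by a lasso tuned with repeated five-fold CV and
    fit on all remaining instances. Test R^2 pools the held-out predictions
    against the observations; train R^2 averages over the LOO fits. Needs at
    least 8 instances to form five folds plus a meaningful holdout.
    """
    config = config or LassoConfig()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 8:
        raise ValueError(f"leave-one-out needs at least 8 instances, got {n}")

    tallies = {name: 0 for name in names}
    preds = np.empty(n)
    train_r2 = []
    fits = []
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        fit = fit_lasso(
            X[rest], y[rest], config, seed=config.seed * 100003 + i, feature_names=names
        )
        preds[i] = fit.predict(X[i : i + 1])[0]
        train_r2.append(r2_corr(y[rest], fit.predict(X[rest])))
        for name in fit.selected_features:
            tallies[name] += 1
        fits.append(fit)

    freq = pd.Series({k: v / n for k, v in tallies.items()}, name="frequency")
    reported = [f for f in names if freq[f] >= config.selection_frequency_threshold]
    iterations = pd.DataFrame(
        [
            {
                "iteration": 0,
                "lam": np.nan,
                "train_r2": float(np.mean(train_r2)),
                "test_r2": r2_corr(y, preds),
                "train_r2_sse": np.nan,
                "test_r2_sse": r2_sse(y, preds),
                "n_selected": len(reported),
                "selected": ",".join(reported),
            }
        ]
    )
    predictions = pd.DataFrame({"observed": y, "predicted": preds})
    return ModelEvaluation(
        mode="cultivar",
        iterations=iterations,
        selection_frequency=freq,
        reported_features=reported,
        config=config,
        predictions=predictions,
        fits=fits,
    )
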