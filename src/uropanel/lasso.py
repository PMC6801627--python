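"""Marker-importance ranking with L1-penalized logistic regression.

Concentrations are log10-transformed (with a small per-marker offset for
zeros) and standardized to unit variance so that penalized coefficients are
comparable across markers.  The regularization parameter is chosen per fit
by 10-fold cross-validated binomial deviance over a log-spaced lambda grid.
Repeating the fit under re-randomized folds yields a distribution of
standardized coefficients per marker; markers are ranked by the mean
absolute coefficient, with the selection frequency (fraction of fits with a
nonzero coefficient) reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._fast import logistic_lasso_path
from .cohort import CohortTable

log = logging.getLogger(__name__)

LAMBDA_GRID_SIZE = 100
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class StandardizationParams:
    """Per-marker transform + center/scale learned from training data."""

    markers: list[str]
    center: np.ndarray
    scale: np.ndarray
    eps: np.ndarray  # per-marker log-transform offset (0 when transform="identity")
    transform: str = "log10_eps"
    dropped: list[str] = field(default_factory=list)

    def apply(self, x: pd.DataFrame) -> np.ndarray:
        """Standardize new data using the stored training statistics."""
        v = x[self.markers].to_numpy(dtype=float)
        if self.transform == "log10_eps":
            v = np.log10(v + self.eps)
        return (v - self.center) / self.scale


def log_transform(x: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """log10(x + eps) with eps = half the smallest positive value per marker."""
    v = x.to_numpy(dtype=float)
    eps = np.empty(v.shape[1])
    for j in range(v.shape[1]):
        col = v[:, j]
        pos = col[np.isfinite(col) & (col > 0)]
        eps[j] = pos.min() / 2.0 if pos.size else 1.0
    return np.log10(v + eps), eps


def standardize(
    cohort_or_x: CohortTable | pd.DataFrame, transform: str = "log10_eps"
) -> tuple[np.ndarray, StandardizationParams]:
    """Transform and scale each marker column to mean 0, sd 1.

    Constant (zero-variance) columns are dropped with a warning and listed
    in the returned parameters.  Returns the standardized matrix for the
    retained markers and the parameters needed to reproduce the mapping on
    held-out data.
    """
    x = cohort_or_x.x if isinstance(cohort_or_x, CohortTable) else cohort_or_x
    if len(x) < 2:
        raise ValueError("standardization needs at least 2 samples")
    if transform == "log10_eps":
        v, eps = log_transform(x)
    elif transform == "identity":
        v, eps = x.to_numpy(dtype=float), np.zeros(x.shape[1])
    else:
        raise ValueError(f"unknown transform {transform!r}")
    center = np.nanmean(v, axis=0)
    scale = np.nanstd(v, axis=0, ddof=0)
    keep = scale > 0
    dropped = [c for c, k in zip(x.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant marker column(s): {dropped}")
    params = StandardizationParams(
        markers=[c for c, k in zip(x.columns, keep) if k],
        center=center[keep],
        scale=scale[keep],
        eps=eps[keep],
        transform=transform,
        dropped=dropped,
    )
    return (v[:, keep] - center[keep]) / scale[keep], params


def lambda_grid(X: np.ndarray, y: np.ndarray,
                size: int = LAMBDA_GRID_SIZE,
                min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Log-spaced grid from lambda_max (all-zero solution) down to
    lambda_max * min_ratio, for the objective (1/n) loss + lambda * ||beta||_1."""
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    return np.geomspace(lam_max, lam_max * min_ratio, size)


def binomial_deviance(intercept: float, coef: np.ndarray,
                      X: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean log-likelihood."""
    eta = np.clip(intercept + X @ coef, -30.0, 30.0)
    return float(2.0 * np.mean(np.log1p(np.exp(eta)) - y * eta))


def fit_l1_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """CV-tuned L1 logistic fit.

    Fits the penalized path on each training fold (stratified folds,
    shuffled with *seed*), selects the lambda minimizing the mean held-out
    binomial deviance, and refits the path on the full data.  Grid points
    that fail to converge in any fold are excluded from selection with a
    warning; if every point fails, an error is raised.

    Returns ``(lambda_selected, intercept, coefficients)``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    L = len(lambdas)
    dev = np.zeros(L)
    ok = np.ones(L, dtype=bool)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        icpt, coefs, conv = logistic_lasso_path(X[tr], y[tr], lambdas)
        ok &= conv
        # held-out deviance for every lambda at once: (L, n_te) linear predictors
        eta = np.clip(icpt[:, None] + coefs @ X[te].T, -30.0, 30.0)
        dev += 2.0 * np.mean(np.log1p(np.exp(eta)) - y[te] * eta, axis=1)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} lambda grid point(s) failed to converge; skipped")
    if not ok.any():
        raise RuntimeError("no lambda grid point converged")
    dev = np.where(ok, dev / n_folds, np.inf)
    best = int(np.argmin(dev))
    icpt, coefs, conv = logistic_lasso_path(X, y, lambdas)
    if not conv[best]:
        raise RuntimeError("full-data refit failed to converge at the selected lambda")
    return float(lambdas[best]), float(icpt[best]), coefs[best].copy()


@dataclass
class LassoImportance:
    """Coefficient distributions over CV iterations and the resulting ranks."""

    markers: list[str]
    coefs: np.ndarray  # (n_iter, p) standardized-scale coefficients
    lambdas_selected: np.ndarray  # (n_iter,)
    table: pd.DataFrame  # marker, rank, mean_abs_coef, selection_freq

    def top(self, k: int) -> list[str]:
        return self.table.sort_values("rank")["marker"].head(k).tolist()

    def draws_long(self) -> pd.DataFrame:
        """Long-format coefficient draws (for violin-style plotting)."""
        recs = []
        for it in range(self.coefs.shape[0]):
            for j, m in enumerate(self.markers):
                recs.append({"iteration": it, "marker": m, "coef": self.coefs[it, j]})
        return pd.DataFrame(recs)


def rank_by_lasso(
    cohort: CohortTable,
    n_iter: int = 2000,
    n_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
) -> LassoImportance:
    """Rank markers by repeated CV-tuned L1 logistic fits (cancer vs benign).

    Each iteration re-randomizes the fold assignment (substream derived from
    the master seed), tunes lambda by :func:`fit_l1_logistic_cv` on the full
    standardized cohort, and records the coefficient vector at the selected
    lambda.  Ranks follow the mean absolute standardized coefficient,
    descending; ties break alphabetically.  Borderline samples, if present,
    are dropped with a warning; samples missing any marker are excluded
    (complete-case).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if (cohort.meta["group"] == "borderline").any():
        warnings.warn("borderline samples present; excluding them from the LASSO ranking")
        cohort = cohort.subset(cohort.meta["group"] != "borderline")
    complete = ~cohort.x.isna().any(axis=1).to_numpy()
    if not complete.all():
        log.info("rank_by_lasso: dropping %d incomplete sample(s)", int((~complete).sum()))
        cohort = cohort.subset(complete)
    y = cohort.labels().astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    X, params = standardize(cohort)
    if lambdas is None:
        lambdas = lambda_grid(X, y)

    p = X.shape[1]
    coefs = np.empty((n_iter, p))
    lams = np.empty(n_iter)
    ss = np.random.SeedSequence(seed)
    fold_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=n_iter)
    for it in range(n_iter):
        lam, icpt, beta = fit_l1_logistic_cv(
            X, y, lambdas=lambdas, n_folds=n_folds, seed=int(fold_seeds[it])
        )
        coefs[it] = beta
        lams[it] = lam

    mean_abs = np.abs(coefs).mean(axis=0)
    sel_freq = (coefs != 0).mean(axis=0)
    order = np.lexsort((np.asarray(params.markers, dtype=object), -mean_abs))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {
            "marker": params.markers,
            "rank": rank,
            "mean_abs_coef": mean_abs,
            "selection_freq": sel_freq,
        }
    ).sort_values("rank", ignore_index=True)
    return LassoImportance(
        markers=params.markers, coefs=coefs, lambdas_selected=lams, table=table
    )
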