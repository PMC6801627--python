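"""Empirical ROC/AUC, DeLong inference and stratified resampling.

The AUC is computed as the Mann–Whitney pair statistic (ties count 0.5) via
midranks in O(n log n).  DeLong's structural-components estimator gives the
variance of a single empirical AUC and the covariance between two AUCs
measured on the same samples, enabling Wald confidence intervals and the
paired two-sided z-test for correlated ROC curves.  Stratified resampling
(subsets without replacement, or bootstrap with replacement) preserves the
cancer-to-benign class ratio via largest-remainder rounding of the per-class
draw counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

SP_GRID_DEFAULT = (70.0, 75.0, 80.0, 85.0, 90.0, 95.0)


@dataclass(frozen=True)
class AucEstimate:
    """Empirical AUC with class counts and a 95% (by default) interval."""

    auc: float
    n_pos: int
    n_neg: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    method: str = "empirical"
    variance: float = float("nan")
    level: float = 0.95


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two correlated AUCs on the same samples."""

    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float
    p: float


@dataclass
class RocCurve:
    """Step-function ROC: decision rule is ``score >= threshold -> positive``."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SubsampleAucSummary:
    """Distribution of AUCs over stratified resampling iterations."""

    mean_auc: float
    sd_auc: float
    n_iter: int
    frac: float
    with_replacement: bool
    full: AucEstimate  # DeLong estimate on the complete data
    aucs: np.ndarray = field(repr=False, default=None)


def _check_classes(scores_pos, scores_neg):
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    return pos, neg


def auc_value(scores_pos, scores_neg) -> float:
    """Mann–Whitney AUC with ties counted 0.5, via midranks."""
    pos, neg = _check_classes(scores_pos, scores_neg)
    m, n = pos.size, neg.size
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def empirical_auc(scores_pos, scores_neg) -> AucEstimate:
    """Point estimate of the AUC (no interval)."""
    pos, neg = _check_classes(scores_pos, scores_neg)
    return AucEstimate(auc=auc_value(pos, neg), n_pos=pos.size, n_neg=neg.size)


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong midrank structural components.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the placement of positive
    score *i* among the negatives and ``v01[j]`` the complementary placement
    of negative score *j* among the positives.
    """
    m, n = pos.size, neg.size
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    auc = float((ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v10, v01


def delong_variance(scores_pos, scores_neg) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC)."""
    pos, neg = _check_classes(scores_pos, scores_neg)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong variance needs at least 2 samples per class")
    auc, v10, v01 = _structural_components(pos, neg)
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    return auc, float(var)


def delong_ci(scores_pos, scores_neg, level: float = 0.95) -> AucEstimate:
    """AUC with a DeLong Wald interval, clipped to [0, 1].

    Degenerate inputs (all structural components constant, e.g. perfect
    separation) give zero variance and a point interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    auc, var = delong_variance(pos, neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return AucEstimate(
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        method="delong",
        variance=var,
        level=level,
    )


def delong_paired_test(scores_a, scores_b, labels) -> DeLongComparison:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    ``scores_a`` and ``scores_b`` are two scorings of the *same* samples;
    ``labels`` is the shared 0/1 (or boolean) class vector with the positive
    class coded truthy.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    m, n = int(y.sum()), int((~y).sum())
    auc_a, v10a, v01a = _structural_components(a[y], a[~y])
    auc_b, v10b, v01b = _structural_components(b[y], b[~y])
    var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
    var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
    ddof = 1
    cov = (
        np.cov(v10a, v10b, ddof=ddof)[0, 1] / m
        + np.cov(v01a, v01b, ddof=ddof)[0, 1] / n
    )
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0.0 or np.isclose(var_diff, 0.0):
        if np.isclose(auc_a, auc_b):
            z, p = 0.0, 1.0
        else:
            log.warning(
                "zero variance of the AUC difference with unequal AUCs "
                "(%.4f vs %.4f); reporting p = 0", auc_a, auc_b
            )
            z, p = np.inf if auc_a > auc_b else -np.inf, 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        variance_a=float(var_a),
        variance_b=float(var_b),
        covariance=float(cov),
        z=float(z),
        p=float(p),
    )


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC with both end points (SN=0,SP=1) and (SN=1,SP=0)."""
    from sklearn.metrics import roc_curve as _sk_roc

    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr)


def sn_at_sp(scores, labels, sp_targets=SP_GRID_DEFAULT) -> pd.DataFrame:
    """Sensitivity at fixed specificity, on the step-function ROC.

    For each target SP (percent) the operating point with the largest SN
    among thresholds achieving SP >= target is reported, together with the
    SP actually achieved there (no interpolation).  The returned SN values
    are non-increasing as the SP target increases.
    """
    curve = roc_curve(scores, labels)
    rows = []
    for target in sp_targets:
        ok = curve.specificity >= target / 100.0
        sn = curve.sensitivity[ok]
        sp = curve.specificity[ok]
        best = np.flatnonzero(sn == sn.max())
        # among max-SN points prefer the highest achieved specificity
        pick = best[np.argmax(sp[best])]
        rows.append(
            {
                "sp_target": float(target),
                "sn": float(100.0 * sn[pick]),
                "sp_achieved": float(100.0 * sp[pick]),
            }
        )
    return pd.DataFrame(rows)


def stratified_counts(n_per_class, frac: float) -> np.ndarray:
    """Per-class draw counts preserving class ratios (largest remainder).

    The total drawn is ``round(frac * N)``; per-class quotas ``frac * n_c``
    are floored and the leftover units go to the classes with the largest
    fractional remainders (ties to the larger class, then lower index).
    """
    n = np.asarray(n_per_class, dtype=float)
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    quota = frac * n
    base = np.floor(quota).astype(int)
    total = int(np.floor(frac * n.sum() + 0.5))
    extra = total - int(base.sum())
    rem = quota - base
    order = np.lexsort((np.arange(n.size), -n, -rem))
    out = base.copy()
    for k in range(extra):
        out[order[k]] += 1
    return out


def stratified_subsample_auc(
    scores,
    labels,
    n_iter: int = 2000,
    frac: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    with_replacement: bool = False,
) -> SubsampleAucSummary:
    """Mean AUC over stratified resampling iterations, plus the full-data DeLong CI.

    Each iteration draws ``frac`` of each class — without replacement by
    default (random subsets), or with replacement (bootstrap) — keeping the
    cancer-to-benign ratio fixed, and records the empirical AUC of the drawn
    set.  Iteration *i* uses an independent random substream spawned from the
    master seed, so results are reproducible and independent of iteration
    order.  The confidence interval reported is the DeLong interval on the
    complete data, alongside the resampling mean.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    counts = stratified_counts([pos_idx.size, neg_idx.size], frac)
    if counts.min() < 2:
        raise ValueError(
            f"per-class subsample sizes {counts.tolist()} too small (need >= 2)"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)
    aucs = np.empty(n_iter)
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        p = rng.choice(pos_idx, size=counts[0], replace=with_replacement)
        q = rng.choice(neg_idx, size=counts[1], replace=with_replacement)
        aucs[i] = auc_value(s[p], s[q])
    full = delong_ci(s[pos_idx], s[neg_idx])
    return SubsampleAucSummary(
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if n_iter > 1 else 0.0,
        n_iter=n_iter,
        frac=frac,
        with_replacement=with_replacement,
        full=full,
        aucs=aucs,
    )
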