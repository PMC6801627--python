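"""Multimarker panel construction, nested cross-validated selection and evaluation.

The search space is every 2–4-marker subset of a candidate pool (by default
the top-8 LASSO-ranked markers).  Selection uses nested cross-validation:
the outer loop repeatedly draws a class-ratio-preserving 80% training set;
inside each training set a (repeated) stratified 10-fold CV scores every
candidate panel by the mean held-out-fold AUC of an unpenalized logistic
model; the winner per panel size is refit on the whole training set and
measured on the untouched 20%.  The final model per size is the modal
winner across outer repetitions, refit on the full cohort with its decision
threshold chosen by maximizing the F-score on the training scores.

Evaluation reports the AUC with a DeLong interval, confusion metrics
(SN/SP/PPV/NPV) at the model threshold, and the sensitivity achieved at a
grid of fixed specificities — overall and within stage subgroups (each
cancer stage group against all benign samples).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._fast import newton_logistic, score_panels_cv
from .cohort import CohortTable
from .lasso import StandardizationParams, log_transform, rank_by_lasso, standardize
from .roc import (
    SP_GRID_DEFAULT,
    AucEstimate,
    auc_value,
    delong_ci,
    sn_at_sp,
    stratified_counts,
)

log = logging.getLogger(__name__)

RIDGE_BASE = 1e-10
RIDGE_STABILIZER = 1e-6
PANEL_SIZES_DEFAULT = (2, 3, 4)


class PanelError(ValueError):
    pass


def enumerate_panels(pool, sizes=PANEL_SIZES_DEFAULT) -> list[tuple[str, ...]]:
    """All unordered marker subsets of each requested size, in deterministic
    lexicographic order (pool sorted alphabetically first)."""
    pool = sorted(pool)
    if not pool:
        raise PanelError("candidate pool is empty")
    out: list[tuple[str, ...]] = []
    for size in sorted(set(sizes)):
        if size > len(pool):
            raise PanelError(f"panel size {size} exceeds pool size {len(pool)}")
        out.extend(itertools.combinations(pool, size))
    return out


def choose_threshold_fscore(scores, labels, beta: float = 1.0) -> float:
    """Decision threshold maximizing the F-score (F1 by default).

    Candidates are the midpoints between adjacent distinct sorted scores
    plus 0 and 1; positive prediction is ``score >= threshold`` with cancer
    as the positive class.  Ties in F-score break toward higher specificity
    (the larger threshold).  All-identical scores give 0.5 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not y.any():
        # no positives: F-score is 0 everywhere; keep the permissive rule
        return 0.0
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn("all scores identical; returning threshold 0.5")
        return 0.5
    cand = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    b2 = beta * beta
    best_f, best_t = -1.0, 0.5
    n_pos = int(y.sum())
    for t in cand:
        pred = s >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        denom = (1 + b2) * tp + fp + b2 * (n_pos - tp)
        f = (1 + b2) * tp / denom if denom > 0 else 0.0
        # strictly-better F wins; equal F prefers the higher threshold
        # (fewer positives -> higher specificity)
        if f > best_f + 1e-12 or (abs(f - best_f) <= 1e-12 and t > best_t):
            best_f, best_t = f, t
    return float(best_t)


@dataclass
class PanelModel:
    """Fitted logistic panel: markers, optional menopause covariate,
    training standardization, coefficients and decision threshold."""

    markers: tuple[str, ...]
    include_menopause: bool
    params: StandardizationParams
    intercept: float
    coefficients: np.ndarray  # marker coefs, then menopause coef if present
    threshold: float
    converged: bool = True
    ridge: float = RIDGE_BASE

    def design(self, cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
        """(X, keep_mask): standardized predictors for *cohort*; rows with
        missing markers (or unknown menopause, for covariate models) are
        masked out."""
        missing = [m for m in self.markers if m not in cohort.markers]
        if missing:
            raise PanelError(f"cohort lacks panel marker(s): {missing}")
        keep = ~cohort.x[list(self.markers)].isna().any(axis=1).to_numpy()
        X = self.params.apply(cohort.x)
        if self.include_menopause:
            men = cohort.meta["menopause"].to_numpy()
            keep &= men != "unknown"
            X = np.column_stack([X, (men == "post").astype(float)])
        return X, keep

    def predict_proba(self, cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, keep_mask) for *cohort* under the stored model."""
        X, keep = self.design(cohort)
        eta = np.clip(self.intercept + X @ self.coefficients, -30.0, 30.0)
        return 1.0 / (1.0 + np.exp(-eta)), keep


def fit_panel(
    cohort: CohortTable,
    markers,
    include_menopause: bool = False,
    threshold_beta: float = 1.0,
) -> PanelModel:
    """Unpenalized logistic panel fit on standardized log concentrations.

    Menopause, when included, is coded post = 1 / pre = 0 and samples with
    unknown status are excluded from the fit.  Perfect separation (fit
    divergence) triggers a refit with a small ridge stabilizer (1e-6) and a
    warning.  The decision threshold maximizes the F-score on the training
    scores.
    """
    markers = tuple(markers)
    if len(markers) < 2:
        raise PanelError("a panel needs at least 2 markers")
    missing = [m for m in markers if m not in cohort.markers]
    if missing:
        raise PanelError(f"cohort lacks panel marker(s): {missing}")
    keep = ~cohort.x[list(markers)].isna().any(axis=1).to_numpy()
    if include_menopause:
        keep &= (cohort.meta["menopause"] != "unknown").to_numpy()
    sub = cohort.subset(keep)
    y = sub.labels().astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise PanelError("need at least 2 samples per class to fit a panel")
    Xs, params = standardize(sub.x[list(markers)])
    if params.dropped:
        raise PanelError(f"constant marker column(s) in training data: {params.dropped}")
    if include_menopause:
        men = (sub.meta["menopause"] == "post").to_numpy(dtype=float)
        Xs = np.column_stack([Xs, men])
    design = np.column_stack([np.ones(len(y)), Xs])

    ridge = RIDGE_BASE
    beta_vec, conv = newton_logistic(design, y, ridge)
    if not conv or np.abs(beta_vec).max() > 1e3:
        warnings.warn(
            "panel fit unstable (possible perfect separation); "
            f"refitting with ridge {RIDGE_STABILIZER:g}"
        )
        ridge = RIDGE_STABILIZER
        beta_vec, conv = newton_logistic(design, y, ridge)
    eta = np.clip(design @ beta_vec, -30.0, 30.0)
    prob = 1.0 / (1.0 + np.exp(-eta))
    thr = choose_threshold_fscore(prob, y, beta=threshold_beta)
    return PanelModel(
        markers=markers,
        include_menopause=include_menopause,
        params=params,
        intercept=float(beta_vec[0]),
        coefficients=beta_vec[1:].copy(),
        threshold=thr,
        converged=bool(conv),
        ridge=ridge,
    )


@dataclass
class SubgroupEvaluation:
    auc: AucEstimate
    sn: float
    sp: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    sn_at_sp: pd.DataFrame = field(repr=False, default=None)


@dataclass
class PanelEvaluation:
    """Per-subgroup performance of a fitted panel on an evaluation cohort."""

    model: PanelModel
    subgroups: dict[str, SubgroupEvaluation]

    def to_dict(self) -> dict:
        out = {
            "markers": list(self.model.markers),
            "include_menopause": self.model.include_menopause,
            "threshold": self.model.threshold,
            "subgroups": {},
        }
        for name, ev in self.subgroups.items():
            out["subgroups"][name] = {
                "auc": round(ev.auc.auc, 3),
                "auc_ci": [round(ev.auc.ci_low, 3), round(ev.auc.ci_high, 3)],
                "n_pos": ev.auc.n_pos,
                "n_neg": ev.auc.n_neg,
                "sn": round(ev.sn, 1),
                "sp": round(ev.sp, 1),
                "ppv": round(ev.ppv, 1),
                "npv": round(ev.npv, 1),
                "confusion": {"tp": ev.tp, "fp": ev.fp, "tn": ev.tn, "fn": ev.fn},
                "sn_at_sp": ev.sn_at_sp.round(1).to_dict(orient="records"),
            }
        return out


def _confusion_metrics(prob, y, thr):
    pred = prob >= thr
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
    return sn, sp, ppv, npv, tp, fp, tn, fn


def evaluate_panel(
    model: PanelModel,
    cohort: CohortTable,
    subgroups=("all", "early", "advanced"),
    sp_targets=SP_GRID_DEFAULT,
) -> PanelEvaluation:
    """Apply a fitted panel to *cohort* and measure its performance.

    Subgroup ``early`` / ``advanced`` evaluations compare the cancers of
    that stage group against all benign samples; a subgroup with fewer than
    2 cancers is skipped with a warning.  Borderline samples, if present,
    are excluded.
    """
    if (cohort.meta["group"] == "borderline").any():
        cohort = cohort.subset(cohort.meta["group"] != "borderline")
    prob, keep = model.predict_proba(cohort)
    sub = cohort.subset(keep)
    prob = prob[keep]
    y = sub.labels()
    stage = sub.stage_group()
    out: dict[str, SubgroupEvaluation] = {}
    for name in subgroups:
        if name == "all":
            sel = np.ones(len(y), dtype=bool)
        else:
            sel = (stage == name) | (y == 0)
        ysel, psel = y[sel], prob[sel]
        if (ysel == 1).sum() < 2 or (ysel == 0).sum() < 2:
            warnings.warn(f"subgroup {name!r} has < 2 samples in a class; skipped")
            continue
        auc = delong_ci(psel[ysel == 1], psel[ysel == 0])
        sn, sp, ppv, npv, tp, fp, tn, fn = _confusion_metrics(psel, ysel, model.threshold)
        grid = sn_at_sp(psel, ysel, sp_targets)
        out[name] = SubgroupEvaluation(
            auc=auc, sn=sn, sp=sp, ppv=ppv, npv=npv,
            tp=tp, fp=fp, tn=tn, fn=fn, sn_at_sp=grid,
        )
    return PanelEvaluation(model=model, subgroups=out)


@dataclass
class NestedCvConfig:
    """Configuration of the nested cross-validated panel search."""

    outer_frac: float = 0.8
    outer_reps: int = 2000
    inner_folds: int = 10
    inner_reps: int = 1
    sizes: tuple[int, ...] = PANEL_SIZES_DEFAULT
    pool: tuple[str, ...] | None = None  # explicit candidate markers
    pool_size: int = 8  # top-M from the LASSO ranking when pool is None
    rank_iters: int = 25  # CV iterations used to derive the pool
    seed: int = 0
    max_fold_retries: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.outer_frac < 1.0:
            raise ValueError("outer_frac must be in (0, 1)")
        if not set(self.sizes) <= {2, 3, 4}:
            raise ValueError("panel sizes must be a subset of {2, 3, 4}")
        if self.outer_reps < 1 or self.inner_reps < 1:
            raise ValueError("repetition counts must be >= 1")


@dataclass
class NestedCvResult:
    """Outcome of the nested CV search."""

    pool: tuple[str, ...]
    best_models: dict[int, PanelModel]  # final full-cohort refit per size
    best_auc: dict[int, AucEstimate]  # full-cohort DeLong estimate per size
    selection: pd.DataFrame  # per candidate: wins, mean inner / held-out AUC
    heldout_mean_auc: dict[int, float]  # outer-aggregated held-out AUC per size
    config: NestedCvConfig = None


def _stratified_split(rng, y, frac):
    """Ratio-preserving train/test index split (largest-remainder counts)."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_pos, n_neg = stratified_counts([pos.size, neg.size], frac)
    tr = np.concatenate(
        [rng.choice(pos, size=n_pos, replace=False),
         rng.choice(neg, size=n_neg, replace=False)]
    )
    mask = np.zeros(y.size, dtype=bool)
    mask[tr] = True
    return mask


def nested_cv_select(cohort: CohortTable, config: NestedCvConfig) -> NestedCvResult:
    """Nested cross-validated search over 2–4-marker panels.

    Outer loop: ``outer_reps`` ratio-preserving draws of ``outer_frac`` of
    each class form the training set.  Inner loop: ``inner_reps`` rounds of
    stratified ``inner_folds``-fold CV on the training set score every
    candidate panel by the mean held-out-fold AUC of a logistic model (the
    ranking is invariant to affine standardization, so inner fits use the
    log-transformed values directly).  The winner per size is refit on the
    full training set — with standardization and an F-score threshold — and
    measured on the untouched test fraction.  The returned best model per
    size is the modal winner across outer repetitions refit on the full
    cohort, with its full-data DeLong AUC estimate.
    """
    if (cohort.meta["group"] == "borderline").any():
        warnings.warn("borderline samples present; excluding them from panel selection")
        cohort = cohort.subset(cohort.meta["group"] != "borderline")
    complete = ~cohort.x.isna().any(axis=1).to_numpy()
    if not complete.all():
        log.info("nested_cv_select: dropping %d incomplete sample(s)", int((~complete).sum()))
        cohort = cohort.subset(complete)
    y = cohort.labels()
    if (y == 1).sum() < 5 or (y == 0).sum() < 5:
        raise PanelError("need at least 5 samples per class for nested CV")

    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)

    if config.pool is not None:
        pool = tuple(config.pool)
        missing = [m for m in pool if m not in cohort.markers]
        if missing:
            raise PanelError(f"pool marker(s) not in cohort: {missing}")
    else:
        m = min(config.pool_size, len(cohort.markers))
        imp = rank_by_lasso(
            cohort, n_iter=config.rank_iters,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        pool = tuple(imp.top(m))
        log.info("nested_cv_select: candidate pool from LASSO ranking: %s", pool)

    panels = enumerate_panels(pool, config.sizes)
    sizes_arr = np.array([len(pnl) for pnl in panels], dtype=np.int64)
    kmax = int(sizes_arr.max())
    pool_index = {name: i for i, name in enumerate(pool)}
    panels_arr = np.full((len(panels), kmax), -1, dtype=np.int64)
    for i, pnl in enumerate(panels):
        for c, name in enumerate(pnl):
            panels_arr[i, c] = pool_index[name]

    logx_all, _ = log_transform(cohort.x[list(pool)])
    yf = y.astype(float)

    n_panels = len(panels)
    win_count = Counter()
    inner_auc_sum = np.zeros(n_panels)
    heldout: dict[int, list[float]] = {s: [] for s in config.sizes}
    winners: dict[int, Counter] = {s: Counter() for s in config.sizes}
    rep_seeds = master.integers(0, 2**31 - 1, size=(config.outer_reps, 2))

    size_masks = {s: sizes_arr == s for s in config.sizes}
    for rep in range(config.outer_reps):
        rng = np.random.default_rng(int(rep_seeds[rep, 0]))
        tr_mask = _stratified_split(rng, y, config.outer_frac)
        Xtr, ytr = logx_all[tr_mask], yf[tr_mask]
        Xte, yte = logx_all[~tr_mask], yf[~tr_mask]

        scores = np.zeros(n_panels)
        for ir in range(config.inner_reps):
            fold_id = _draw_folds(
                ytr, config.inner_folds,
                int(rep_seeds[rep, 1]) + ir, config.max_fold_retries,
            )
            scores += score_panels_cv(
                Xtr, ytr, fold_id, config.inner_folds,
                panels_arr, sizes_arr, RIDGE_STABILIZER,
            )
        scores /= config.inner_reps
        inner_auc_sum += scores

        for s in config.sizes:
            mask = size_masks[s]
            idx = np.flatnonzero(mask)
            best = idx[int(np.argmax(scores[mask]))]
            winners[s][panels[best]] += 1
            win_count[panels[best]] += 1
            # refit the winner on the full outer-training set, measure held out
            cols = panels_arr[best, : s]
            design = np.column_stack([np.ones(Xtr.shape[0]), Xtr[:, cols]])
            beta_vec, _ = newton_logistic(design, ytr, RIDGE_STABILIZER)
            te_score = beta_vec[0] + Xte[:, cols] @ beta_vec[1:]
            heldout[s].append(auc_value(te_score[yte == 1], te_score[yte == 0]))

    rows = []
    for i, pnl in enumerate(panels):
        rows.append(
            {
                "panel": "+".join(pnl),
                "size": int(sizes_arr[i]),
                "wins": win_count.get(pnl, 0),
                "mean_inner_auc": inner_auc_sum[i] / config.outer_reps,
            }
        )
    selection = pd.DataFrame(rows).sort_values(
        ["size", "wins", "mean_inner_auc"], ascending=[True, False, False],
        ignore_index=True,
    )

    best_models: dict[int, PanelModel] = {}
    best_auc: dict[int, AucEstimate] = {}
    heldout_mean: dict[int, float] = {}
    for s in config.sizes:
        modal = winners[s].most_common(1)[0][0]
        model = fit_panel(cohort, modal)
        prob, keep = model.predict_proba(cohort)
        ysub = y[keep]
        best_models[s] = model
        best_auc[s] = delong_ci(prob[keep][ysub == 1], prob[keep][ysub == 0])
        heldout_mean[s] = float(np.mean(heldout[s]))
    return NestedCvResult(
        pool=pool,
        best_models=best_models,
        best_auc=best_auc,
        selection=selection,
        heldout_mean_auc=heldout_mean,
        config=config,
    )


def _draw_folds(y, n_folds, seed, max_retries):
    """Stratified fold assignment; redrawn (logged) if a fold lacks a class."""
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % (2**31 - 1))
        fold_id = np.empty(y.size, dtype=np.int64)
        try:
            for f, (_, te) in enumerate(skf.split(np.zeros_like(y), y)):
                fold_id[te] = f
        except ValueError as exc:
            raise PanelError(f"cannot form {n_folds} stratified folds: {exc}") from exc
        ok = all(
            (y[fold_id == f] == 1).any() and (y[fold_id == f] == 0).any()
            for f in range(n_folds)
        )
        if ok:
            return fold_id
        log.info("fold draw %d left a fold without both classes; redrawing", attempt)
    raise PanelError("could not draw folds containing both classes in every fold")
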