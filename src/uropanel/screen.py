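"""Per-marker differential screening and single-marker AUC ranking.

Benign vs cancer screening uses Welch's t-test on log10-transformed
concentrations (skewed, heteroscedastic assay data) with familywise
correction over the markers actually testable; the effect direction is
taken from the difference of raw class medians.  Multi-group contrasts
(e.g. benign / early-stage / advanced-stage) use one-way ANOVA with
Tukey's HSD.  Single markers are ranked by the stratified-resampling mean
AUC, overall and within stage subgroups (each cancer stage group against
all benign samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .lasso import log_transform
from .roc import AucEstimate, SubsampleAucSummary, delong_ci, stratified_subsample_auc

log = logging.getLogger(__name__)


@dataclass
class MarkerScreenResult:
    marker: str
    direction: str  # "higher_in_cancer" | "lower_in_cancer"
    p_raw: float
    p_corrected: float
    auc_all: AucEstimate | None = None
    auc_early: AucEstimate | None = None
    auc_advanced: AucEstimate | None = None
    testable: bool = True


def _two_class_values(cohort: CohortTable, marker: str):
    y = cohort.labels()
    v = cohort.x[marker].to_numpy(dtype=float)
    keep = np.isfinite(v)
    return v[keep], y[keep]


def screen_markers(
    cohort: CohortTable, correction: str = "bonferroni", compute_auc: bool = True
) -> list[MarkerScreenResult]:
    """Benign-vs-cancer test per marker with multiplicity correction.

    Results are sorted by corrected p ascending (untestable markers last);
    the correction denominator counts only testable markers.  *correction*
    is ``"bonferroni"`` (familywise, default) or ``"bh"``
    (Benjamini–Hochberg false discovery rate).
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    if (cohort.meta["group"] == "borderline").any():
        warnings.warn("borderline samples present; excluding them from screening")
        cohort = cohort.subset(cohort.meta["group"] != "borderline")
    logx, _ = log_transform(cohort.x)
    y = cohort.labels()
    stage = cohort.stage_group()

    results: list[MarkerScreenResult] = []
    p_raw_list: list[float] = []
    for j, marker in enumerate(cohort.markers):
        v = logx[:, j]
        keep = np.isfinite(v)
        vpos, vneg = v[keep & (y == 1)], v[keep & (y == 0)]
        raw = cohort.x[marker].to_numpy(dtype=float)
        if vpos.size < 2 or vneg.size < 2:
            results.append(
                MarkerScreenResult(marker, "higher_in_cancer", np.nan, np.nan, testable=False)
            )
            continue
        t, p = stats.ttest_ind(vpos, vneg, equal_var=False)
        med_diff = np.nanmedian(raw[y == 1]) - np.nanmedian(raw[y == 0])
        direction = "higher_in_cancer" if med_diff >= 0 else "lower_in_cancer"
        res = MarkerScreenResult(marker, direction, float(p), np.nan)
        if compute_auc:
            fin = np.isfinite(raw)
            res.auc_all = delong_ci(raw[fin & (y == 1)], raw[fin & (y == 0)])
            for attr, grp in (("auc_early", "early"), ("auc_advanced", "advanced")):
                sel = fin & ((stage == grp) | (y == 0))
                spos = raw[sel & (y == 1)]
                sneg = raw[sel & (y == 0)]
                if spos.size >= 2 and sneg.size >= 2:
                    setattr(res, attr, delong_ci(spos, sneg))
        results.append(res)
        p_raw_list.append(float(p))

    m = len(p_raw_list)
    if m:
        praw = np.array(p_raw_list)
        if correction == "bonferroni":
            pcorr = np.minimum(praw * m, 1.0)
        else:
            pcorr = stats.false_discovery_control(praw, method="bh")
        it = iter(pcorr)
        for res in results:
            if res.testable:
                res.p_corrected = float(next(it))
    results.sort(key=lambda r: (not r.testable, r.p_corrected if r.testable else 1.0))
    return results


def screen_table(results: list[MarkerScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "marker": r.marker,
                "direction": r.direction,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "testable": r.testable,
                "auc_all": r.auc_all.auc if r.auc_all else np.nan,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(values, groups) -> pd.DataFrame:
    """One-way ANOVA across >= 3 levels with Tukey HSD pairwise comparisons.

    Returns a table of level pairs with mean differences and Tukey-adjusted
    p-values; the ANOVA F statistic and p-value are attached as
    ``DataFrame.attrs["anova_f"]`` / ``attrs["anova_p"]``.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 3:
        raise ValueError(
            "anova_tukey needs >= 3 group levels; use a two-group test instead"
        )
    samples = [v[g == lev] for lev in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each level needs >= 2 observations")
    f, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            rows.append(
                {
                    "level_a": levels[a],
                    "level_b": levels[b],
                    "mean_diff": float(samples[a].mean() - samples[b].mean()),
                    "p_adj": float(hsd.pvalue[a, b]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["anova_f"] = float(f)
    out.attrs["anova_p"] = float(p)
    return out


def rank_single_markers(
    cohort: CohortTable,
    n_iter: int = 2000,
    frac: float = 0.8,
    seed: int = 0,
    with_replacement: bool = False,
) -> pd.DataFrame:
    """Stratified-resampling mean AUC per marker: all samples and per stage.

    One row per marker, sorted by the all-sample mean AUC descending.  The
    stage columns compare each cancer stage subgroup against all benign
    samples.  AUCs below 0.5 are reported as-is (orientation preserved);
    the screening direction captures the sign separately.
    """
    if (cohort.meta["group"] == "borderline").any():
        warnings.warn("borderline samples present; excluding them from ranking")
        cohort = cohort.subset(cohort.meta["group"] != "borderline")
    y = cohort.labels()
    stage = cohort.stage_group()
    ss = np.random.SeedSequence(seed)
    rows = []
    for j, marker in enumerate(cohort.markers):
        v = cohort.x[marker].to_numpy(dtype=float)
        fin = np.isfinite(v)
        row: dict = {"marker": marker}
        for label, sel in (
            ("all", fin),
            ("early", fin & ((stage == "early") | (y == 0))),
            ("advanced", fin & ((stage == "advanced") | (y == 0))),
        ):
            if (y[sel] == 1).sum() < 3 or (y[sel] == 0).sum() < 3:
                row[f"auc_{label}"] = np.nan
                continue
            summ: SubsampleAucSummary = stratified_subsample_auc(
                v[sel], y[sel], n_iter=n_iter, frac=frac,
                seed=ss.spawn(1)[0], with_replacement=with_replacement,
            )
            row[f"auc_{label}"] = summ.mean_auc
            row[f"ci_low_{label}"] = summ.full.ci_low
            row[f"ci_high_{label}"] = summ.full.ci_high
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("auc_all", ascending=False, ignore_index=True)
    return table
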