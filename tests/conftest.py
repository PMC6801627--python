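"""Shared fixtures: programmatically built cohorts (no data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uropanel import CohortTable, apply_exclusions, generate_cohort, paperlike_scenario


def build_study_accounting_cohort(n_markers: int = 3, seed: int = 0) -> CohortTable:
    """Cohort reproducing the emulated study's accounting exactly.

    295 samples: 125 benign / 12 borderline / 158 malignant; benign
    histologies 44 endometriosis, 30 teratoma (one with unknown menopausal
    status), 16 mucinous cystadenoma, 9 serous cystadenoma, 5 inflammation,
    21 others; malignant histologies 111 serous adenocarcinoma, 12 mucinous,
    15 endometrioid, 12 clear cell, 3 other EOC, 2 granulosa, 1 dysgerminoma,
    2 other non-EOC; FIGO stages 36/12/91/19; postmenopausal 25 benign,
    2 borderline, 92 malignant.  Marker values are arbitrary positives.
    """
    rows = []

    def add(group, histology, count):
        for _ in range(count):
            rows.append({"group": group, "histology": histology})

    add("benign", "endometriosis", 44)
    add("benign", "teratoma", 30)
    add("benign", "mucinous cystadenoma", 16)
    add("benign", "serous cystadenoma", 9)
    add("benign", "inflammation", 5)
    add("benign", "other benign", 21)
    add("borderline", "borderline tumor", 12)
    add("malignant", "serous adenocarcinoma", 111)
    add("malignant", "mucinous adenocarcinoma", 12)
    add("malignant", "endometrioid adenocarcinoma", 15)
    add("malignant", "clear cell carcinoma", 12)
    add("malignant", "other EOC", 3)
    add("malignant", "granulosa cell tumor", 2)
    add("malignant", "dysgerminoma", 1)
    add("malignant", "other non-EOC", 2)
    meta = pd.DataFrame(rows)
    meta["sample_id"] = [f"P{i:03d}" for i in range(len(meta))]

    stage = []
    stages = ["I"] * 36 + ["II"] * 12 + ["III"] * 91 + ["IV"] * 19
    it = iter(stages)
    for g in meta["group"]:
        stage.append(next(it) if g == "malignant" else "none")
    meta["figo_stage"] = stage

    men = []
    counters = {"benign": 0, "borderline": 0, "malignant": 0}
    quota = {"benign": 25, "borderline": 2, "malignant": 92}
    unknown_done = False
    for g, h in zip(meta["group"], meta["histology"]):
        if g == "benign" and h == "teratoma" and not unknown_done:
            men.append("unknown")
            unknown_done = True
            continue
        if counters[g] < quota[g]:
            men.append("post")
            counters[g] += 1
        else:
            men.append("pre")
    meta["menopause"] = men

    rng = np.random.default_rng(seed)
    meta["age"] = np.round(rng.uniform(20, 82, len(meta)), 1)
    meta = meta[["sample_id", "group", "histology", "figo_stage", "menopause", "age"]]
    x = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=1.0, size=(len(meta), n_markers)),
        columns=[f"M{j}" for j in range(n_markers)],
    )
    return CohortTable(meta, x)


@pytest.fixture(scope="session")
def study_accounting_cohort() -> CohortTable:
    return build_study_accounting_cohort()


@pytest.fixture(scope="session")
def paperlike_cohort():
    """One generated study-like cohort (with borderline samples) + truth."""
    cohort, truth = generate_cohort(paperlike_scenario(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def analyzed_cohort(paperlike_cohort):
    """The paperlike cohort after the default borderline exclusion."""
    cohort, truth = paperlike_cohort
    return apply_exclusions(cohort), truth
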