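"""Cohort tables: reading, validation, exclusion filtering and accounting.

A cohort is a set of patients with pelvic masses, each carrying a pathology
group (``benign`` / ``borderline`` / ``malignant``), clinical metadata
(histology, FIGO stage, menopausal status, age) and a vector of urinary
marker concentrations in marker-native units.  Borderline tumors — ovarian
neoplasms of low malignant potential — are conventionally excluded from the
benign-vs-cancer analysis; :func:`apply_exclusions` implements that rule.

The table is stored as two aligned :class:`pandas.DataFrame` objects:
``meta`` with one row per sample and the fixed clinical columns, and ``x``
with one column per marker (``NaN`` marks a missing measurement).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("benign", "borderline", "malignant")
STAGES = ("I", "II", "III", "IV", "none")
EARLY_STAGES = ("I", "II")
ADVANCED_STAGES = ("III", "IV")
MENOPAUSE_LEVELS = ("pre", "post", "unknown")
META_COLUMNS = ("sample_id", "group", "histology", "figo_stage", "menopause", "age")
MISSING_TOKEN = "NA"

#: default exclusion rule: drop borderline tumors before benign-vs-cancer analysis
DEFAULT_EXCLUSIONS = {"group": ("borderline",)}


class CohortError(ValueError):
    """Invalid cohort content (labels, values, identifiers)."""


class SchemaError(CohortError):
    """Input file does not match the expected column layout."""


@dataclass
class CohortTable:
    """Samples × markers concentration table with per-sample clinical metadata.

    Attributes
    ----------
    meta
        One row per sample with columns ``sample_id, group, histology,
        figo_stage, menopause, age`` (in input order).
    x
        Concentrations, one column per marker, aligned row-for-row with
        ``meta``; ``NaN`` encodes a missing measurement.
    """

    meta: pd.DataFrame
    x: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def markers(self) -> list[str]:
        return list(self.x.columns)

    @property
    def group_counts(self) -> dict[str, int]:
        vc = self.meta["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}

    def labels(self, positive: str = "malignant") -> np.ndarray:
        """0/1 label vector with *positive* coded 1."""
        return (self.meta["group"].to_numpy() == positive).astype(np.int64)

    def stage_group(self) -> np.ndarray:
        """Per-sample stage group: 'early' (I–II), 'advanced' (III–IV) or 'none'."""
        st = self.meta["figo_stage"].to_numpy()
        out = np.full(len(st), "none", dtype=object)
        out[np.isin(st, EARLY_STAGES)] = "early"
        out[np.isin(st, ADVANCED_STAGES)] = "advanced"
        return out

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """New cohort keeping rows where *mask* is true (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(
            self.meta.loc[mask].reset_index(drop=True),
            self.x.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(self.meta.copy(), self.x.copy())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if list(self.meta.columns) != list(META_COLUMNS):
            raise SchemaError(
                f"metadata columns must be {META_COLUMNS}, got {tuple(self.meta.columns)}"
            )
        if len(self.meta) != len(self.x):
            raise CohortError("metadata and concentration tables differ in length")
        if len(self.x.columns) == 0:
            raise SchemaError("cohort has no marker columns")
        if self.x.columns.duplicated().any():
            dup = self.x.columns[self.x.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate marker names: {dup}")
        sid = self.meta["sample_id"]
        if sid.duplicated().any():
            dup = sid[sid.duplicated()].tolist()
            raise CohortError(f"duplicate sample_id: {dup[:5]}")
        bad = ~self.meta["group"].isin(GROUPS)
        if bad.any():
            raise CohortError(
                f"unknown group label(s): {sorted(self.meta.loc[bad, 'group'].unique())}"
            )
        bad = ~self.meta["figo_stage"].isin(STAGES)
        if bad.any():
            raise CohortError(
                f"unknown FIGO stage label(s): {sorted(self.meta.loc[bad, 'figo_stage'].unique())}"
            )
        bad = ~self.meta["menopause"].isin(MENOPAUSE_LEVELS)
        if bad.any():
            raise CohortError(
                f"unknown menopause label(s): {sorted(self.meta.loc[bad, 'menopause'].unique())}"
            )
        vals = self.x.to_numpy(dtype=float)
        neg = np.where(np.nan_to_num(vals, nan=0.0) < 0)
        if neg[0].size:
            i, j = int(neg[0][0]), int(neg[1][0])
            raise CohortError(
                f"negative concentration at sample "
                f"{self.meta['sample_id'].iloc[i]!r}, marker {self.x.columns[j]!r}"
            )


def read_cohort(path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort from a CSV/TSV file.

    The file must have one header row with the six metadata columns
    (``sample_id, group, histology, figo_stage, menopause, age``) followed by
    one column per marker.  Delimiter (comma or tab) is auto-detected;
    encoding is UTF-8 and the missing token is ``NA``.

    Parameters
    ----------
    path
        File path or readable text handle.
    schema
        Optional mapping from canonical metadata column names to the names
        used in the file, e.g. ``{"group": "pathology"}``.
    """
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
        dtype={0: str},
    )
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in df.columns]
        if missing:
            raise SchemaError(f"mapped columns absent from file: {missing}")
        df = df.rename(columns=rename)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"required metadata columns missing: {missing}")
    marker_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not marker_cols:
        raise SchemaError("no marker columns found after the metadata columns")

    meta = df[list(META_COLUMNS)].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    for col in ("group", "histology", "menopause"):
        meta[col] = meta[col].astype(str).str.strip()
    meta["figo_stage"] = (
        meta["figo_stage"].fillna("none").astype(str).str.strip().replace({"nan": "none"})
    )
    meta["menopause"] = meta["menopause"].replace({"nan": "unknown"})
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")

    x = df[marker_cols].copy()
    for col in marker_cols:
        try:
            x[col] = pd.to_numeric(x[col])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"non-numeric concentration in column {col!r}: {exc}") from exc

    cohort = CohortTable(meta.reset_index(drop=True), x.reset_index(drop=True))
    log.info("read cohort: %s", cohort.group_counts)
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as TSV (``NA`` for missing values); round-trips losslessly."""
    df = pd.concat([cohort.meta, cohort.x], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def apply_exclusions(
    cohort: CohortTable, rules: dict[str, tuple] | None = None
) -> CohortTable:
    """Drop samples matching any exclusion rule; returns a new table.

    *rules* maps a metadata field to the values to exclude.  The default
    drops borderline tumors, leaving the benign-vs-malignant contrast.
    Idempotent: re-applying the same rules is a no-op.
    """
    if rules is None:
        rules = DEFAULT_EXCLUSIONS
    drop = np.zeros(cohort.n_samples, dtype=bool)
    for fld, values in rules.items():
        if fld not in META_COLUMNS:
            raise CohortError(f"exclusion rule references unknown field {fld!r}")
        vals = (values,) if isinstance(values, str) else tuple(values)
        drop |= cohort.meta[fld].isin(vals).to_numpy()
    log.info("apply_exclusions: dropping %d of %d samples", int(drop.sum()), len(drop))
    return cohort.subset(~drop)


def _pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (0.0 when the denominator is 0)."""
    if denom == 0:
        return 0.0
    return float(np.floor(1000.0 * count / denom + 0.5) / 10.0)


@dataclass
class CohortSummary:
    """Cohort accounting: counts and one-decimal percentages per stratum.

    Group percentages use the grand total as denominator; histology and
    menopause percentages use their group's total; FIGO-stage percentages
    use the malignant total.
    """

    total: int
    group_counts: dict[str, int]
    group_pct: dict[str, float]
    histology: dict[str, dict[str, dict[str, float]]]
    menopause: dict[str, dict[str, dict[str, float]]]
    stage_counts: dict[str, int]
    stage_pct: dict[str, float]
    early_count: int = 0
    advanced_count: int = 0
    early_pct: float = 0.0
    advanced_pct: float = 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "groups": {
                g: {"count": self.group_counts[g], "pct": self.group_pct[g]}
                for g in GROUPS
            },
            "histology": self.histology,
            "menopause": self.menopause,
            "figo_stage": {
                s: {"count": self.stage_counts[s], "pct": self.stage_pct[s]}
                for s in self.stage_counts
            },
            "stage_groups": {
                "early": {"count": self.early_count, "pct": self.early_pct},
                "advanced": {"count": self.advanced_count, "pct": self.advanced_pct},
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Counts and percentages per group, histology, menopause and FIGO stage."""
    if cohort.n_samples == 0:
        raise CohortError("cannot summarize an empty cohort")
    total = cohort.n_samples
    gcounts = cohort.group_counts
    gpct = {g: _pct(gcounts[g], total) for g in GROUPS}

    histology: dict[str, dict] = {}
    menopause: dict[str, dict] = {}
    for g in GROUPS:
        sub = cohort.meta[cohort.meta["group"] == g]
        denom = len(sub)
        histology[g] = {
            h: {"count": int(c), "pct": _pct(int(c), denom)}
            for h, c in sub["histology"].value_counts().items()
        }
        menopause[g] = {
            m: {"count": int((sub["menopause"] == m).sum()),
                "pct": _pct(int((sub["menopause"] == m).sum()), denom)}
            for m in MENOPAUSE_LEVELS
        }

    mal = cohort.meta[cohort.meta["group"] == "malignant"]
    n_mal = len(mal)
    stage_counts = {s: int((mal["figo_stage"] == s).sum()) for s in ("I", "II", "III", "IV")}
    stage_pct = {s: _pct(stage_counts[s], n_mal) for s in stage_counts}
    early = stage_counts["I"] + stage_counts["II"]
    advanced = stage_counts["III"] + stage_counts["IV"]
    return CohortSummary(
        total=total,
        group_counts=gcounts,
        group_pct=gpct,
        histology=histology,
        menopause=menopause,
        stage_counts=stage_counts,
        stage_pct=stage_pct,
        early_count=early,
        advanced_count=advanced,
        early_pct=_pct(early, n_mal),
        advanced_pct=_pct(advanced, n_mal),
    )
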