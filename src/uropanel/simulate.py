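"""Synthetic urinary-biomarker cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-marker concentrations are log-normal — log10 concentrations
are (multivariate) normal with unit marginal variance — and the cancer
class is shifted by a standardized effect size ``d`` per marker.  Under
this equal-variance binormal model the population AUC of a single marker
has the closed form ``AUC = Phi(d / sqrt(2))``, so marker effects can be
calibrated to target AUCs exactly (:func:`effect_size_from_auc`).

Cohort composition defaults mirror the study being emulated: 125 benign,
12 borderline and 158 malignant samples (48 early-stage, 110
advanced-stage), a menopausal-status covariate enriched in the cancer
class, and ages drawn from the reported per-group distributions.
Borderline tumors are generated at half the cancer offset — intermediate
biology — and are expected to be excluded by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .cohort import CohortTable

# Table-style composition defaults of the emulated study
N_BENIGN, N_BORDERLINE, N_EARLY, N_ADVANCED = 125, 12, 48, 110
P_POST_BENIGN = 25 / 124  # one benign (teratoma) patient has unknown status
P_POST_CANCER = 92 / 158

_BENIGN_HISTOLOGY = (
    ("endometriosis", 44), ("teratoma", 30), ("mucinous cystadenoma", 16),
    ("serous cystadenoma", 9), ("inflammation", 5), ("other benign", 21),
)
_MALIGNANT_HISTOLOGY = (
    ("serous adenocarcinoma", 111), ("mucinous adenocarcinoma", 12),
    ("endometrioid adenocarcinoma", 15), ("clear cell carcinoma", 12),
    ("other EOC", 3), ("granulosa cell tumor", 2), ("dysgerminoma", 1),
    ("other non-EOC", 2),
)
_STAGE_EARLY = (("I", 36), ("II", 12))
_STAGE_ADVANCED = (("III", 91), ("IV", 19))

#: the 19 markers of the emulated 23-plex with no planted effect
NULL_MARKERS = (
    "VCAM", "Leptin", "Prolactin", "CRP", "PDGF-AA", "NCAM", "Mesomark",
    "MPO", "Cyfra21-1", "CA19-9", "IL6", "MIF", "ApoAI", "ApoCIII",
    "PAI-1", "CA125", "OPN", "IL8", "CA15-3",
)


def effect_size_from_auc(target_auc: float) -> float:
    """Standardized mean difference d with binormal AUC equal to *target_auc*.

    Inverts ``AUC = Phi(d / sqrt(2))``; requires ``0.5 < target_auc < 1``.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError(f"target AUC must be in (0.5, 1), got {target_auc}")
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


@dataclass(frozen=True)
class MarkerSpec:
    """One marker's planted effect.

    Give either a single target AUC (``auc``) applying to all cancers, or
    stage-specific targets (``auc_early`` / ``auc_advanced``); alternatively
    pass effect sizes ``d`` / ``d_early`` / ``d_advanced`` directly.
    ``direction`` +1 means higher in cancer, -1 lower in cancer.
    """

    name: str
    auc: float | None = None
    auc_early: float | None = None
    auc_advanced: float | None = None
    d: float | None = None
    d_early: float | None = None
    d_advanced: float | None = None
    direction: int = +1

    def effects(self) -> tuple[float, float]:
        """(d_early, d_advanced) as unsigned magnitudes."""
        if self.d is not None:
            return self.d, self.d
        if self.d_early is not None or self.d_advanced is not None:
            de = self.d_early if self.d_early is not None else 0.0
            da = self.d_advanced if self.d_advanced is not None else 0.0
            return de, da
        if self.auc is not None:
            d = effect_size_from_auc(self.auc)
            return d, d
        de = effect_size_from_auc(self.auc_early) if self.auc_early else 0.0
        da = effect_size_from_auc(self.auc_advanced) if self.auc_advanced else 0.0
        return de, da

    @property
    def informative(self) -> bool:
        de, da = self.effects()
        return de != 0.0 or da != 0.0


@dataclass
class SimulationConfig:
    """Cohort composition, marker effects and covariate model."""

    markers: list[MarkerSpec]
    n_benign: int = N_BENIGN
    n_borderline: int = N_BORDERLINE
    n_cancer_early: int = N_EARLY
    n_cancer_advanced: int = N_ADVANCED
    correlation: np.ndarray | None = None  # log-scale, identity if None
    p_post_benign: float = P_POST_BENIGN
    p_post_cancer: float = P_POST_CANCER
    one_unknown_menopause: bool = True  # mirror the single unstated-status patient
    seed: int = 0

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        for n in (self.n_benign, self.n_borderline, self.n_cancer_early,
                  self.n_cancer_advanced):
            if n < 0:
                raise ValueError("class counts must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    effects: dict[str, tuple[float, float]]  # name -> signed (d_early, d_advanced)
    informative: tuple[str, ...]
    latent_score: np.ndarray = field(repr=False, default=None)  # Bayes-optimal linear score


def _draw_categorical(rng, items, n):
    names = [k for k, _ in items]
    w = np.array([c for _, c in items], dtype=float)
    return rng.choice(names, size=n, p=w / w.sum())


def _truncated_normal(rng, mean, sd, low, n):
    a = (low - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort; fully determined by ``config.seed``.

    log10 concentrations are multivariate normal with unit marginal
    variances: benign mean 0, cancer mean ``direction * d`` per marker
    (stage-specific where configured), borderline at half the average
    cancer offset.  A per-marker baseline (uniform in [1, 4] log10 units)
    shifts all classes equally, giving concentration scales spanning
    orders of magnitude without affecting any class contrast.
    """
    rng = np.random.default_rng(config.seed)
    p = len(config.markers)
    if p == 0:
        raise ValueError("config must specify at least one marker")
    names = [m.name for m in config.markers]

    if config.correlation is None:
        chol = np.eye(p)
    else:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (p, p) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric p x p matrix")
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc

    nb, nl, ne, na = (config.n_benign, config.n_borderline,
                      config.n_cancer_early, config.n_cancer_advanced)
    n = nb + nl + ne + na
    group = np.array(
        ["benign"] * nb + ["borderline"] * nl + ["malignant"] * (ne + na), dtype=object
    )
    stage = np.array(["none"] * (nb + nl)
                     + ["early"] * ne + ["advanced"] * na, dtype=object)

    d_early = np.array([m.effects()[0] * m.direction for m in config.markers])
    d_adv = np.array([m.effects()[1] * m.direction for m in config.markers])
    d_mid = 0.5 * 0.5 * (d_early + d_adv)  # borderline: half the average offset
    mean = np.zeros((n, p))
    mean[stage == "early"] = d_early
    mean[stage == "advanced"] = d_adv
    mean[group == "borderline"] = d_mid

    z = rng.standard_normal((n, p)) @ chol.T + mean
    baseline = rng.uniform(1.0, 4.0, size=p)
    conc = np.power(10.0, z + baseline)

    figo = np.full(n, "none", dtype=object)
    figo[stage == "early"] = _draw_categorical(rng, _STAGE_EARLY, ne)
    figo[stage == "advanced"] = _draw_categorical(rng, _STAGE_ADVANCED, na)

    histology = np.empty(n, dtype=object)
    histology[group == "benign"] = _draw_categorical(rng, _BENIGN_HISTOLOGY, nb)
    histology[group == "borderline"] = "borderline tumor"
    histology[group == "malignant"] = _draw_categorical(rng, _MALIGNANT_HISTOLOGY, ne + na)

    menopause = np.empty(n, dtype=object)
    is_cancer = group == "malignant"
    p_post = np.where(is_cancer, config.p_post_cancer, config.p_post_benign)
    menopause[:] = np.where(rng.uniform(size=n) < p_post, "post", "pre")
    if config.one_unknown_menopause and nb > 0:
        k = int(np.flatnonzero(group == "benign")[0])
        histology[k] = "teratoma"
        menopause[k] = "unknown"

    age = np.empty(n)
    age[~is_cancer] = _truncated_normal(rng, 40.6, 12.2, 18.0, int((~is_cancer).sum()))
    age[is_cancer] = _truncated_normal(rng, 53.8, 10.4, 18.0, int(is_cancer.sum()))

    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "group": group,
            "histology": histology,
            "figo_stage": figo,
            "menopause": menopause,
            "age": np.round(age, 1),
        }
    )
    x = pd.DataFrame(conc, columns=names)
    cohort = CohortTable(meta, x)

    effects = {
        m.name: (m.effects()[0] * m.direction, m.effects()[1] * m.direction)
        for m in config.markers
    }
    informative = tuple(m.name for m in config.markers if m.informative)
    # Bayes-optimal linear discriminant on the log scale (identity covariance)
    w = 0.5 * (d_early + d_adv)
    if config.correlation is not None:
        w = np.linalg.solve(np.asarray(config.correlation, dtype=float), w)
    latent = z @ w
    truth = GroundTruth(effects=effects, informative=informative, latent_score=latent)
    return cohort, truth


def paperlike_scenario(seed: int = 0, correlated: bool = False) -> SimulationConfig:
    """Default study-like scenario: 4 informative + 19 null markers.

    Informative markers are calibrated to the emulated study's all-sample
    single-marker AUCs — HE4 0.822 (higher in cancer), CEA 0.627 and
    creatinine 0.622 (both lower in cancer) — and TTR stage-specifically
    (AUC 0.789 early / 0.757 advanced, higher in cancer), so the TTR analog
    outperforms its own advanced-stage column early, mirroring the pattern
    that motivates a multimarker panel.  The remaining 19 markers of the
    23-plex carry no effect.  ``correlated=True`` adds uniform r = 0.3
    among the informative markers, a stress preset for panel-level tests.
    """
    markers = [
        MarkerSpec("HE4", auc=0.822, direction=+1),
        MarkerSpec("TTR", auc_early=0.789, auc_advanced=0.757, direction=+1),
        MarkerSpec("CEA", auc=0.627, direction=-1),
        MarkerSpec("Creatinine", auc=0.622, direction=-1),
    ]
    markers += [MarkerSpec(name) for name in NULL_MARKERS]
    corr = None
    if correlated:
        p = len(markers)
        corr = np.eye(p)
        for i in range(4):
            for j in range(4):
                if i != j:
                    corr[i, j] = 0.3
    return SimulationConfig(markers=markers, correlation=corr, seed=seed)


def binormal_single_marker(
    d: float,
    n_benign: int,
    n_cancer: int,
    seed: int = 0,
    name: str = "marker",
) -> SimulationConfig:
    """Minimal scenario: one marker with explicit effect size, no borderline."""
    return SimulationConfig(
        markers=[MarkerSpec(name, d=abs(d), direction=+1 if d >= 0 else -1)],
        n_benign=n_benign,
        n_borderline=0,
        n_cancer_early=0,
        n_cancer_advanced=n_cancer,
        seed=seed,
    )
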