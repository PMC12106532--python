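"""Synthetic paediatric sepsis/healthy cohort generator.

Generates cohorts whose statistical structure mirrors the discovery study
the downstream analysis is designed for: a discovery cohort of 39 sepsis
and 19 healthy children (validation: 20 + 15), ~20 true cell populations
of which 4 are enriched and 7 depleted in sepsis, planted inter-subset
correlation structure that differs by group (one dense cross-lineage
mixed-sign factor in health; two sparse all-positive modules in sepsis),
and clinical covariates coupled to specific subset frequencies
(monocyte-procalcitonin r=0.68, Th17-lactate r=0.57).

Model
-----
Subject-level subset abundances follow a logistic-normal: a log-ratio
vector is drawn from a group-specific Gaussian and closed onto the simplex
with a softmax.  Unlike a Dirichlet this supports planted positive *and*
negative correlations between subset frequencies, which the network module
must later recover.  Event-level intensities are zero-inflated lognormal
per marker (see :mod:`immunet.panel`).

Sepsis effect sizes are specified as Cohen's d on the observed frequency
scale; a deterministic internal Monte-Carlo calibration converts them into
additive log-ratio shifts (the closure makes the mapping nonlinear).
Clinical lab couplings are linear-in-frequency with Gaussian noise whose
variance is set analytically from the calibrated frequency moments, so the
population Pearson correlation equals the coupling target exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import as_rng, check_psd, closure
from .panel import (
    MarkerPanel,
    PopulationArchetype,
    centroid_separation,
    default_archetypes,
    default_panel,
)
from .preprocess import EventMatrix

# fixed internal seed for scenario calibration (part of the model
# definition, independent of any cohort-generation seed)
_CALIBRATION_SEED = 271828
_CALIBRATION_N = 8000

#: target Cohen's d (frequency scale) per differential archetype index;
#: positive = enriched in sepsis.  Indices follow DEFAULT_ARCHETYPE_SPEC.
DEFAULT_EFFECT_TARGETS: dict[int, float] = {
    0: 1.5,   # CD15+CD14+ monocytes (largest effect)
    1: 1.4,   # CD45RA-CX3CR1+CTLA4+CD4+ T
    2: 1.3,   # CD45RA-IL17A+CD4+ T
    3: 1.2,   # Ki67+ B
    4: -1.2,  # naive Treg
    5: -1.1,  # temra CD4
    6: -1.0,  # temra CD8
    7: -0.9,  # GATA3+CD56++ NK
    8: -0.8,  # Lin-HLADR+IL8+
    9: -1.0,  # IL8+ naive CD8
    10: -1.1,  # IL8+ naive CD4
}

#: baseline healthy mean frequencies (%) per archetype
DEFAULT_BASE_FREQ = np.array(
    [2.5, 1.0, 0.8, 0.8, 2.0, 2.5, 3.0, 1.5, 1.5, 3.0, 4.0,
     11.0, 6.0, 7.0, 2.0, 9.0, 9.0, 9.0, 3.0, 1.4]
)

_LOGRATIO_SD = 0.35          # per-subset biological dispersion, log-ratio scale
_FACTOR_RHO = 0.8            # planted block correlation magnitude

# healthy: one rank-1 factor over small/medium cross-lineage subsets;
# negative loadings on naive Treg (4), central-memory CD4 (13) and
# PD1+CD152+TIGIT+ emCD4 (14) plant the negative (regulatory) edges.
# Loading signs are roughly mass-balanced so compositional closure does
# not attenuate the planted structure.
_HEALTHY_BLOCK = (4, 5, 6, 7, 8, 9, 10, 13, 14, 18)
_HEALTHY_NEGATIVE = (4, 13, 14)
# sepsis: two disjoint all-positive equicorrelated modules (CD4-centric
# and CD8-centric), nothing across them
_SEPSIS_MODULES = ((1, 2, 13, 14), (6, 9, 12))

DEFAULT_COUPLINGS = (
    ("CD15+CD14+ monocytes", "procalcitonin", 0.68),
    ("CD45RA-IL17A+CD4+ T", "lactate", 0.57),
)

#: lab location/scale for the linear-in-frequency clinical model
_LAB_PARAMS = {
    "procalcitonin": (20.0, 6.0),  # ng/mL
    "lactate": (2.5, 0.55),        # mmol/L
    "crp": (120.0, 55.0),          # mg/L
    "wbc": (11.0, 4.5),            # 10^9/L
}

#: outcome prevalences among sepsis subjects and logistic slopes on the
#: standardized frequencies of the three non-proliferative enriched subsets
_OUTCOME_SPEC = {
    "severe_sepsis": (0.746, (0.8, 0.6, 0.6)),
    "septic_shock": (0.729, (0.7, 0.6, 0.7)),
    "multiorgan_dysfunction": (0.695, (0.7, 0.5, 0.6)),
    "picu_mortality": (0.136, (0.9, 0.6, 0.9)),
}
_OUTCOME_SUBSETS = (0, 1, 2)  # monocytes, CX3CR1+CTLA4+ CD4, Th17

# age-group sampling follows the cohort table: (upper bounds in years,
# probabilities) per group
_AGE_BANDS = ((1 / 12, 1.0, 12.0, 18.0), (1 / 365,))
_AGE_PROBS = {
    "sepsis": np.array([0.017, 0.186, 0.559, 0.237]),
    "healthy": np.array([0.059, 0.088, 0.735, 0.118]),
}

SEPSIS, HEALTHY = "sepsis", "healthy"


def _build_correlation(n_subsets: int) -> tuple[np.ndarray, np.ndarray]:
    """Planted log-ratio correlation matrices (healthy, sepsis)."""
    r_h = np.eye(n_subsets)
    sign = {i: (-1.0 if i in _HEALTHY_NEGATIVE else 1.0) for i in _HEALTHY_BLOCK}
    for i in _HEALTHY_BLOCK:
        for j in _HEALTHY_BLOCK:
            if i != j:
                r_h[i, j] = _FACTOR_RHO * sign[i] * sign[j]
    r_s = np.eye(n_subsets)
    for module in _SEPSIS_MODULES:
        for i in module:
            for j in module:
                if i != j:
                    r_s[i, j] = _FACTOR_RHO
    return r_h, r_s


@dataclass
class CohortScenario:
    """Everything needed to generate one cohort reproducibly.

    ``group_shift`` holds the calibrated additive log-ratio shifts applied
    to sepsis subjects; ``freq_moments`` holds the population mean/sd of
    each subset's frequency (%) per group, computed during calibration and
    used for the clinical couplings and outcome models.
    """

    n_sepsis: int
    n_healthy: int
    archetypes: list[PopulationArchetype]
    panel: MarkerPanel
    base_logratio_mean: np.ndarray
    group_shift: np.ndarray
    covariance_healthy: np.ndarray
    covariance_sepsis: np.ndarray
    clinical_couplings: tuple[tuple[str, str, float], ...]
    outcome_model: dict[str, tuple[float, dict[str, float]]]
    events_per_subject: int = 60_000
    seed: int = 0
    effect_targets: dict[int, float] = field(default_factory=dict)
    freq_moments: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    planted_adjacency: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        check_psd(self.covariance_healthy, "covariance_healthy")
        check_psd(self.covariance_sepsis, "covariance_sepsis")
        for _, _, r in self.clinical_couplings:
            if abs(r) >= 1:
                raise ValueError(f"coupling |r| must be < 1, got {r}")

    @property
    def n_subsets(self) -> int:
        return len(self.archetypes)

    @property
    def subset_names(self) -> list[str]:
        return [a.name for a in self.archetypes]

    def subject_ids(self) -> tuple[list[str], list[str]]:
        sep = [f"S{i + 1:03d}" for i in range(self.n_sepsis)]
        hea = [f"H{i + 1:03d}" for i in range(self.n_healthy)]
        return sep, hea


def _calibrate_shifts(
    base: np.ndarray,
    cov_h: np.ndarray,
    cov_s: np.ndarray,
    targets: dict[int, float],
    n_sepsis: int,
    n_healthy: int,
) -> tuple[np.ndarray, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Find log-ratio shifts achieving the target frequency-scale Cohen's d.

    Uses common random numbers (one fixed draw of standard normals) so the
    objective is smooth and the fixed-point iteration deterministic.
    """
    k = len(base)
    rng = np.random.default_rng(np.random.SeedSequence(_CALIBRATION_SEED))
    zh = rng.standard_normal((_CALIBRATION_N, k))
    zs = rng.standard_normal((_CALIBRATION_N, k))
    lh = np.linalg.cholesky(cov_h + 1e-12 * np.eye(k))
    ls = np.linalg.cholesky(cov_s + 1e-12 * np.eye(k))
    xh = base + zh @ lh.T
    fh = closure(xh) * 100.0
    sd0 = np.sqrt(np.diag(cov_h))
    shift = np.zeros(k)
    for i, d in targets.items():
        shift[i] = d * sd0[i]
    w_s, w_h = n_sepsis - 1, n_healthy - 1
    for _ in range(10):
        fs = closure(base + shift + zs @ ls.T) * 100.0
        for i, d in targets.items():
            pooled = np.sqrt(
                (w_s * fs[:, i].var(ddof=1) + w_h * fh[:, i].var(ddof=1))
                / (w_s + w_h)
            )
            realized = (fs[:, i].mean() - fh[:, i].mean()) / pooled
            if abs(realized) < 1e-3:
                shift[i] += np.sign(d) * 0.05
            else:
                shift[i] *= np.clip(d / realized, 0.25, 4.0)
    fs = closure(base + shift + zs @ ls.T) * 100.0
    moments = {
        HEALTHY: (fh.mean(axis=0), fh.std(axis=0, ddof=1)),
        SEPSIS: (fs.mean(axis=0), fs.std(axis=0, ddof=1)),
    }
    return shift, moments


def _calibrate_outcomes(
    names: list[str],
    moments: dict[str, tuple[np.ndarray, np.ndarray]],
    base: np.ndarray,
    shift: np.ndarray,
    cov_s: np.ndarray,
) -> dict[str, tuple[float, dict[str, float]]]:
    """Intercept-calibrate the logistic outcome models to target prevalences."""
    k = len(base)
    rng = np.random.default_rng(np.random.SeedSequence(_CALIBRATION_SEED + 1))
    ls = np.linalg.cholesky(cov_s + 1e-12 * np.eye(k))
    fs = closure(base + shift + rng.standard_normal((_CALIBRATION_N, k)) @ ls.T) * 100.0
    mu, sd = moments[SEPSIS]
    z = (fs[:, list(_OUTCOME_SUBSETS)] - mu[list(_OUTCOME_SUBSETS)]) / sd[
        list(_OUTCOME_SUBSETS)
    ]
    out = {}
    for outcome, (prev, betas) in _OUTCOME_SPEC.items():
        eta = z @ np.asarray(betas)
        b0 = brentq(lambda b: expit(b + eta).mean() - prev, -20.0, 20.0)
        out[outcome] = (
            float(b0),
            {names[i]: float(b) for i, b in zip(_OUTCOME_SUBSETS, betas)},
        )
    return out


def build_default_scenario(
    n_sepsis: int = 39,
    n_healthy: int = 19,
    events_per_subject: int = 60_000,
    seed: int = 0,
) -> CohortScenario:
    """The default discovery scenario: 39 sepsis + 19 healthy subjects,
    20 archetypes (11 differential: 4 enriched, 7 depleted), planted
    group-specific correlation structure and clinical couplings."""
    panel = default_panel()
    archetypes = default_archetypes(panel)
    k = len(archetypes)
    base = np.log(DEFAULT_BASE_FREQ / DEFAULT_BASE_FREQ.sum())
    r_h, r_s = _build_correlation(k)
    sd = np.full(k, _LOGRATIO_SD)
    cov_h = np.outer(sd, sd) * r_h
    cov_s = np.outer(sd, sd) * r_s
    shift, moments = _calibrate_shifts(
        base, cov_h, cov_s, DEFAULT_EFFECT_TARGETS, n_sepsis, n_healthy
    )
    names = [a.name for a in archetypes]
    outcome_model = _calibrate_outcomes(names, moments, base, shift, cov_s)
    adjacency = {
        HEALTHY: [
            (i, j) for i in _HEALTHY_BLOCK for j in _HEALTHY_BLOCK if i < j
        ],
        SEPSIS: [
            (i, j)
            for module in _SEPSIS_MODULES
            for i in module
            for j in module
            if i < j
        ],
    }
    return CohortScenario(
        n_sepsis=n_sepsis,
        n_healthy=n_healthy,
        archetypes=archetypes,
        panel=panel,
        base_logratio_mean=base,
        group_shift=shift,
        covariance_healthy=cov_h,
        covariance_sepsis=cov_s,
        clinical_couplings=DEFAULT_COUPLINGS,
        outcome_model=outcome_model,
        events_per_subject=events_per_subject,
        seed=seed,
        effect_targets=dict(DEFAULT_EFFECT_TARGETS),
        freq_moments=moments,
        planted_adjacency=adjacency,
    )


def build_validation_scenario(seed: int = 0, events_per_subject: int = 60_000) -> CohortScenario:
    """The validation scenario: 20 sepsis + 15 healthy subjects."""
    return build_default_scenario(
        n_sepsis=20, n_healthy=15, events_per_subject=events_per_subject, seed=seed
    )


def build_null_scenario(
    n_sepsis: int = 39,
    n_healthy: int = 19,
    events_per_subject: int = 60_000,
    seed: int = 0,
) -> CohortScenario:
    """A no-effect scenario for type-I-error simulation: zero group shift
    and identical (healthy) covariance in both groups, so the two groups
    have identical frequency distributions."""
    sc = build_default_scenario(
        n_sepsis=n_sepsis,
        n_healthy=n_healthy,
        events_per_subject=events_per_subject,
        seed=seed,
    )
    sc.group_shift = np.zeros_like(sc.group_shift)
    sc.covariance_sepsis = sc.covariance_healthy.copy()
    sc.effect_targets = {}
    sc.planted_adjacency = {
        HEALTHY: sc.planted_adjacency[HEALTHY],
        SEPSIS: sc.planted_adjacency[HEALTHY],
    }
    return sc


def simulate_compositions(
    scenario: CohortScenario, group: str, rng, n: int | None = None
) -> np.ndarray:
    """Draw per-subject composition vectors (rows sum to 1) for *group*."""
    if group not in (SEPSIS, HEALTHY):
        raise ValueError(f"group must be 'sepsis' or 'healthy', got {group!r}")
    rng = as_rng(rng)
    if n is None:
        n = scenario.n_sepsis if group == SEPSIS else scenario.n_healthy
    mean = scenario.base_logratio_mean.copy()
    if group == SEPSIS:
        mean = mean + scenario.group_shift
        cov = scenario.covariance_sepsis
    else:
        cov = scenario.covariance_healthy
    check_psd(cov)
    k = len(mean)
    if np.allclose(cov, 0):
        x = np.tile(mean, (n, 1))
    else:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        x = mean + rng.standard_normal((n, k)) @ chol.T
    return closure(x)


def simulate_events(
    composition: np.ndarray,
    archetypes: list[PopulationArchetype],
    events_per_subject: int,
    rng,
    panel: MarkerPanel | None = None,
    subject_id: str = "S000",
    group: str = SEPSIS,
) -> EventMatrix:
    """Draw one subject's event matrix (raw scale) with true labels.

    Each event is assigned a population by a multinomial draw weighted by
    the subject's composition, then its marker intensities come from that
    archetype's zero-inflated lognormal model.
    """
    if not archetypes:
        raise ValueError("archetype list is empty")
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (len(archetypes),):
        raise ValueError(
            f"composition length {composition.shape} does not match "
            f"{len(archetypes)} archetypes"
        )
    if events_per_subject < 1:
        raise ValueError("events_per_subject must be >= 1")
    rng = as_rng(rng)
    panel = panel or default_panel()
    counts = rng.multinomial(events_per_subject, composition)
    n_markers = len(panel)
    values = np.empty((events_per_subject, n_markers))
    labels = np.empty(events_per_subject, dtype=int)
    row = 0
    for pop_idx, (arch, cnt) in enumerate(zip(archetypes, counts)):
        if cnt == 0:
            continue
        expressed = rng.random((cnt, n_markers)) >= arch.dropout
        intensity = rng.lognormal(
            mean=np.log(arch.mean_raw), sigma=arch.dispersion, size=(cnt, n_markers)
        )
        values[row : row + cnt] = expressed * intensity
        labels[row : row + cnt] = pop_idx
        row += cnt
    order = rng.permutation(events_per_subject)
    return EventMatrix(
        subject_id=subject_id,
        group=group,
        markers=list(panel.markers),
        values=values[order],
        scale="raw",
        labels=labels[order],
    )


def _draw_ages(group: str, n: int, rng) -> np.ndarray:
    probs = _AGE_PROBS[group] / _AGE_PROBS[group].sum()
    bands = ((0.0, 1 / 12), (1 / 12, 1.0), (1.0, 12.0), (12.0, 18.0))
    idx = rng.choice(4, size=n, p=probs)
    lo = np.array([bands[i][0] for i in idx])
    hi = np.array([bands[i][1] for i in idx])
    return lo + rng.random(n) * (hi - lo)


def _coupled_lab(freq, mu, sd, target_r, loc, scale, rng):
    """loc + scale * (r * z(freq) + sqrt(1-r^2) * eps): population Pearson
    correlation with freq equals target_r exactly."""
    z = (freq - mu) / sd
    eps = rng.standard_normal(len(freq))
    return loc + scale * (target_r * z + np.sqrt(1 - target_r**2) * eps)


def simulate_clinical(
    scenario: CohortScenario,
    compositions: np.ndarray,
    group: str,
    rng,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Generate the clinical table for one group's composition matrix.

    Sepsis subjects receive severity scores (pSOFA always >= 2, matching
    the organ-dysfunction-based sepsis definition), labs coupled to subset
    frequencies per the scenario, and outcomes from the logistic model.
    Healthy subjects carry missing severity/lab fields and negative
    outcomes.
    """
    rng = as_rng(rng)
    compositions = np.atleast_2d(np.asarray(compositions, dtype=float))
    n = compositions.shape[0]
    if subject_ids is None:
        prefix = "S" if group == SEPSIS else "H"
        subject_ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    freq = compositions * 100.0
    rec = pd.DataFrame({"subject_id": subject_ids, "group": group})
    rec["age_years"] = _draw_ages(group, n, rng)
    sites = ("respiratory", "systemic", "gastrointestinal",
             "central nervous system", "musculoskeletal", "genitourinary")
    site_p = np.array([0.712, 0.085, 0.119, 0.034, 0.034, 0.017])
    numeric = ["psofa", "pelod2", "pim3", "crp", "procalcitonin", "lactate", "wbc"]
    outcomes = list(_OUTCOME_SPEC)
    if group == HEALTHY:
        for col in numeric:
            rec[col] = np.nan
        rec["site_of_infection"] = pd.array([pd.NA] * n, dtype="string")
        for col in outcomes:
            rec[col] = False
        return rec

    names = scenario.subset_names
    mu, sd = scenario.freq_moments[SEPSIS]
    zsub = (freq[:, list(_OUTCOME_SUBSETS)] - mu[list(_OUTCOME_SUBSETS)]) / sd[
        list(_OUTCOME_SUBSETS)
    ]
    severity = zsub.mean(axis=1)

    def score(loc, scale, lo, hi, coupling=0.45):
        raw = loc + scale * (
            coupling * severity + np.sqrt(1 - coupling**2) * rng.standard_normal(n)
        )
        return np.clip(np.round(raw), lo, hi)

    rec["psofa"] = score(8.0, 4.4, 2, 24)
    rec["pelod2"] = score(6.0, 3.7, 0, 33)
    pim_raw = np.log(3.4) + 0.9 * (
        0.35 * severity + np.sqrt(1 - 0.35**2) * rng.standard_normal(n)
    )
    rec["pim3"] = np.clip(np.exp(pim_raw), 0.1, 60.0).round(2)

    coupled_vars = {var: (name, r) for name, var, r in scenario.clinical_couplings}
    for var, (loc, scale) in _LAB_PARAMS.items():
        if var in coupled_vars:
            name, r = coupled_vars[var]
            i = names.index(name)
            vals = _coupled_lab(freq[:, i], mu[i], sd[i], r, loc, scale, rng)
        else:
            vals = loc + scale * rng.standard_normal(n)
        rec[var] = np.maximum(vals, 0.05).round(3)
    rec["site_of_infection"] = pd.array(
        rng.choice(sites, size=n, p=site_p / site_p.sum()), dtype="string"
    )
    for outcome in outcomes:
        b0, betas = scenario.outcome_model[outcome]
        eta = b0 + sum(
            beta * zsub[:, _OUTCOME_SUBSETS.index(names.index(name))]
            for name, beta in betas.items()
        )
        rec[outcome] = rng.random(n) < expit(eta)
    return rec[
        ["subject_id", "group", "age_years"] + numeric + ["site_of_infection"] + outcomes
    ]


def simulate_frequency_table(
    scenario: CohortScenario, rng
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Composition-level cohort: exact subset-frequency table (%), group
    labels, and clinical table — no event-level sampling.

    This is the fast path used for statistical simulations where the
    binomial event-sampling noise (negligible at 50,000 events) is not of
    interest.
    """
    rng = as_rng(rng)
    comp_s = simulate_compositions(scenario, SEPSIS, rng)
    comp_h = simulate_compositions(scenario, HEALTHY, rng)
    ids_s, ids_h = scenario.subject_ids()
    clin_s = simulate_clinical(scenario, comp_s, SEPSIS, rng, ids_s)
    clin_h = simulate_clinical(scenario, comp_h, HEALTHY, rng, ids_h)
    freq = pd.DataFrame(
        np.vstack([comp_s, comp_h]) * 100.0,
        index=ids_s + ids_h,
        columns=scenario.subset_names,
    )
    groups = pd.Series([SEPSIS] * len(ids_s) + [HEALTHY] * len(ids_h), index=freq.index)
    clinical = pd.concat([clin_s, clin_h], ignore_index=True)
    return freq, groups, clinical


def generate_cohort(scenario: CohortScenario, outdir) -> Path:
    """Write a full cohort to disk: one event TSV per subject, the clinical
    table, and a truth sidecar (JSON) for recovery testing.

    Fully reproducible from ``scenario.seed``.
    """
    outdir = Path(outdir)
    events_dir = outdir / "events"
    events_dir.mkdir(parents=True, exist_ok=True)
    sep = centroid_separation(scenario.archetypes)
    if sep < 1.0:
        warnings.warn(
            f"archetype centroid separation {sep:.2f} is small; populations "
            "may not be recoverable by clustering"
        )
    rng = as_rng(scenario.seed)
    comp_s = simulate_compositions(scenario, SEPSIS, rng)
    comp_h = simulate_compositions(scenario, HEALTHY, rng)
    ids_s, ids_h = scenario.subject_ids()
    clinical = pd.concat(
        [
            simulate_clinical(scenario, comp_s, SEPSIS, rng, ids_s),
            simulate_clinical(scenario, comp_h, HEALTHY, rng, ids_h),
        ],
        ignore_index=True,
    )
    for ids, comps, group in ((ids_s, comp_s, SEPSIS), (ids_h, comp_h, HEALTHY)):
        for sid, comp in zip(ids, comps):
            em = simulate_events(
                comp,
                scenario.archetypes,
                scenario.events_per_subject,
                rng,
                scenario.panel,
                subject_id=sid,
                group=group,
            )
            em.to_tsv(events_dir / f"{sid}.tsv")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth = {
        "subset_names": scenario.subset_names,
        "lineages": [a.lineage for a in scenario.archetypes],
        "compositions": {
            sid: comp.tolist()
            for sid, comp in zip(ids_s + ids_h, np.vstack([comp_s, comp_h]))
        },
        "group_shift": scenario.group_shift.tolist(),
        "effect_targets": {str(k): v for k, v in scenario.effect_targets.items()},
        "covariance_healthy": scenario.covariance_healthy.tolist(),
        "covariance_sepsis": scenario.covariance_sepsis.tolist(),
        "clinical_couplings": [list(c) for c in scenario.clinical_couplings],
        "planted_adjacency": {
            g: [list(p) for p in pairs]
            for g, pairs in scenario.planted_adjacency.items()
        },
        "events_per_subject": scenario.events_per_subject,
        "seed": scenario.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir
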