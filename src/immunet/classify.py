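"""Subset-frequency diagnostic/prognostic models and ROC evaluation.

The biomarker panel models are logistic regressions on subset frequencies
(optionally age-adjusted): the 4-subset diagnostic model (CD15+CD14+
monocytes, CD45RA-CX3CR1+CTLA4+CD4+ T, CD45RA-IL17A+CD4+ T, Ki67+ B) and
the 3-subset variant without Ki67+ B used for outcome prediction among
sepsis subjects.  Performance: trapezoidal AUROC (identical to the
Mann-Whitney rank estimator), DeLong-style asymptotic 95% CI, and
sensitivity/specificity/PPV/NPV at the Youden-J cutoff.  Comparator
models evaluate clinical severity scores and routine labs on the same
metric contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SEPSIS, HEALTHY = "sepsis", "healthy"

FOUR_SUBSETS = (
    "CD15+CD14+ monocytes",
    "CD45RA-CX3CR1+CTLA4+CD4+ T",
    "CD45RA-IL17A+CD4+ T",
    "Ki67+ B",
)
THREE_SUBSETS = FOUR_SUBSETS[:3]

COMPARATORS = ("psofa", "pelod2", "pim3", "crp", "procalcitonin", "lactate")


# ---------------------------------------------------------------- ROC ----

def trapezoid_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the trapezoidal rule over the ROC curve at every threshold."""
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney rank estimator: P(case score > control score) + ties/2."""
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds) sweeping 'predict positive if score >= t'."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.where(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = distinct + 1 - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return fpr, tpr, thresholds


def delong_ci(scores, labels, level: float = 0.95):
    """DeLong asymptotic variance of the AUC -> (auc, lo, hi), clipped."""
    labels = np.asarray(labels, dtype=bool)
    pos, neg = np.asarray(scores)[labels], np.asarray(scores)[~labels]
    m, n = len(pos), len(neg)
    # placement values via midranks
    all_scores = np.concatenate([pos, neg])
    rk_all = stats.rankdata(all_scores)
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    v10 = (rk_all[:m] - rk_pos) / n          # per-case placements
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m    # per-control placements
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(auc), float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


@dataclass
class ClassifierMetrics:
    model: str
    outcome: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_cases: int
    n_controls: int
    confusion: dict = field(default_factory=dict)
    separation_flag: bool = False

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "outcome": self.outcome,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        d.update(self.confusion)
        return d


def roc_metrics(scores, labels, model: str = "model", outcome: str = "outcome") -> ClassifierMetrics:
    """Full metric set at the Youden-J-optimal cutoff.

    The cutoff rule is 'positive if score >= cutoff'; among ties in J the
    lowest threshold index (highest sensitivity) wins, deterministically.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate single-class input")
    fpr, tpr, thresholds = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    _, lo, hi = delong_ci(scores, labels)
    j = tpr - fpr
    best = int(np.argmax(j))
    cutoff = float(thresholds[best])
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return ClassifierMetrics(
        model=model,
        outcome=outcome,
        auc=auc,
        auc_ci=(lo, hi),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        n_cases=n_pos,
        n_controls=n_neg,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def predictive_values(sensitivity, specificity, n_cases, n_controls):
    """(PPV, NPV) implied by sensitivity/specificity at given class sizes."""
    tp = sensitivity * n_cases
    fp = (1 - specificity) * n_controls
    tn = specificity * n_controls
    fn = (1 - sensitivity) * n_cases
    return tp / (tp + fp), tn / (tn + fn)


# ------------------------------------------------------------- models ----

@dataclass(frozen=True)
class ModelSpec:
    """Predictor list + outcome for a subset-based classifier."""

    name: str
    predictors: tuple[str, ...]
    outcome: str = "sepsis"       # sepsis | severe_sepsis | septic_shock | picu_mortality
    adjust_age: bool = True

    def __post_init__(self):
        if self.outcome not in (
            "sepsis", "severe_sepsis", "septic_shock",
            "multiorgan_dysfunction", "picu_mortality",
        ):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def four_subset_spec(outcome="sepsis", adjust_age=True) -> ModelSpec:
    return ModelSpec("4-subset", FOUR_SUBSETS, outcome, adjust_age)


def three_subset_spec(outcome="picu_mortality", adjust_age=True) -> ModelSpec:
    return ModelSpec("3-subset", THREE_SUBSETS, outcome, adjust_age)


def _design(spec: ModelSpec, freq_table, clinical):
    clin = clinical.set_index("subject_id")
    if spec.outcome == "sepsis":
        subjects = [s for s in freq_table.index if s in clin.index]
    else:
        # prognostic outcomes are defined among sepsis subjects only
        subjects = [
            s for s in freq_table.index
            if s in clin.index and clin.loc[s, "group"] == SEPSIS
        ]
    missing = [p for p in spec.predictors if p not in freq_table.columns]
    if missing:
        raise ValueError(f"predictors missing from frequency table: {missing}")
    x = freq_table.loc[subjects, list(spec.predictors)].copy()
    if spec.adjust_age:
        x["age_years"] = clin.loc[subjects, "age_years"].to_numpy()
    if spec.outcome == "sepsis":
        y = (clin.loc[subjects, "group"] == SEPSIS).to_numpy()
    else:
        y = clin.loc[subjects, spec.outcome].to_numpy().astype(bool)
    return x, pd.Series(y, index=subjects)


@dataclass
class SubsetLogitResults:
    spec: ModelSpec
    params: pd.Series
    scores: pd.Series            # predicted probabilities per subject
    labels: pd.Series
    metrics: ClassifierMetrics
    separation_flag: bool = False

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Logistic model '{self.spec.name}' for outcome '{self.spec.outcome}'"
            + ("  [perfect separation: penalized fit]" if self.separation_flag else ""),
            "  coefficients:",
        ]
        lines += [f"    {k:>28s}  {v:+.4f}" for k, v in self.params.items()]
        lines += [
            f"  AUC {m.auc:.3f} (95% CI {m.auc_ci[0]:.3f}-{m.auc_ci[1]:.3f})  "
            f"cases={m.n_cases} controls={m.n_controls}",
            f"  at Youden cutoff {m.cutoff:.4f}: sens {m.sensitivity:.1%}, "
            f"spec {m.specificity:.1%}, PPV {m.ppv:.1%}, NPV {m.npv:.1%}",
        ]
        return "\n".join(lines)


class SubsetLogit:
    """Logistic classifier on subset frequencies (+ age covariate).

    Fits by maximum likelihood (statsmodels); on perfect separation or
    non-convergence falls back to a deterministic L2-penalized fit and
    flags it.  ``fit()`` returns results carrying per-subject predicted
    probabilities and the ROC metric set.
    """

    def __init__(self, spec: ModelSpec, freq_table: pd.DataFrame, clinical: pd.DataFrame):
        self.spec = spec
        self.x, self.y = _design(spec, freq_table, clinical)
        if self.y.nunique() < 2:
            raise ValueError(f"outcome {spec.outcome!r} has a single class")

    def fit(self) -> SubsetLogitResults:
        import statsmodels.api as sm

        xmat = sm.add_constant(self.x.to_numpy(dtype=float))
        yvec = self.y.to_numpy(dtype=float)
        names = ["const"] + list(self.x.columns)
        separation = False
        params = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(yvec, xmat).fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", True) or np.any(
                    ~np.isfinite(fit.bse)
                ):
                    separation = True
                else:
                    params = fit.params
            except Exception:
                separation = True
        if separation:
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
            lr.fit(self.x.to_numpy(dtype=float), yvec)
            params = np.r_[lr.intercept_, lr.coef_.ravel()]
        probs = 1.0 / (1.0 + np.exp(-(xmat @ params)))
        scores = pd.Series(probs, index=self.x.index, name="score")
        metrics = roc_metrics(
            probs, yvec.astype(bool), model=self.spec.name, outcome=self.spec.outcome
        )
        metrics.separation_flag = separation
        return SubsetLogitResults(
            spec=self.spec,
            params=pd.Series(params, index=names),
            scores=scores,
            labels=self.y,
            metrics=metrics,
            separation_flag=separation,
        )


def fit_model(spec: ModelSpec, freq_table: pd.DataFrame, clinical: pd.DataFrame) -> SubsetLogitResults:
    return SubsetLogit(spec, freq_table, clinical).fit()


def comparator_models(
    clinical: pd.DataFrame,
    outcome: str = "picu_mortality",
    variables=COMPARATORS,
) -> dict[str, ClassifierMetrics]:
    """Single-variable ROC for clinical scores/labs against an outcome
    among sepsis subjects (the variable itself is the score; AUC is
    invariant to monotone rescaling so no model fit is needed)."""
    clin = clinical[clinical["group"] == SEPSIS]
    y = clin[outcome].to_numpy().astype(bool)
    out = {}
    for var in variables:
        if var not in clin.columns:
            continue
        vals = clin[var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() == 0:
            warnings.warn(f"comparator {var!r} all-missing; skipped")
            continue
        if y[ok].all() or not y[ok].any():
            warnings.warn(f"outcome degenerate among non-missing {var!r}; skipped")
            continue
        out[var] = roc_metrics(vals[ok], y[ok], model=var, outcome=outcome)
    return out


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Demographics/clinical characteristics table: median (IQR) for
    continuous fields per group, n (%) for categorical/boolean fields."""
    rows = []
    continuous = ["age_years", "wbc", "crp", "procalcitonin", "lactate",
                  "psofa", "pim3", "pelod2"]
    booleans = ["multiorgan_dysfunction", "severe_sepsis", "septic_shock",
                "picu_mortality"]
    for group, sub in clinical.groupby("group"):
        n = len(sub)
        for var in continuous:
            vals = sub[var].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cell = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            else:
                cell = ""
            rows.append({"group": group, "variable": var, "value": cell, "n": n})
        for var in booleans:
            k = int(sub[var].sum())
            pct = 100.0 * k / n if n else 0.0
            rows.append(
                {"group": group, "variable": var,
                 "value": f"{k} ({pct:.1f})", "n": n}
            )
        if "site_of_infection" in sub and sub["site_of_infection"].notna().any():
            for site, k in sub["site_of_infection"].value_counts().items():
                rows.append(
                    {"group": group, "variable": f"site: {site}",
                     "value": f"{k} ({100.0 * k / n:.1f})", "n": n}
                )
    return pd.DataFrame(rows)
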