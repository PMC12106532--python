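"""Per-subset differential abundance between sepsis and healthy groups.

Mann-Whitney U (two-sided; exact for small tie-free samples, otherwise the
tie/continuity-corrected normal approximation) with Bonferroni correction
across all retained subsets, classical pooled-SD Cohen's d with a normal
approximation 95% CI, an age-stratified sensitivity analysis (cut at 1
year), and Pearson/Spearman correlation matrices between subset
frequencies and clinical covariates among sepsis subjects.

The significance threshold (default 0.1) applies to the Bonferroni
ADJUSTED p-value; raw p-values are reported alongside so either reading
of the "cutoff p < 0.1 after correction" convention can be inspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SEPSIS, HEALTHY = "sepsis", "healthy"

#: coefficient used per clinical variable: Pearson for continuous labs,
#: Spearman for ordinal severity scores
CLINICAL_COEFFICIENTS = {
    "crp": "pearson",
    "procalcitonin": "pearson",
    "lactate": "pearson",
    "wbc": "pearson",
    "psofa": "spearman",
    "pelod2": "spearman",
    "pim3": "spearman",
}


def cohens_d(x: np.ndarray, y: np.ndarray, hedges: bool = False):
    """Pooled-SD Cohen's d of x (sepsis) vs y (healthy) with 95% CI.

    Positive d = higher in x.  CI from the standard normal approximation
    of the d sampling variance.  Returns (d, lo, hi); d is NaN when the
    pooled SD is zero.
    """
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled <= 0:
        return np.nan, np.nan, np.nan
    d = (np.mean(x) - np.mean(y)) / pooled
    if hedges:
        d *= 1 - 3 / (4 * (n1 + n2) - 9)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return d, d - 1.96 * se, d + 1.96 * se


@dataclass
class DifferentialAbundanceResults:
    """Per-subset test table plus the settings that produced it."""

    table: pd.DataFrame
    alpha: float
    m: int
    n_sepsis: int
    n_healthy: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        sig = self.table["significant"].sum()
        up = ((self.table["direction"] == "up") & self.table["significant"]).sum()
        lines = [
            "Differential abundance (Mann-Whitney U, Bonferroni-corrected)",
            f"  subsets tested (m): {self.m}   sepsis n={self.n_sepsis}, "
            f"healthy n={self.n_healthy}",
            f"  significant at adjusted p < {self.alpha}: {sig} "
            f"({up} up, {sig - up} down in sepsis)",
            "",
            self.table.round(4).to_string(),
        ]
        return "\n".join(lines)


class DifferentialAbundance:
    """Model: subset frequency table + group labels -> per-subset tests.

    Parameters
    ----------
    freq_table : DataFrame, subjects x subsets (percent of CD45+ events)
    groups : Series mapping subject -> {'sepsis', 'healthy'}
    alpha : adjusted-p significance threshold (default 0.1)
    """

    def __init__(self, freq_table: pd.DataFrame, groups: pd.Series, alpha: float = 0.1):
        self.freq = freq_table
        self.groups = groups.reindex(freq_table.index)
        if self.groups.isna().any():
            missing = list(freq_table.index[self.groups.isna()])
            raise ValueError(f"missing group labels for subjects {missing}")
        self.alpha = alpha
        self._mask_s = (self.groups == SEPSIS).to_numpy()
        self._mask_h = (self.groups == HEALTHY).to_numpy()
        if self._mask_s.sum() == 0 or self._mask_h.sum() == 0:
            raise ValueError("both groups must be non-empty")

    def fit(self, hedges: bool = False) -> DifferentialAbundanceResults:
        x = self.freq.to_numpy(dtype=float)
        xs, xh = x[self._mask_s], x[self._mask_h]
        m = x.shape[1]
        mw = stats.mannwhitneyu(xs, xh, alternative="two-sided", axis=0, method="auto")
        rows = []
        for j, subset in enumerate(self.freq.columns):
            d, lo, hi = cohens_d(xs[:, j], xh[:, j], hedges=hedges)
            raw_p = float(mw.pvalue[j]) if np.ndim(mw.pvalue) else float(mw.pvalue)
            adj_p = min(1.0, raw_p * m)
            q1s, q3s = np.percentile(xs[:, j], [25, 75])
            q1h, q3h = np.percentile(xh[:, j], [25, 75])
            rows.append(
                {
                    "subset": subset,
                    "median_sepsis": np.median(xs[:, j]),
                    "iqr_sepsis": q3s - q1s,
                    "median_healthy": np.median(xh[:, j]),
                    "iqr_healthy": q3h - q1h,
                    "U": float(mw.statistic[j]),
                    "p_raw": raw_p,
                    "p_adj": adj_p,
                    "cohens_d": d,
                    "d_ci_low": lo,
                    "d_ci_high": hi,
                    "direction": "up" if (np.isnan(d) or d >= 0) else "down",
                    "significant": adj_p < self.alpha,
                }
            )
        table = pd.DataFrame(rows).set_index("subset")
        return DifferentialAbundanceResults(
            table=table,
            alpha=self.alpha,
            m=m,
            n_sepsis=int(self._mask_s.sum()),
            n_healthy=int(self._mask_h.sum()),
        )


def test_subsets(
    freq_table: pd.DataFrame, groups: pd.Series, alpha: float = 0.1
) -> DifferentialAbundanceResults:
    """Mann-Whitney + Bonferroni + effect sizes for every subset column."""
    return DifferentialAbundance(freq_table, groups, alpha=alpha).fit()


def effect_sizes(
    freq_table: pd.DataFrame, groups: pd.Series, hedges: bool = False
) -> pd.DataFrame:
    """Per-subset Cohen's d (sepsis minus healthy) with 95% CI."""
    res = DifferentialAbundance(freq_table, groups).fit(hedges=hedges)
    return res.table[["cohens_d", "d_ci_low", "d_ci_high", "direction"]]


def stratify_by_age(
    freq_table: pd.DataFrame,
    clinical: pd.DataFrame,
    groups: pd.Series,
    cut: float = 1.0,
    alpha: float = 0.1,
) -> dict[str, DifferentialAbundanceResults | None]:
    """Sensitivity analysis: rerun the group tests within age strata
    (> cut years vs <= cut years).  Strata with fewer than 2 subjects in
    either group are skipped with a warning."""
    ages = clinical.set_index("subject_id")["age_years"].reindex(freq_table.index)
    if ages.isna().any():
        raise ValueError("ages missing for some subjects")
    out: dict[str, DifferentialAbundanceResults | None] = {}
    for name, mask in (("older", ages > cut), ("younger", ages <= cut)):
        sub = freq_table[mask.to_numpy()]
        sub_groups = groups.reindex(sub.index)
        counts = sub_groups.value_counts()
        if counts.get(SEPSIS, 0) < 2 or counts.get(HEALTHY, 0) < 2:
            warnings.warn(
                f"stratum {name!r} (cut {cut}y) has <2 subjects per group; skipped"
            )
            out[name] = None
            continue
        out[name] = DifferentialAbundance(sub, sub_groups, alpha=alpha).fit()
    return out


def clinical_correlations(
    freq_table: pd.DataFrame,
    clinical: pd.DataFrame,
    subsets: list[str] | None = None,
    variables: list[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Subset-frequency vs clinical-covariate correlations (sepsis only).

    Pearson for continuous labs, Spearman for ordinal severity scores;
    pairwise-complete observations.  Returns a long-form table with one
    row per (subset, variable) pair; pairs with n < ``min_n`` are withheld.
    """
    clin = clinical[clinical["group"] == SEPSIS].set_index("subject_id")
    common = [s for s in freq_table.index if s in clin.index]
    if not common:
        raise ValueError("no sepsis subjects shared between tables")
    freq = freq_table.loc[common]
    clin = clin.loc[common]
    variables = variables or [v for v in CLINICAL_COEFFICIENTS if v in clin.columns]
    subsets = subsets or list(freq.columns)
    rows = []
    for subset in subsets:
        for var in variables:
            kind = CLINICAL_COEFFICIENTS.get(var, "spearman")
            pair = pd.DataFrame({"f": freq[subset], "v": clin[var]}).dropna()
            if len(pair) < min_n:
                rows.append(
                    {"subset": subset, "variable": var, "type": kind,
                     "estimate": np.nan, "p": np.nan, "n": len(pair)}
                )
                continue
            if kind == "pearson":
                r, p = stats.pearsonr(pair["f"], pair["v"])
            else:
                r, p = stats.spearmanr(pair["f"], pair["v"])
            rows.append(
                {"subset": subset, "variable": var, "type": kind,
                 "estimate": float(r), "p": float(p), "n": len(pair)}
            )
    return pd.DataFrame(rows)


def correlation_matrix(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form correlation table to subsets x variables."""
    return long_table.pivot(index="subset", columns="variable", values="estimate")
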