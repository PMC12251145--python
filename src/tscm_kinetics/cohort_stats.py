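"""Cohort-level statistics that sit outside the ODE machinery.

Covers the multipotency index (a base-10 entropy of the phenotypes a sorted
subset differentiates into, self excluded), the self-renewal percentage,
relative gene expression from qPCR cycle thresholds, the model-independent
log-linear decline analysis of the cross-sectional yellow-fever cohort, and
thin wrappers over the standard nonparametric group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DifferentiationProfile",
    "multipotency_index",
    "self_renewal_fraction",
    "relative_expression",
    "yfv_decline_regression",
    "group_compare",
]


@dataclass(frozen=True)
class DifferentiationProfile:
    """Divided-cell counts (or proportions) by destination phenotype.

    ``source`` names the input subset; ``counts`` maps each of the n=6
    phenotype labels to the number (or proportion) of divided cells observed
    with that phenotype after stimulation.
    """

    source: str
    counts: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.source not in self.counts:
            raise ValueError(f"source {self.source!r} not among count labels")


def multipotency_index(profile: DifferentiationProfile) -> float:
    """MI = -sum_i p_i log10 p_i over destinations i != source.

    p_i is the proportion of *differentiated* cells (those that changed
    phenotype) with phenotype i; zero-proportion categories contribute 0
    (the x log x -> 0 limit). Returns NaN when no cell differentiated: the
    index is undefined, not zero. Scale-invariant, so raw counts and
    proportions give the same value.
    """
    others = np.array(
        [v for k, v in profile.counts.items() if k != profile.source], dtype=float
    )
    total = others.sum()
    if total == 0:
        return float("nan")
    p = others / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log10(nz)))


def self_renewal_fraction(profile: DifferentiationProfile) -> float:
    """Percentage of divided cells that kept the input phenotype.

    NaN when no cell divided.
    """
    divided = float(sum(profile.counts.values()))
    if divided == 0:
        return float("nan")
    return 100.0 * profile.counts[profile.source] / divided


def relative_expression(ct_gene: float, ct_housekeeping: float) -> float:
    """Expression relative to the housekeeping gene: 2^-(CT_gene - CT_hk)."""
    if not (np.isfinite(ct_gene) and np.isfinite(ct_housekeeping)):
        raise ValueError("CT values must be finite")
    return float(2.0 ** (-(ct_gene - ct_housekeeping)))


def yfv_decline_regression(
    cohort: pd.DataFrame,
    exclude_low_frequency: bool = False,
    include_multiple_vaccination: bool = False,
) -> dict:
    """Per-subset log10 decline slopes and their contrast.

    ``cohort`` columns: years, frequency (of antigen-specific cells within
    the subset), subset; optional flags low_frequency and
    multiple_vaccination. Frequencies are log10-transformed and regressed on
    years within each subset; the slope difference is tested with a
    years-by-subset interaction in a single OLS fit. The two flag arguments
    reproduce the alternative analysis variant (drop very-low-frequency
    donors, keep multiple vaccinees).
    """
    df = cohort.copy()
    for col in ("years", "frequency", "subset"):
        if col not in df.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    if not include_multiple_vaccination and "multiple_vaccination" in df.columns:
        df = df[~df["multiple_vaccination"].astype(bool)]
    if exclude_low_frequency and "low_frequency" in df.columns:
        df = df[~df["low_frequency"].astype(bool)]
    df = df[df["frequency"] > 0].copy()
    subsets = sorted(df["subset"].unique())
    if len(subsets) != 2:
        raise ValueError(f"expected exactly 2 subsets, got {subsets}")
    counts = df["subset"].value_counts()
    if counts.min() < 3:
        raise ValueError("need at least 3 points per subset for the regression")
    df["log10_freq"] = np.log10(df["frequency"])

    per_subset = {}
    for s in subsets:
        sub = df[df["subset"] == s]
        fit = smf.ols("log10_freq ~ years", data=sub).fit()
        per_subset[s] = {
            "slope_per_year": float(fit.params["years"]),
            "slope_se": float(fit.bse["years"]),
            "intercept": float(fit.params["Intercept"]),
            "n": int(len(sub)),
        }
    inter = smf.ols("log10_freq ~ years * C(subset)", data=df).fit()
    term = [t for t in inter.params.index if t.startswith("years:")][0]
    return {
        "subsets": per_subset,
        "slope_difference": float(inter.params[term]),
        "interaction_pvalue": float(inter.pvalues[term]),
        "n_total": int(len(df)),
    }


def group_compare(
    values_a,
    values_b,
    paired: bool = False,
    method: str = "wilcoxon",
) -> dict:
    """Two-tailed nonparametric comparison of two samples.

    ``method``: "wilcoxon" (signed-rank when paired, rank-sum otherwise) or
    "spearman" (correlation of paired vectors). The signed-rank test uses the
    exact null for n <= 25 and the normal approximation beyond.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "spearman":
        if a.shape != b.shape:
            raise ValueError("spearman requires equal-length vectors")
        if a.size < 3 or np.all(a == a[0]) or np.all(b == b[0]):
            raise ValueError("degenerate input for spearman correlation")
        rho, p = stats.spearmanr(a, b)
        return {"method": "spearman", "statistic": float(rho), "pvalue": float(p),
                "n": int(a.size)}
    if method != "wilcoxon":
        raise ValueError(f"unknown method {method!r}")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return {"method": "wilcoxon-signed-rank", "statistic": 0.0,
                    "pvalue": 1.0, "n": int(a.size)}
        how = "exact" if a.size <= 25 and not np.any(diffs == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=how)
        return {"method": "wilcoxon-signed-rank", "statistic": float(res.statistic),
                "pvalue": float(res.pvalue), "n": int(a.size)}
    if a.size == 0 or b.size == 0 or (np.all(a == a.flat[0]) and np.all(b == a.flat[0])):
        raise ValueError("degenerate groups for rank-sum test")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"method": "wilcoxon-rank-sum", "statistic": float(res.statistic),
            "pvalue": float(res.pvalue), "n": int(a.size + b.size)}
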