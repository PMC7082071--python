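"""Statistics for RT-qPCR (ddCt) and dual-luciferase reporter assays.

Relative expression follows the comparative ddCt method: per sample,
technical replicates are averaged, the reference Ct is the arithmetic mean
over reference genes, dCt = target - reference, ddCt = mean dCt(case) -
mean dCt(control) and fold change = 2^(-ddCt).  Group comparison uses a
two-sided Welch t-test on dCt values.  Luciferase ratios
(experimental / control luminescence per well) are compared across
constructs with one-way ANOVA plus Bonferroni-adjusted pairwise Welch
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EfficiencyFit:
    """Standard-curve fit: Ct against log10 template amount."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification factor per cycle, 10^(-1/slope); 2 is the ideal."""
        return float(10.0 ** (-1.0 / self.slope))

    @property
    def valid(self) -> bool:
        return self.slope < 0


@dataclass
class RelativeExpression:
    gene: str
    delta_ct_case: np.ndarray
    delta_ct_control: np.ndarray
    delta_delta_ct: float
    fold_change: float
    sd_delta_ct_case: float
    sd_delta_ct_control: float
    p: float


def primer_efficiency(dilution_log10, ct) -> EfficiencyFit:
    """Least-squares standard curve; efficiency = 10^(-1/slope)."""
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size != y.size:
        raise ValueError("dilution and Ct lists differ in length")
    if x.size < 3:
        raise ValueError("need at least three dilution points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in dilution series")
    fit = stats.linregress(x, y)
    return EfficiencyFit(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=float(fit.rvalue**2))


def _mean_ct(expr: pd.DataFrame, gene: str, sample: str) -> float:
    sub = expr[(expr["gene"] == gene) & (expr["sample_id"] == sample)]
    if sub.empty:
        raise ValueError(f"no Ct measurements for gene {gene!r} in sample {sample!r}")
    return float(sub["ct"].mean())


def relative_expression(
    expr: pd.DataFrame,
    target: str,
    references: list[str],
    case_ids: list[str],
    control_ids: list[str],
    efficiencies: dict[str, float] | None = None,
) -> RelativeExpression:
    """Comparative ddCt relative expression of ``target`` in cases vs controls.

    Technical replicates are averaged per (gene, sample); multiple
    reference genes are combined by arithmetic mean of their Cts.  With
    ``efficiencies`` (gene -> amplification factor) an efficiency-corrected
    fold change E_target^(-dmean_target) / E_ref^(-dmean_ref) replaces the
    classic 2^(-ddCt).
    """
    if not references:
        raise ValueError("at least one reference gene required")

    def dct(sample: str) -> float:
        ref_ct = float(np.mean([_mean_ct(expr, r, sample) for r in references]))
        return _mean_ct(expr, target, sample) - ref_ct

    d_case = np.array([dct(s) for s in case_ids], dtype=float)
    d_ctrl = np.array([dct(s) for s in control_ids], dtype=float)
    ddct = float(d_case.mean() - d_ctrl.mean())
    if efficiencies is None:
        fold = float(2.0 ** (-ddct))
    else:
        e_t = efficiencies[target]
        d_t = np.mean([_mean_ct(expr, target, s) for s in case_ids]) - np.mean(
            [_mean_ct(expr, target, s) for s in control_ids]
        )
        ref_fold = 1.0
        for r in references:
            d_r = np.mean([_mean_ct(expr, r, s) for s in case_ids]) - np.mean(
                [_mean_ct(expr, r, s) for s in control_ids]
            )
            ref_fold *= efficiencies[r] ** (-d_r)
        ref_fold **= 1.0 / len(references)
        fold = float(e_t ** (-d_t) / ref_fold)
    p = expression_group_test(d_case, d_ctrl) if min(d_case.size, d_ctrl.size) >= 2 else float("nan")
    return RelativeExpression(
        gene=target,
        delta_ct_case=d_case,
        delta_ct_control=d_ctrl,
        delta_delta_ct=ddct,
        fold_change=fold,
        sd_delta_ct_case=float(d_case.std(ddof=1)) if d_case.size > 1 else 0.0,
        sd_delta_ct_control=float(d_ctrl.std(ddof=1)) if d_ctrl.size > 1 else 0.0,
        p=p,
    )


def expression_group_test(delta_ct_case, delta_ct_control) -> float:
    """Two-sided Welch t-test on dCt values; 1.0 for indistinguishable groups."""
    a = np.asarray(delta_ct_case, dtype=float)
    b = np.asarray(delta_ct_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two dCt values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def luciferase_normalize(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well experimental/control luminescence ratio, grouped by construct."""
    if (plate["lum_control"] <= 0).any():
        well = plate.loc[plate["lum_control"] <= 0, "well"].iloc[0]
        raise ValueError(f"non-positive control luminescence in well {well}")
    out = plate[["construct", "well"]].copy()
    out["ratio"] = plate["lum_experimental"] / plate["lum_control"]
    return out


@dataclass
class AnovaResult:
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    significant: dict[tuple[str, str], bool]
    alpha: float


def anova_bonferroni(groups: dict[str, list[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise Welch t-tests.

    Pairwise p-values are multiplied by the number of pairs and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two values")
    values = list(arrays.values())
    if all(np.allclose(v, values[0][0]) for v in values):
        anova_p = 1.0  # no variance anywhere: F = 0
    else:
        anova_p = float(stats.f_oneway(*values).pvalue)
    pairs = list(combinations(sorted(arrays), 2))
    pairwise: dict[tuple[str, str], float] = {}
    for x, y in pairs:
        a, b = arrays[x], arrays[y]
        if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
            raw = 1.0 if a.mean() == b.mean() else 0.0
        else:
            raw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        pairwise[(x, y)] = min(1.0, raw * len(pairs))
    significant = {k: p < alpha for k, p in pairwise.items()}
    return AnovaResult(anova_p=anova_p, pairwise_p=pairwise, significant=significant, alpha=alpha)
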