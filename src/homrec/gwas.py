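"""Case/control association scan with QC, permutation and genomic control.

The association statistic is the 2x2 allelic chi-square (1 df, no
continuity correction) on alternate/reference allele counts.  Allele
counting is ploidy-aware: a hemizygous male contributes a single X allele.
Empirical significance uses the max-T permutation scheme (case/control
labels permuted, sex held fixed), and stratification is summarised by the
genomic inflation factor lambda = median(chi2) / median of a 1-df
chi-square null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix

#: median of the chi-square distribution with one degree of freedom
CHI2_1DF_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))


@dataclass
class QCReport:
    """Marker-QC attrition; each marker counts against the first filter that removed it."""

    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_call_rate - self.removed_maf - self.removed_hwe

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["call_rate", "maf", "hwe", "retained"],
                "n_markers": [self.removed_call_rate, self.removed_maf, self.removed_hwe, self.n_retained],
            }
        )


@dataclass
class AssociationResult:
    """Per-marker association statistics plus scan-level summaries."""

    table: pd.DataFrame  # marker_id, chromosome, position_bp, counts, chi2, p_raw, p_gc, [p_point, p_genome]
    lambda_gc: float
    n_perm: int

    def top_marker(self) -> pd.Series:
        return self.table.loc[self.table["chi2"].idxmax()]


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts with the parity fixed by the allele
    counts, the probabilities no greater than that of the observed count
    under the exact (hypergeometric-style) HWE distribution, using the
    standard mid-point recurrence.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    if n_rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    het_obs = n_het
    mid = int(n_rare * (2 * n - n_rare) / (2 * n))
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((rare-h+2)(common-h+2))
    h = mid
    rare, common = n_rare, 2 * n - n_rare
    while h >= 2:
        num = h * (h - 1)
        den = (rare - h + 2) * (common - h + 2)
        probs[h - 2] = probs[h] * num / den
        h -= 2
    h = mid
    while h + 2 <= min(rare, common):
        num = (rare - h) * (common - h)
        den = (h + 2) * (h + 1)
        probs[h + 2] = probs[h] * num / den
        h += 2
    total = sum(probs.values())
    p_obs = probs[het_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1.0 + 1e-10)) / total
    return min(1.0, p)


def _alt_total_counts(gm: GenotypeMatrix, row_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele and total-allele counts per marker over a sample mask."""
    dos = gm.dosage[row_mask].astype(np.float64)
    ploidy = gm.ploidy()[row_mask].astype(np.float64)
    observed = dos != MISSING
    alt = np.where(observed, dos * ploidy / 2.0, 0.0).sum(axis=0)
    total = np.where(observed, ploidy, 0.0).sum(axis=0)
    return alt, total


def qc_filter(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-4,
    hwe_in_controls_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers failing call-rate, MAF or HWE criteria (in that order).

    MAF counts male X dosages as single alleles; the HWE exact test uses
    diploid samples only (controls only by default).
    """
    for thr in (maf_min, call_rate_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    n_input = gm.n_markers
    observed = gm.dosage != MISSING
    call_rate = observed.mean(axis=0)
    fail_call = call_rate < call_rate_min

    alt, total = _alt_total_counts(gm, np.ones(gm.n_samples, dtype=bool))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = maf < maf_min

    status = samples.set_index("sample_id").loc[gm.samples, "status"].to_numpy()
    hwe_mask = (status == "control") if hwe_in_controls_only else np.ones(gm.n_samples, dtype=bool)
    diploid = gm.ploidy() == 2
    fail_hwe = np.zeros(n_input, dtype=bool)
    for j in range(n_input):
        use = hwe_mask & diploid[:, j] & observed[:, j]
        d = gm.dosage[use, j]
        if d.size == 0:
            continue
        p = hwe_exact_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        fail_hwe[j] = p < hwe_p_min

    removed_call = int(fail_call.sum())
    removed_maf = int((fail_maf & ~fail_call).sum())
    removed_hwe = int((fail_hwe & ~fail_call & ~fail_maf).sum())
    keep = ~(fail_call | fail_maf | fail_hwe)
    report = QCReport(n_input, removed_call, removed_maf, removed_hwe)
    if not keep.any():
        raise ValueError(f"no markers survive QC: {report}")
    return gm.subset_markers(np.flatnonzero(keep)), report


def allelic_chi2(case_alt: float, case_ref: float, ctrl_alt: float, ctrl_ref: float) -> tuple[float, float]:
    """2x2 allele-count chi-square (df 1, no continuity correction).

    A monomorphic table (zero allele column) returns ``(0.0, 1.0)``.
    """
    a, b, c, d = case_alt, case_ref, ctrl_alt, ctrl_ref
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0:
        raise ValueError("both case and control rows must have alleles")
    if c1 == 0 or c2 == 0:
        return 0.0, 1.0
    n = r1 + r2
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _chi2_vectorized(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    den = r1 * r2 * c1 * c2
    n = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(den > 0, n * (a * d - b * c) ** 2 / np.maximum(den, 1e-300), 0.0)
    return chi2


def genomic_lambda(chi2s) -> float:
    """Genomic-control inflation factor: median chi2 over its 1-df null median."""
    chi2s = np.asarray(chi2s, dtype=float)
    if chi2s.size == 0:
        raise ValueError("empty chi-square list")
    return float(np.median(chi2s) / CHI2_1DF_MEDIAN)


def gc_adjusted_p(chi2s) -> tuple[float, np.ndarray]:
    """Lambda and genomic-control adjusted p-values (lambda floored at 1)."""
    lam = genomic_lambda(chi2s)
    adj = np.asarray(chi2s, dtype=float) / max(lam, 1.0)
    return lam, stats.chi2.sf(adj, 1)


def _case_mask(samples: pd.DataFrame, gm: GenotypeMatrix, case_statuses) -> tuple[np.ndarray, np.ndarray]:
    status = samples.set_index("sample_id").loc[gm.samples, "status"].to_numpy()
    cases = np.isin(status, sorted(case_statuses))
    controls = status == "control"
    return cases, controls


def association_scan(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    case_statuses={"case_type1"},
) -> AssociationResult:
    """Allelic chi-square scan of cases (given statuses) against controls."""
    cases, controls = _case_mask(samples, gm, case_statuses)
    if not cases.any() or not controls.any():
        raise ValueError("need at least one case and one control")
    case_alt, case_tot = _alt_total_counts(gm, cases)
    ctrl_alt, ctrl_tot = _alt_total_counts(gm, controls)
    informative = (case_tot > 0) & (ctrl_tot > 0)
    if not informative.any():
        raise ValueError("no marker genotyped in both cases and controls")
    chi2 = _chi2_vectorized(case_alt, case_tot - case_alt, ctrl_alt, ctrl_tot - ctrl_alt)
    chi2[~informative] = 0.0
    lam, p_gc = gc_adjusted_p(chi2)
    table = pd.DataFrame(
        {
            "marker_id": gm.markers["marker_id"],
            "chromosome": gm.markers["chromosome"],
            "position_bp": gm.markers["position_bp"],
            "case_alt": case_alt,
            "case_ref": case_tot - case_alt,
            "ctrl_alt": ctrl_alt,
            "ctrl_ref": ctrl_tot - ctrl_alt,
            "chi2": chi2,
            "p_raw": stats.chi2.sf(chi2, 1),
            "p_gc": p_gc,
        }
    )
    table.loc[~informative, ["p_raw", "p_gc"]] = 1.0
    return AssociationResult(table=table, lambda_gc=lam, n_perm=0)


def permutation_empirical(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    case_statuses={"case_type1"},
    n_perm: int = 100_000,
    seed: int = 0,
    chunk_size: int = 1000,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Pointwise and genome-wide (max-T) empirical p-values.

    Case/control labels are permuted among the included samples; sex (and
    therefore X ploidy) travels with the sample, not the label.  Empirical
    p-values use the (r + 1) / (n + 1) estimator.  With ``exhaustive`` the
    full set of case-label assignments is enumerated instead (only feasible
    for tiny cohorts) and p = r / n over all assignments, the observed one
    included.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    cases, controls = _case_mask(samples, gm, case_statuses)
    incl = np.flatnonzero(cases | controls)
    k = int(cases.sum())
    dos = gm.dosage[incl].astype(np.float64)
    ploidy = gm.ploidy()[incl].astype(np.float64)
    observed_mask = dos != MISSING
    ALT = np.where(observed_mask, dos * ploidy / 2.0, 0.0)
    TOT = np.where(observed_mask, ploidy, 0.0)
    tot_alt = ALT.sum(axis=0)
    tot_all = TOT.sum(axis=0)

    is_case = cases[incl].astype(np.float64)
    obs_case_alt = is_case @ ALT
    obs_case_tot = is_case @ TOT
    obs_chi2 = _chi2_vectorized(
        obs_case_alt,
        obs_case_tot - obs_case_alt,
        tot_alt - obs_case_alt,
        (tot_all - obs_case_tot) - (tot_alt - obs_case_alt),
    )

    m = gm.n_markers
    exceed_point = np.zeros(m, dtype=np.int64)
    exceed_genome = np.zeros(m, dtype=np.int64)

    def run_block(B: np.ndarray) -> None:
        nonlocal exceed_point, exceed_genome
        case_alt = B @ ALT
        case_tot = B @ TOT
        ctrl_alt = tot_alt - case_alt
        chi2 = _chi2_vectorized(case_alt, case_tot - case_alt, ctrl_alt, (tot_all - case_tot) - ctrl_alt)
        tol = 1e-12
        exceed_point += (chi2 >= obs_chi2[None, :] - tol).sum(axis=0)
        maxes = chi2.max(axis=1)
        exceed_genome += (maxes[:, None] >= obs_chi2[None, :] - tol).sum(axis=0)

    if exhaustive:
        from itertools import combinations

        combos = list(combinations(range(len(incl)), k))
        B = np.zeros((len(combos), len(incl)))
        for r, combo in enumerate(combos):
            B[r, list(combo)] = 1.0
        run_block(B)
        n_total = len(combos)
        p_point = exceed_point / n_total
        p_genome = exceed_genome / n_total
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_perm:
            b = min(chunk_size, n_perm - done)
            B = np.zeros((b, len(incl)))
            for r in range(b):
                B[r, rng.permutation(len(incl))[:k]] = 1.0
            run_block(B)
            done += b
        p_point = (exceed_point + 1) / (n_perm + 1)
        p_genome = (exceed_genome + 1) / (n_perm + 1)

    return pd.DataFrame(
        {"marker_id": gm.markers["marker_id"], "p_point": p_point, "p_genome": p_genome}
    )
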