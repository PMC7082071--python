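"""Association statistics: HWE exact test, allelic chi-square, QC, permutation, lambda."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from homrec.datatypes import MISSING
from homrec.gwas import (
    CHI2_1DF_MEDIAN,
    allelic_chi2,
    association_scan,
    gc_adjusted_p,
    genomic_lambda,
    hwe_exact_test,
    permutation_empirical,
    qc_filter,
)

from conftest import build_gm, build_samples


# ---------------------------------------------------------------- HWE exact


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent brute force: log-factorial probability of every het count."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    common = 2 * n - rare

    def log_prob(h):
        na, nb = (rare - h) // 2, (common - h) // 2
        return (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(na + 1)
            - math.lgamma(nb + 1)
            - math.lgamma(h + 1)
            + math.lgamma(rare + 1)
            + math.lgamma(common + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = [h for h in range(rare % 2, rare + 1, 2) if (common - h) >= 0]
    probs = {h: math.exp(log_prob(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-10)) / total


@pytest.mark.parametrize(
    "counts", [(3, 5, 2), (0, 2, 8), (5, 0, 5), (10, 1, 0), (7, 12, 3), (1, 1, 1), (20, 5, 20)]
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-9)


def test_hwe_monomorphic_and_symmetry():
    assert hwe_exact_test(1, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 25) == 1.0
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, h, b = rng.integers(0, 15, 3)
        if a + h + b == 0:
            continue
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), rel=1e-12)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# --------------------------------------------------------- allelic chi-square


def test_chi2_reproduces_printed_segregation_pvalues():
    """12 hom-alt cases vs 67 controls: the two published control distributions."""
    _, p1 = allelic_chi2(24, 0, 2 * 4 + 22, 2 * 41 + 22)  # controls 41/22/4
    assert float(f"{p1:.1e}") == pytest.approx(1.6e-13)
    _, p2 = allelic_chi2(24, 0, 9, 2 * 58 + 9)  # controls 58/9/0
    assert float(f"{p2:.1e}") == pytest.approx(4.0e-25)


def test_chi2_monomorphic_and_equal_frequencies():
    assert allelic_chi2(0, 10, 0, 20) == (0.0, 1.0)
    chi2, p = allelic_chi2(5, 5, 10, 10)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_matches_contingency_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 60, 4)
        chi2, p = allelic_chi2(a, b, c, d)
        oracle = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        assert chi2 == pytest.approx(oracle.statistic, rel=1e-10)
        assert p == pytest.approx(oracle.pvalue, rel=1e-10)


# ------------------------------------------------------------------ QC filter


def test_qc_attribution_order_call_rate_then_maf_then_hwe():
    # m1: 20% missing; m2: MAF 0 (monomorphic); m3: extreme HWE violation; m4: clean
    n = 40
    dosage = np.ones((n, 4), dtype=np.int8)
    dosage[:, 0] = 1
    dosage[: n // 5, 0] = MISSING
    dosage[:, 1] = 0
    dosage[:, 2] = 1  # all het: HWE-impossible at this sample size
    dosage[:, 3] = np.array([0, 1, 2, 1] * 10, dtype=np.int8)
    gm = build_gm(dosage)
    samples = build_samples(gm, ["control"] * n)
    kept, report = qc_filter(gm, samples, call_rate_min=0.95, maf_min=0.05, hwe_p_min=1e-4)
    assert report.removed_call_rate == 1
    assert report.removed_maf == 1
    assert report.removed_hwe == 1
    assert report.n_retained == 1 == kept.n_markers
    assert kept.markers["marker_id"].tolist() == ["m4"]


def test_qc_survivors_match_independent_recheck(sim_default):
    gm, _, samples, _, _ = sim_default
    kept, report = qc_filter(gm, samples)
    assert report.n_input == gm.n_markers
    assert report.n_retained == kept.n_markers
    # independent per-marker recheck of the surviving set
    controls = samples.set_index("sample_id").loc[gm.samples, "status"].to_numpy() == "control"
    ploidy = gm.ploidy()
    surviving = set(kept.markers["marker_id"])
    for j in range(gm.n_markers):
        d = gm.dosage[:, j].astype(float)
        obs = d != MISSING
        call = obs.mean()
        alt = (d[obs] * ploidy[obs, j] / 2).sum()
        tot = ploidy[obs, j].sum()
        f = alt / tot
        maf = min(f, 1 - f)
        dc = gm.dosage[controls & obs & (ploidy[:, j] == 2), j]
        p_hwe = (
            hwe_enumeration_oracle(int((dc == 0).sum()), int((dc == 1).sum()), int((dc == 2).sum()))
            if dc.size
            else 1.0
        )
        expect_keep = call >= 0.95 and maf >= 0.05 and p_hwe >= 1e-4
        assert (gm.markers["marker_id"].iloc[j] in surviving) == expect_keep


# ----------------------------------------------------------- association scan


def test_fully_separating_marker_has_maximal_chi2(sim_default):
    gm, _, samples, _, truth = sim_default
    assoc = association_scan(gm, samples)
    top = assoc.top_marker()
    lo, hi = truth.risk_interval_bp
    assert top["chromosome"] == "15"
    assert lo <= top["position_bp"] <= hi


def test_male_x_cases_contribute_single_alleles():
    dosage = np.array([[2], [2], [0], [0], [0]], dtype=np.int8)
    gm = build_gm(dosage, chroms=["X"], sex=["male", "male", "female", "female", "female"])
    samples = build_samples(gm, ["case_type1", "case_type1", "control", "control", "control"])
    assoc = association_scan(gm, samples)
    row = assoc.table.iloc[0]
    assert row["case_alt"] == 2  # one allele per hemizygous male, not two
    assert row["case_ref"] == 0
    assert row["ctrl_ref"] == 6


def test_artificial_complete_separation_tops_the_scan():
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    dosage[:6, 7] = 2
    dosage[6:, 7] = 0
    gm = build_gm(dosage)
    samples = build_samples(gm, ["case_type1"] * 6 + ["control"] * 6)
    assoc = association_scan(gm, samples)
    assert assoc.top_marker()["marker_id"] == "m8"


# ------------------------------------------------------------- permutation


def _perm_toy():
    dosage = np.array([[2, 0], [2, 1], [0, 0], [0, 2]], dtype=np.int8)
    gm = build_gm(dosage)
    samples = build_samples(gm, ["case_type1", "case_type1", "control", "control"])
    return gm, samples


def test_permutation_matches_exhaustive_enumeration_oracle():
    """All C(4,2) case-label assignments, enumerated independently."""
    gm, samples = _perm_toy()
    res = permutation_empirical(gm, samples, exhaustive=True)

    def chi2_of(case_rows, col):
        d = gm.dosage[:, col].astype(float)
        a = d[list(case_rows)].sum()
        b = 2 * len(case_rows) - a
        c = d.sum() - a
        dd = 2 * (4 - len(case_rows)) - c
        return sps.chi2_contingency([[a, b], [c, dd]], correction=False).statistic if min(a + c, b + dd) > 0 else 0.0

    obs = [chi2_of((0, 1), j) for j in range(2)]
    assigns = list(combinations(range(4), 2))
    for j in range(2):
        dist = [chi2_of(rows, j) for rows in assigns]
        expect_point = sum(x >= obs[j] - 1e-12 for x in dist) / len(assigns)
        maxes = [max(chi2_of(rows, 0), chi2_of(rows, 1)) for rows in assigns]
        expect_genome = sum(x >= obs[j] - 1e-12 for x in maxes) / len(assigns)
        assert res["p_point"].iloc[j] == pytest.approx(expect_point)
        assert res["p_genome"].iloc[j] == pytest.approx(expect_genome)


def test_sampled_permutation_approaches_enumeration():
    gm, samples = _perm_toy()
    exact = permutation_empirical(gm, samples, exhaustive=True)
    sampled = permutation_empirical(gm, samples, n_perm=4000, seed=3)
    assert np.allclose(sampled["p_point"], exact["p_point"], atol=0.03)


def test_genome_wide_p_dominates_pointwise_and_sample_order_invariance(sim_default):
    gm, _, samples, _, _ = sim_default
    sub = gm.subset_markers(np.arange(0, gm.n_markers, 25))
    res = permutation_empirical(gm=sub, samples=samples, n_perm=200, seed=7)
    assert (res["p_genome"] >= res["p_point"] - 1e-12).all()
    assert (res["p_point"] >= 1 / 201).all()

    # exhaustive p-values must not depend on sample order
    dosage = np.array([[2, 0], [2, 1], [0, 0], [0, 2], [1, 1]], dtype=np.int8)
    gm_a = build_gm(dosage)
    samples_a = build_samples(gm_a, ["case_type1", "case_type1", "control", "control", "control"])
    order = [3, 0, 4, 1, 2]
    gm_b = build_gm(dosage[order], sample_ids=[f"s{i + 1}" for i in order])
    samples_b = build_samples(gm_b, [samples_a["status"].tolist()[i] for i in order])
    res_a = permutation_empirical(gm_a, samples_a, exhaustive=True)
    res_b = permutation_empirical(gm_b, samples_b, exhaustive=True)
    assert np.allclose(res_a["p_point"], res_b["p_point"])
    assert np.allclose(res_a["p_genome"], res_b["p_genome"])


def test_single_marker_point_equals_genome():
    gm, samples = _perm_toy()
    sub = gm.subset_markers(np.array([0]))
    res = permutation_empirical(sub, samples, n_perm=500, seed=1)
    assert res["p_point"].iloc[0] == res["p_genome"].iloc[0]
    with pytest.raises(ValueError):
        permutation_empirical(sub, samples, n_perm=0)


# ------------------------------------------------------------ genomic control


def test_genomic_lambda_arithmetic():
    assert genomic_lambda([CHI2_1DF_MEDIAN] * 5) == pytest.approx(1.0)
    assert genomic_lambda([2 * CHI2_1DF_MEDIAN] * 7) == pytest.approx(2.0)
    lam, adj = gc_adjusted_p(np.full(3, 2 * CHI2_1DF_MEDIAN))
    assert adj[0] == pytest.approx(sps.chi2.sf(CHI2_1DF_MEDIAN, 1))
    lam2, adj2 = gc_adjusted_p(np.full(3, 0.5 * CHI2_1DF_MEDIAN))
    assert adj2[0] == pytest.approx(sps.chi2.sf(0.5 * CHI2_1DF_MEDIAN, 1))  # lambda floored at 1
    with pytest.raises(ValueError):
        genomic_lambda([])
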