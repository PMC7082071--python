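"""Recessive filtering, obligate-carrier refinement and segregation statistics."""

import numpy as np
import pandas as pd
import pytest

from homrec.datatypes import MISSING, VariantTable, make_sample_table
from homrec.filtering import (
    FilterConfig,
    carrier_constraint,
    format_percent,
    genotype_frequency_report,
    rank_candidates,
    recessive_filter,
    segregation_stats,
)


def make_vt(genotypes, sample_ids, positions=None, chrom="15"):
    g = np.asarray(genotypes, dtype=np.int8)
    n_var = g.shape[0]
    positions = positions or [1000 * (i + 1) for i in range(n_var)]
    variants = pd.DataFrame(
        {
            "chromosome": [chrom] * n_var,
            "position_bp": positions,
            "ref_allele": ["G"] * n_var,
            "alt_allele": ["A"] * n_var,
            "annotation": ["intronic"] * n_var,
            "gene": [f"G{i + 1}" for i in range(n_var)],
        }
    )
    return VariantTable(variants, sample_ids, g)


def cohort(n_cases, n_controls, carrier=False):
    ids = [f"c{i}" for i in range(n_cases)] + [f"k{i}" for i in range(n_controls)]
    statuses = ["case_type1"] * n_cases + ["control"] * n_controls
    obligate = [False] * (n_cases + n_controls)
    if carrier:
        obligate[-1] = True
    return ids, make_sample_table(ids, ["female"] * len(ids), statuses, obligate)


def test_recessive_filter_keeps_perfect_segregation_and_drops_hom_alt_control():
    ids, samples = cohort(2, 3)
    vt = make_vt(
        [
            [2, 2, 0, 0, 0],  # perfect
            [2, 2, 0, 0, 2],  # hom-alt control
            [2, 1, 0, 0, 0],  # het case
        ],
        ids,
    )
    kept = recessive_filter(vt, samples, FilterConfig(max_control_het_frac=0.0))
    assert kept.variants["gene"].tolist() == ["G1"]
    relaxed = recessive_filter(
        vt, samples, FilterConfig(max_control_het_frac=0.0, allow_control_hom_alt=True)
    )
    assert relaxed.variants["gene"].tolist() == ["G1", "G2"]


def test_control_het_fraction_boundary_is_strict():
    """With 100 controls at 1%: one heterozygote passes, two do not."""
    ids, samples = cohort(1, 100)
    one_het = [2] + [1] + [0] * 99
    two_het = [2] + [1, 1] + [0] * 98
    vt = make_vt([one_het, two_het], ids)
    kept = recessive_filter(vt, samples, FilterConfig(max_control_het_frac=0.01))
    assert kept.variants["gene"].tolist() == ["G1"]


def test_missing_case_genotype_policy():
    ids, samples = cohort(2, 2)
    vt = make_vt([[2, MISSING, 0, 0]], ids)
    strict = recessive_filter(vt, samples, FilterConfig(missing_policy="fail_variant"))
    assert strict.n_variants == 0
    lenient = recessive_filter(vt, samples, FilterConfig(missing_policy="exclude_sample"))
    assert lenient.n_variants == 1


def test_region_restriction():
    from homrec.blocks import HaplotypeBlock

    ids, samples = cohort(1, 2)
    vt = make_vt([[2, 0, 0], [2, 0, 0]], ids, positions=[500, 5000])
    region = HaplotypeBlock("15", 1, 1000, [], np.empty(0, dtype=np.int8))
    kept = recessive_filter(vt, samples, FilterConfig(region=region))
    assert kept.variants["position_bp"].tolist() == [500]


def test_filter_monotone_in_het_fraction():
    rng = np.random.default_rng(4)
    ids, samples = cohort(3, 30)
    g = rng.choice([0, 1, 2], size=(40, 33), p=[0.5, 0.3, 0.2]).astype(np.int8)
    g[:, :3] = 2  # all cases hom-alt so the het criterion is what varies
    vt = make_vt(g, ids)
    kept_sets = []
    for frac in (0.0, 0.05, 0.1, 0.3, 1.0):
        kept = recessive_filter(vt, samples, FilterConfig(max_control_het_frac=frac, allow_control_hom_alt=True))
        kept_sets.append(set(kept.variants["gene"]))
    for small, big in zip(kept_sets, kept_sets[1:]):
        assert small <= big


def test_carrier_constraint_keeps_het_drops_homozygous_carriers():
    ids, samples = cohort(2, 3, carrier=True)
    carrier = ids[-1]
    vt = make_vt(
        [
            [2, 2, 0, 0, 2],  # carrier hom-alt: an old haplotype passenger
            [2, 2, 0, 0, 1],  # carrier het: causal candidate
            [2, 2, 0, 0, 0],  # carrier hom-ref
            [2, 2, 0, 0, MISSING],  # missing carrier genotype: kept with warning
        ],
        ids,
    )
    with pytest.warns(UserWarning, match="missing"):
        kept = carrier_constraint(vt, [carrier])
    assert kept.variants["gene"].tolist() == ["G2", "G4"]
    dropped = carrier_constraint(vt, [carrier], on_missing="drop")
    assert dropped.variants["gene"].tolist() == ["G2"]


def test_carrier_constraint_is_a_subset_of_the_unconstrained_filter(sim_default):
    gm, vt, samples, _, truth = sim_default
    cfg = FilterConfig(max_control_het_frac=0.5, allow_control_hom_alt=True)
    base = recessive_filter(vt, samples, cfg)
    carriers = samples.loc[samples["obligate_carrier"], "sample_id"].tolist()
    constrained = carrier_constraint(base, carriers)
    base_keys = set(map(tuple, base.variants[["chromosome", "position_bp"]].values))
    sub_keys = set(map(tuple, constrained.variants[["chromosome", "position_bp"]].values))
    assert sub_keys < base_keys
    assert ("15", truth.causal_position_bp) in sub_keys


def test_segregation_reproduces_printed_counts_and_pvalues():
    """12 hom-alt cases vs controls 41/22/4 and 58/9/0."""
    ids = [f"c{i}" for i in range(12)] + [f"k{i}" for i in range(67)]
    samples = make_sample_table(ids, ["female"] * 79, ["case_type1"] * 12 + ["control"] * 67)
    ppt1 = [2] * 12 + [0] * 41 + [1] * 22 + [2] * 4
    hivep3 = [2] * 12 + [0] * 58 + [1] * 9
    vt = make_vt([ppt1, hivep3], ids)

    s1 = segregation_stats(vt, 0, samples)
    assert (s1.ctrl_hom_ref, s1.ctrl_het, s1.ctrl_hom_alt) == (41, 22, 4)
    assert float(f"{s1.p:.1e}") == pytest.approx(1.6e-13)
    assert s1.penetrance == pytest.approx(12 / 16)  # 12 affected of 16 homozygotes

    s2 = segregation_stats(vt, 1, samples)
    assert float(f"{s2.p:.1e}") == pytest.approx(4.0e-25)
    assert s2.penetrance == pytest.approx(1.0)


def test_penetrance_undefined_without_homozygotes():
    ids, samples = cohort(0 + 2, 2)
    vt = make_vt([[1, 1, 1, 0]], ids)
    s = segregation_stats(vt, 0, samples)
    assert s.penetrance is None and not s.penetrance_defined
    assert s.p > 0  # association still computed


def test_x_variant_allele_counts_respect_ploidy():
    ids = ["m1s", "m2s", "f1s", "f2s"]
    samples = make_sample_table(ids, ["male", "male", "female", "female"], ["case_type1"] * 2 + ["control"] * 2)
    vt = make_vt([[2, 2, 0, 0]], ids, chrom="X")
    s = segregation_stats(vt, 0, samples)
    # two hemizygous male cases contribute 2 alt alleles of 2 (not 4)
    from homrec.gwas import allelic_chi2

    chi2, p = allelic_chi2(2, 0, 0, 4)
    assert s.chi2 == pytest.approx(chi2)


def test_rank_candidates_order_ratio_and_oracle():
    ids, samples = cohort(2, 4)
    vt = make_vt([[2, 2, 1, 0, 0, 0], [2, 2, 0, 0, 0, 0], [2, 2, 2, 0, 0, 0]], ids)
    stats = [segregation_stats(vt, i, samples) for i in range(3)]
    ranked = rank_candidates(vt, stats)
    # independent sort oracle
    oracle = sorted(
        range(3),
        key=lambda i: (
            stats[i].p,
            -(stats[i].penetrance if stats[i].penetrance is not None else -1),
            int(vt.variants["position_bp"].iloc[i]),
        ),
    )
    assert ranked["gene"].tolist() == [f"G{i + 1}" for i in oracle]
    assert ranked["p_ratio_vs_best"].iloc[0] == pytest.approx(ranked["p"].iloc[1] / ranked["p"].iloc[0])
    assert (ranked["p_ratio_vs_best"].iloc[1:] >= 1.0).all()


def test_rank_ratio_spans_twelve_orders_of_magnitude():
    ids = [f"c{i}" for i in range(12)] + [f"k{i}" for i in range(67)]
    samples = make_sample_table(ids, ["female"] * 79, ["case_type1"] * 12 + ["control"] * 67)
    strong = [2] * 12 + [0] * 58 + [1] * 9
    weak = [2] * 12 + [0] * 41 + [1] * 22 + [2] * 4
    vt = make_vt([weak, strong], ids)
    ranked = rank_candidates(vt, [segregation_stats(vt, i, samples) for i in range(2)])
    assert ranked["p_ratio_vs_best"].iloc[0] > 1e10  # "10 billion times stronger"


def test_rank_tie_on_p_prefers_complete_penetrance():
    ids, samples = cohort(2, 2)
    vt = make_vt([[2, 2, 0, 0], [2, 2, 0, 0]], ids)
    stats = [segregation_stats(vt, i, samples) for i in range(2)]
    stats[0] = type(stats[0])(**{**stats[0].__dict__, "penetrance": 0.75})
    ranked = rank_candidates(vt, stats)
    assert ranked["penetrance"].tolist() == [1.0, 0.75]


def test_genotype_frequency_report_breed_screening_rendering():
    rep = genotype_frequency_report(456, 55, 3)
    assert rep["display"].tolist() == ["88.7", "10.7", "0.58"]
    assert rep["count"].sum() == 514
    assert format_percent(100.0 * 3 / 514) == "0.58"
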