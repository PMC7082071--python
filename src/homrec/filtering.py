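"""Recessive-model candidate filtering and segregation statistics.

The core inference of the discovery pipeline: keep variants compatible
with a fully recessive model (every case homozygous alternate, controls
essentially free of the homozygote), optionally restricted to a critical
region; then tighten with obligate carriers, who must be heterozygous for
the true causal allele; finally tabulate segregation, penetrance and the
case/control allelic test per surviving candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlock
from .datatypes import MISSING, VariantTable
from .gwas import allelic_chi2

HOM_REF, HET, HOM_ALT = 0, 1, 2


@dataclass
class FilterConfig:
    """Recessive-filter thresholds.

    ``max_control_het_frac`` bounds the heterozygous fraction among
    controls (strict <= on the real-valued product, no ceiling).
    ``allow_control_hom_alt`` tolerates alternate-homozygous controls -
    needed inside a closed breed where an old haplotype legitimately puts
    unaffected homozygotes in the cohort; the strict default models
    filtering against an outside control panel.
    """

    max_control_het_frac: float = 0.01
    allow_control_hom_alt: bool = False
    region: HaplotypeBlock | None = None
    missing_policy: str = "fail_variant"  # or "exclude_sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_control_het_frac <= 1.0:
            raise ValueError("max_control_het_frac must lie in [0, 1]")
        if self.missing_policy not in ("fail_variant", "exclude_sample"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class SegregationStats:
    """Genotype counts by status, penetrance and the allelic association test."""

    case_hom_ref: int
    case_het: int
    case_hom_alt: int
    ctrl_hom_ref: int
    ctrl_het: int
    ctrl_hom_alt: int
    penetrance: float | None
    chi2: float
    p: float

    @property
    def penetrance_defined(self) -> bool:
        return self.penetrance is not None


def _status_masks(vt: VariantTable, samples: pd.DataFrame, case_status: str = "case_type1"):
    status = samples.set_index("sample_id").loc[vt.samples, "status"].to_numpy()
    return status == case_status, status == "control"


def recessive_filter(
    vt: VariantTable, samples: pd.DataFrame, cfg: FilterConfig, case_status: str = "case_type1"
) -> VariantTable:
    """Keep variants compatible with the recessive model.

    Conditions: every case hom-alt (missing handled per
    ``cfg.missing_policy``); no hom-alt control unless allowed; control
    het count <= ``max_control_het_frac`` x n_controls; position inside
    ``cfg.region`` when set.
    """
    cases, controls = _status_masks(vt, samples, case_status)
    if not cases.any() or not controls.any():
        raise ValueError("need at least one case and one control")
    g = vt.genotypes
    n_controls = int(controls.sum())

    case_g = g[:, cases]
    if cfg.missing_policy == "fail_variant":
        cases_ok = np.all(case_g == HOM_ALT, axis=1)
    else:  # exclude_sample: missing case genotypes do not count against the variant
        cases_ok = np.all((case_g == HOM_ALT) | (case_g == MISSING), axis=1)

    ctrl_g = g[:, controls]
    hom_alt_ctrl = (ctrl_g == HOM_ALT).sum(axis=1)
    het_ctrl = (ctrl_g == HET).sum(axis=1)
    ctrl_ok = np.ones(vt.n_variants, dtype=bool) if cfg.allow_control_hom_alt else hom_alt_ctrl == 0
    het_ok = het_ctrl <= cfg.max_control_het_frac * n_controls

    keep = cases_ok & ctrl_ok & het_ok
    if cfg.region is not None:
        chroms = vt.variants["chromosome"].to_numpy()
        pos = vt.variants["position_bp"].to_numpy()
        in_region = np.array(
            [cfg.region.contains(c, p) for c, p in zip(chroms, pos)], dtype=bool
        )
        keep &= in_region
    return vt.subset(np.flatnonzero(keep))


def carrier_constraint(
    vt: VariantTable, carriers: list[str], on_missing: str = "keep_warn"
) -> VariantTable:
    """Keep variants where every obligate carrier is heterozygous.

    A carrier genotype of hom-ref or hom-alt excludes the variant; a
    missing carrier genotype keeps it with a warning (``on_missing =
    "keep_warn"``) or drops it (``"drop"``).
    """
    if on_missing not in ("keep_warn", "drop"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    idx = [vt.sample_index(c) for c in carriers]
    keep = np.ones(vt.n_variants, dtype=bool)
    for i in idx:
        col = vt.genotypes[:, i]
        keep &= (col == HET) | (col == MISSING)
        n_missing = int(((col == MISSING) & keep).sum())
        if n_missing and on_missing == "keep_warn":
            warnings.warn(
                f"obligate carrier {vt.samples[i]!r} has {n_missing} missing genotype(s); "
                "variants retained",
                stacklevel=2,
            )
        elif on_missing == "drop":
            keep &= col != MISSING
    return vt.subset(np.flatnonzero(keep))


def segregation_stats(
    vt: VariantTable,
    variant_index: int,
    samples: pd.DataFrame,
    case_status: str = "case_type1",
) -> SegregationStats:
    """Genotype counts, penetrance and allelic chi-square for one variant.

    Penetrance is the affected fraction of all alternate homozygotes among
    samples with a known phenotype; undefined (None) when no homozygote
    exists.  Allele counts respect ploidy: a male X call contributes one
    allele.
    """
    cases, controls = _status_masks(vt, samples, case_status)
    if not cases.any() or not controls.any():
        raise ValueError("need genotypes for at least one case and one control")
    g = vt.genotypes[variant_index]
    meta = samples.set_index("sample_id").loc[vt.samples]
    status = meta["status"].to_numpy()
    sex = meta["sex"].to_numpy()
    chrom = vt.variants["chromosome"].iloc[variant_index]
    hap = (sex == "male") & (chrom == "X")

    def counts(mask):
        sub = g[mask]
        return int((sub == HOM_REF).sum()), int((sub == HET).sum()), int((sub == HOM_ALT).sum())

    c_rr, c_ra, c_aa = counts(cases)
    k_rr, k_ra, k_aa = counts(controls)

    def alleles(mask):
        sub, h = g[mask], hap[mask]
        ok = sub != MISSING
        alt = np.where(h, (sub == HOM_ALT).astype(int), sub)
        total = np.where(h, 1, 2)
        return float(alt[ok].sum()), float(total[ok].sum())

    case_alt, case_tot = alleles(cases)
    ctrl_alt, ctrl_tot = alleles(controls)
    chi2, p = allelic_chi2(case_alt, case_tot - case_alt, ctrl_alt, ctrl_tot - ctrl_alt)

    known = status != "unknown"
    hom_alt_known = (g == HOM_ALT) & known
    n_hom = int(hom_alt_known.sum())
    affected_hom = int((hom_alt_known & (status == case_status)).sum())
    penetrance = affected_hom / n_hom if n_hom > 0 else None
    return SegregationStats(c_rr, c_ra, c_aa, k_rr, k_ra, k_aa, penetrance, chi2, p)


def rank_candidates(vt: VariantTable, stats: list[SegregationStats]) -> pd.DataFrame:
    """Rank candidates by p ascending, ties by penetrance (complete first), then position.

    ``p_ratio_vs_best`` gives each variant's p relative to the winner; the
    winner's row reports how many times weaker the runner-up is.
    """
    if len(stats) != vt.n_variants:
        raise ValueError("one SegregationStats per variant required")
    rows = []
    for i, s in enumerate(stats):
        v = vt.variants.iloc[i]
        rows.append(
            {
                "chromosome": v["chromosome"],
                "position_bp": int(v["position_bp"]),
                "ref_allele": v["ref_allele"],
                "alt_allele": v["alt_allele"],
                "annotation": v["annotation"],
                "gene": v["gene"],
                "case_hom_alt": s.case_hom_alt,
                "ctrl_hom_ref": s.ctrl_hom_ref,
                "ctrl_het": s.ctrl_het,
                "ctrl_hom_alt": s.ctrl_hom_alt,
                "penetrance": s.penetrance if s.penetrance is not None else np.nan,
                "chi2": s.chi2,
                "p": s.p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_ratio_vs_best"] = []
        return df
    df = df.sort_values(
        by=["p", "penetrance", "position_bp"],
        ascending=[True, False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    best_p = df["p"].iloc[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["p"] / best_p if best_p > 0 else np.where(df["p"] > 0, np.inf, 1.0)
    df["p_ratio_vs_best"] = ratio
    if len(df) > 1 and best_p > 0:
        df.loc[0, "p_ratio_vs_best"] = df["p"].iloc[1] / best_p
    return df


def format_percent(p: float) -> str:
    """Genotype-frequency rendering: one decimal at >= 1%, two significant figures below."""
    return f"{p:.1f}" if p >= 1.0 else f"{p:.2g}"


def genotype_frequency_report(n_hom_ref: int, n_het: int, n_hom_alt: int) -> pd.DataFrame:
    """Cohort genotype frequencies as percentages, with display strings."""
    total = n_hom_ref + n_het + n_hom_alt
    if total == 0:
        raise ValueError("no genotyped samples")
    rows = []
    for label, n in (("hom_ref", n_hom_ref), ("het", n_het), ("hom_alt", n_hom_alt)):
        pct = 100.0 * n / total
        rows.append({"genotype": label, "count": n, "percent": pct, "display": format_percent(pct)})
    return pd.DataFrame(rows)
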