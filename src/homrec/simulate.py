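"""Forward simulation of a closed dog-breed cohort for pipeline testing.

The generator reproduces the population structure that makes recessive
discovery in an inbred breed hard: a multi-megabase *risk haplotype*
segregating at appreciable frequency carries several old "decoy" variants
on every copy, while the truly causal variant arose recently and is present
on only a fraction of risk-haplotype copies.  Dogs homozygous for the risk
segment but lacking the causal allele are therefore healthy, old decoy
variants mimic association with incomplete penetrance, and only an obligate
carrier (an unaffected parent of a case, necessarily heterozygous for the
causal allele yet homozygous for the decoys) separates the two.

The model is a founder-haplotype pool with random union of gametes: each
chromosome has a pool of founder haplotypes drawn per-marker from a minor
allele frequency distribution, one of which donates the risk segment.  An
independent X-linked risk segment produces a second, clinically distinct
disease type (hemizygous males / homozygous females affected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    VariantTable,
    make_expression_table,
    make_luciferase_plate,
    make_marker_map,
    make_sample_table,
)


class SimulationError(RuntimeError):
    """Raised when a configuration cannot produce the requested cohort."""


@dataclass
class SimulationConfig:
    """Knobs of the breed-population generator.

    Defaults mirror the discovery-cohort conditions the pipeline is meant
    to face: 12 type-1 cases, 6 type-2 cases and 67 controls genotyped on a
    few hundred markers per chromosome, a ~7 Mb autosomal risk segment at
    15% haplotype frequency carrying four old decoy variants, and a causal
    allele present on 60% of risk-haplotype copies (``recent_fraction``).
    """

    seed: int = 0
    n_markers: Mapping[str, int] = field(default_factory=lambda: {"1": 500, "15": 500, "X": 250})
    chrom_length_bp: Mapping[str, int] = field(
        default_factory=lambda: {"1": 120_000_000, "15": 64_000_000, "X": 124_000_000}
    )
    n_case_type1: int = 12
    n_case_type2: int = 6
    n_controls: int = 67
    risk_hap_freq: float = 0.15
    x_risk_freq: float = 0.15
    n_decoy_variants: int = 4
    n_background_variants: int = 20
    recent_fraction: float = 0.6
    x_locus: bool = True
    phenocopy_rate: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_founder_haplotypes: int = 30
    risk_interval_bp: tuple[int, int] = (200_000, 7_400_000)
    x_interval_bp: tuple[int, int] = (38_000_000, 53_700_000)
    causal_position_bp: int = 1_430_000
    recombination_rate: float = 0.0  # per-adjacent-marker switch prob when forming a gamete
    missing_rate: float = 0.005
    make_obligate_carrier: bool = True
    max_retries: int = 5000

    def validate(self) -> None:
        for name in ("risk_hap_freq", "x_risk_freq", "recent_fraction", "phenocopy_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.recent_fraction <= 0:
            raise ValueError("recent_fraction must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_case_type1 < 1:
            raise ValueError("need at least one type-1 case")
        start, end = self.risk_interval_bp
        if not start <= self.causal_position_bp <= end:
            raise ValueError("causal position must lie inside the risk interval")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated cohort."""

    causal_chrom: str
    causal_position_bp: int
    decoy_positions_bp: list[int]
    risk_interval_bp: tuple[int, int]
    x_interval_bp: tuple[int, int] | None
    # per-sample counts of risk-haplotype copies / causal-allele copies on CFA-like chr
    risk_copies: dict[str, int]
    causal_copies: dict[str, int]
    risk_hom_control_present: bool
    expression_fold_changes: dict[str, float] = field(default_factory=dict)


class _Chrom:
    """Founder pool for one chromosome."""

    def __init__(self, rng, name, n_markers, length, maf_range, n_founders):
        self.name = name
        pool = np.unique(rng.integers(1, length + 1, size=n_markers * 2 + 16))
        while pool.size < n_markers:  # collisions are rare at these densities
            pool = np.unique(np.concatenate([pool, rng.integers(1, length + 1, size=n_markers)]))
        self.positions = np.sort(rng.permutation(pool)[:n_markers])
        self.maf = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
        self.founders = (rng.random((n_founders, n_markers)) < self.maf).astype(np.int8)
        self.risk_markers: np.ndarray | None = None  # indices of the shared segment

    def set_risk_interval(self, start, end):
        self.risk_markers = np.flatnonzero((self.positions >= start) & (self.positions <= end))

    def draw_hap(self, rng, recomb):
        """A gamete: one founder, optionally a recombinant mosaic of two."""
        i = rng.integers(1, len(self.founders))  # founder 0 reserved for the risk pattern
        hap = self.founders[i].copy()
        if recomb > 0:
            j = rng.integers(1, len(self.founders))
            switch = rng.random(len(hap)) < recomb
            use_j = np.logical_xor.accumulate(switch)
            hap[use_j] = self.founders[j][use_j]
        return hap

    def draw_risk_hap(self, rng, recomb):
        """A risk-haplotype copy: founder-0 alleles across the risk segment."""
        hap = self.draw_hap(rng, recomb)
        hap[self.risk_markers] = self.founders[0][self.risk_markers]
        return hap


@dataclass
class _Individual:
    sex: str
    haps: dict  # chrom -> list of (allele vector, carries_risk, carries_causal)
    x_risk_copies: int


def _draw_individual(rng, cfg: SimulationConfig, chroms: dict[str, _Chrom], sex=None) -> _Individual:
    sex = sex or ("male" if rng.random() < 0.5 else "female")
    haps: dict[str, list] = {}
    x_risk = 0
    for name, ch in chroms.items():
        n_copies = 1 if (name == "X" and sex == "male") else 2
        copies = []
        for _ in range(n_copies):
            if name == "15" and rng.random() < cfg.risk_hap_freq:
                hap = ch.draw_risk_hap(rng, cfg.recombination_rate)
                causal = rng.random() < cfg.recent_fraction
                copies.append((hap, True, causal))
            elif name == "X" and cfg.x_locus and rng.random() < cfg.x_risk_freq:
                hap = ch.draw_risk_hap(rng, cfg.recombination_rate)
                x_risk += 1
                copies.append((hap, True, False))
            else:
                copies.append((ch.draw_hap(rng, cfg.recombination_rate), False, False))
        haps[name] = copies
    return _Individual(sex=sex, haps=haps, x_risk_copies=x_risk)


def _force_type1(rng, cfg, chroms, ind: _Individual) -> _Individual:
    """Make both chr-15 copies risk haplotypes carrying the causal allele."""
    ch = chroms["15"]
    ind.haps["15"] = [
        (ch.draw_risk_hap(rng, cfg.recombination_rate), True, True),
        (ch.draw_risk_hap(rng, cfg.recombination_rate), True, True),
    ]
    return ind


def _force_x_affected(rng, cfg, chroms, ind: _Individual) -> _Individual:
    ch = chroms["X"]
    n = len(ind.haps["X"])
    ind.haps["X"] = [(ch.draw_risk_hap(rng, cfg.recombination_rate), True, False) for _ in range(n)]
    ind.x_risk_copies = n
    return ind


def _is_type1(ind: _Individual) -> bool:
    h = ind.haps["15"]
    return len(h) == 2 and all(c[2] for c in h)


def _is_type2(ind: _Individual, cfg: SimulationConfig) -> bool:
    if not cfg.x_locus or "X" not in ind.haps:
        return False
    return ind.x_risk_copies == len(ind.haps["X"])


def _risk_copies(ind: _Individual) -> int:
    return sum(1 for c in ind.haps["15"] if c[1])


def _causal_copies(ind: _Individual) -> int:
    return sum(1 for c in ind.haps["15"] if c[2])


def simulate_breed_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, VariantTable, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate a cohort with genotypes, candidate variants, phenotypes and pedigree.

    Returns ``(genotypes, variant_table, sample_table, pedigree, truth)``.
    Deterministic for a fixed config (seed included).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    chroms: dict[str, _Chrom] = {}
    for name, m in cfg.n_markers.items():
        chroms[name] = _Chrom(
            rng, name, m, cfg.chrom_length_bp[name], cfg.maf_range, cfg.n_founder_haplotypes
        )
    if "15" not in chroms:
        raise SimulationError("configuration must include chromosome '15' markers")
    chroms["15"].set_risk_interval(*cfg.risk_interval_bp)
    if chroms["15"].risk_markers.size == 0:
        raise SimulationError("no markers fall inside the risk interval")
    if "X" in chroms and cfg.x_locus:
        chroms["X"].set_risk_interval(*cfg.x_interval_bp)

    individuals: list[_Individual] = []
    statuses: list[str] = []
    sample_ids: list[str] = []

    def add(ind, status, prefix):
        individuals.append(ind)
        statuses.append(status)
        sample_ids.append(f"{prefix}{len(sample_ids) + 1:03d}")

    # type-1 cases: forced homozygous for the risk haplotype with causal allele
    for _ in range(cfg.n_case_type1):
        for _try in range(cfg.max_retries):
            ind = _force_type1(rng, cfg, chroms, _draw_individual(rng, cfg, chroms))
            if not _is_type2(ind, cfg):
                break
        else:
            raise SimulationError("could not draw a type-1 case free of the X locus")
        add(ind, "case_type1", "case1_")

    # type-2 cases: X-locus affected, not causal-homozygous
    for _ in range(cfg.n_case_type2):
        if not (cfg.x_locus and "X" in chroms):
            raise SimulationError("type-2 cases requested but x_locus disabled")
        for _try in range(cfg.max_retries):
            ind = _force_x_affected(rng, cfg, chroms, _draw_individual(rng, cfg, chroms))
            if not _is_type1(ind):
                break
        else:
            raise SimulationError("could not draw a type-2 case free of the causal genotype")
        add(ind, "case_type2", "case2_")

    # controls: unaffected at both loci; phenocopies relabelled as type-2-like disease
    for _ in range(cfg.n_controls):
        for _try in range(cfg.max_retries):
            ind = _draw_individual(rng, cfg, chroms)
            if not _is_type1(ind) and not _is_type2(ind, cfg):
                break
        else:
            raise SimulationError("could not draw an unaffected control; frequencies too high")
        status = "control"
        if cfg.phenocopy_rate > 0 and rng.random() < cfg.phenocopy_rate:
            status = "case_type2"  # clinically affected without the type-1 genotype
        add(ind, status, "ctrl_")

    # guarantee (bounded retries) one control homozygous for the risk segment
    # but without the causal allele -- the confound the analysis must survive
    def discordant(ind):
        return _risk_copies(ind) == 2 and _causal_copies(ind) == 0

    risk_hom_control_present = any(
        discordant(ind) for ind, st in zip(individuals, statuses) if st == "control"
    )
    if cfg.recent_fraction < 1.0 and not risk_hom_control_present:
        for _try in range(cfg.max_retries):
            ind = _draw_individual(rng, cfg, chroms)
            if discordant(ind) and not _is_type2(ind, cfg):
                # replace the last plain control
                idx = max(i for i, st in enumerate(statuses) if st == "control")
                individuals[idx] = ind
                risk_hom_control_present = True
                break

    obligate = [False] * len(individuals)
    ped_rows = []
    if cfg.make_obligate_carrier:
        # explicit construction: risk/risk diplotype with exactly one causal copy,
        # attached in the pedigree as a parent of the first type-1 case
        ch = chroms["15"]
        carrier = _draw_individual(rng, cfg, chroms, sex="female")
        # with recent_fraction < 1 the carrier's second copy is an old risk
        # haplotype without the causal allele (so it is homozygous for every
        # decoy yet heterozygous for the causal variant); at 1.0 no such
        # copy exists, so the second haplotype is a plain one
        if cfg.recent_fraction < 1.0:
            second = (ch.draw_risk_hap(rng, cfg.recombination_rate), True, False)
        else:
            second = (ch.draw_hap(rng, cfg.recombination_rate), False, False)
        carrier.haps["15"] = [
            (ch.draw_risk_hap(rng, cfg.recombination_rate), True, True),
            second,
        ]
        if _is_type2(carrier, cfg):
            carrier.haps["X"] = [
                (chroms["X"].draw_hap(rng, cfg.recombination_rate), False, False)
                for _ in carrier.haps["X"]
            ]
            carrier.x_risk_copies = 0
        add(carrier, "control", "carrier_")
        obligate.append(False)
        obligate[-1] = True
        child = sample_ids[0]  # first type-1 case
        ped_rows.append({"child_id": child, "sire_id": "0", "dam_id": sample_ids[-1]})
    while len(obligate) < len(individuals):
        obligate.append(False)

    # ---- assemble GenotypeMatrix ----
    chrom_order = list(cfg.n_markers.keys())
    marker_ids, chrom_col, pos_col = [], [], []
    for name in chrom_order:
        ch = chroms[name]
        for k, p in enumerate(ch.positions):
            marker_ids.append(f"chr{name}_m{k + 1}")
            chrom_col.append(name)
            pos_col.append(int(p))
    markers = make_marker_map(marker_ids, chrom_col, pos_col)

    n = len(individuals)
    dosage = np.empty((n, len(marker_ids)), dtype=np.int8)
    col = 0
    for name in chrom_order:
        m = cfg.n_markers[name]
        block = np.empty((n, m), dtype=np.int8)
        for i, ind in enumerate(individuals):
            copies = ind.haps[name]
            if len(copies) == 1:  # male X: hemizygous stored as 0/2
                block[i] = copies[0][0] * 2
            else:
                block[i] = copies[0][0] + copies[1][0]
        dosage[:, col : col + m] = block
        col += m
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    sexes = np.array([ind.sex for ind in individuals], dtype=object)
    gm = GenotypeMatrix(samples=sample_ids, markers=markers, dosage=dosage, sex=sexes)
    sample_table = make_sample_table(sample_ids, list(sexes), statuses, obligate)
    pedigree = pd.DataFrame(ped_rows, columns=["child_id", "sire_id", "dam_id"])

    # ---- candidate VariantTable: decoys + causal + background noise ----
    start, end = cfg.risk_interval_bp
    decoy_pool = [p for p in range(start + 50_000, end - 50_000, (end - start) // (cfg.n_decoy_variants + 2))]
    decoy_positions = sorted(rng.choice(decoy_pool, size=cfg.n_decoy_variants, replace=False).tolist())
    decoy_positions = [int(p) for p in decoy_positions if p != cfg.causal_position_bp]

    var_rows, var_genos = [], []
    annos = ["exonic", "splicing", "exonic", "splicing", "intergenic"]
    for d, pos in enumerate(decoy_positions):
        calls = np.array([_risk_copies(ind) for ind in individuals], dtype=np.int8)
        var_rows.append(
            {
                "chromosome": "15",
                "position_bp": pos,
                "ref_allele": "C",
                "alt_allele": "T",
                "annotation": annos[d % len(annos)],
                "gene": f"DECOY{d + 1}",
            }
        )
        var_genos.append(calls)
    causal_calls = np.array([_causal_copies(ind) for ind in individuals], dtype=np.int8)
    var_rows.append(
        {
            "chromosome": "15",
            "position_bp": cfg.causal_position_bp,
            "ref_allele": "G",
            "alt_allele": "A",
            "annotation": "intronic",
            "gene": "TARGET1",
        }
    )
    var_genos.append(causal_calls)
    # unlinked background variants on autosomes, random population frequency
    bg_chroms = [c for c in chrom_order if c != "X"]
    for b in range(cfg.n_background_variants):
        chrom = bg_chroms[b % len(bg_chroms)]
        pos = int(rng.integers(1, cfg.chrom_length_bp[chrom]))
        f = rng.uniform(0.05, 0.5)
        calls = ((rng.random(n) < f).astype(np.int8) + (rng.random(n) < f).astype(np.int8))
        var_rows.append(
            {
                "chromosome": chrom,
                "position_bp": pos,
                "ref_allele": "A",
                "alt_allele": "C",
                "annotation": "intergenic",
                "gene": f"BG{b + 1}",
            }
        )
        var_genos.append(calls)

    vdf = pd.DataFrame(var_rows)
    order = np.lexsort((vdf["position_bp"].to_numpy(), vdf["chromosome"].to_numpy()))
    vdf = vdf.iloc[order].reset_index(drop=True)
    vt = VariantTable(vdf, sample_ids, np.vstack(var_genos)[order])

    truth = SimulationTruth(
        causal_chrom="15",
        causal_position_bp=cfg.causal_position_bp,
        decoy_positions_bp=decoy_positions,
        risk_interval_bp=cfg.risk_interval_bp,
        x_interval_bp=cfg.x_interval_bp if cfg.x_locus else None,
        risk_copies={sid: _risk_copies(ind) for sid, ind in zip(sample_ids, individuals)},
        causal_copies={sid: _causal_copies(ind) for sid, ind in zip(sample_ids, individuals)},
        risk_hom_control_present=risk_hom_control_present,
    )
    return gm, vt, sample_table, pedigree, truth


def simulate_expression_cts(
    genes: dict[str, float],
    n_case: int,
    n_control: int,
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    reference_genes: tuple[str, ...] = ("GAPDH", "YWHAZ"),
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for the ddCt pipeline.

    ``genes`` maps target gene -> fold change in cases; reference genes are
    appended with fold 1.  Case Ct for a gene with fold change ``F`` sits
    ``log2(F)`` cycles below the control baseline (doubling per cycle), with
    Gaussian measurement noise of ``noise_sd`` cycles per replicate.
    """
    if any(f <= 0 for f in genes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    all_genes = dict(genes)
    for ref in reference_genes:
        all_genes.setdefault(ref, 1.0)
    baselines = {g: 20.0 + 5.0 * rng.random() for g in all_genes}
    rows = []
    samples = [("case", f"case_{i + 1}") for i in range(n_case)] + [
        ("control", f"ctrl_{i + 1}") for i in range(n_control)
    ]
    for gene, fold in all_genes.items():
        shift = -np.log2(fold) if gene not in reference_genes else 0.0
        for group, sid in samples:
            mu = baselines[gene] + (shift if group == "case" else 0.0)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample_id": sid,
                        "replicate": rep,
                        "ct": mu + rng.normal(0.0, noise_sd) if noise_sd > 0 else mu,
                    }
                )
    return make_expression_table(pd.DataFrame(rows))


def simulate_luciferase_plate(
    effect_wt: float,
    effect_mt: float,
    n_wells: int,
    cv: float,
    seed: int,
    baseline_lum: float = 1e5,
) -> pd.DataFrame:
    """Simulate a dual-reporter plate.

    Expected experimental/control ratio is 1 for the empty vector,
    ``effect_wt`` for the wild-type construct (a silencer: < 1) and
    ``effect_mt`` for the mutant (silencing disrupted: > ``effect_wt``),
    with multiplicative noise of coefficient of variation ``cv``.
    """
    if effect_wt <= 0 or effect_mt <= 0:
        raise ValueError("effects must be positive")
    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    well = 1
    for construct, effect in (("empty", 1.0), ("wild_type", effect_wt), ("mutant", effect_mt)):
        for _ in range(n_wells):
            ctrl = baseline_lum * (1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0))
            ratio = effect * (1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0))
            rows.append(
                {
                    "construct": construct,
                    "well": well,
                    "lum_experimental": ratio * ctrl,
                    "lum_control": ctrl,
                }
            )
            well += 1
    return make_luciferase_plate(pd.DataFrame(rows))
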