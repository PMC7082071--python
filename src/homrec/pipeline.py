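"""End-to-end type-1 discovery: scan -> block -> recessive filter -> carrier -> ranking.

The run report records every stage's candidate counts, the final ranked
candidates, and full provenance (package version, seed, configuration
hash) in every output file.  Reports contain no timestamps, so a repeated
run with the same configuration and seed is byte-identical; timestamped
progress goes to the logger only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .blocks import HaplotypeBlock, block_carriers, detect_shared_block
from .datatypes import GenotypeMatrix, VariantTable
from .filtering import (
    FilterConfig,
    carrier_constraint,
    rank_candidates,
    recessive_filter,
    segregation_stats,
)
from .gwas import AssociationResult, QCReport, association_scan, permutation_empirical, qc_filter
from .io import write_report_tsv

logger = logging.getLogger("homrec")


@dataclass
class DiscoveryConfig:
    """Settings for :func:`run_type1_discovery`.

    The default filter settings suit an in-breed cohort, where unaffected
    risk-haplotype homozygotes and heterozygous carriers are expected among
    the controls: alternate-homozygous controls are tolerated and the
    heterozygous-control bound is loose, leaving the obligate-carrier
    constraint and the segregation ranking to separate old haplotype
    passengers from the causal variant.
    """

    case_status: str = "case_type1"
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    n_perm: int = 0  # 0 skips permutation; the field-standard default is 100,000
    seed: int = 0
    anchor_marker: str | None = None  # default: top association marker
    tolerate_missing_in_block: bool = True
    filter_config: FilterConfig = field(
        default_factory=lambda: FilterConfig(max_control_het_frac=0.5, allow_control_hom_alt=True)
    )
    carriers: list[str] | None = None  # default: obligate carriers from the sample table

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["filter_config"]["region"] = None  # region is derived, not configured
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class DiscoveryReport:
    qc: QCReport
    association: AssociationResult
    block: HaplotypeBlock
    carrier_ids: list[str]
    stage_counts: dict[str, int]
    candidates: pd.DataFrame  # ranked
    candidates_no_carrier: pd.DataFrame
    config: DiscoveryConfig
    seed: int

    def provenance(self) -> str:
        return f"homrec {__version__} seed={self.seed} config={self.config.config_hash()}"

    def summary_dict(self) -> dict:
        top = self.association.top_marker()
        best = self.candidates.iloc[0].to_dict() if len(self.candidates) else None
        return {
            "version": __version__,
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
            "qc": {
                "n_input": self.qc.n_input,
                "removed_call_rate": self.qc.removed_call_rate,
                "removed_maf": self.qc.removed_maf,
                "removed_hwe": self.qc.removed_hwe,
                "n_retained": self.qc.n_retained,
            },
            "lambda_gc": self.association.lambda_gc,
            "top_marker": {
                "marker_id": top["marker_id"],
                "chromosome": top["chromosome"],
                "position_bp": int(top["position_bp"]),
                "chi2": float(top["chi2"]),
                "p_raw": float(top["p_raw"]),
            },
            "block": {
                "chromosome": self.block.chromosome,
                "start_bp": self.block.start_bp,
                "end_bp": self.block.end_bp,
                "span_mb": self.block.span_mb,
            },
            "carriers": self.carrier_ids,
            "stage_counts": self.stage_counts,
            "final_candidate": best,
        }


def run_type1_discovery(
    gm: GenotypeMatrix,
    vt: VariantTable,
    samples: pd.DataFrame,
    cfg: DiscoveryConfig | None = None,
) -> DiscoveryReport:
    """Execute the full discovery chain on in-memory inputs.

    An empty final candidate set is a reported finding, not an error.
    """
    cfg = cfg or DiscoveryConfig()
    logger.info("QC: %d markers in", gm.n_markers)
    gm_qc, qc = qc_filter(
        gm, samples, maf_min=cfg.maf_min, call_rate_min=cfg.call_rate_min, hwe_p_min=cfg.hwe_p_min
    )
    logger.info("QC: %d markers retained", qc.n_retained)

    assoc = association_scan(gm_qc, samples, case_statuses={cfg.case_status})
    if cfg.n_perm > 0:
        perm = permutation_empirical(
            gm_qc, samples, case_statuses={cfg.case_status}, n_perm=cfg.n_perm, seed=cfg.seed
        )
        assoc.table = assoc.table.merge(perm, on="marker_id")
        assoc.n_perm = cfg.n_perm
    top = assoc.top_marker()
    logger.info("top marker %s (chi2=%.2f)", top["marker_id"], top["chi2"])

    case_ids = list(samples.loc[samples["status"] == cfg.case_status, "sample_id"])
    if cfg.anchor_marker is not None:
        block = detect_shared_block(
            gm_qc, case_ids, cfg.anchor_marker, tolerate_missing=cfg.tolerate_missing_in_block
        )
    else:
        # default anchor is the top association marker; when the cases are not
        # homozygous-concordant there (the signal can peak just outside the
        # shared segment), fall back down the chi2 ranking
        block = None
        ranking = assoc.table.sort_values("chi2", ascending=False)["marker_id"]
        for rank, candidate in enumerate(ranking):
            try:
                block = detect_shared_block(
                    gm_qc, case_ids, str(candidate), tolerate_missing=cfg.tolerate_missing_in_block
                )
            except ValueError:
                continue
            if rank > 0:
                logger.warning(
                    "top marker unusable as anchor; anchored at rank-%d marker %s", rank + 1, candidate
                )
            break
        if block is None:
            raise ValueError("no marker is homozygous-concordant across the cases")
    logger.info("critical region %s:%d-%d (%.1f Mb)", block.chromosome, block.start_bp, block.end_bp, block.span_mb)

    fcfg = dataclasses.replace(cfg.filter_config, region=block)
    filtered = recessive_filter(vt, samples, fcfg, case_status=cfg.case_status)
    carriers = (
        cfg.carriers
        if cfg.carriers is not None
        else list(samples.loc[samples["obligate_carrier"].astype(bool), "sample_id"])
    )
    final = carrier_constraint(filtered, carriers) if carriers else filtered

    def ranked(v: VariantTable) -> pd.DataFrame:
        stats_list = [
            segregation_stats(v, i, samples, case_status=cfg.case_status) for i in range(v.n_variants)
        ]
        return rank_candidates(v, stats_list)

    stage_counts = {
        "variants_input": vt.n_variants,
        "after_recessive_filter": filtered.n_variants,
        "after_carrier_constraint": final.n_variants,
    }
    logger.info("stage counts: %s", stage_counts)
    return DiscoveryReport(
        qc=qc,
        association=assoc,
        block=block,
        carrier_ids=carriers,
        stage_counts=stage_counts,
        candidates=ranked(final),
        candidates_no_carrier=ranked(filtered),
        config=cfg,
        seed=cfg.seed,
    )


def write_discovery_report(report: DiscoveryReport, out_dir: str | os.PathLike, force: bool = False) -> None:
    """Write association, QC, block and candidate tables plus a JSON summary.

    Refuses to overwrite an existing report directory unless ``force``.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    expected = ["association.tsv", "qc_report.tsv", "block.tsv", "candidates.tsv", "run_summary.json"]
    stale = [f for f in expected if os.path.exists(os.path.join(out, f))]
    if stale and not force:
        raise FileExistsError(
            f"output directory {out!r} already holds {stale}; pass force=True/--force to overwrite"
        )
    prov = report.provenance()
    write_report_tsv(report.association.table, os.path.join(out, "association.tsv"), header_comment=prov)
    write_report_tsv(report.qc.as_frame(), os.path.join(out, "qc_report.tsv"), header_comment=prov)
    block_df = pd.DataFrame(
        [
            {
                "chromosome": report.block.chromosome,
                "start_bp": report.block.start_bp,
                "end_bp": report.block.end_bp,
                "span_bp": report.block.span_bp,
                "span_mb": report.block.span_mb,
            }
        ]
    )
    write_report_tsv(block_df, os.path.join(out, "block.tsv"), header_comment=prov)
    write_report_tsv(report.candidates, os.path.join(out, "candidates.tsv"), header_comment=prov)
    with open(os.path.join(out, "run_summary.json"), "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
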