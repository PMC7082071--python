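"""Shared-homozygosity block detection and critical-region delimitation.

In a recessive disease within a closed breed, all cases are expected to be
homozygous (identical by descent) across the segment carrying the causal
allele.  Starting from an anchor marker (typically the top association
marker) the block is extended marker-by-marker in both directions while
every case remains homozygous - or hemizygous, on the male X - for the
same allele; the first heterozygous or opposite-homozygous case genotype
stops the extension.  Bounds are the positions of the outermost concordant
markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class HaplotypeBlock:
    """A chromosome interval homozygous for one shared allele pattern.

    ``allele_pattern`` holds the shared homozygous dosage (0 or 2) per
    marker inside the bounds; ``-1`` marks markers where every detection
    case was missing (tolerated during extension).
    """

    chromosome: str
    start_bp: int
    end_bp: int
    marker_ids: list[str]
    allele_pattern: np.ndarray

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("block start must not exceed end")
        if len(self.marker_ids) != len(self.allele_pattern):
            raise ValueError("allele pattern must cover exactly the block markers")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def span_mb(self) -> float:
        return block_span_mb(self.start_bp, self.end_bp)

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return chromosome == self.chromosome and self.start_bp <= position_bp <= self.end_bp


def block_span_mb(start_bp: int, end_bp: int) -> float:
    """Inclusive span in megabases, rounded half-up to one decimal."""
    if end_bp < start_bp:
        raise ValueError("end coordinate precedes start")
    mb = Decimal(end_bp - start_bp + 1) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _concordant_hom(dosages: np.ndarray, tolerate_missing: bool) -> tuple[bool, int]:
    """Whether all case dosages agree on one homozygous value.

    Returns ``(ok, pattern)`` with pattern in {0, 2} or -1 when every case
    is missing.  Heterozygous (dosage 1) or discordant homozygous calls
    break concordance.
    """
    present = dosages[dosages != MISSING]
    if present.size == 0:
        return tolerate_missing, MISSING
    if (present == 1).any():
        return False, MISSING
    vals = np.unique(present)
    if vals.size != 1:
        return False, MISSING
    if present.size < dosages.size and not tolerate_missing:
        return False, MISSING
    return True, int(vals[0])


def detect_shared_block(
    gm: GenotypeMatrix,
    case_ids: list[str],
    anchor_marker: str,
    tolerate_missing: bool = True,
) -> HaplotypeBlock:
    """Extend the case-shared homozygous block around ``anchor_marker``."""
    rows = [gm.samples.index(s) for s in case_ids]
    anchor = gm.marker_index(anchor_marker)
    chrom = gm.markers["chromosome"].iloc[anchor]
    on_chrom = np.flatnonzero(gm.markers["chromosome"].to_numpy() == chrom)
    pos_in_chrom = int(np.flatnonzero(on_chrom == anchor)[0])

    anchor_dos = gm.dosage[rows, anchor]
    for r, d in zip(rows, anchor_dos):
        if d == MISSING or d == 1:
            raise ValueError(
                f"anchor marker {anchor_marker!r} is not homozygous-genotyped in case "
                f"{gm.samples[r]!r}"
            )
    ok, _ = _concordant_hom(anchor_dos, tolerate_missing=False)
    if not ok:
        bad = gm.samples[rows[int(np.argmax(anchor_dos != anchor_dos[0]))]]
        raise ValueError(f"cases disagree at anchor marker {anchor_marker!r} (e.g. {bad!r})")

    lo = hi = pos_in_chrom
    while lo - 1 >= 0:
        ok, _ = _concordant_hom(gm.dosage[rows, on_chrom[lo - 1]], tolerate_missing)
        if not ok:
            break
        lo -= 1
    while hi + 1 < len(on_chrom):
        ok, _ = _concordant_hom(gm.dosage[rows, on_chrom[hi + 1]], tolerate_missing)
        if not ok:
            break
        hi += 1

    idx = on_chrom[lo : hi + 1]
    pattern = np.array(
        [_concordant_hom(gm.dosage[rows, j], tolerate_missing)[1] for j in idx], dtype=np.int8
    )
    return HaplotypeBlock(
        chromosome=str(chrom),
        start_bp=int(gm.markers["position_bp"].iloc[idx[0]]),
        end_bp=int(gm.markers["position_bp"].iloc[idx[-1]]),
        marker_ids=list(gm.markers["marker_id"].iloc[idx]),
        allele_pattern=pattern,
    )


def block_carriers(
    gm: GenotypeMatrix, block: HaplotypeBlock, sample_ids: list[str] | None = None
) -> pd.Series:
    """Classify samples against the block's homozygous allele pattern.

    ``risk_homozygous``: matches the pattern homozygously (or hemizygously
    on the X) at every non-missing block marker.  ``non_carrier``: opposite
    homozygous somewhere, which excludes even a single copy of the risk
    haplotype.  Everything else (a heterozygous marker) is
    ``heterozygous_or_partial``.
    """
    sample_ids = sample_ids if sample_ids is not None else list(gm.samples)
    try:
        cols = np.array([gm.marker_index(m) for m in block.marker_ids])
    except KeyError as exc:
        raise ValueError(f"block marker missing from genotype matrix: {exc}") from exc
    informative = block.allele_pattern != MISSING
    cols = cols[informative]
    pattern = block.allele_pattern[informative].astype(np.int16)

    labels = {}
    for sid in sample_ids:
        d = gm.dosage[gm.samples.index(sid), cols].astype(np.int16)
        known = d != MISSING
        dd, pp = d[known], pattern[known]
        if dd.size == 0 or np.all(dd == pp):
            labels[sid] = "risk_homozygous"
        elif np.any((dd != 1) & (dd != pp)):  # opposite homozygote: zero risk copies
            labels[sid] = "non_carrier"
        else:
            labels[sid] = "heterozygous_or_partial"
    return pd.Series(labels, name="block_carrier_status")


def block_to_bed_row(block: HaplotypeBlock, name: str = "critical_region") -> str:
    """Half-open 0-based BED line for the block (the only 0-based output)."""
    return f"{block.chromosome}\t{block.start_bp - 1}\t{block.end_bp}\t{name}"
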