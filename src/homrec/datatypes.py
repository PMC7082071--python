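"""Core in-memory containers shared by every homrec module.

Conventions
-----------
* Genomic coordinates are 1-based and inclusive everywhere in the public
  API.  Half-open 0-based intervals appear only in BED output.
* Genotype dosage counts copies of ``allele_b`` (the "alt" allele of the
  marker map): 0, 1 or 2, with ``-1`` as the single missing sentinel.
* Male samples are haploid (ploidy 1) on chromosome ``"X"``; a hemizygous
  alternate call is stored as dosage 2 so that ``dosage * ploidy / 2``
  always yields the alternate-allele count.
* Per-variant genotype calls use 0 = hom_ref, 1 = het, 2 = hom_alt,
  -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

SEXES = ("male", "female", "unknown")
STATUSES = ("case_type1", "case_type2", "control", "unknown")

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "sex", "status", "obligate_carrier"]
PEDIGREE_COLUMNS = ["child_id", "sire_id", "dam_id"]
VARIANT_COLUMNS = ["chromosome", "position_bp", "ref_allele", "alt_allele", "annotation", "gene"]

ANNOTATIONS = ("exonic", "splicing", "intronic", "intergenic", "other")


def make_marker_map(
    marker_ids: Sequence[str],
    chromosomes: Sequence[str],
    positions_bp: Sequence[int],
    allele_a: Sequence[str] | None = None,
    allele_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble and validate a marker map DataFrame.

    Positions must be >= 1 and strictly increasing within a chromosome.
    """
    n = len(marker_ids)
    df = pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "chromosome": list(chromosomes),
            "position_bp": np.asarray(positions_bp, dtype=np.int64),
            "allele_a": list(allele_a) if allele_a is not None else ["A"] * n,
            "allele_b": list(allele_b) if allele_b is not None else ["G"] * n,
        }
    )
    validate_marker_map(df)
    return df


def validate_marker_map(df: pd.DataFrame) -> None:
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id: {dup!r}")
    if (df["position_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1")
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom!r}")


@dataclass
class GenotypeMatrix:
    """Samples x markers alternate-allele dosage with a marker map.

    ``dosage`` is an int8 array of shape (n_samples, n_markers) holding
    0/1/2 or :data:`MISSING`.  ``sex`` is a per-sample array over
    :data:`SEXES`; ploidy follows from sex and chromosome.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=object)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def ploidy(self) -> np.ndarray:
        """Per (sample, marker) ploidy: 1 on male X, 2 elsewhere."""
        is_x = (self.markers["chromosome"].to_numpy() == "X")[None, :]
        is_male = (self.sex == "male")[:, None]
        return np.where(is_x & is_male, 1, 2).astype(np.int8)

    def validate(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(self.sex) != len(self.samples):
            raise ValueError("sex array length does not match samples")
        validate_marker_map(self.markers)
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        # dosage 1 is impossible on a haploid (male X) entry
        hemi_het = (self.dosage == 1) & (self.ploidy() == 1)
        if hemi_het.any():
            i, j = np.argwhere(hemi_het)[0]
            raise ValueError(
                f"heterozygous call for haploid sample {self.samples[i]!r} "
                f"at marker {self.markers['marker_id'].iloc[j]!r}"
            )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to a boolean/index marker mask."""
        markers = self.markers.iloc[keep].reset_index(drop=True)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=markers,
            dosage=self.dosage[:, keep],
            sex=self.sex.copy(),
        )

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.markers["marker_id"].to_numpy() == marker_id)
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(idx[0])


def make_sample_table(
    sample_ids: Sequence[str],
    sex: Sequence[str],
    status: Sequence[str],
    obligate_carrier: Sequence[bool] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "sex": list(sex),
            "status": list(status),
            "obligate_carrier": list(obligate_carrier)
            if obligate_carrier is not None
            else [False] * len(sample_ids),
        }
    )
    validate_sample_table(df)
    return df


def validate_sample_table(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    bad_status = set(df["status"]) - set(STATUSES)
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    # an obligate carrier is by definition unaffected by the recessive disease
    clash = df[(df["obligate_carrier"].astype(bool)) & (df["status"] == "case_type1")]
    if len(clash):
        raise ValueError(
            f"sample {clash['sample_id'].iloc[0]!r} marked obligate carrier but has "
            "status case_type1"
        )


def validate_pedigree(ped: pd.DataFrame, known_ids: Sequence[str] | None = None) -> None:
    """Check parent links: referenced ids exist and no sample is its own ancestor."""
    parents: dict[str, set[str]] = {}
    for _, row in ped.iterrows():
        links = {p for p in (row["sire_id"], row["dam_id"]) if p not in ("", "0", None) and not pd.isna(p)}
        parents[row["child_id"]] = links
        if known_ids is not None:
            missing = (links | {row["child_id"]}) - set(known_ids)
            if missing:
                raise ValueError(f"pedigree references unknown sample ids: {sorted(missing)}")

    def ancestors(s: str, seen: set[str]) -> None:
        for p in parents.get(s, ()):  # walk upwards
            if p in seen:
                raise ValueError(f"pedigree cycle involving {p!r}")
            ancestors(p, seen | {p})

    for child in parents:
        ancestors(child, {child})


@dataclass
class VariantTable:
    """Candidate variants with per-sample genotype calls.

    ``variants`` holds :data:`VARIANT_COLUMNS`; ``genotypes`` is an int8
    array of shape (n_variants, n_samples) over {0, 1, 2, -1}.
    """

    variants: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype array shape does not match variants x samples")
        if (self.variants["ref_allele"] == self.variants["alt_allele"]).any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, keep: np.ndarray) -> "VariantTable":
        return VariantTable(
            variants=self.variants.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[keep],
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in variant table") from None


def make_expression_table(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["gene", "sample_id", "replicate", "ct"])
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def make_luciferase_plate(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["construct", "well", "lum_experimental", "lum_control"])
    bad = set(df["construct"]) - {"wild_type", "mutant", "empty"}
    if bad:
        raise ValueError(f"unknown construct labels: {sorted(bad)}")
    if (df["lum_control"] <= 0).any():
        well = df.loc[df["lum_control"] <= 0, "well"].iloc[0]
        raise ValueError(f"non-positive control luminescence in well {well}")
    return df
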