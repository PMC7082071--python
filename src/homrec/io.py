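"""Readers and writers for the external text formats homrec consumes.

PLINK text ``.ped``/``.map`` pairs, VCF v4.x (via pysam), and headered TSV
tables for samples, pedigrees, Ct values and luminescence readings.  All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    VariantTable,
    make_expression_table,
    make_luciferase_plate,
    make_marker_map,
    make_sample_table,
    validate_pedigree,
    validate_sample_table,
)

_PED_SEX = {"1": "male", "2": "female"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_STATUS = {"2": "case_type1", "1": "control"}
_STATUS_PED = {"case_type1": "2", "case_type2": "2", "control": "1", "unknown": "0"}


class PlinkReadResult(NamedTuple):
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    male_x_het_set_missing: int


def read_genotypes_plink_text(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    alleles: pd.DataFrame | None = None,
    affected_status: str = "case_type1",
) -> PlinkReadResult:
    """Read a PLINK text fileset into a :class:`GenotypeMatrix` and sample table.

    Dosage counts copies of ``allele_b``.  The 4-column ``.map`` carries no
    allele labels, so allele order is taken in order of first appearance in
    the ``.ped`` unless an ``alleles`` frame (columns ``marker_id``,
    ``allele_a``, ``allele_b``) pins it down.  ``"0 0"`` pairs become
    missing.  Heterozygous calls of male samples on chromosome X are set
    missing and counted in ``male_x_het_set_missing``.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, marker_id, _cm, pos = fields
            map_rows.append((chrom, marker_id, int(pos)))
    n_markers = len(map_rows)
    marker_ids = [r[1] for r in map_rows]
    if len(set(marker_ids)) != n_markers:
        seen: set[str] = set()
        for mid in marker_ids:
            if mid in seen:
                raise ValueError(f"duplicate marker id: {mid!r}")
            seen.add(mid)

    pinned: dict[str, tuple[str, str]] = {}
    if alleles is not None:
        for _, row in alleles.iterrows():
            pinned[row["marker_id"]] = (str(row["allele_a"]), str(row["allele_b"]))

    sample_ids: list[str] = []
    sexes: list[str] = []
    statuses: list[str] = []
    raw_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex_code, pheno = fields[:6]
            sample_ids.append(iid)
            sexes.append(_PED_SEX.get(sex_code, "unknown"))
            status = _PED_STATUS.get(pheno, "unknown")
            statuses.append(affected_status if status == "case_type1" else status)
            raw_pairs.append(list(zip(fields[6::2], fields[7::2])))

    n_samples = len(sample_ids)
    # establish allele order per marker: pinned, else first-seen in file order
    order: list[tuple[str | None, str | None]] = []
    for j in range(n_markers):
        if marker_ids[j] in pinned:
            order.append(pinned[marker_ids[j]])
            continue
        a = b = None
        for i in range(n_samples):
            for al in raw_pairs[i][j]:
                if al == "0":
                    continue
                if a is None:
                    a = al
                elif al != a and b is None:
                    b = al
            if b is not None:
                break
        order.append((a, b))

    dosage = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    chroms = [r[0] for r in map_rows]
    n_male_x_het = 0
    for i in range(n_samples):
        male = sexes[i] == "male"
        for j in range(n_markers):
            a1, a2 = raw_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            allele_a, allele_b = order[j]
            for al in (a1, a2):
                if al not in (allele_a, allele_b):
                    raise ValueError(
                        f"{ped_path}: sample {sample_ids[i]!r}, marker "
                        f"{marker_ids[j]!r}: unexpected allele {al!r}"
                    )
            d = (a1 == allele_b) + (a2 == allele_b)
            if male and chroms[j] == "X" and d == 1:
                n_male_x_het += 1
                continue  # left missing
            dosage[i, j] = d

    markers = make_marker_map(
        marker_ids,
        chroms,
        [r[2] for r in map_rows],
        allele_a=[a if a is not None else "A" for a, _ in order],
        allele_b=[
            b if b is not None else ("G" if a != "G" else "T") for a, b in order
        ],
    )
    gm = GenotypeMatrix(samples=sample_ids, markers=markers, dosage=dosage, sex=np.array(sexes, dtype=object))
    samples = make_sample_table(sample_ids, sexes, statuses)
    return PlinkReadResult(gm, samples, n_male_x_het)


def write_genotypes_plink_text(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write a PLINK text fileset (4-column .map, 6+2m-column .ped)."""
    with open(map_path, "w") as fh:
        for _, m in gm.markers.iterrows():
            fh.write(f"{m['chromosome']}\t{m['marker_id']}\t0\t{m['position_bp']}\n")
    status_by_id = dict(zip(samples["sample_id"], samples["status"]))
    aa = gm.markers["allele_a"].to_numpy()
    bb = gm.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            sex = _SEX_PED[gm.sex[i]]
            pheno = _STATUS_PED.get(status_by_id.get(sid, "unknown"), "0")
            fields = ["FAM", sid, "0", "0", sex, pheno]
            for j in range(gm.n_markers):
                d = gm.dosage[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [aa[j], aa[j]]
                elif d == 1:
                    fields += [aa[j], bb[j]]
                else:
                    fields += [bb[j], bb[j]]
            fh.write(" ".join(fields) + "\n")


_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


class VcfReadResult(NamedTuple):
    variants: VariantTable
    n_skipped_multiallelic: int


def read_variant_table_vcf(
    vcf_path: str | os.PathLike,
    samples: pd.DataFrame,
    ann_key: str = "ANN_CLASS",
    gene_key: str = "GENE",
    split_multiallelic: bool = False,
) -> VcfReadResult:
    """Read candidate variants from a VCF into a :class:`VariantTable`.

    Annotation class and gene label are taken from the named INFO keys
    (defaulting to ``other``/empty when absent).  Multi-allelic records are
    split into biallelic rows when ``split_multiallelic`` is set, otherwise
    skipped and tallied.
    """
    validate_sample_table(samples)
    cohort = list(samples["sample_id"])
    vf = pysam.VariantFile(os.fspath(vcf_path))
    vcf_samples = list(vf.header.samples)
    if not vcf_samples or "GT" not in vf.header.formats:
        raise ValueError(f"{vcf_path}: no genotype (GT) sample columns")
    missing_ids = set(cohort) - set(vcf_samples)
    if missing_ids:
        raise ValueError(f"{vcf_path}: cohort samples absent from VCF: {sorted(missing_ids)}")

    rows = []
    genos = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        alt_indices = range(1, len(alts) + 1)
        if len(alts) != 1:
            if not split_multiallelic or len(alts) == 0:
                n_skipped += 1
                continue
        for k in alt_indices:
            calls = np.full(len(cohort), MISSING, dtype=np.int8)
            for si, sid in enumerate(cohort):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                # collapse to presence of this alt allele
                mapped = tuple(1 if a == k else 0 for a in gt)
                if len(mapped) == 1:  # haploid call
                    calls[si] = 2 if mapped[0] else 0
                else:
                    calls[si] = _GT_CODE[mapped]
            ann = rec.info.get(ann_key, "other")
            gene = rec.info.get(gene_key, "")
            if isinstance(ann, tuple):
                ann = ann[0]
            if isinstance(gene, tuple):
                gene = gene[0]
            rows.append(
                {
                    "chromosome": rec.chrom,
                    "position_bp": rec.pos,
                    "ref_allele": rec.ref,
                    "alt_allele": alts[k - 1],
                    "annotation": str(ann),
                    "gene": str(gene),
                }
            )
            genos.append(calls)
    vf.close()
    variants = pd.DataFrame(
        rows, columns=["chromosome", "position_bp", "ref_allele", "alt_allele", "annotation", "gene"]
    )
    genotypes = np.vstack(genos) if genos else np.empty((0, len(cohort)), dtype=np.int8)
    return VcfReadResult(VariantTable(variants, cohort, genotypes), n_skipped)


_REV_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_variant_table_vcf(
    vt: VariantTable,
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
    ann_key: str = "ANN_CLASS",
    gene_key: str = "GENE",
) -> None:
    """Write a :class:`VariantTable` as an uncompressed VCF v4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=%s,Number=1,Type=String,Description="Annotation class">' % ann_key)
    header.add_line('##INFO=<ID=%s,Number=1,Type=String,Description="Gene label">' % gene_key)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = contig_lengths or {}
    for chrom in pd.unique(vt.variants["chromosome"]):
        length = contigs.get(chrom, int(vt.variants.loc[vt.variants["chromosome"] == chrom, "position_bp"].max()) + 1000)
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sid in vt.samples:
        header.add_sample(sid)
    out = pysam.VariantFile(os.fspath(path), "w", header=header)
    for i, row in vt.variants.iterrows():
        rec = out.new_record(
            contig=row["chromosome"],
            start=int(row["position_bp"]) - 1,
            alleles=(row["ref_allele"], row["alt_allele"]),
        )
        rec.info[ann_key] = row["annotation"]
        if row["gene"]:
            rec.info[gene_key] = row["gene"]
        for si in range(len(vt.samples)):
            g = int(vt.genotypes[i, si])
            rec.samples[si]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}[g]
        out.write(rec)
    out.close()


def write_report_tsv(
    records: pd.DataFrame,
    path: str | os.PathLike,
    sig_digits: int = 6,
    header_comment: str | None = None,
) -> None:
    """Write a result table as TSV with deterministic column order.

    Floats are rendered with ``sig_digits`` significant digits so that a
    re-read equals the written table to rendered precision.  An optional
    ``#``-prefixed comment line records provenance (version, seed, hash).
    """
    if records.columns.empty:
        raise ValueError("refusing to write a table with no columns")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records.to_csv(fh, sep="\t", index=False, float_format=f"%.{sig_digits}g")


def read_report_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_sample_table_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    df["obligate_carrier"] = df["obligate_carrier"].astype(bool)
    validate_sample_table(df)
    return df


def write_sample_table_tsv(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | os.PathLike, known_ids=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("0")
    validate_pedigree(df, known_ids)
    return df


def write_pedigree_tsv(ped: pd.DataFrame, path: str | os.PathLike) -> None:
    ped.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return make_expression_table(pd.read_csv(path, sep="\t", comment="#"))


def read_luciferase_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return make_luciferase_plate(pd.read_csv(path, sep="\t", comment="#"))
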