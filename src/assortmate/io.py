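"""Readers and writers for the standard formats the pipeline touches.

VCF in (via cyvcf2, GT required and AD used when present), delimited mate
pair tables and sample metadata, GFF3 gene models (via gffutils), and the
per-locus result table out. All output tables are UTF-8 TSV with a header
row and "NA" for missing values; coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    Classification,
    Cohort,
    GeneFeature,
    GenotypeMatrix,
    Individual,
    Locus,
    LocusAssortResult,
    MatePairSet,
    Origin,
    Sex,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

RESULT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "n_pairs_used", "observed_mean",
    "null_mean", "null_sd", "percentile", "classification",
]


def _sniff_delimiter(path: PathLike) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

def read_metadata(path: PathLike) -> Cohort:
    """Read individual metadata (columns: id, sex, origin) into a Cohort."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "sex"):
        if required not in cols:
            raise ValueError(f"metadata file {path} lacks a '{required}' column")
    individuals = []
    for _, row in df.iterrows():
        sex_raw = row[cols["sex"]]
        sex = Sex(sex_raw.strip().lower()) if isinstance(sex_raw, str) and sex_raw.strip() else None
        origin = Origin.unknown
        if "origin" in cols and isinstance(row[cols["origin"]], str):
            origin = Origin(row[cols["origin"]].strip().lower())
        individuals.append(Individual(id=str(row[cols["id"]]).strip(), sex=sex, origin=origin))
    return Cohort(individuals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: PathLike, cohort_metadata: Union[Cohort, PathLike]) -> tuple[Cohort, GenotypeMatrix]:
    """Load biallelic SNPs from a VCF into a minor-allele dosage matrix.

    Multiallelic and indel records are skipped (their count is logged).
    Missing GT calls become ``MISSING``. Dosages are encoded against the
    per-locus minor allele computed over all genotyped samples; AD depths
    are carried along when the VCF provides them.

    Samples present in the VCF but absent from the metadata are kept with
    origin=unknown and a warning.
    """
    from cyvcf2 import VCF  # heavy import, keep local

    meta = cohort_metadata if isinstance(cohort_metadata, Cohort) else read_metadata(cohort_metadata)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)

    individuals = []
    for s in samples:
        if s in meta:
            individuals.append(meta[s])
        else:
            warnings.warn(f"sample {s!r} in VCF absent from metadata; origin set to unknown")
            individuals.append(Individual(id=s, origin=Origin.unknown))
    cohort = Cohort(individuals)

    loci: list[Locus] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[Optional[np.ndarray]] = []
    n_skipped = 0
    any_ad = False
    vcf_has_ad = any(h.info().get("ID") == "AD" for h in vcf.header_iter()
                     if h.type == "FORMAT")
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        loci.append(Locus(var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        ad = var.format("AD") if vcf_has_ad else None
        if ad is not None:
            ad = np.asarray(ad, dtype=np.int32)[:, :2]
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative
            any_ad = True
            depth_cols.append(ad)
        else:
            depth_cols.append(None)
    vcf.close()

    if n_skipped:
        logger.info("skipped %d multiallelic/indel records in %s", n_skipped, path)
    if not loci:
        raise ValueError(f"no biallelic SNP records found in {path}")

    dosage = np.column_stack(dosage_cols)
    allele_depths = None
    if any_ad:
        allele_depths = np.zeros(dosage.shape + (2,), dtype=np.int32)
        for j, col in enumerate(depth_cols):
            if col is not None:
                allele_depths[:, j, :] = col

    matrix = GenotypeMatrix(loci, samples, dosage, allele_depths)  # alt-counted
    return cohort, matrix.encode_minor()


def write_vcf(matrix: GenotypeMatrix, path: PathLike, source: str = "assortmate") -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 with GT and AD fields.

    GT is reconstructed from the dosage and the per-locus minor-allele
    orientation, so a round trip through :func:`read_vcf` preserves the
    dosage matrix of a minor-encoded input exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(l.chrom for l in matrix.locus_ids):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individual_ids) + "\n")
        has_ad = matrix.allele_depths is not None
        fmt = "GT:AD" if has_ad else "GT"
        order = np.lexsort(([l.pos for l in matrix.locus_ids],
                            [l.chrom for l in matrix.locus_ids]))
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in order:
            locus = matrix.locus_ids[j]
            cells = []
            for i in range(matrix.n_individuals):
                d = int(matrix.dosage[i, j])
                alt_count = d if matrix.minor_is_alt[j] else (2 - d if d != MISSING else MISSING)
                gt = gt_strings[alt_count]
                if has_ad:
                    r, a = matrix.allele_depths[i, j]
                    cells.append(f"{gt}:{r},{a}")
                else:
                    cells.append(gt)
            fh.write(f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}"
                     f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# mate pair tables
# ---------------------------------------------------------------------------

def read_pairs(path: PathLike, cohort: Cohort) -> dict[str, MatePairSet]:
    """Read a mate-pair table into MatePairSets keyed by group label.

    The table must have columns female_id, male_id and may have a group
    column; rows without one fall into the "default" group. Duplicate rows
    are dropped with a warning; pairs referencing unknown individuals or
    mismatched sexes raise an error naming the row.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("female_id", "male_id"):
        if required not in cols:
            raise ValueError(f"pair table {path} lacks a '{required}' column")
    group_col = cols.get("group")

    seen: set[tuple[str, str, str]] = set()
    grouped: dict[str, list[tuple[str, str]]] = {}
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):  # 1 = header line
        f = str(row[cols["female_id"]]).strip()
        m = str(row[cols["male_id"]]).strip()
        g = str(row[group_col]).strip() if group_col else "default"
        if (f, m, g) in seen:
            warnings.warn(f"duplicate pair ({f}, {m}) in group {g!r} at row {rownum}; dropped")
            continue
        seen.add((f, m, g))
        for ind_id, expected in ((f, Sex.female), (m, Sex.male)):
            if ind_id not in cohort:
                raise ValueError(f"row {rownum}: individual {ind_id!r} not in cohort")
            if cohort[ind_id].sex is not expected:
                raise ValueError(
                    f"row {rownum}: {ind_id!r} recorded as {cohort[ind_id].sex}, "
                    f"expected {expected.value} (check column order)"
                )
        grouped.setdefault(g, []).append((f, m))
    return {g: MatePairSet(group_label=g, pairs=p) for g, p in grouped.items()}


def write_pairs(pair_sets: dict[str, MatePairSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["female_id", "male_id", "group"])
        for g in sorted(pair_sets):
            for f, m in pair_sets[g].pairs:
                w.writerow([f, m, g])


def write_metadata(cohort: Cohort, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "sex", "origin"])
        for ind in cohort.individuals:
            w.writerow([ind.id, ind.sex.value if ind.sex else "NA", ind.origin.value])


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(results: list[LocusAssortResult], path: PathLike) -> None:
    """Write per-locus results as TSV, sorted by (chromosome, position)."""
    rows = sorted(results, key=lambda r: (r.locus.chrom, r.locus.pos, r.locus.ref, r.locus.alt))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(RESULT_COLUMNS)
        for r in rows:
            w.writerow([
                r.locus.chrom, r.locus.pos, r.locus.ref, r.locus.alt,
                r.n_pairs_used,
                "NA" if np.isnan(r.observed_mean) else repr(float(r.observed_mean)),
                "NA" if np.isnan(r.null_mean) else repr(float(r.null_mean)),
                "NA" if np.isnan(r.null_sd) else repr(float(r.null_sd)),
                "NA" if np.isnan(r.percentile) else repr(float(r.percentile)),
                r.classification.value,
            ])


def read_results(path: PathLike) -> list[LocusAssortResult]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    out = []
    for _, row in df.iterrows():
        out.append(LocusAssortResult(
            locus=Locus(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"])),
            n_pairs_used=int(row["n_pairs_used"]),
            observed_mean=float(row["observed_mean"]) if pd.notna(row["observed_mean"]) else float("nan"),
            percentile=float(row["percentile"]) if pd.notna(row["percentile"]) else float("nan"),
            classification=Classification(row["classification"]),
            null_mean=float(row["null_mean"]) if pd.notna(row["null_mean"]) else float("nan"),
            null_sd=float(row["null_sd"]) if pd.notna(row["null_sd"]) else float("nan"),
        ))
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_genes(path: PathLike) -> list[GeneFeature]:
    """Parse gene features (GFF3 type 'gene' only) from a GFF3 file."""
    import gffutils

    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed GFF3 in {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        gene_name = feat.attributes.get("Name", [""])[0]
        genes.append(GeneFeature(seqid=feat.seqid, start=feat.start, end=feat.end,
                                 strand=feat.strand or ".", gene_id=gene_id,
                                 gene_name=gene_name))
    return genes
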