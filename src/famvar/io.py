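"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x (via cyvcf2 for reading; a deterministic text writer for output),
6-column PED, BED3+label region files, and TSVs for annotations, genotype
count tables, protein domain architectures and FPKM expression matrices.
All readers log record counts at INFO level.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import pandas as pd
from cyvcf2 import VCF

from .core import (
    Affection,
    AnnotationRecord,
    Call,
    Consequence,
    GenotypeCounts,
    GenotypeCountTable,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Predictor,
    RegionSet,
    Sex,
    UnsupportedInputError,
    ValidationError,
    VariantRecord,
    VariantSet,
    VcfParseError,
)

logger = logging.getLogger(__name__)

_INFO_FIELDS = ("GENE", "CDNA", "PROT", "CSQ")


# ---------------------------------------------------------------------------
# VCF

def _info_per_alt(value, i: int, n_alt: int) -> str:
    """Pick the i-th entry of a possibly comma-joined per-ALT INFO value."""
    if value is None:
        return ""
    s = str(value)
    if n_alt > 1 and "," in s:
        parts = s.split(",")
        return parts[i] if i < len(parts) else ""
    return s


def read_vcf(path: str | os.PathLike) -> tuple[VariantSet, GenotypeMatrix]:
    """Read a multi-sample VCF into a variant set and genotype matrix.

    Multi-allelic sites are split into one record per ALT allele; phased
    genotypes are collapsed to unphased dosage states; a genotype with any
    missing allele becomes :attr:`Call.MISSING`. Only diploid GT fields are
    supported.
    """
    path = os.fspath(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises plain Exceptions
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    variants = VariantSet()
    gm = GenotypeMatrix()
    for s in samples:
        gm._samples.setdefault(s, None)

    n_records = 0
    try:
        for rec_idx, v in enumerate(vcf, start=1):
            n_records += 1
            alts = v.ALT or []
            gts = v.genotypes  # per sample: [allele_1, ..., allele_p, phased]
            for i, alt in enumerate(alts):
                rec = VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    gene=_info_per_alt(v.INFO.get("GENE"), i, len(alts)),
                    cdna_change=_info_per_alt(v.INFO.get("CDNA"), i, len(alts)),
                    protein_change=_info_per_alt(v.INFO.get("PROT"), i, len(alts)),
                    consequence=Consequence(
                        _info_per_alt(v.INFO.get("CSQ"), i, len(alts)) or "missense"
                    ),
                    rsid=v.ID or "",
                )
                allele_no = i + 1
                for sample, gt in zip(samples, gts):
                    alleles = list(gt[:-1])  # last element is the phased flag
                    if len(alleles) != 2:
                        raise UnsupportedInputError(
                            f"record {rec_idx}: sample {sample!r} has ploidy "
                            f"{len(alleles)}; only diploid GT is supported"
                        )
                    if any(a < 0 for a in alleles):
                        call = Call.MISSING
                    else:
                        dosage = sum(1 for a in alleles if a == allele_no)
                        call = Call(dosage)
                    gm.set(sample, rec.key, call)
                variants.add(rec)
    except (UnsupportedInputError, ValidationError):
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path!r} at record {n_records + 1}: {exc}"
        ) from exc
    logger.info("read %d variant records (%d samples) from %s",
                len(variants), len(samples), path)
    return variants, gm


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=CDNA,Number=A,Type=String,Description="HGVS cDNA change">
##INFO=<ID=PROT,Number=A,Type=String,Description="HGVS protein change">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {Call.HOM_REF: "0/0", Call.HET: "0/1",
              Call.HOM_ALT: "1/1", Call.MISSING: "./."}


def write_vcf(path: str | os.PathLike, variants: VariantSet,
              gm: GenotypeMatrix, samples: list[str] | None = None) -> None:
    """Write biallelic records with GT fields; header is fixed so output is
    byte-deterministic for identical inputs."""
    samples = samples if samples is not None else gm.samples
    chroms: dict[str, None] = {}
    for rec in variants:
        chroms.setdefault(rec.chrom, None)
    lines = [_VCF_HEADER]
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
    for rec in sorted(variants, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info_parts = []
        for tag, val in zip(_INFO_FIELDS,
                            (rec.gene, rec.cdna_change, rec.protein_change,
                             rec.consequence.value)):
            if val:
                info_parts.append(f"{tag}={val}")
        info = ";".join(info_parts) or "."
        gts = "\t".join(_GT_STRING[gm.call(s, rec.key)] for s in samples)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}"
            f"\t.\t.\t{info}\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    logger.info("wrote %d variant records to %s", len(variants), path)


# ---------------------------------------------------------------------------
# PED

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFFECTION = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Columns: family, individual, father, mother, sex, phenotype. ``0`` means
    missing parent; phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown.
    """
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}"
                )
            _fam, ind_id, father, mother, sex, phen = fields[:6]
            individuals.append(Individual(
                id=ind_id,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                affection=_PED_AFFECTION.get(phen, Affection.UNKNOWN),
            ))
    ped = Pedigree(individuals)
    logger.info("read pedigree of %d individuals from %s", len(ped), path)
    return ped


def write_pedigree(path: str | os.PathLike, ped: Pedigree,
                   family_id: str = "FAM1") -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
                Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in ped:
            fh.write("\t".join([
                family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
                sex_code[ind.sex], aff_code[ind.affection],
            ]) + "\n")


def mark_genotyped(ped: Pedigree, samples: Iterable[str]) -> None:
    """Flag pedigree members present in a genotyped sample roster."""
    roster = set(samples)
    for ind in ped:
        ind.genotyped = ind.id in roster


# ---------------------------------------------------------------------------
# Genotype count tables

def parse_genotype_triplet(cell: str) -> GenotypeCounts | None:
    """Parse a ``"MM/Mm/mm"`` triplet string; ``"NA"`` means cohort absent."""
    cell = cell.strip()
    if cell.upper() == "NA":
        return None
    parts = cell.split("/")
    if len(parts) != 3:
        raise ValidationError(f"expected 'MM/Mm/mm' triplet, got {cell!r}")
    try:
        nums = [int(p) for p in parts]
    except ValueError as exc:
        raise ValidationError(f"non-integer genotype count in {cell!r}") from exc
    if any(n < 0 for n in nums):
        raise ValidationError(f"negative genotype count in {cell!r}")
    return GenotypeCounts(*nums)


def read_counts(path: str | os.PathLike) -> GenotypeCountTable:
    """Read a wide TSV of genotype count triplets.

    First column names the variant; every further column is a cohort whose
    cells are ``"MM/Mm/mm"`` strings or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a variant column plus >=1 cohort")
    table = GenotypeCountTable()
    variant_col = df.columns[0]
    for _, row in df.iterrows():
        for cohort in df.columns[1:]:
            table.set(row[variant_col], cohort, parse_genotype_triplet(row[cohort]))
    logger.info("read genotype counts for %d variants x %d cohorts from %s",
                len(table.variants), len(table.cohorts), path)
    return table


def write_counts(path: str | os.PathLike, table: GenotypeCountTable,
                 variant_col: str = "variant") -> None:
    rows = []
    for variant in table.variants:
        row: dict[str, str] = {variant_col: variant}
        for cohort in table.cohorts:
            counts = table.get(variant, cohort)
            row[cohort] = "NA" if counts is None else "/".join(map(str, counts.as_tuple()))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations

_PREDICTOR_ALIASES = {
    "deleterious": Predictor.DELETERIOUS,
    "damaging": Predictor.DAMAGING,
    "probably_damaging": Predictor.DAMAGING,
    "neutral": Predictor.NEUTRAL,
    "tolerated": Predictor.TOLERATED,
    "benign": Predictor.BENIGN,
    "na": Predictor.MISSING,
    "missing": Predictor.MISSING,
    "": Predictor.MISSING,
}


def _parse_predictor(cell: str) -> Predictor:
    try:
        return _PREDICTOR_ALIASES[str(cell).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown predictor call {cell!r}") from None


def read_annotations(path: str | os.PathLike) -> dict:
    """Read the variant annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    ann: dict = {}
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        maf_cell = row.get("control_maf", "NA")
        maf = None if maf_cell.upper() in ("NA", "") else float(maf_cell)
        ann[key] = AnnotationRecord(
            variant_key=key,
            in_dbsnp135=row.get("in_dbsnp135", "0") == "1",
            in_1000g=row.get("in_1000g", "0") == "1",
            in_esp=row.get("in_esp", "0") == "1",
            in_exac_nonpsych=row.get("in_exac_nonpsych", "0") == "1",
            provean=_parse_predictor(row.get("provean", "NA")),
            sift=_parse_predictor(row.get("sift", "NA")),
            polyphen=_parse_predictor(row.get("polyphen", "NA")),
            control_maf=maf,
        )
    logger.info("read %d annotation records from %s", len(ann), path)
    return ann


def write_annotations(path: str | os.PathLike, ann: dict) -> None:
    rows = []
    for key, rec in ann.items():
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "in_dbsnp135": int(rec.in_dbsnp135),
            "in_1000g": int(rec.in_1000g),
            "in_esp": int(rec.in_esp),
            "in_exac_nonpsych": int(rec.in_exac_nonpsych),
            "provean": rec.provean.value,
            "sift": rec.sift.value,
            "polyphen": rec.polyphen.value,
            "control_maf": "NA" if rec.control_maf is None
                           else format(rec.control_maf, ".6g"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions (BED3 + label)

def read_regions(path: str | os.PathLike) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: need >=3 BED columns")
            label = fields[3] if len(fields) > 3 else f"region{lineno}"
            intervals.append((fields[0], int(fields[1]), int(fields[2]), label))
    rs = RegionSet(intervals)
    logger.info("read %d regions from %s", len(rs), path)
    return rs


def write_regions(path: str | os.PathLike, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# Expression (long-format FPKM TSV)

def read_fpkm(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format FPKM table with columns gene, species, tissue, fpkm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "species": str,
                                            "tissue": str})
    required = {"gene", "species", "tissue", "fpkm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    if (df["fpkm"] < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    logger.info("read %d FPKM rows from %s", len(df), path)
    return df
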