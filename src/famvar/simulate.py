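"""Synthetic pedigree/cohort generators with known ground truth.

The generators emulate the study design the pipeline is built for: a
three-generation family segregating a fully penetrant dominant rare
heterozygous variant (exomes available for two affected and two unaffected
members, one affected founder-spouse deceased and untyped), a sporadic case
cohort with low-rate hotspot mutations in one protein region, a large
control exome cohort lacking deleterious variants in that region, and a
cross-species tissue FPKM matrix with a brain-maximal target gene.

Every generator is driven by one integer seed through named sub-streams,
and all file writers are deterministic, so identical spec + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Affection,
    AnnotationRecord,
    Call,
    ConfigError,
    Consequence,
    GenotypeCounts,
    GenotypeCountTable,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Predictor,
    RegionSet,
    Sex,
    VariantKey,
    VariantRecord,
    VariantSet,
)
from .expression import ExpressionMatrix
from . import io as fio

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# Sub-stream ids so generators stay independent under one global seed.
_STREAM_FAMILY = 1
_STREAM_COHORTS = 2
_STREAM_EXPRESSION = 3


@dataclass(frozen=True)
class CohortSpec:
    """Sporadic case / control cohort design.

    Defaults reproduce the study scale: 120 sporadic cases, 1136 control
    exomes, 205 Sanger-screened controls; three case-enriched hotspot
    variants each carried by ~1/120 cases and absent from controls.
    """

    n_cases: int = 120
    n_controls: int = 1136
    n_sanger_controls: int = 205
    n_hotspot_variants: int = 3
    n_region_background: int = 8
    hotspot_carrier_rate_cases: float = 1 / 120
    hotspot_carrier_rate_controls: float = 0.0


@dataclass(frozen=True)
class SimulationSpec:
    """Design of one synthetic dataset.

    ``n_background_variants`` approximates the coding-impact variant yield
    of a family exome study after consequence filtering; background
    population MAFs follow a Beta(0.3, 3) spectrum rescaled to (0, 0.5);
    ``fraction_in_databases`` is the fraction of background variants present
    in the public databases. The causal variant is a fully penetrant
    dominant heterozygous missense inside the designated linkage region.
    """

    seed: int = 1
    n_background_variants: int = 5000
    background_maf_beta: tuple[float, float] = (0.3, 3.0)
    fraction_in_databases: float = 0.95
    novel_absent_in_controls: float = 0.6
    causal_gene: str = "TENM4"
    causal_cdna: str = "c.6724C>T"
    causal_protein: str = "p.R2242C"
    chrom_lengths: dict = field(default_factory=lambda: {"1": 2_000_000,
                                                         "2": 2_000_000})
    linkage_region: tuple[str, int, int, str] = ("2", 1_000_000, 1_500_000,
                                                 "SCZD2-like")
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        for rate in (self.fraction_in_databases, self.novel_absent_in_controls,
                     self.cohort.hotspot_carrier_rate_cases,
                     self.cohort.hotspot_carrier_rate_controls):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"rate {rate} outside [0,1]")
        if self.n_background_variants < 0:
            raise ConfigError("n_background_variants must be >= 0")

    def regions(self) -> RegionSet:
        return RegionSet([self.linkage_region])


# ---------------------------------------------------------------------------
# Family

#: Three-generation family. Generation I was never examined (affection
#: unknown); the rare allele enters through founder I-2. II-2 is the
#: affected, deceased and therefore untyped daughter of generation I; II-1
#: her unaffected married-in spouse; their children are III-1 (unaffected)
#: and III-2/3/4 (affected). Exome/Sanger genotypes exist for II-1, III-1,
#: III-2, III-3 and III-4.
def fig1_pedigree() -> Pedigree:
    return Pedigree([
        Individual("I-1", None, None, Sex.MALE, Affection.UNKNOWN),
        Individual("I-2", None, None, Sex.FEMALE, Affection.UNKNOWN),
        Individual("II-1", None, None, Sex.MALE, Affection.UNAFFECTED,
                   genotyped=True),
        Individual("II-2", "I-1", "I-2", Sex.FEMALE, Affection.AFFECTED),
        Individual("III-1", "II-1", "II-2", Sex.FEMALE, Affection.UNAFFECTED,
                   genotyped=True),
        Individual("III-2", "II-1", "II-2", Sex.MALE, Affection.AFFECTED,
                   genotyped=True),
        Individual("III-3", "II-1", "II-2", Sex.MALE, Affection.AFFECTED,
                   genotyped=True),
        Individual("III-4", "II-1", "II-2", Sex.MALE, Affection.AFFECTED,
                   genotyped=True),
    ])


_CONSEQ_CLASSES = np.array([c.value for c in (
    Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.NONCODING,
    Consequence.SPLICE_SITE, Consequence.STOP_GAINED,
    Consequence.FRAMESHIFT_INDEL, Consequence.INFRAME_INDEL)])
_CONSEQ_PROBS = np.array([0.50, 0.33, 0.05, 0.03, 0.02, 0.04, 0.03])


@dataclass
class SimulatedFamily:
    spec: SimulationSpec
    pedigree: Pedigree
    variants: VariantSet
    genotypes: GenotypeMatrix          # typed individuals only
    truth_genotypes: GenotypeMatrix    # every pedigree member
    truth: pd.DataFrame
    causal_key: VariantKey

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "family.vcf",
            "ped": out / "family.ped",
            "ann": out / "annotations.tsv",
            "bed": out / "linkage.bed",
            "truth": out / "family_truth.tsv",
        }
        fio.write_vcf(paths["vcf"], self.variants, self.genotypes)
        fio.write_pedigree(paths["ped"], self.pedigree)
        fio.write_annotations(paths["ann"], simulate_annotations(self.truth))
        fio.write_regions(paths["bed"], self.spec.regions())
        self.truth.to_csv(paths["truth"], sep="\t", index=False,
                          float_format="%.8g")
        return paths


def _draw_predictors(rng: np.random.Generator, is_missense: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Background predictor calls; non-missense variants get no calls."""
    n = is_missense.size

    def one(p_del: float, del_label: str, neu_label: str) -> np.ndarray:
        u = rng.random(n)
        out = np.where(u < p_del, del_label,
                       np.where(u < p_del + 0.10, Predictor.MISSING.value,
                                neu_label))
        return np.where(is_missense, out, Predictor.MISSING.value)

    return (one(0.25, Predictor.DELETERIOUS.value, Predictor.NEUTRAL.value),
            one(0.30, Predictor.DAMAGING.value, Predictor.TOLERATED.value),
            one(0.30, Predictor.DAMAGING.value, Predictor.BENIGN.value))


def simulate_family(spec: SimulationSpec) -> SimulatedFamily:
    """Generate the family exome dataset with one planted causal variant."""
    rng = np.random.default_rng([_STREAM_FAMILY, spec.seed])
    ped = fig1_pedigree()
    n_bg = spec.n_background_variants
    chroms = list(spec.chrom_lengths)

    # --- variant sites ------------------------------------------------
    chrom_idx = rng.integers(0, len(chroms), size=n_bg)
    pos = np.array([rng.integers(1, spec.chrom_lengths[chroms[i]] + 1)
                    for i in chrom_idx]) if n_bg else np.array([], dtype=int)
    ref_i = rng.integers(0, 4, size=n_bg)
    alt_i = (ref_i + rng.integers(1, 4, size=n_bg)) % 4
    a, b = spec.background_maf_beta
    mafs = rng.beta(a, b, size=n_bg) * 0.5
    conseq = rng.choice(_CONSEQ_CLASSES, size=n_bg, p=_CONSEQ_PROBS)
    in_db = rng.random(n_bg) < spec.fraction_in_databases
    in_1000g = in_db & (rng.random(n_bg) < 0.8)
    in_esp = in_db & (rng.random(n_bg) < 0.7)
    in_exac = in_db & (rng.random(n_bg) < 0.7)
    # Novel variants may genuinely be absent from the in-house controls.
    absent_ctrl = (~in_db) & (rng.random(n_bg) < spec.novel_absent_in_controls)
    control_maf = np.where(absent_ctrl, 0.0, mafs)
    provean, sift, polyphen = _draw_predictors(
        rng, conseq == Consequence.MISSENSE.value)

    causal_chrom, lstart, lend, _ = spec.linkage_region
    causal_pos = int((lstart + lend) // 2)

    rows = []
    seen: set[VariantKey] = set()
    for i in range(n_bg):
        key = (chroms[chrom_idx[i]], int(pos[i]), str(_BASES[ref_i[i]]),
               str(_BASES[alt_i[i]]))
        if key in seen or (key[0] == causal_chrom and key[1] == causal_pos):
            continue
        seen.add(key)
        rows.append(dict(
            chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
            gene=f"G{i:05d}", cdna_change="", protein_change="",
            consequence=conseq[i], rsid=f"rs9{i:06d}" if in_db[i] else "",
            maf=float(mafs[i]), is_causal=False,
            in_dbsnp135=bool(in_db[i]), in_1000g=bool(in_1000g[i]),
            in_esp=bool(in_esp[i]), in_exac_nonpsych=bool(in_exac[i]),
            provean=provean[i], sift=sift[i], polyphen=polyphen[i],
            control_maf=float(control_maf[i]),
        ))
    rows.append(dict(
        chrom=causal_chrom, pos=causal_pos, ref="C", alt="T",
        gene=spec.causal_gene, cdna_change=spec.causal_cdna,
        protein_change=spec.causal_protein,
        consequence=Consequence.MISSENSE.value, rsid="",
        maf=0.0, is_causal=True,
        in_dbsnp135=False, in_1000g=False, in_esp=False,
        in_exac_nonpsych=False,
        provean=Predictor.DELETERIOUS.value, sift=Predictor.DAMAGING.value,
        polyphen=Predictor.DAMAGING.value, control_maf=0.0,
    ))
    truth = pd.DataFrame(rows).sort_values(["chrom", "pos", "ref", "alt"],
                                           ignore_index=True)
    regions = spec.regions()
    truth["in_linkage"] = [regions.contains(c, p)
                           for c, p in zip(truth.chrom, truth.pos)]

    variants = VariantSet(
        VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, gene=r.gene,
                      cdna_change=r.cdna_change, protein_change=r.protein_change,
                      consequence=Consequence(r.consequence), rsid=r.rsid)
        for r in truth.itertuples())
    keys = [v.key for v in variants]
    causal_key = next(v.key for v, r in zip(variants, truth.itertuples())
                      if r.is_causal)

    # --- gene dropping ------------------------------------------------
    n_var = len(keys)
    maf_vec = truth["maf"].to_numpy()
    dosage: dict[str, np.ndarray] = {}
    for founder in ("I-1", "I-2", "II-1"):
        dosage[founder] = rng.binomial(2, maf_vec)
    order = ["II-2", "III-1", "III-2", "III-3", "III-4"]
    for ind_id in order:
        ind = ped[ind_id]
        transmit_f = rng.random(n_var) < dosage[ind.father_id] / 2.0
        transmit_m = rng.random(n_var) < dosage[ind.mother_id] / 2.0
        dosage[ind_id] = transmit_f.astype(int) + transmit_m.astype(int)

    # Overwrite the causal site with the fully penetrant dominant pattern:
    # heterozygous in every affected member and in the transmitting founder
    # I-2, absent everywhere else.
    ci = keys.index(causal_key)
    for ind in ped:
        het = ind.affection is Affection.AFFECTED or ind.id == "I-2"
        dosage[ind.id][ci] = 1 if het else 0

    truth_gm = GenotypeMatrix()
    gm = GenotypeMatrix()
    typed = [ind.id for ind in ped if ind.genotyped]
    for ind in ped:
        d = dosage[ind.id]
        for j, key in enumerate(keys):
            truth_gm.set(ind.id, key, Call(int(d[j])))
    for ind_id in typed:
        d = dosage[ind_id]
        for j, key in enumerate(keys):
            gm.set(ind_id, key, Call(int(d[j])))

    logger.info("simulated family dataset: %d variants, causal %s",
                len(variants), causal_key)
    return SimulatedFamily(spec=spec, pedigree=ped, variants=variants,
                           genotypes=gm, truth_genotypes=truth_gm,
                           truth=truth, causal_key=causal_key)


def simulate_annotations(truth: pd.DataFrame) -> dict[VariantKey, AnnotationRecord]:
    """Materialize the annotation table recorded in a truth table."""
    ann: dict[VariantKey, AnnotationRecord] = {}
    for r in truth.itertuples():
        key = (r.chrom, int(r.pos), r.ref, r.alt)
        ann[key] = AnnotationRecord(
            variant_key=key,
            in_dbsnp135=bool(r.in_dbsnp135), in_1000g=bool(r.in_1000g),
            in_esp=bool(r.in_esp), in_exac_nonpsych=bool(r.in_exac_nonpsych),
            provean=Predictor(r.provean), sift=Predictor(r.sift),
            polyphen=Predictor(r.polyphen),
            control_maf=float(r.control_maf),
        )
    return ann


# ---------------------------------------------------------------------------
# Sporadic cohorts

@dataclass
class SimulatedCohorts:
    spec: SimulationSpec
    cases: GenotypeCountTable
    controls: GenotypeCountTable
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"cases": out / "case_counts.tsv",
                 "controls": out / "control_counts.tsv",
                 "truth": out / "cohort_truth.tsv"}
        fio.write_counts(paths["cases"], self.cases)
        fio.write_counts(paths["controls"], self.controls)
        self.truth.to_csv(paths["truth"], sep="\t", index=False,
                          float_format="%.8g")
        return paths


def _hwe_counts(rng: np.random.Generator, n: int, q: float) -> GenotypeCounts:
    """Multinomial genotype counts under Hardy-Weinberg with allele freq q."""
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
    mm, het, hom = rng.multinomial(n, probs)
    return GenotypeCounts(int(mm), int(het), int(hom))


def simulate_cohorts(spec: SimulationSpec) -> SimulatedCohorts:
    """Generate Table-3-style genotype count tables for cases and controls.

    Hotspot (YD-region) deleterious missense variants are seeded into cases
    at ``hotspot_carrier_rate_cases`` per variant and into controls at
    ``hotspot_carrier_rate_controls``; background variants in the same exons
    draw genotype counts from Hardy-Weinberg at their population MAF in
    every cohort. Counts always sum to the cohort sizes.
    """
    rng = np.random.default_rng([_STREAM_COHORTS, spec.seed])
    c = spec.cohort
    cases = GenotypeCountTable()
    controls = GenotypeCountTable()
    rows = []

    # Residue positions inside / outside the YD block of the bundled
    # synthetic architecture (1850..2450 of 2769).
    hotspot_residues = rng.integers(1860, 2440, size=c.n_hotspot_variants)
    for i, residue in enumerate(hotspot_residues):
        name = f"p.Y{int(residue)}C"
        case_carriers = int(rng.binomial(c.n_cases,
                                         c.hotspot_carrier_rate_cases))
        ctrl_carriers = int(rng.binomial(c.n_controls,
                                         c.hotspot_carrier_rate_controls))
        sanger_carriers = int(rng.binomial(c.n_sanger_controls,
                                           c.hotspot_carrier_rate_controls))
        cases.set(name, "SCZ",
                  GenotypeCounts(c.n_cases - case_carriers, case_carriers, 0))
        controls.set(name, "Con_Sanger",
                     GenotypeCounts(c.n_sanger_controls - sanger_carriers,
                                    sanger_carriers, 0))
        controls.set(name, "CON_exome",
                     GenotypeCounts(c.n_controls - ctrl_carriers,
                                    ctrl_carriers, 0))
        rows.append(dict(variant=name, protein_change=name, hotspot=True,
                         residue=int(residue),
                         consequence=Consequence.MISSENSE.value,
                         maf=float("nan"), case_carriers=case_carriers,
                         control_carriers=ctrl_carriers + sanger_carriers))

    a, b = spec.background_maf_beta
    for i in range(c.n_region_background):
        residue = int(rng.integers(1800, 2500))
        name = f"p.S{residue}S"
        q = float(rng.beta(a, b) * 0.5)
        case_counts = _hwe_counts(rng, c.n_cases, q)
        exome_counts = _hwe_counts(rng, c.n_controls, q)
        sanger_na = rng.random() < 0.3  # some variants never Sanger-screened
        sanger_counts = None if sanger_na else _hwe_counts(
            rng, c.n_sanger_controls, q)
        cases.set(name, "SCZ", case_counts)
        controls.set(name, "Con_Sanger", sanger_counts)
        controls.set(name, "CON_exome", exome_counts)
        rows.append(dict(variant=name, protein_change=name, hotspot=False,
                         residue=residue,
                         consequence=Consequence.SYNONYMOUS.value, maf=q,
                         case_carriers=case_counts.n_Mm + case_counts.n_mm,
                         control_carriers=exome_counts.n_Mm + exome_counts.n_mm
                         + (0 if sanger_counts is None
                            else sanger_counts.n_Mm + sanger_counts.n_mm)))

    truth = pd.DataFrame(rows)
    logger.info("simulated cohorts: %d hotspot + %d background variants",
                c.n_hotspot_variants, c.n_region_background)
    return SimulatedCohorts(spec=spec, cases=cases, controls=controls,
                            truth=truth)


# ---------------------------------------------------------------------------
# Expression

DEFAULT_SPECIES = ("human", "macaque", "mouse", "opossum")
DEFAULT_TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")


def simulate_expression(seed: int, brain_factor: float = 4.0,
                        gene: str = "TENM4",
                        species: tuple[str, ...] = DEFAULT_SPECIES,
                        tissues: tuple[str, ...] = DEFAULT_TISSUES,
                        n_background_genes: int = 3) -> ExpressionMatrix:
    """FPKM matrix whose target gene is brain-maximal in every species.

    The target gene's brain FPKM is exactly ``brain_factor`` times the
    maximum over the other tissues in each species; background genes have
    unconstrained lognormal profiles.
    """
    if brain_factor <= 1.0:
        raise ConfigError(f"brain_factor must be > 1, got {brain_factor}")
    if "brain" not in tissues:
        raise ConfigError("tissue panel must include 'brain'")
    rng = np.random.default_rng([_STREAM_EXPRESSION, seed])
    rows = []
    for sp in species:
        other = {t: float(rng.lognormal(np.log(5.0), 0.6))
                 for t in tissues if t != "brain"}
        brain = brain_factor * max(other.values())
        for t in tissues:
            rows.append(dict(gene=gene, species=sp, tissue=t,
                             fpkm=brain if t == "brain" else other[t]))
        for g in range(n_background_genes):
            for t in tissues:
                rows.append(dict(gene=f"BG{g}", species=sp, tissue=t,
                                 fpkm=float(rng.lognormal(np.log(3.0), 0.8))))
    return ExpressionMatrix(pd.DataFrame(rows))


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of a spec with a different seed."""
    return replace(spec, seed=seed)
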