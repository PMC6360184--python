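"""Protein-domain mapping and region-restricted rare-variant burden testing.

Missense/stop positions parsed from HGVS p. strings are mapped onto a
protein domain architecture (teneurin-style: N-terminal domain, EGF-like
repeats, NHL repeats, YD repeats, transmembrane segment). The burden test
compares carriers of qualifying variants — rare, predictor-consensus
deleterious, falling in the requested region class — between cases and
controls with a two-sided Fisher exact test on the carrier table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .association import ContingencyTable2x2, fisher_exact_two_sided
from .cascade import predictor_consensus
from .core import (
    AnnotationTable,
    Consequence,
    CoordinateError,
    HgvsParseError,
    ValidationError,
    VariantSet,
)

logger = logging.getLogger(__name__)

REGION_CLASSES = ("N_terminal", "EGF_like", "NHL", "YD_repeat",
                  "transmembrane", "other")

INTER_DOMAIN = "other/inter-domain"


@dataclass(frozen=True)
class DomainRegion:
    name: str
    region_class: str
    aa_start: int  # 1-based inclusive
    aa_end: int


@dataclass
class DomainArchitecture:
    protein_id: str
    length: int
    regions: list[DomainRegion]

    def __post_init__(self) -> None:
        for r in self.regions:
            if not (1 <= r.aa_start <= r.aa_end <= self.length):
                raise ValidationError(
                    f"region {r.name} [{r.aa_start},{r.aa_end}] outside "
                    f"protein of length {self.length}"
                )
            if r.region_class not in REGION_CLASSES:
                raise ValidationError(f"unknown region class {r.region_class!r}")


# Matches p.R2242C, p.Q2735X, p.Arg2242Cys, p.K1922K ...
_HGVS_P = re.compile(
    r"^p\.\(?([A-Z][a-z]{2}|[A-Z\*])(\d+)([A-Z][a-z]{2}|[A-Z\*]|=|del|dup|fs.*)?\)?$"
)


def parse_protein_position(protein_change: str) -> int:
    """Residue index from an HGVS p. string (e.g. ``p.R2242C`` -> 2242)."""
    m = _HGVS_P.match(protein_change.strip())
    if not m:
        raise HgvsParseError(f"cannot parse protein change {protein_change!r}")
    return int(m.group(2))


def map_protein_position(protein_change: str,
                         arch: DomainArchitecture) -> tuple[str, str]:
    """``(region_class, region_name)`` containing the residue of a p. string.

    Residues outside every annotated region map to ``("other",
    "other/inter-domain")``; residues beyond the protein length raise
    :class:`CoordinateError`.
    """
    residue = parse_protein_position(protein_change)
    if residue > arch.length:
        raise CoordinateError(
            f"residue {residue} beyond {arch.protein_id} length {arch.length}"
        )
    for region in arch.regions:
        if region.aa_start <= residue <= region.aa_end:
            return region.region_class, region.name
    return "other", INTER_DOMAIN


@dataclass
class QualifyingRules:
    """Which variants count toward the burden.

    Defaults: protein-altering consequences, deleterious consensus from all
    three predictors, and absence from the public databases (novelty).
    """

    consequences: frozenset = frozenset({Consequence.MISSENSE,
                                         Consequence.STOP_GAINED,
                                         Consequence.SPLICE_SITE,
                                         Consequence.FRAMESHIFT_INDEL,
                                         Consequence.INFRAME_INDEL})
    predictor_rule: str = "all_three"
    require_novel: bool = True
    max_control_maf: float | None = None


def qualifying_variants(variants: VariantSet, ann: AnnotationTable,
                        arch: DomainArchitecture, region_class: str,
                        rules: QualifyingRules | None = None) -> VariantSet:
    """Variants passing the qualifying rules that map to ``region_class``."""
    rules = rules or QualifyingRules()
    if region_class not in REGION_CLASSES:
        raise ValidationError(f"unknown region class {region_class!r}")
    pool = VariantSet(v for v in variants
                      if v.consequence in rules.consequences and v.protein_change)
    _, consensus = predictor_consensus(pool, ann, rules.predictor_rule)
    kept = []
    for v in consensus:
        rec = ann.get(v.key)
        if rules.require_novel and rec is not None and (
                rec.in_dbsnp135 or rec.in_1000g or rec.in_esp
                or rec.in_exac_nonpsych):
            continue
        if (rules.max_control_maf is not None and rec is not None
                and rec.control_maf is not None
                and rec.control_maf > rules.max_control_maf):
            continue
        cls, _name = map_protein_position(v.protein_change, arch)
        if cls == region_class:
            kept.append(v)
    logger.info("%d of %d variants qualify in region class %s",
                len(kept), len(variants), region_class)
    return VariantSet(kept)


@dataclass(frozen=True)
class BurdenInput:
    """Carrier counts: individuals bearing >=1 qualifying variant in a region."""

    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int

    def __post_init__(self) -> None:
        if not (0 <= self.case_carriers <= self.case_n):
            raise ValidationError("case carriers exceed case sample size")
        if not (0 <= self.control_carriers <= self.control_n):
            raise ValidationError("control carriers exceed control sample size")


def burden_test(b: BurdenInput) -> float:
    """Two-sided Fisher exact p-value on the carrier 2x2 table."""
    table = ContingencyTable2x2(
        b.case_carriers, b.case_n - b.case_carriers,
        b.control_carriers, b.control_n - b.control_carriers,
    )
    return fisher_exact_two_sided(table)


# ---------------------------------------------------------------------------
# Architecture I/O

def read_domains(path) -> DomainArchitecture:
    """Read a domain architecture TSV.

    Columns: protein_id, protein_length, region_name, class, aa_start,
    aa_end (one row per region; protein_id/length repeated).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "protein_length", "region_name", "class",
                "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    if df["protein_id"].nunique() != 1:
        raise ValidationError(f"{path}: expected exactly one protein")
    regions = [DomainRegion(r.region_name, r["class"], int(r.aa_start),
                            int(r.aa_end)) for _, r in df.iterrows()]
    arch = DomainArchitecture(protein_id=df["protein_id"].iloc[0],
                              length=int(df["protein_length"].iloc[0]),
                              regions=regions)
    logger.info("read architecture of %s (%d aa, %d regions)",
                arch.protein_id, arch.length, len(arch.regions))
    return arch


def tenm4_architecture() -> DomainArchitecture:
    """The bundled synthetic TENM4 domain architecture.

    TENM4's published residue coordinates per domain are not tabulated in
    the sources this package follows, so the bundled TSV is a synthetic
    stand-in: a 2769-residue protein whose region boundaries are chosen to
    reproduce the published qualitative assignments (R325 in the teneurin
    N-terminus; E1098 between the EGF-like and NHL repeats; I1913, R2242
    and D2294 inside the YD-repeat block; Q2735 C-terminal of it). Replace
    the TSV with curated coordinates for real analyses.
    """
    ref = resources.files("famvar.data") / "tenm4_domains.synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_domains(path)
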