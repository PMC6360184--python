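"""Domain types shared across the pipeline.

The central objects are deliberately small and format-agnostic: a coding
variant keyed by ``(chrom, pos, ref, alt)``, a sample-by-variant genotype
matrix over a four-state call enum, a pedigree with parent links and
affection status, a per-variant annotation record (database membership,
in-silico predictor calls, control-cohort allele frequency), per-cohort
genotype count triplets, and a set of labelled genomic intervals.

Coordinate conventions: VCF positions are 1-based; interval sets (BED) are
0-based half-open. Conversion happens only inside :meth:`RegionSet.contains`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
from intervaltree import IntervalTree

__all__ = [
    "FamvarError",
    "VcfParseError",
    "UnsupportedInputError",
    "PedigreeStructureError",
    "ReferentialError",
    "ValidationError",
    "ConfigError",
    "MendelianInconsistencyError",
    "NoControlDataError",
    "UndefinedFrequencyError",
    "UndefinedTestError",
    "CoordinateError",
    "HgvsParseError",
    "GeneLookupError",
    "Consequence",
    "Call",
    "Sex",
    "Affection",
    "VariantKey",
    "VariantRecord",
    "GenotypeMatrix",
    "Individual",
    "Pedigree",
    "AnnotationRecord",
    "GenotypeCountTable",
    "RegionSet",
]


# ---------------------------------------------------------------------------
# Errors

class FamvarError(Exception):
    """Base class for all errors raised by this package."""


class VcfParseError(FamvarError):
    pass


class UnsupportedInputError(FamvarError):
    pass


class PedigreeStructureError(FamvarError):
    pass


class ReferentialError(FamvarError):
    pass


class ValidationError(FamvarError):
    pass


class ConfigError(FamvarError):
    pass


class MendelianInconsistencyError(FamvarError):
    pass


class NoControlDataError(FamvarError):
    pass


class UndefinedFrequencyError(FamvarError):
    pass


class UndefinedTestError(FamvarError):
    pass


class CoordinateError(FamvarError):
    pass


class HgvsParseError(FamvarError):
    pass


class GeneLookupError(FamvarError):
    pass


# ---------------------------------------------------------------------------
# Enums

class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_SITE = "splice_site"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    NONCODING = "noncoding"


#: Consequence classes retained by the coding-impact filter: nonsynonymous
#: SNVs, splice-site variants and coding indels.
CODING_IMPACT = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.SPLICE_SITE,
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.INFRAME_INDEL,
    }
)


class Call(enum.IntEnum):
    """Diploid genotype call collapsed to allele dosage (phase discarded)."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1

    @property
    def carries_alt(self) -> bool:
        return self in (Call.HET, Call.HOM_ALT)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Variants

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One coding variant (one ALT allele; multi-allelic sites are split).

    ``cdna_change``/``protein_change`` are HGVS annotation strings
    (e.g. ``c.6724C>T`` / ``p.R2242C``); they are never used as identity —
    the key is ``(chrom, pos, ref, alt)``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    consequence: Consequence = Consequence.MISSENSE
    rsid: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles are identical: {self.ref}")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """Ordered, key-unique collection of :class:`VariantRecord`."""

    def __init__(self, records: Iterable[VariantRecord] = ()) -> None:
        self._by_key: dict[VariantKey, VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        if rec.key in self._by_key:
            raise ValidationError(f"duplicate variant key {rec.key}")
        self._by_key[rec.key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._by_key.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def __getitem__(self, key: VariantKey) -> VariantRecord:
        return self._by_key[key]

    def keys(self) -> list[VariantKey]:
        return list(self._by_key)

    def subset(self, keys: Iterable[VariantKey]) -> "VariantSet":
        wanted = set(keys)
        return VariantSet(r for r in self if r.key in wanted)


# ---------------------------------------------------------------------------
# Genotypes

class GenotypeMatrix:
    """Mapping ``(sample_id, variant_key) -> Call``.

    Samples and variants keep insertion order so writers are deterministic.
    """

    def __init__(self) -> None:
        self._calls: dict[tuple[str, VariantKey], Call] = {}
        self._samples: dict[str, None] = {}
        self._variants: dict[VariantKey, None] = {}

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    @property
    def variant_keys(self) -> list[VariantKey]:
        return list(self._variants)

    def set(self, sample: str, key: VariantKey, call: Call) -> None:
        self._samples.setdefault(sample, None)
        self._variants.setdefault(key, None)
        self._calls[(sample, key)] = Call(call)

    def call(self, sample: str, key: VariantKey) -> Call:
        return self._calls.get((sample, key), Call.MISSING)

    def has_sample(self, sample: str) -> bool:
        return sample in self._samples

    def __len__(self) -> int:
        return len(self._calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self._samples.keys() == other._samples.keys()
            and self._variants.keys() == other._variants.keys()
            and self._calls == other._calls
        )


# ---------------------------------------------------------------------------
# Pedigree

@dataclass
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A family: individuals with parent links, affection and typed flags.

    Invariants enforced at construction: parent ids refer to existing
    individuals; an individual has either both parents or neither; the
    parent relation is acyclic.
    """

    def __init__(self, individuals: Iterable[Individual]) -> None:
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeStructureError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for ind in self._members.values():
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeStructureError(
                    f"{ind.id!r} has exactly one parent recorded; need both or neither"
                )
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise ReferentialError(
                        f"{ind.id!r} references unknown parent {pid!r}"
                    )
                g.add_edge(ind.id, pid)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeStructureError("parent relation contains a cycle")

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._members[ind_id]
        except KeyError:
            raise ReferentialError(f"no individual {ind_id!r} in pedigree") from None

    def ids(self) -> list[str]:
        return list(self._members)

    def children_of(self, ind_id: str) -> list[Individual]:
        return [
            m for m in self._members.values()
            if ind_id in (m.father_id, m.mother_id)
        ]

    def co_parent(self, child: Individual, parent_id: str) -> str | None:
        """The other parent of ``child`` relative to ``parent_id``."""
        if child.father_id == parent_id:
            return child.mother_id
        if child.mother_id == parent_id:
            return child.father_id
        raise ReferentialError(f"{parent_id!r} is not a parent of {child.id!r}")

    def affected(self) -> list[Individual]:
        return [m for m in self if m.affection is Affection.AFFECTED]

    def unaffected(self) -> list[Individual]:
        return [m for m in self if m.affection is Affection.UNAFFECTED]

    def founders(self) -> list[Individual]:
        return [m for m in self if m.is_founder]


# ---------------------------------------------------------------------------
# Annotations

class Predictor(str, enum.Enum):
    DELETERIOUS = "deleterious"  # PROVEAN's damaging label
    DAMAGING = "damaging"        # SIFT / PolyPhen-2 damaging label
    NEUTRAL = "neutral"
    TOLERATED = "tolerated"
    BENIGN = "benign"
    MISSING = "missing"

    @property
    def is_deleterious(self) -> bool:
        return self in (Predictor.DELETERIOUS, Predictor.DAMAGING)


@dataclass(frozen=True)
class AnnotationRecord:
    """Database membership, predictor calls and control MAF for one variant."""

    variant_key: VariantKey
    in_dbsnp135: bool = False
    in_1000g: bool = False
    in_esp: bool = False
    in_exac_nonpsych: bool = False
    provean: Predictor = Predictor.MISSING
    sift: Predictor = Predictor.MISSING
    polyphen: Predictor = Predictor.MISSING
    control_maf: float | None = None

    def __post_init__(self) -> None:
        if self.control_maf is not None and not (0.0 <= self.control_maf <= 1.0):
            raise ValidationError(
                f"control_maf must be in [0,1], got {self.control_maf}"
            )


AnnotationTable = Mapping[VariantKey, AnnotationRecord]


# ---------------------------------------------------------------------------
# Genotype count tables

@dataclass(frozen=True)
class GenotypeCounts:
    """(n_MM, n_Mm, n_mm): major-homozygote, heterozygote, minor-homozygote."""

    n_MM: int
    n_Mm: int
    n_mm: int

    def __post_init__(self) -> None:
        for n in (self.n_MM, self.n_Mm, self.n_mm):
            if not isinstance(n, int) or n < 0:
                raise ValidationError(f"genotype counts must be non-negative ints: {self}")

    @property
    def total(self) -> int:
        return self.n_MM + self.n_Mm + self.n_mm

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_MM + other.n_MM, self.n_Mm + other.n_Mm, self.n_mm + other.n_mm
        )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_MM, self.n_Mm, self.n_mm)


class GenotypeCountTable:
    """Per (variant, cohort) genotype count triplets; cohorts may be absent (NA)."""

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], GenotypeCounts | None] = {}
        self._variants: dict[str, None] = {}
        self._cohorts: dict[str, None] = {}

    def set(self, variant: str, cohort: str, counts: GenotypeCounts | None) -> None:
        self._variants.setdefault(variant, None)
        self._cohorts.setdefault(cohort, None)
        self._data[(variant, cohort)] = counts

    def get(self, variant: str, cohort: str) -> GenotypeCounts | None:
        return self._data.get((variant, cohort))

    @property
    def variants(self) -> list[str]:
        return list(self._variants)

    @property
    def cohorts(self) -> list[str]:
        return list(self._cohorts)


# ---------------------------------------------------------------------------
# Regions

@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open, sorted per chromosome."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"empty/inverted interval {chrom}:{start}-{end}"
                )
        self.intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True if a 1-based genomic position falls in any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos_1based - 1))

    def labels_at(self, chrom: str, pos_1based: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos_1based - 1])

    def __len__(self) -> int:
        return len(self.intervals)
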