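"""Step-wise variant prioritization cascade under a dominant family model.

The cascade mirrors the classic family-exome discovery recipe: keep coding
impact variants (nonsynonymous SNVs, splice-site variants, coding indels);
remove anything present in the public databases (dbSNP 135, 1000 Genomes,
NHLBI ESP, non-psychiatric ExAC); keep heterozygous variants shared by the
affected and absent from the unaffected; keep variants rare or absent in
in-house control exomes; require deleterious consensus across PROVEAN, SIFT
and PolyPhen-2; and finally intersect with previously reported linkage
regions. Every stage records per-column counts and an audit trail naming
the stage that removed each variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    CODING_IMPACT,
    AnnotationTable,
    AnnotationRecord,
    Call,
    ConfigError,
    GenotypeMatrix,
    Pedigree,
    Predictor,
    ReferentialError,
    RegionSet,
    VariantKey,
    VariantSet,
)

logger = logging.getLogger(__name__)

DB_STAGE_FLAGS: dict[str, tuple[str, ...]] = {
    "dbsnp": ("in_dbsnp135",),
    "dbsnp_1000g": ("in_dbsnp135", "in_1000g"),
    "dbsnp_1000g_esp": ("in_dbsnp135", "in_1000g", "in_esp"),
    "plus_exac": ("in_dbsnp135", "in_1000g", "in_esp", "in_exac_nonpsych"),
}


@dataclass
class CascadeConfig:
    """Tunable knobs of the cascade.

    ``maf_threshold`` is the in-house control-exome frequency cut (default
    1%, compared inclusively — set ``maf_inclusive`` False for a strict
    ``<``). Under ``predictor_rule = "all_three"`` a variant needs a
    deleterious/damaging call from every predictor, with no missing call.
    """

    inheritance_model: str = "dominant"
    maf_threshold: float = 0.01
    maf_inclusive: bool = True
    require_absent_in_controls: bool = True
    predictor_rule: str = "all_three"
    missing_genotype_compatible: bool = False
    include_exac: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ConfigError(f"maf_threshold must be in (0,1], got {self.maf_threshold}")
        if self.inheritance_model != "dominant":
            raise ConfigError(
                f"inheritance model {self.inheritance_model!r} not implemented"
            )
        if self.predictor_rule not in ("all_three", "any", "majority"):
            raise ConfigError(f"unknown predictor_rule {self.predictor_rule!r}")


@dataclass
class StageResult:
    name: str
    survivors: set[VariantKey]
    removed: set[VariantKey]
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CascadeResult:
    stages: list[StageResult]
    audit: dict[VariantKey, str]  # variant -> "survived" or removing stage
    survivors: set[VariantKey]
    predictor_sets: dict[str, set[VariantKey]] = field(default_factory=dict)

    def stage_counts(self) -> pd.DataFrame:
        """Stage-by-column count table (rows follow cascade order)."""
        rows = [dict(stage=s.name, **s.counts) for s in self.stages]
        return pd.DataFrame(rows).set_index("stage")

    def assert_monotone(self) -> None:
        df = self.stage_counts()
        for col in df.columns:
            vals = df[col].to_numpy()
            if not (vals[1:] <= vals[:-1]).all():
                raise AssertionError(f"counts increase down stages in column {col!r}")


def _annotation_for(ann: AnnotationTable, key: VariantKey) -> AnnotationRecord:
    rec = ann.get(key)
    if rec is None:
        logger.warning("no annotation record for %s; treated as novel", key)
        rec = AnnotationRecord(variant_key=key)
    return rec


# ---------------------------------------------------------------------------
# Individual filters

def consequence_filter(variants: VariantSet) -> VariantSet:
    """Keep nonsynonymous SNVs, splice-site variants and coding indels."""
    return VariantSet(v for v in variants if v.consequence in CODING_IMPACT)


def database_filter(variants: VariantSet, ann: AnnotationTable,
                    stage: str) -> VariantSet:
    """Keep variants absent from every database of the requested stage."""
    try:
        flags = DB_STAGE_FLAGS[stage]
    except KeyError:
        raise ConfigError(f"unknown database stage {stage!r}") from None
    kept = []
    for v in variants:
        rec = _annotation_for(ann, v.key)
        if not any(getattr(rec, f) for f in flags):
            kept.append(v)
    return VariantSet(kept)


def segregation_filter(variants: VariantSet, gm: GenotypeMatrix, ped: Pedigree,
                       affected_ids: list[str], unaffected_ids: list[str],
                       cfg: CascadeConfig | None = None) -> VariantSet:
    """Dominant-model cosegregation filter.

    Keeps variants heterozygous in every listed affected individual and
    homozygous-reference in every listed unaffected individual. A missing
    call removes the variant unless ``cfg.missing_genotype_compatible``.
    """
    cfg = cfg or CascadeConfig()
    for ind_id in list(affected_ids) + list(unaffected_ids):
        if ind_id not in ped:
            raise ReferentialError(f"individual {ind_id!r} not in pedigree")
    kept = []
    for v in variants:
        ok = True
        for ind_id in affected_ids:
            call = gm.call(ind_id, v.key)
            if call is Call.MISSING:
                ok = ok and cfg.missing_genotype_compatible
            elif call is not Call.HET:
                ok = False
        for ind_id in unaffected_ids:
            call = gm.call(ind_id, v.key)
            if call is Call.MISSING:
                ok = ok and cfg.missing_genotype_compatible
            elif call is not Call.HOM_REF:
                ok = False
        if ok:
            kept.append(v)
    return VariantSet(kept)


def control_maf_filter(variants: VariantSet, ann: AnnotationTable,
                       threshold: float, *, inclusive: bool = True
                       ) -> tuple[VariantSet, VariantSet]:
    """Split by in-house control frequency.

    Returns ``(pass_set, absent_set)``: variants at or under the threshold,
    and the subset never seen in controls (MAF 0 or missing).
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"MAF threshold must be in (0,1], got {threshold}")
    passed, absent = [], []
    for v in variants:
        rec = _annotation_for(ann, v.key)
        m = rec.control_maf
        if m is None or m == 0.0:
            passed.append(v)
            absent.append(v)
        elif (m <= threshold) if inclusive else (m < threshold):
            passed.append(v)
    return VariantSet(passed), VariantSet(absent)


def predictor_consensus(variants: VariantSet, ann: AnnotationTable,
                        rule: str = "all_three"
                        ) -> tuple[dict[str, set[VariantKey]], VariantSet]:
    """Per-predictor deleterious sets and the consensus set under ``rule``.

    ``all_three``: deleterious by every predictor with no call missing;
    ``any``: deleterious by at least one; ``majority``: by at least two.
    """
    per: dict[str, set[VariantKey]] = {"provean": set(), "sift": set(), "polyphen": set()}
    consensus = []
    for v in variants:
        rec = _annotation_for(ann, v.key)
        calls = {"provean": rec.provean, "sift": rec.sift, "polyphen": rec.polyphen}
        for name, call in calls.items():
            if call.is_deleterious:
                per[name].add(v.key)
        n_del = sum(c.is_deleterious for c in calls.values())
        n_missing = sum(c is Predictor.MISSING for c in calls.values())
        if rule == "all_three":
            hit = n_del == 3 and n_missing == 0
        elif rule == "any":
            hit = n_del >= 1
        else:  # majority
            hit = n_del >= 2
        if hit:
            consensus.append(v)
    return per, VariantSet(consensus)


def intersect_linkage(variants: VariantSet, regions: RegionSet) -> VariantSet:
    """Keep variants whose position falls inside a linkage region."""
    return VariantSet(v for v in variants if regions.contains(v.chrom, v.pos))


# ---------------------------------------------------------------------------
# Full cascade

def _column_counts(variants: VariantSet, gm: GenotypeMatrix,
                   ann: AnnotationTable, affected_ids: list[str],
                   threshold: float, inclusive: bool) -> dict[str, int]:
    """Table-style per-column counts for one stage's surviving set.

    Columns: variants carried by each affected exome individually, shared by
    all affected, heterozygous-shared with control MAF under the threshold,
    and heterozygous-shared never seen in controls.
    """
    counts: dict[str, int] = {"variants": len(variants)}
    per_carrier = {a: 0 for a in affected_ids}
    shared = het_maf = het_absent = 0
    for v in variants:
        calls = {a: gm.call(a, v.key) for a in affected_ids}
        for a, c in calls.items():
            if c.carries_alt:
                per_carrier[a] += 1
        if all(c.carries_alt for c in calls.values()):
            shared += 1
            if all(c is Call.HET for c in calls.values()):
                rec = _annotation_for(ann, v.key)
                m = rec.control_maf
                if m is None or m == 0.0:
                    het_maf += 1
                    het_absent += 1
                elif (m <= threshold) if inclusive else (m < threshold):
                    het_maf += 1
    for a in affected_ids:
        counts[f"carried_{a}"] = per_carrier[a]
    counts["shared_affected"] = shared
    counts["het_shared_maf_pass"] = het_maf
    counts["het_shared_absent_controls"] = het_absent
    return counts


def run_cascade(variants: VariantSet, gm: GenotypeMatrix, ped: Pedigree,
                ann: AnnotationTable, regions: RegionSet,
                cfg: CascadeConfig, affected_ids: list[str],
                unaffected_ids: list[str]) -> CascadeResult:
    """Run the full prioritization cascade and record the audit trail.

    Stage order is fixed: consequence, the nested database filters,
    dominant segregation, control MAF, predictor consensus, linkage-region
    intersection.
    """
    audit: dict[VariantKey, str] = {}
    stages: list[StageResult] = []
    current = variants

    def _advance(name: str, surviving: VariantSet) -> VariantSet:
        nonlocal current
        removed = {v.key for v in current} - {v.key for v in surviving}
        for key in removed:
            audit[key] = name
        stages.append(StageResult(
            name=name,
            survivors={v.key for v in surviving},
            removed=removed,
            counts=_column_counts(surviving, gm, ann, affected_ids,
                                  cfg.maf_threshold, cfg.maf_inclusive),
        ))
        current = surviving
        return surviving

    _advance("consequence", consequence_filter(current))
    db_stages = ["dbsnp", "dbsnp_1000g", "dbsnp_1000g_esp"]
    if cfg.include_exac:
        db_stages.append("plus_exac")
    for stage in db_stages:
        _advance(f"not_in_{stage}", database_filter(current, ann, stage))
    _advance("segregation",
             segregation_filter(current, gm, ped, affected_ids, unaffected_ids, cfg))
    pass_set, absent_set = control_maf_filter(
        current, ann, cfg.maf_threshold, inclusive=cfg.maf_inclusive)
    _advance("control_maf", absent_set if cfg.require_absent_in_controls else pass_set)
    per_pred, consensus = predictor_consensus(current, ann, cfg.predictor_rule)
    _advance("predictor_consensus", consensus)
    final = _advance("linkage", intersect_linkage(current, regions))

    survivors = {v.key for v in final}
    for key in survivors:
        audit[key] = "survived"
    logger.info("cascade: %d input variants -> %d prioritized candidates",
                len(variants), len(survivors))
    return CascadeResult(stages=stages, audit=audit, survivors=survivors,
                         predictor_sets=per_pred)
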