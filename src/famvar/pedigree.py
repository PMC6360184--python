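"""Genotype inference for untyped relatives and the cosegregation verdict.

The inference implements the classic deduction used when a deceased founder
cannot be sampled: under a rare allele with no de novo events, a
heterozygous child whose typed co-parent is homozygous reference must have
received the alternate allele from the untyped parent, who is therefore an
obligate heterozygote. Conversely, if every child is typed homozygous
reference (and the spouse is typed), the allele was never transmitted and
the untyped parent is called a non-carrier under this deterministic
convention. Anything in between is indeterminate.

Cosegregation is judged under full-penetrance dominant semantics: the
variant tracks with disease iff every affected individual is heterozygous
(typed or inferred) and every typed unaffected individual is homozygous
reference.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .core import (
    Affection,
    Call,
    GenotypeMatrix,
    MendelianInconsistencyError,
    Pedigree,
    ValidationError,
    VariantKey,
)

logger = logging.getLogger(__name__)


class InferredState(str, enum.Enum):
    INFERRED_HET = "inferred_het"
    INFERRED_NONCARRIER = "inferred_noncarrier"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class InferredGenotype:
    individual_id: str
    variant_key: VariantKey
    state: InferredState
    #: (relative_id, observed call) pairs justifying the inference.
    basis: tuple[tuple[str, Call], ...] = ()

    def __post_init__(self) -> None:
        if self.state is not InferredState.INDETERMINATE and not self.basis:
            raise ValidationError("non-indeterminate inference requires a basis")


def validate_mendelian(ped: Pedigree, gm: GenotypeMatrix,
                       variant_key: VariantKey) -> None:
    """Raise if any typed trio is inconsistent under the no-de-novo model."""
    for child in ped:
        if child.is_founder:
            continue
        child_call = gm.call(child.id, variant_key)
        father_call = gm.call(child.father_id, variant_key)
        mother_call = gm.call(child.mother_id, variant_key)
        if (child_call.carries_alt
                and father_call is Call.HOM_REF and mother_call is Call.HOM_REF):
            raise MendelianInconsistencyError(
                f"{child.id!r} carries the alternate allele at {variant_key} "
                "but both parents are typed homozygous reference "
                "(de novo events are not modeled)"
            )


def infer_founder_genotype(ped: Pedigree, gm: GenotypeMatrix,
                           variant_key: VariantKey,
                           target_id: str) -> InferredGenotype:
    """Infer an untyped individual's genotype from spouse and children.

    Assumes the rare allele enters each nuclear family through at most one
    parent and that no de novo mutation occurred; a child carrying the
    allele while the typed co-parent is homozygous reference makes the
    target an obligate heterozygote. Raises
    :class:`MendelianInconsistencyError` on trio patterns impossible under
    those assumptions (anywhere in the pedigree).
    """
    target = ped[target_id]
    if gm.call(target_id, variant_key) is not Call.MISSING:
        raise ValidationError(f"{target_id!r} is already genotyped at {variant_key}")
    validate_mendelian(ped, gm, variant_key)

    children = ped.children_of(target_id)
    basis: list[tuple[str, Call]] = []
    obligate = False
    all_children_hom_ref = bool(children)
    spouses_typed: dict[str, Call] = {}

    for child in children:
        co_parent_id = ped.co_parent(child, target_id)
        co_call = (gm.call(co_parent_id, variant_key)
                   if co_parent_id is not None else Call.MISSING)
        if co_parent_id is not None and co_call is not Call.MISSING:
            spouses_typed.setdefault(co_parent_id, co_call)
        child_call = gm.call(child.id, variant_key)
        if child_call is Call.MISSING:
            all_children_hom_ref = False
            continue
        basis.append((child.id, child_call))
        if child_call is not Call.HOM_REF:
            all_children_hom_ref = False
        if co_call is Call.HOM_REF:
            if child_call is Call.HOM_ALT:
                raise MendelianInconsistencyError(
                    f"{child.id!r} is homozygous alternate at {variant_key} but "
                    f"co-parent {co_parent_id!r} is homozygous reference"
                )
            if child_call is Call.HET:
                # Alternate allele must have come from the untyped target.
                obligate = True

    for spouse_id, call in spouses_typed.items():
        basis.append((spouse_id, call))

    if obligate:
        return InferredGenotype(target_id, variant_key,
                                InferredState.INFERRED_HET, tuple(basis))
    if all_children_hom_ref and spouses_typed:
        # Complete no-transmission pattern: every child typed hom-ref.
        return InferredGenotype(target_id, variant_key,
                                InferredState.INFERRED_NONCARRIER, tuple(basis))
    return InferredGenotype(target_id, variant_key, InferredState.INDETERMINATE)


@dataclass
class CosegregationDetail:
    individual_id: str
    affection: Affection
    call: str            # observed call, inferred state, or "untyped"
    consistent: bool | None  # None when the individual did not contribute


@dataclass
class CosegregationVerdict:
    cosegregates: bool
    reason: str
    detail: list[CosegregationDetail] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.cosegregates


def check_cosegregation(ped: Pedigree, gm: GenotypeMatrix,
                        inferred: dict[str, InferredGenotype] | list[InferredGenotype],
                        variant_key: VariantKey) -> CosegregationVerdict:
    """Full-penetrance dominant cosegregation verdict for one variant.

    True iff every affected individual is heterozygous (typed or inferred)
    and every typed unaffected individual is homozygous reference. Untyped
    unaffected individuals without an inference are skipped with a warning;
    an affected individual whose genotype cannot be established fails the
    verdict with reason "insufficient genotypes".
    """
    if isinstance(inferred, list):
        inferred = {ig.individual_id: ig for ig in inferred}
    detail: list[CosegregationDetail] = []
    failures: list[str] = []
    insufficient = False
    n_affected = 0

    for ind in sorted(ped, key=lambda i: i.id):
        call = gm.call(ind.id, variant_key)
        ig = inferred.get(ind.id)
        if ind.affection is Affection.AFFECTED:
            n_affected += 1
            if call is not Call.MISSING:
                ok = call is Call.HET
                detail.append(CosegregationDetail(ind.id, ind.affection,
                                                  call.name.lower(), ok))
                if not ok:
                    failures.append(f"affected {ind.id} is {call.name.lower()}")
            elif ig is not None and ig.state is InferredState.INFERRED_HET:
                detail.append(CosegregationDetail(ind.id, ind.affection,
                                                  ig.state.value, True))
            elif ig is not None and ig.state is InferredState.INFERRED_NONCARRIER:
                detail.append(CosegregationDetail(ind.id, ind.affection,
                                                  ig.state.value, False))
                failures.append(f"affected {ind.id} inferred non-carrier")
            else:
                detail.append(CosegregationDetail(ind.id, ind.affection,
                                                  "untyped", False))
                insufficient = True
        elif ind.affection is Affection.UNAFFECTED:
            if call is Call.MISSING:
                logger.warning("unaffected %r untyped at %s; skipped",
                               ind.id, variant_key)
                detail.append(CosegregationDetail(ind.id, ind.affection,
                                                  "untyped", None))
                continue
            ok = call is Call.HOM_REF
            detail.append(CosegregationDetail(ind.id, ind.affection,
                                              call.name.lower(), ok))
            if not ok:
                failures.append(f"unaffected {ind.id} is {call.name.lower()}")
        else:
            detail.append(CosegregationDetail(ind.id, ind.affection,
                                              call.name.lower()
                                              if call is not Call.MISSING
                                              else "untyped", None))

    if n_affected == 0:
        return CosegregationVerdict(False, "no affected individuals in pedigree",
                                    detail)
    if insufficient:
        return CosegregationVerdict(False, "insufficient genotypes", detail)
    if failures:
        return CosegregationVerdict(False, "; ".join(failures), detail)
    return CosegregationVerdict(True, "all affected heterozygous, "
                                      "all typed unaffected homozygous reference",
                                detail)
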