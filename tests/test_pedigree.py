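"""Untyped-relative genotype inference and the cosegregation verdict."""

from __future__ import annotations

import pytest

from famvar.core import (
    Affection,
    Call,
    GenotypeMatrix,
    Individual,
    MendelianInconsistencyError,
    Pedigree,
    Sex,
)
from famvar.pedigree import (
    InferredState,
    check_cosegregation,
    infer_founder_genotype,
)
from famvar.simulate import SimulationSpec, fig1_pedigree, simulate_family

KEY = ("11", 1_000_000, "C", "T")


def _gm(calls: dict[str, Call]) -> GenotypeMatrix:
    gm = GenotypeMatrix()
    for sample, call in calls.items():
        gm.set(sample, KEY, call)
    return gm


class TestInference:
    def test_obligate_het_from_children_and_spouse(self):
        """Untyped II-2: spouse hom-ref, three het children -> obligate het,
        with all four relatives in the basis."""
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF, "III-1": Call.HOM_REF,
                  "III-2": Call.HET, "III-3": Call.HET, "III-4": Call.HET})
        ig = infer_founder_genotype(ped, gm, KEY, "II-2")
        assert ig.state is InferredState.INFERRED_HET
        basis_ids = {rid for rid, _ in ig.basis}
        assert basis_ids == {"II-1", "III-1", "III-2", "III-3", "III-4"}

    def test_no_genotyped_relatives_indeterminate(self):
        ped = fig1_pedigree()
        ig = infer_founder_genotype(ped, _gm({}), KEY, "II-2")
        assert ig.state is InferredState.INDETERMINATE
        assert ig.basis == ()

    def test_complete_no_transmission_infers_noncarrier(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HET, "III-1": Call.HOM_REF,
                  "III-2": Call.HOM_REF, "III-3": Call.HOM_REF,
                  "III-4": Call.HOM_REF})
        ig = infer_founder_genotype(ped, gm, KEY, "II-2")
        assert ig.state is InferredState.INFERRED_NONCARRIER

    def test_incomplete_no_transmission_indeterminate(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF, "III-1": Call.HOM_REF,
                  "III-2": Call.HOM_REF, "III-4": Call.HOM_REF})  # III-3 untyped
        ig = infer_founder_genotype(ped, gm, KEY, "II-2")
        assert ig.state is InferredState.INDETERMINATE

    def test_het_child_of_two_hom_ref_parents_is_error(self):
        """De novo events are not modeled: a het child with both parents typed
        hom-ref is a Mendelian inconsistency wherever it sits."""
        ped = Pedigree([
            Individual("F", None, None, Sex.MALE, Affection.UNKNOWN),
            Individual("M", None, None, Sex.FEMALE, Affection.UNKNOWN),
            Individual("C", "F", "M", Sex.MALE, Affection.AFFECTED),
            Individual("U", None, None, Sex.FEMALE, Affection.UNKNOWN),
        ])
        gm = _gm({"F": Call.HOM_REF, "M": Call.HOM_REF, "C": Call.HET})
        with pytest.raises(MendelianInconsistencyError):
            infer_founder_genotype(ped, gm, KEY, "U")

    def test_hom_alt_child_with_hom_ref_coparent_is_error(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF, "III-2": Call.HOM_ALT})
        with pytest.raises(MendelianInconsistencyError):
            infer_founder_genotype(ped, gm, KEY, "II-2")

    def test_sound_on_synthetic_families(self):
        """Against the generator's hidden truth for the untyped II-2 over
        100 seeds: obligate-het inferences are always correct, and a
        non-carrier inference can be wrong only in the one way its logic
        allows — a heterozygous parent who happened to transmit to no typed
        child (probability 2^-k per variant, so a bounded minority)."""
        n_het = n_noncarrier = n_untransmitted_het = 0
        for seed in range(1, 101):
            fam = simulate_family(SimulationSpec(seed=seed,
                                                 n_background_variants=20))
            children = [i.id for i in fam.pedigree.children_of("II-2")]
            for key in list(fam.genotypes.variant_keys):
                try:
                    ig = infer_founder_genotype(fam.pedigree, fam.genotypes,
                                                key, "II-2")
                except MendelianInconsistencyError:
                    continue  # background draw violated no-de-novo; no claim
                if ig.state is InferredState.INDETERMINATE:
                    continue
                true_call = fam.truth_genotypes.call("II-2", key)
                if ig.state is InferredState.INFERRED_HET:
                    n_het += 1
                    # obligate-carrier deduction is always sound
                    assert true_call.carries_alt
                    # and exact when some child received the ref allele
                    if any(fam.genotypes.call(c, key) is Call.HOM_REF
                           for c in children):
                        assert true_call is Call.HET
                else:
                    n_noncarrier += 1
                    # the premise of the deduction must always hold
                    assert all(fam.genotypes.call(c, key) is Call.HOM_REF
                               for c in children)
                    if true_call is not Call.HOM_REF:
                        assert true_call is Call.HET  # never hom-alt
                        n_untransmitted_het += 1
            # the planted rare causal variant: inference exact every time
            ig = infer_founder_genotype(fam.pedigree, fam.genotypes,
                                        fam.causal_key, "II-2")
            assert ig.state is InferredState.INFERRED_HET
            assert fam.truth_genotypes.call("II-2", fam.causal_key) is Call.HET
        assert n_het > 50 and n_noncarrier > 200
        # untransmitted hets are the rare exception, not the rule
        assert n_untransmitted_het < 0.15 * n_noncarrier


class TestCosegregation:
    def _family_gm(self, iii3=Call.HET):
        return _gm({"II-1": Call.HOM_REF, "III-1": Call.HOM_REF,
                    "III-2": Call.HET, "III-3": iii3, "III-4": Call.HET})

    def _inferred_ii2(self, ped, gm):
        return {"II-2": infer_founder_genotype(ped, gm, KEY, "II-2")}

    def test_family_pattern_cosegregates(self):
        ped = fig1_pedigree()
        gm = self._family_gm()
        verdict = check_cosegregation(ped, gm, self._inferred_ii2(ped, gm), KEY)
        assert verdict.cosegregates

    def test_one_noncarrier_affected_fails(self):
        """A candidate absent from one affected member does not cosegregate
        (the exclusion pattern for a competing candidate gene)."""
        ped = fig1_pedigree()
        gm = self._family_gm(iii3=Call.HOM_REF)
        verdict = check_cosegregation(ped, gm, self._inferred_ii2(ped, gm), KEY)
        assert not verdict.cosegregates
        assert "III-3" in verdict.reason

    def test_unaffected_carrier_fails(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF, "III-1": Call.HET,
                  "III-2": Call.HET, "III-3": Call.HET, "III-4": Call.HET})
        verdict = check_cosegregation(ped, gm, self._inferred_ii2(ped, gm), KEY)
        assert not verdict.cosegregates

    def test_affected_without_genotype_or_inference_fails(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF, "III-1": Call.HOM_REF,
                  "III-2": Call.HET, "III-3": Call.HET, "III-4": Call.HET})
        verdict = check_cosegregation(ped, gm, {}, KEY)
        assert not verdict.cosegregates
        assert verdict.reason == "insufficient genotypes"

    def test_zero_affected_pedigree_fails_explicitly(self):
        ped = Pedigree([Individual("A", None, None, Sex.MALE,
                                   Affection.UNAFFECTED)])
        verdict = check_cosegregation(ped, _gm({"A": Call.HOM_REF}), {}, KEY)
        assert not verdict.cosegregates
        assert "no affected" in verdict.reason

    def test_untyped_unaffected_does_not_block(self):
        ped = fig1_pedigree()
        gm = _gm({"II-1": Call.HOM_REF,  # III-1 untyped here
                  "III-2": Call.HET, "III-3": Call.HET, "III-4": Call.HET})
        verdict = check_cosegregation(ped, gm, self._inferred_ii2(ped, gm), KEY)
        assert verdict.cosegregates

    def test_verdict_invariant_to_member_order(self):
        members = [
            Individual("A", None, None, Sex.MALE, Affection.AFFECTED),
            Individual("B", None, None, Sex.FEMALE, Affection.UNAFFECTED),
            Individual("C", None, None, Sex.MALE, Affection.AFFECTED),
        ]
        gm = _gm({"A": Call.HET, "B": Call.HOM_REF, "C": Call.HET})
        verdicts = {check_cosegregation(Pedigree(order), gm, {}, KEY).cosegregates
                    for order in (members, members[::-1],
                                  [members[1], members[2], members[0]])}
        assert verdicts == {True}
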