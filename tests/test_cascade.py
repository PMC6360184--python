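"""Filtering cascade: individual filters, full run, audit and monotonicity."""

from __future__ import annotations

import pytest

from famvar.cascade import (
    CascadeConfig,
    consequence_filter,
    control_maf_filter,
    database_filter,
    intersect_linkage,
    predictor_consensus,
    run_cascade,
    segregation_filter,
)
from famvar.core import (
    AnnotationRecord,
    Call,
    ConfigError,
    Consequence,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Predictor,
    ReferentialError,
    RegionSet,
    VariantRecord,
    VariantSet,
)
from famvar.simulate import (
    SimulationSpec,
    fig1_pedigree,
    simulate_annotations,
    simulate_family,
)

AFFECTED = ["III-2", "III-4"]
UNAFFECTED = ["II-1", "III-1"]


def _variant(i, consequence=Consequence.MISSENSE, chrom="1"):
    return VariantRecord(chrom, 1000 + i, "A", "G", gene=f"G{i}",
                         consequence=consequence)


def _ann(rec, **kw):
    return AnnotationRecord(variant_key=rec.key, **kw)


class TestConsequenceFilter:
    def test_keeps_coding_impact_only(self):
        vs = VariantSet([
            _variant(0, Consequence.MISSENSE),
            _variant(1, Consequence.SYNONYMOUS),
            _variant(2, Consequence.NONCODING),
            _variant(3, Consequence.SPLICE_SITE),
            _variant(4, Consequence.FRAMESHIFT_INDEL),
        ])
        kept = {v.gene for v in consequence_filter(vs)}
        assert kept == {"G0", "G3", "G4"}

    def test_all_synonymous_gives_empty(self):
        vs = VariantSet([_variant(i, Consequence.SYNONYMOUS) for i in range(4)])
        assert len(consequence_filter(vs)) == 0

    def test_planted_causal_survives(self, family):
        kept = consequence_filter(family.variants)
        assert family.causal_key in kept


class TestDatabaseFilter:
    def test_dbsnp_member_removed(self):
        v = _variant(0)
        ann = {v.key: _ann(v, in_dbsnp135=True)}
        assert len(database_filter(VariantSet([v]), ann, "dbsnp")) == 0

    def test_all_flags_false_retained_at_every_stage(self):
        v = _variant(0)
        ann = {v.key: _ann(v)}
        for stage in ("dbsnp", "dbsnp_1000g", "dbsnp_1000g_esp", "plus_exac"):
            assert v.key in database_filter(VariantSet([v]), ann, stage)

    def test_planted_known_vs_novel(self):
        """10 database members + 5 novel variants: exactly the novel survive."""
        known = [_variant(i) for i in range(10)]
        novel = [_variant(i) for i in range(10, 15)]
        ann = {v.key: _ann(v, in_dbsnp135=(i % 3 == 0), in_1000g=(i % 3 == 1),
                           in_esp=(i % 3 == 2)) for i, v in enumerate(known)}
        ann.update({v.key: _ann(v) for v in novel})
        kept = database_filter(VariantSet(known + novel), ann,
                               "dbsnp_1000g_esp")
        assert {v.key for v in kept} == {v.key for v in novel}

    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigError):
            database_filter(VariantSet(), {}, "nosuch")

    def test_commutes_with_consequence_filter(self, family, annotations):
        a = database_filter(consequence_filter(family.variants), annotations,
                            "plus_exac")
        b = consequence_filter(database_filter(family.variants, annotations,
                                               "plus_exac"))
        assert {v.key for v in a} == {v.key for v in b}


class TestSegregationFilter:
    def _setup(self, calls):
        v = _variant(0)
        gm = GenotypeMatrix()
        for sample, call in calls.items():
            gm.set(sample, v.key, call)
        return VariantSet([v]), gm, fig1_pedigree(), v.key

    def test_dominant_pattern_retained(self):
        vs, gm, ped, key = self._setup({"III-2": Call.HET, "III-4": Call.HET,
                                        "II-1": Call.HOM_REF,
                                        "III-1": Call.HOM_REF})
        assert key in segregation_filter(vs, gm, ped, AFFECTED, UNAFFECTED)

    def test_carrier_unaffected_removed(self):
        vs, gm, ped, _ = self._setup({"III-2": Call.HET, "III-4": Call.HET,
                                      "II-1": Call.HET,
                                      "III-1": Call.HOM_REF})
        assert len(segregation_filter(vs, gm, ped, AFFECTED, UNAFFECTED)) == 0

    def test_hom_alt_affected_removed_under_het_rule(self):
        vs, gm, ped, _ = self._setup({"III-2": Call.HOM_ALT, "III-4": Call.HET,
                                      "II-1": Call.HOM_REF,
                                      "III-1": Call.HOM_REF})
        assert len(segregation_filter(vs, gm, ped, AFFECTED, UNAFFECTED)) == 0

    def test_missing_call_conservative_vs_permissive(self):
        vs, gm, ped, key = self._setup({"III-2": Call.HET,
                                        "III-4": Call.MISSING,
                                        "II-1": Call.HOM_REF,
                                        "III-1": Call.HOM_REF})
        assert len(segregation_filter(vs, gm, ped, AFFECTED, UNAFFECTED)) == 0
        permissive = CascadeConfig(missing_genotype_compatible=True)
        assert key in segregation_filter(vs, gm, ped, AFFECTED, UNAFFECTED,
                                         permissive)

    def test_unknown_individual_rejected(self):
        vs, gm, ped, _ = self._setup({"III-2": Call.HET})
        with pytest.raises(ReferentialError):
            segregation_filter(vs, gm, ped, ["IV-9"], UNAFFECTED)

    def test_planted_variant_satisfies_predicate(self, family):
        kept = segregation_filter(family.variants, family.genotypes,
                                  family.pedigree, AFFECTED, UNAFFECTED)
        assert family.causal_key in kept
        for v in kept:
            for a in AFFECTED:
                assert family.genotypes.call(a, v.key) is Call.HET
            for u in UNAFFECTED:
                assert family.genotypes.call(u, v.key) is Call.HOM_REF


class TestControlMafFilter:
    def test_threshold_and_absence_sets(self):
        vs = VariantSet([_variant(i) for i in range(3)])
        mafs = [0.0, 0.004, 0.02]
        ann = {v.key: _ann(v, control_maf=m) for v, m in zip(vs, mafs)}
        passed, absent = control_maf_filter(vs, ann, 0.01)
        assert len(passed) == 2 and len(absent) == 1

    def test_low_maf_passes_but_not_absent(self):
        v = _variant(0)
        ann = {v.key: _ann(v, control_maf=0.005)}
        passed, absent = control_maf_filter(VariantSet([v]), ann, 0.01)
        assert v.key in passed and v.key not in absent

    def test_missing_maf_counts_as_absent(self):
        v = _variant(0)
        ann = {v.key: _ann(v, control_maf=None)}
        passed, absent = control_maf_filter(VariantSet([v]), ann, 0.01)
        assert v.key in passed and v.key in absent

    def test_boundary_is_inclusive_by_default(self):
        v = _variant(0)
        ann = {v.key: _ann(v, control_maf=0.01)}
        passed, _ = control_maf_filter(VariantSet([v]), ann, 0.01)
        assert v.key in passed
        strict, _ = control_maf_filter(VariantSet([v]), ann, 0.01,
                                       inclusive=False)
        assert v.key not in strict

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_validation(self, bad):
        with pytest.raises(ConfigError):
            control_maf_filter(VariantSet(), {}, bad)


class TestPredictorConsensus:
    def _one(self, provean, sift, polyphen, rule="all_three"):
        v = _variant(0)
        ann = {v.key: _ann(v, provean=provean, sift=sift, polyphen=polyphen)}
        _, consensus = predictor_consensus(VariantSet([v]), ann, rule)
        return v.key in consensus

    def test_unanimous_deleterious_in_consensus(self):
        assert self._one(Predictor.DELETERIOUS, Predictor.DAMAGING,
                         Predictor.DAMAGING)

    def test_one_tolerated_breaks_all_three(self):
        assert not self._one(Predictor.DELETERIOUS, Predictor.TOLERATED,
                             Predictor.DAMAGING)

    def test_missing_call_breaks_all_three_but_not_majority(self):
        assert not self._one(Predictor.DELETERIOUS, Predictor.MISSING,
                             Predictor.DAMAGING)
        assert self._one(Predictor.DELETERIOUS, Predictor.MISSING,
                         Predictor.DAMAGING, rule="majority")

    def test_per_predictor_and_consensus_sizes(self):
        """14-variant fixture engineered to give per-predictor sets of size
        6/8/9 and an all-three consensus of size 4."""
        vs = VariantSet([_variant(i) for i in range(14)])
        D, T = True, False
        # (provean_del, sift_dam, polyphen_dam) per variant
        profile = [
            (D, D, D), (D, D, D), (D, D, D), (D, D, D),   # consensus of 4
            (D, D, T), (D, T, D),                          # provean -> 6
            (T, D, D), (T, D, D), (T, D, D),               # sift -> 8
            (T, T, D),                                     # polyphen -> 9
            (T, T, T), (T, T, T), (T, T, T), (T, T, T),
        ]
        ann = {}
        for v, (p, s, pp) in zip(vs, profile):
            ann[v.key] = _ann(
                v,
                provean=Predictor.DELETERIOUS if p else Predictor.NEUTRAL,
                sift=Predictor.DAMAGING if s else Predictor.TOLERATED,
                polyphen=Predictor.DAMAGING if pp else Predictor.BENIGN)
        per, consensus = predictor_consensus(vs, ann, "all_three")
        assert (len(per["provean"]), len(per["sift"]), len(per["polyphen"])) \
            == (6, 8, 9)
        assert len(consensus) == 4


class TestIntersectLinkage:
    def test_boundary_cases(self):
        v = _variant(0, chrom="2")  # pos 1000 (1-based)
        inside_left = RegionSet([("2", 999, 1000, "r")])    # [999,1000) holds 999
        inside = RegionSet([("2", 999, 1010, "r")])
        outside = RegionSet([("2", 989, 999, "r")])
        assert intersect_linkage(VariantSet([v]), inside_left)
        assert intersect_linkage(VariantSet([v]), inside)
        assert len(intersect_linkage(VariantSet([v]), outside)) == 0

    def test_exactly_one_of_four_in_region(self):
        vs = VariantSet([
            VariantRecord("2", 1_200_000, "A", "G"),
            VariantRecord("2", 900_000, "A", "G"),
            VariantRecord("1", 1_200_000, "A", "G"),
            VariantRecord("2", 1_600_000, "A", "G"),
        ])
        region = RegionSet([("2", 1_000_000, 1_500_000, "SCZD2-like")])
        kept = intersect_linkage(vs, region)
        assert [v.pos for v in kept] == [1_200_000]
        assert kept.keys()[0][0] == "2"


class TestRunCascade:
    def test_empty_input_all_zero(self, small_spec):
        gm = GenotypeMatrix()
        res = run_cascade(VariantSet(), gm, fig1_pedigree(), {},
                          small_spec.regions(), CascadeConfig(),
                          AFFECTED, UNAFFECTED)
        assert (res.stage_counts()["variants"] == 0).all()
        assert res.survivors == set()

    def test_recovers_planted_causal_uniquely(self, family, annotations,
                                              small_spec):
        res = run_cascade(family.variants, family.genotypes, family.pedigree,
                          annotations, small_spec.regions(), CascadeConfig(),
                          AFFECTED, UNAFFECTED)
        assert res.survivors == {family.causal_key}

    def test_audit_partitions_input(self, family, annotations, small_spec):
        """Every input variant is exactly once a survivor or an elimination."""
        res = run_cascade(family.variants, family.genotypes, family.pedigree,
                          annotations, small_spec.regions(), CascadeConfig(),
                          AFFECTED, UNAFFECTED)
        assert set(res.audit) == {v.key for v in family.variants}
        stage_names = {s.name for s in res.stages}
        for key, fate in res.audit.items():
            if key in res.survivors:
                assert fate == "survived"
            else:
                assert fate in stage_names

    def test_counts_monotone_over_many_seeds(self):
        """Stage counts never increase down the cascade, and the survivor set
        equals the set predicted independently from the generator's truth
        table plus realized genotypes (100 seeds)."""
        from famvar.core import Call as C
        for seed in range(1, 101):
            spec = SimulationSpec(seed=seed, n_background_variants=300)
            fam = simulate_family(spec)
            ann = simulate_annotations(fam.truth)
            res = run_cascade(fam.variants, fam.genotypes, fam.pedigree, ann,
                              spec.regions(), CascadeConfig(),
                              AFFECTED, UNAFFECTED)
            res.assert_monotone()
            assert family_truth_survivors(fam, ann) == res.survivors
            assert fam.causal_key in res.survivors


def family_truth_survivors(fam, ann):
    """Expected final survivors computed from planted truth, independently
    of the cascade implementation."""
    from famvar.core import CODING_IMPACT, Call

    expected = set()
    regions = fam.spec.regions()
    for r in fam.truth.itertuples():
        key = (r.chrom, int(r.pos), r.ref, r.alt)
        rec = ann[key]
        if Consequence(r.consequence) not in CODING_IMPACT:
            continue
        if r.in_dbsnp135 or r.in_1000g or r.in_esp or r.in_exac_nonpsych:
            continue
        calls = {s: fam.genotypes.call(s, key)
                 for s in AFFECTED + UNAFFECTED}
        if not all(calls[a] is Call.HET for a in AFFECTED):
            continue
        if not all(calls[u] is Call.HOM_REF for u in UNAFFECTED):
            continue
        if r.control_maf != 0.0:
            continue
        if not (rec.provean.is_deleterious and rec.sift.is_deleterious
                and rec.polyphen.is_deleterious):
            continue
        if not regions.contains(r.chrom, int(r.pos)):
            continue
        expected.add(key)
    return expected
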