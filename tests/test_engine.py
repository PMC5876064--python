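"""Rule registry and per-criterion evaluation."""

from __future__ import annotations

import json

import pytest

from myh7rules.engine import (
    AppliedRule,
    RuleSpec,
    build_registry,
    evaluate_all,
    evaluate_annotation_rules,
    evaluate_functional,
    evaluate_pm1,
    evaluate_pvs1_moderate,
)
from myh7rules.evidence import (
    AnnotationEvidence,
    AssayClass,
    AssayDirection,
    ComputationalConsensus,
    Consequence,
    DiseaseContext,
    EvidenceBundle,
    FunctionalEvidence,
    Phenotype,
    PopulationFrequencyRecord,
    ProbandObservation,
    SegregationRecord,
    VariantIdentity,
)
from myh7rules.io import report_to_dict
from myh7rules.combine import classify_bundle


def _variant(consequence=Consequence.MISSENSE, aa=500, repeat=False):
    return VariantIdentity(consequence=consequence, aa_position=aa, in_repeat_region=repeat)


class TestRegistry:
    def test_audit_counts(self, config):
        audit = config.registry.audit()
        assert audit["base_rules"] == 28
        assert audit["removed"] == 9
        assert audit["disease_gene"] == 12
        assert audit["modified_strength"] == 5
        assert audit["no_change"] == 7

    def test_removed_set_is_exactly_the_inapplicable_rules(self, config):
        removed = {s.code for s in config.registry.base_rules() if s.specification == "removed"}
        assert removed == {"PVS1", "PM3", "PP2", "PP4", "PP5", "BS2", "BP1", "BP3", "BP6"}

    def test_gating_declared_in_data(self, config):
        for code in ("PS4", "PS4_Moderate", "PS4_Supporting", "PP1", "PP1_Moderate", "PP1_Strong"):
            assert config.registry[code].gating == ("PM2",)

    def test_strength_must_match_code_suffix(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RuleSpec(code="PS4_Moderate", direction="pathogenic", strength="strong",
                     specification="modified-strength", base="PS4")

    def test_unknown_gating_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown gating"):
            build_registry({"rules": [
                {"code": "PS4", "direction": "pathogenic", "strength": "strong",
                 "specification": "disease-gene", "gating": ["PMX"]},
            ]})

    def test_yaml_round_trip(self, config):
        import yaml

        text = config.registry.to_yaml()
        rebuilt = build_registry(yaml.safe_load(text))
        assert rebuilt.audit() == config.registry.audit()


class TestPM1:
    @pytest.mark.parametrize("aa, met", [(180, False), (181, True), (500, True),
                                         (937, True), (938, False)])
    def test_head_domain_boundaries(self, aa, met):
        assert evaluate_pm1(_variant(aa=aa)).met is met

    def test_restricted_to_missense(self):
        assert not evaluate_pm1(_variant(consequence=Consequence.NONSENSE, aa=500)).met

    def test_requires_a_position(self):
        assert not evaluate_pm1(_variant(aa=None)).met


class TestPVS1Moderate:
    @pytest.mark.parametrize(
        "consequence, met",
        [(Consequence.NONSENSE, True), (Consequence.FRAMESHIFT, True),
         (Consequence.CANONICAL_SPLICE, True), (Consequence.MISSENSE, False),
         (Consequence.SYNONYMOUS, False)],
    )
    def test_lof_classes(self, consequence, met):
        rule = evaluate_pvs1_moderate(_variant(consequence=consequence))
        assert rule.met is met
        assert rule.strength == "moderate"

    def test_lof_alone_is_uncertain_significance(self, config):
        bundle = EvidenceBundle(
            variant=_variant(consequence=Consequence.FRAMESHIFT),
            disease_context=DiseaseContext.HCM,
        )
        report = classify_bundle(bundle, config)
        assert report.classification.met_codes() == ["PVS1_Moderate"]
        assert report.classification.tier.value == "uncertain significance"


class TestFunctional:
    def test_knockin_damaging_meets_ps3(self):
        ps3, bs3 = evaluate_functional(
            [FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.DAMAGING)]
        )
        assert ps3.met and not bs3.met

    def test_knockin_benign_meets_bs3(self):
        ps3, bs3 = evaluate_functional(
            [FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.BENIGN)]
        )
        assert bs3.met and not ps3.met

    @pytest.mark.parametrize(
        "assay",
        [AssayClass.IN_VITRO, AssayClass.TRANSGENIC_DOSAGE, AssayClass.KNOCKOUT, AssayClass.OTHER],
    )
    def test_other_assay_classes_never_qualify(self, assay):
        ps3, bs3 = evaluate_functional([FunctionalEvidence(assay, AssayDirection.DAMAGING)])
        assert not ps3.met and not bs3.met

    def test_no_evidence(self):
        ps3, bs3 = evaluate_functional([])
        assert not ps3.met and not bs3.met


class TestAnnotationRules:
    def _met(self, rules):
        return {r.code for r in rules if r.met}

    def test_computational_consensus_routes_pp3_bp4(self):
        pp3 = evaluate_annotation_rules(
            AnnotationEvidence(computational_consensus=ComputationalConsensus.PATHOGENIC_SUPPORTING),
            _variant(),
        )
        assert self._met(pp3) == {"PP3"}
        bp4 = evaluate_annotation_rules(
            AnnotationEvidence(computational_consensus=ComputationalConsensus.BENIGN_SUPPORTING),
            _variant(),
        )
        assert self._met(bp4) == {"BP4"}
        neither = evaluate_annotation_rules(
            AnnotationEvidence(computational_consensus=ComputationalConsensus.CONFLICTING),
            _variant(),
        )
        assert self._met(neither) == set()

    def test_pm4_inframe_indel_excludes_repeat_regions(self):
        in_ok = evaluate_annotation_rules(
            AnnotationEvidence(), _variant(consequence=Consequence.INFRAME_INDEL, aa=1500)
        )
        assert "PM4" in self._met(in_ok)
        repeat = evaluate_annotation_rules(
            AnnotationEvidence(),
            _variant(consequence=Consequence.INFRAME_INDEL, aa=1500, repeat=True),
        )
        assert "PM4" not in self._met(repeat)

    def test_pm4_stop_loss(self):
        rules = evaluate_annotation_rules(
            AnnotationEvidence(), _variant(consequence=Consequence.STOP_LOSS, aa=1936)
        )
        assert "PM4" in self._met(rules)

    def test_bp7_requires_synonymous_consequence(self):
        ann = AnnotationEvidence(splice_no_impact_not_conserved=True)
        syn = evaluate_annotation_rules(ann, _variant(consequence=Consequence.SYNONYMOUS))
        assert "BP7" in self._met(syn)
        mis = evaluate_annotation_rules(ann, _variant(consequence=Consequence.MISSENSE))
        assert "BP7" not in self._met(mis)

    def test_lookup_booleans(self):
        ann = AnnotationEvidence(
            same_aa_known_pathogenic=True,
            different_change_at_pathogenic_residue=True,
            in_cis_with_pathogenic=True,
            alternate_molecular_basis=True,
        )
        assert self._met(evaluate_annotation_rules(ann, _variant())) == {
            "PS1", "PM5", "BP2", "BP5",
        }


class TestEvaluateAll:
    def _worked_style(self, worked_examples, label):
        return next(b for b in worked_examples if label in b.bundle_id)

    def test_multiple_proband_worked_example_rules(self, config, worked_examples):
        bundle = self._worked_style(worked_examples, "R1420W")
        met = {r.code for r in evaluate_all(bundle, config) if r.met}
        assert met == {"PM2", "PS4_Moderate", "PP3"}

    def test_de_novo_worked_example_rules(self, config, worked_examples):
        bundle = self._worked_style(worked_examples, "R1909P")
        met = {r.code for r in evaluate_all(bundle, config) if r.met}
        assert met == {"PM2", "PM6", "PP3"}

    def test_empty_bundle_meets_nothing(self, config):
        bundle = EvidenceBundle(
            variant=VariantIdentity(consequence=Consequence.OTHER),
            disease_context=DiseaseContext.HCM,
        )
        assert [r.code for r in evaluate_all(bundle, config) if r.met] == []

    def test_removed_rules_never_appear(self, config, worked_examples):
        removed = {"PVS1", "PM3", "PP2", "PP4", "PP5", "BS2", "BP1", "BP3", "BP6"}
        for bundle in worked_examples:
            codes = {r.code for r in evaluate_all(bundle, config)}
            assert codes.isdisjoint(removed)

    def test_one_applied_rule_per_base(self, config, worked_examples):
        for bundle in worked_examples:
            bases = [r.base for r in evaluate_all(bundle, config)]
            assert len(bases) == len(set(bases))

    def test_gating_soundness_ps4_pp1_require_pm2(self, config):
        bundle = EvidenceBundle(
            variant=_variant(aa=1500),
            disease_context=DiseaseContext.HCM,
            population_frequencies=[PopulationFrequencyRecord("NFE", 10, 100000, True)],
            probands=[
                ProbandObservation(f"P{i}", phenotype=Phenotype.HCM) for i in range(20)
            ],
            segregations=[SegregationRecord("F1", meioses=9)],
        )
        met = {r.code for r in evaluate_all(bundle, config) if r.met}
        assert "PM2" not in met
        assert not any(code.startswith(("PS4", "PP1")) for code in met)

    def test_traces_are_deterministic(self, config, worked_examples):
        for bundle in worked_examples:
            first = json.dumps(report_to_dict(classify_bundle(bundle, config)), sort_keys=True)
            second = json.dumps(report_to_dict(classify_bundle(bundle, config)), sort_keys=True)
            assert first == second

    def test_invalid_bundle_rejected(self, config):
        bundle = EvidenceBundle(
            variant=_variant(),
            disease_context="not-a-context",
        )
        with pytest.raises(ValueError, match="disease_context"):
            evaluate_all(bundle, config)

    def test_quasi_case_control_reported_alongside_ps4(self, config, worked_examples):
        bundle = self._worked_style(worked_examples, "R1420W")
        ps4 = next(r for r in evaluate_all(bundle, config) if r.base == "PS4")
        stats = ps4.inputs["quasi_case_control"]
        assert set(stats) == {"NFE", "AFR"}
        assert stats["NFE"]["p_value"] < 0.01
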