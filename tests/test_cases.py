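"""Case-level evidence: proband counting, PS4, segregation, de novo."""

from __future__ import annotations

import math

import hypothesis.strategies as st
import pytest
from hypothesis import given

from _oracles import fisher_oracle
from myh7rules.cases import (
    CohortModel,
    CohortSizes,
    Individual,
    Pedigree,
    PedigreeError,
    SegregationEvidence,
    count_eligible_probands,
    count_informative_meioses,
    default_cohort_model,
    evaluate_de_novo,
    lod_score,
    quasi_case_control,
    tier_pp1,
    tier_ps4,
)
from myh7rules.evidence import (
    DeNovoObservation,
    DiseaseContext,
    Phenotype,
    ProbandObservation,
    SegregationRecord,
)


def _probands(*phenotypes, prefix="P"):
    return [
        ProbandObservation(f"{prefix}{i}", phenotype=p) for i, p in enumerate(phenotypes)
    ]


class TestProbandCounting:
    def test_empty_list(self):
        assert count_eligible_probands([], DiseaseContext.HCM)[0] == 0

    def test_hcm_context_excludes_lvnc_and_plain_dcm(self):
        obs = _probands(
            Phenotype.HCM,
            Phenotype.LVNC_ISOLATED,
            Phenotype.DCM,
            Phenotype.DCM_WITH_PRIOR_HCM,
        )
        count, trace = count_eligible_probands(obs, DiseaseContext.HCM)
        assert count == 2
        reasons = {t["proband_id"]: t["reason"] for t in trace if not t["eligible"]}
        assert "LVNC" in reasons["P1"]
        assert "DCM" in reasons["P2"]

    def test_dcm_context_counts_dcm_and_prior_hcm_but_not_lvnc(self):
        obs = _probands(Phenotype.DCM, Phenotype.DCM_WITH_PRIOR_HCM, Phenotype.LVNC_ISOLATED)
        assert count_eligible_probands(obs, DiseaseContext.DCM)[0] == 2

    def test_rcm_context_counts_only_rcm(self):
        obs = _probands(Phenotype.RCM, Phenotype.HCM, Phenotype.OTHER)
        assert count_eligible_probands(obs, DiseaseContext.RCM)[0] == 1

    def test_suspected_duplicates_collapse_to_one(self):
        obs = [
            ProbandObservation("A", cohort_id="c1", phenotype=Phenotype.HCM),
            ProbandObservation("B", cohort_id="c2", phenotype=Phenotype.HCM, duplicate_of="A"),
        ]
        count, trace = count_eligible_probands(obs, DiseaseContext.HCM)
        assert count == 1
        assert trace[0]["cluster"] == trace[1]["cluster"]

    def test_duplicate_chains_collapse_transitively(self):
        obs = [
            ProbandObservation("A", phenotype=Phenotype.HCM),
            ProbandObservation("B", phenotype=Phenotype.HCM, duplicate_of="A"),
            ProbandObservation("C", phenotype=Phenotype.HCM, duplicate_of="B"),
            ProbandObservation("D", phenotype=Phenotype.HCM),
        ]
        assert count_eligible_probands(obs, DiseaseContext.HCM)[0] == 2

    @given(
        tags=st.lists(st.sampled_from(list(Phenotype)), max_size=12),
        context=st.sampled_from(list(DiseaseContext)),
    )
    def test_eligibility_filter_is_idempotent(self, tags, context):
        obs = _probands(*tags)
        count1, trace = count_eligible_probands(obs, context)
        survivors = [o for o, t in zip(obs, trace) if t["eligible"]]
        count2, _ = count_eligible_probands(survivors, context)
        assert count1 == count2


class TestQuasiCaseControl:
    def test_empty_table_convention(self):
        model = CohortModel({"NFE": CohortSizes(100, 1000)}, assumed_control_carriers=0)
        res = quasi_case_control(0, model, "NFE")
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_two_carriers_against_afr_proxy_matches_enumeration(self):
        model = CohortModel({"AFR": CohortSizes(500, 5203)}, assumed_control_carriers=2)
        res = quasi_case_control(2, model, "AFR")
        a, b = res.table[0]
        c, d = res.table[1]
        assert (a, b, c, d) == (2, 498, 2, 5201)
        assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))

    def test_strong_enrichment_is_significant(self):
        model = CohortModel({"NFE": CohortSizes(2500, 33370)}, assumed_control_carriers=2)
        res = quasi_case_control(15, model, "NFE")
        assert res.p_value < 1e-6
        assert res.odds_ratio > 10
        assert res.p_value == pytest.approx(fisher_oracle(15, 2485, 2, 33368), abs=1e-9)

    def test_default_model_reproduces_conventional_odds_ratio_ladder(self):
        """At the 2/6/15 count thresholds the default NFE cohorts give the
        odds-ratio ladder ~13.4 / 40.1 / 100."""
        model = default_cohort_model()
        ors = [quasi_case_control(k, model, "NFE").odds_ratio for k in (2, 6, 15)]
        assert ors[0] == pytest.approx(13.4, abs=0.1)
        assert ors[1] == pytest.approx(40.1, abs=0.1)
        assert ors[2] == pytest.approx(100, rel=0.02)

    def test_infinite_odds_ratio_when_controls_carry_none(self):
        model = CohortModel({"NFE": CohortSizes(100, 1000)}, assumed_control_carriers=0)
        assert quasi_case_control(3, model, "NFE").odds_ratio == math.inf

    def test_unknown_ancestry_is_an_input_error(self):
        with pytest.raises(ValueError):
            quasi_case_control(1, default_cohort_model(), "MARS")


class TestPS4Tiers:
    @pytest.mark.parametrize(
        "count, expected",
        [(0, None), (1, None), (2, "PS4_Supporting"), (5, "PS4_Supporting"),
         (6, "PS4_Moderate"), (14, "PS4_Moderate"), (15, "PS4"), (40, "PS4")],
    )
    def test_count_thresholds_with_pm2(self, count, expected):
        assert tier_ps4(count, pm2_met=True) == expected

    def test_no_tier_without_pm2(self):
        assert tier_ps4(15, pm2_met=False) is None

    @given(count=st.integers(0, 100))
    def test_monotone_in_count(self, count):
        rank = {None: 0, "PS4_Supporting": 1, "PS4_Moderate": 2, "PS4": 3}
        assert rank[tier_ps4(count + 1, True)] >= rank[tier_ps4(count, True)]


class TestLod:
    @pytest.mark.parametrize("n, expected", [(3, 0.9), (5, 1.5), (7, 2.1), (0, 0.0)])
    def test_reference_values(self, n, expected):
        assert round(lod_score(n), 1) == expected

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    def test_linearity(self, a, b):
        assert lod_score(a + b) == pytest.approx(lod_score(a) + lod_score(b), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lod_score(-1)


def _trio(child_carrier=True) -> Pedigree:
    return Pedigree(
        "F1",
        {
            "dad": Individual("dad", affected=True, carrier=True),
            "mom": Individual("mom", affected=False, carrier=False),
            "kid": Individual("kid", father="dad", mother="mom", affected=True,
                              carrier=child_carrier),
        },
    )


class TestMeiosisCounting:
    def test_direct_counts_sum_across_families(self):
        ev = count_informative_meioses(
            [SegregationRecord("F1", meioses=2), SegregationRecord("F2", meioses=1)]
        )
        assert ev.meioses == 3
        assert ev.lod == pytest.approx(lod_score(3))
        assert round(ev.lod, 1) == 0.9

    def test_trio_pedigree_counts_one_transmission(self):
        rec = SegregationRecord("F1", pedigree_ref="F1")
        ev = count_informative_meioses([rec], {"F1": _trio()})
        assert ev.meioses == 1
        assert not ev.nonsegregation

    def test_unaffected_carrier_connector_is_traversed(self):
        ped = Pedigree(
            "F1",
            {
                "gf": Individual("gf", affected=True, carrier=True),
                "gm": Individual("gm", affected=False, carrier=False),
                "mid": Individual("mid", father="gf", mother="gm", affected=False, carrier=True),
                "spouse": Individual("spouse", affected=False, carrier=False),
                "kid": Individual("kid", father="mid", mother="spouse", affected=True, carrier=True),
            },
        )
        ev = count_informative_meioses([SegregationRecord("F1", pedigree_ref="F1")], {"F1": ped})
        assert ev.meioses == 2  # two transmissions link the affected carriers

    def test_affected_noncarrier_flags_nonsegregation_and_zeroes_family(self):
        ped = _trio(child_carrier=False)
        ev = count_informative_meioses([SegregationRecord("F1", pedigree_ref="F1")], {"F1": ped})
        assert ev.nonsegregation
        assert ev.meioses == 0

    def test_nonsegregating_family_does_not_poison_other_families(self):
        records = [
            SegregationRecord("F1", meioses=4, nonsegregation=True),
            SegregationRecord("F2", meioses=3),
        ]
        ev = count_informative_meioses(records)
        assert ev.nonsegregation
        assert ev.meioses == 3
        assert ev.per_family["F1"]["meioses"] == 0

    def test_unknown_parent_reference_is_an_error(self):
        ped = Pedigree("F1", {"kid": Individual("kid", father="ghost")})
        with pytest.raises(PedigreeError):
            count_informative_meioses([SegregationRecord("F1", pedigree_ref="F1")], {"F1": ped})

    def test_pedigree_cycle_is_an_error(self):
        ped = Pedigree(
            "F1",
            {
                "a": Individual("a", father="b"),
                "b": Individual("b", father="a"),
            },
        )
        with pytest.raises(PedigreeError):
            count_informative_meioses([SegregationRecord("F1", pedigree_ref="F1")], {"F1": ped})

    def test_unresolvable_reference_is_an_error(self):
        with pytest.raises(PedigreeError):
            count_informative_meioses([SegregationRecord("F1", pedigree_ref="F1")], {})


class TestPP1Tiers:
    @pytest.mark.parametrize(
        "n, expected",
        [(0, None), (2, None), (3, "PP1"), (4, "PP1"), (5, "PP1_Moderate"),
         (6, "PP1_Moderate"), (7, "PP1_Strong"), (12, "PP1_Strong")],
    )
    def test_meiosis_thresholds_with_pm2(self, n, expected):
        ev = SegregationEvidence(meioses=n, lod=lod_score(n), nonsegregation=False)
        code, bs4 = tier_pp1(ev, pm2_met=True)
        assert code == expected
        assert not bs4

    def test_single_family_suffices(self):
        ev = count_informative_meioses([SegregationRecord("F1", meioses=7)])
        assert tier_pp1(ev, pm2_met=True)[0] == "PP1_Strong"

    def test_requires_pm2(self):
        ev = SegregationEvidence(meioses=7, lod=lod_score(7), nonsegregation=False)
        assert tier_pp1(ev, pm2_met=False) == (None, False)

    def test_nonsegregation_sets_bs4_and_blocks_pp1(self):
        ev = SegregationEvidence(meioses=0, lod=0.0, nonsegregation=True)
        assert tier_pp1(ev, pm2_met=True) == (None, True)

    @given(n=st.integers(0, 30))
    def test_monotone_in_meioses(self, n):
        rank = {None: 0, "PP1": 1, "PP1_Moderate": 2, "PP1_Strong": 3}
        ev_lo = SegregationEvidence(n, lod_score(n), False)
        ev_hi = SegregationEvidence(n + 1, lod_score(n + 1), False)
        assert rank[tier_pp1(ev_hi, True)[0]] >= rank[tier_pp1(ev_lo, True)[0]]


def _dn(paternity=True, qualifying=True):
    return DeNovoObservation(
        paternity_confirmed=paternity,
        maternity_confirmed=False,
        parents_genotype_negative=qualifying,
        parents_phenotype_negative=qualifying,
        family_history_negative=qualifying,
    )


class TestDeNovo:
    def test_confirmed_paternity_is_strong(self):
        assert evaluate_de_novo([_dn(paternity=True)]) == "PS2"

    def test_unconfirmed_paternity_is_moderate(self):
        assert evaluate_de_novo([_dn(paternity=False)]) == "PM6"

    def test_three_unconfirmed_occurrences_upgrade_to_strong(self):
        assert evaluate_de_novo([_dn(paternity=False)] * 3) == "PS2"
        assert evaluate_de_novo([_dn(paternity=False)] * 2) == "PM6"

    def test_no_observations(self):
        assert evaluate_de_novo([]) is None

    def test_disqualified_observation_contributes_nothing(self):
        assert evaluate_de_novo([_dn(paternity=True, qualifying=False)]) is None

    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            max_size=6,
        )
    )
    def test_ps2_and_pm6_are_mutually_exclusive(self, flags):
        obs = [
            DeNovoObservation(p, False, g, ph, fh) for p, g, ph, fh in flags
        ]
        assert evaluate_de_novo(obs) in (None, "PS2", "PM6")
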