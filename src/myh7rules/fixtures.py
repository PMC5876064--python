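"""Synthetic evidence generator covering every rule path.

Emits evidence bundles exercising each non-removed rule's activation and
non-activation, the count boundaries of the tiered rules (proband counts
1/2/5/6/14/15, meioses 2..7, de novo occurrences 1/2/3, filtering AF
straddling each frequency threshold), the phenotype counting filters
(isolated LVNC, DCM in an HCM context), combination scenarios reaching
every tier, and conflict scenarios. The accompanying manifest records
the intended rule activations and intended tier for every bundle; it is
ground truth by construction and serves as the end-to-end recovery
surface. Generation is deterministic given the seed: identical seeds
produce byte-identical files.

What this emulates -- and what it does not: bundles mirror the *shape*
of curated evidence (counts, flags, cohort AC/AN) at the study's stated
thresholds, not the messiness of real curation (ambiguous phenotypes
beyond the encoded tags, conflicting duplicate links, partial pedigrees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .evidence import (
    AnnotationEvidence,
    AssayClass,
    AssayDirection,
    ComputationalConsensus,
    Consequence,
    DeNovoObservation,
    DiseaseContext,
    EvidenceBundle,
    ExpertOverride,
    FunctionalEvidence,
    Phenotype,
    PopulationFrequencyRecord,
    ProbandObservation,
    SegregationRecord,
    Tier,
    VariantIdentity,
    bundle_to_dict,
)

__all__ = ["FixtureSet", "generate_fixtures", "SCENARIOS"]

# Reference frequency records: absent / extremely rare (PM2), between the
# PM2 and BS1 thresholds (no rule), at BS1/BA1 levels, and undersampled.
_FREQ = {
    "pm2": [("NFE", 0, 120000, True)],
    "pm2_rare": [("NFE", 1, 66740, True)],
    "neutral": [("NFE", 10, 100000, True)],  # filtering AF ~5.4e-5
    "bs1": [("NFE", 35, 100000, True)],  # filtering AF ~2.6e-4
    "bs1_ineligible": [("SAS", 35, 100000, False)],
    "ba1": [("NFE", 120, 100000, True)],  # filtering AF ~1.0e-3
    "low_an": [("NFE", 0, 500, True)],
    "none": [],
}


def _denovo(paternity: bool, qualifying: bool = True) -> DeNovoObservation:
    return DeNovoObservation(
        paternity_confirmed=paternity,
        maternity_confirmed=False,
        parents_genotype_negative=qualifying,
        parents_phenotype_negative=qualifying,
        family_history_negative=qualifying,
    )


@dataclass
class Scenario:
    name: str
    intended_rules: frozenset[str]
    intended_tier: Tier
    build: Callable[[np.random.Generator, str], EvidenceBundle]


def _make_builder(
    *,
    consequence: Consequence = Consequence.MISSENSE,
    aa: Optional[int] = 1500,
    in_repeat: bool = False,
    freq: str = "neutral",
    probands: int = 0,
    phenotypes: Optional[list[Phenotype]] = None,
    duplicate_last: bool = False,
    meioses: Optional[list[int]] = None,
    nonsegregation: bool = False,
    de_novo: Optional[list[DeNovoObservation]] = None,
    functional: Optional[list[FunctionalEvidence]] = None,
    annotations: Optional[AnnotationEvidence] = None,
    override: Optional[ExpertOverride] = None,
    context: DiseaseContext = DiseaseContext.HCM,
) -> Callable[[np.random.Generator, str], EvidenceBundle]:
    def build(rng: np.random.Generator, bundle_id: str) -> EvidenceBundle:
        tags = phenotypes
        if tags is None:
            default_tag = Phenotype(context.value)
            tags = [default_tag] * probands
        prob_records = [
            ProbandObservation(
                proband_id=f"{bundle_id}-P{i + 1}",
                cohort_id=f"cohort-{int(rng.integers(1, 6))}",
                phenotype=tag,
            )
            for i, tag in enumerate(tags)
        ]
        if duplicate_last and len(prob_records) >= 2:
            prob_records[-1].duplicate_of = prob_records[0].proband_id
        segs = [
            SegregationRecord(
                family_id=f"{bundle_id}-F{i + 1}", meioses=n, nonsegregation=nonsegregation
            )
            for i, n in enumerate(meioses or [])
        ]
        pops = [
            PopulationFrequencyRecord(
                population=label, ac=ac, an=an, deeply_characterized=deep
            )
            for label, ac, an, deep in _FREQ[freq]
        ]
        return EvidenceBundle(
            variant=VariantIdentity(
                hgvs_p=f"synthetic:{bundle_id}",
                consequence=consequence,
                aa_position=aa,
                in_repeat_region=in_repeat,
            ),
            disease_context=context,
            population_frequencies=pops,
            probands=prob_records,
            segregations=segs,
            de_novo=list(de_novo or []),
            functional=list(functional or []),
            annotations=annotations or AnnotationEvidence(),
            expert_override=override,
            bundle_id=bundle_id,
        )

    return build


def _scenario(name, rules, tier, **kwargs) -> Scenario:
    return Scenario(
        name=name,
        intended_rules=frozenset(rules),
        intended_tier=tier,
        build=_make_builder(**kwargs),
    )


VUS = Tier.UNCERTAIN

SCENARIOS: list[Scenario] = [
    # --- frequency rules straddling each threshold ---
    _scenario("freq_ba1", {"BA1"}, Tier.BENIGN, freq="ba1"),
    _scenario("freq_bs1_eligible", {"BS1"}, Tier.LIKELY_BENIGN, freq="bs1"),
    _scenario("freq_bs1_ineligible_population", set(), VUS, freq="bs1_ineligible"),
    _scenario("freq_pm2_absent", {"PM2"}, VUS, freq="pm2"),
    _scenario("freq_pm2_rare", {"PM2"}, VUS, freq="pm2_rare"),
    _scenario("freq_between_thresholds", set(), VUS, freq="neutral"),
    _scenario("freq_low_an_ignored", set(), VUS, freq="low_an"),
    # --- PS4 proband-count boundaries (PM2 met) ---
    _scenario("probands_1", {"PM2"}, VUS, freq="pm2", probands=1),
    _scenario("probands_2", {"PM2", "PS4_Supporting"}, VUS, freq="pm2", probands=2),
    _scenario("probands_5", {"PM2", "PS4_Supporting"}, VUS, freq="pm2", probands=5),
    _scenario("probands_6", {"PM2", "PS4_Moderate"}, VUS, freq="pm2", probands=6),
    _scenario("probands_14", {"PM2", "PS4_Moderate"}, VUS, freq="pm2", probands=14),
    _scenario("probands_15", {"PM2", "PS4"}, Tier.LIKELY_PATHOGENIC, freq="pm2", probands=15),
    _scenario("probands_15_no_pm2", set(), VUS, freq="neutral", probands=15),
    _scenario(
        "probands_phenotype_filters",
        {"PM2", "PS4_Supporting"},
        VUS,
        freq="pm2",
        phenotypes=[
            Phenotype.HCM,
            Phenotype.HCM,
            Phenotype.HCM,
            Phenotype.LVNC_ISOLATED,
            Phenotype.LVNC_ISOLATED,
            Phenotype.DCM,
            Phenotype.DCM,
            Phenotype.DCM_WITH_PRIOR_HCM,
        ],
    ),
    _scenario(
        "probands_suspected_duplicates",
        {"PM2", "PS4_Supporting"},
        VUS,
        freq="pm2",
        probands=3,
        duplicate_last=True,
    ),
    # --- PP1 meiosis boundaries (PM2 met) ---
    _scenario("meioses_2", {"PM2"}, VUS, freq="pm2", meioses=[2]),
    _scenario("meioses_3", {"PM2", "PP1"}, VUS, freq="pm2", meioses=[3]),
    _scenario("meioses_4", {"PM2", "PP1"}, VUS, freq="pm2", meioses=[4]),
    _scenario("meioses_5", {"PM2", "PP1_Moderate"}, VUS, freq="pm2", meioses=[5]),
    _scenario("meioses_6", {"PM2", "PP1_Moderate"}, VUS, freq="pm2", meioses=[6]),
    _scenario(
        "meioses_7", {"PM2", "PP1_Strong"}, Tier.LIKELY_PATHOGENIC, freq="pm2", meioses=[7]
    ),
    _scenario("meioses_3_no_pm2", set(), VUS, freq="neutral", meioses=[3]),
    _scenario(
        "meioses_pooled_families", {"PM2", "PP1_Moderate"}, VUS, freq="pm2", meioses=[2, 3]
    ),
    _scenario(
        "nonsegregation_bs4", {"BS4"}, VUS, freq="neutral", meioses=[4], nonsegregation=True
    ),
    # --- de novo occurrences ---
    _scenario("denovo_paternity_confirmed", {"PS2"}, VUS, de_novo=[_denovo(True)]),
    _scenario("denovo_unconfirmed_1", {"PM6"}, VUS, de_novo=[_denovo(False)]),
    _scenario("denovo_unconfirmed_2", {"PM6"}, VUS, de_novo=[_denovo(False)] * 2),
    _scenario("denovo_unconfirmed_3_upgrade", {"PS2"}, VUS, de_novo=[_denovo(False)] * 3),
    _scenario(
        "denovo_disqualified_history", set(), VUS, de_novo=[_denovo(True, qualifying=False)]
    ),
    # --- head-domain (PM1) boundaries and LOF routing ---
    _scenario("pm1_inside_head", {"PM1"}, VUS, aa=500),
    _scenario("pm1_lower_boundary", {"PM1"}, VUS, aa=181),
    _scenario("pm1_below_boundary", set(), VUS, aa=180),
    _scenario("pm1_upper_boundary", {"PM1"}, VUS, aa=937),
    _scenario("pm1_above_boundary", set(), VUS, aa=938),
    _scenario(
        "lof_nonsense", {"PVS1_Moderate"}, VUS, consequence=Consequence.NONSENSE, aa=500
    ),
    _scenario(
        "lof_frameshift", {"PVS1_Moderate"}, VUS, consequence=Consequence.FRAMESHIFT, aa=700
    ),
    _scenario(
        "lof_splice", {"PVS1_Moderate"}, VUS, consequence=Consequence.CANONICAL_SPLICE, aa=None
    ),
    # --- functional assays ---
    _scenario(
        "functional_knockin_damaging",
        {"PS3"},
        VUS,
        functional=[FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.DAMAGING)],
    ),
    _scenario(
        "functional_knockin_benign",
        {"BS3"},
        VUS,
        functional=[FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.BENIGN)],
    ),
    _scenario(
        "functional_invitro_ignored",
        set(),
        VUS,
        functional=[FunctionalEvidence(AssayClass.IN_VITRO, AssayDirection.DAMAGING)],
    ),
    _scenario(
        "functional_transgenic_ignored",
        set(),
        VUS,
        functional=[FunctionalEvidence(AssayClass.TRANSGENIC_DOSAGE, AssayDirection.DAMAGING)],
    ),
    # --- annotation rules ---
    _scenario(
        "ps1_same_aa", {"PS1"}, VUS, annotations=AnnotationEvidence(same_aa_known_pathogenic=True)
    ),
    _scenario(
        "pm5_same_residue",
        {"PM5"},
        VUS,
        annotations=AnnotationEvidence(different_change_at_pathogenic_residue=True),
    ),
    _scenario("pm4_inframe", {"PM4"}, VUS, consequence=Consequence.INFRAME_INDEL, aa=1500),
    _scenario(
        "pm4_inframe_repeat",
        set(),
        VUS,
        consequence=Consequence.INFRAME_INDEL,
        aa=1500,
        in_repeat=True,
    ),
    _scenario("pm4_stop_loss", {"PM4"}, VUS, consequence=Consequence.STOP_LOSS, aa=1936),
    _scenario(
        "pp3_consensus",
        {"PP3"},
        VUS,
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.PATHOGENIC_SUPPORTING
        ),
    ),
    _scenario(
        "bp4_consensus",
        {"BP4"},
        VUS,
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.BENIGN_SUPPORTING
        ),
    ),
    _scenario(
        "bp2_in_trans",
        {"BP2"},
        VUS,
        annotations=AnnotationEvidence(in_trans_without_increased_severity=True),
    ),
    _scenario(
        "bp2_in_cis", {"BP2"}, VUS, annotations=AnnotationEvidence(in_cis_with_pathogenic=True)
    ),
    _scenario(
        "bp5_alternate_basis",
        {"BP5"},
        VUS,
        annotations=AnnotationEvidence(alternate_molecular_basis=True),
    ),
    _scenario(
        "bp7_synonymous",
        {"BP7"},
        VUS,
        consequence=Consequence.SYNONYMOUS,
        aa=600,
        annotations=AnnotationEvidence(splice_no_impact_not_conserved=True),
    ),
    _scenario(
        "bp7_requires_synonymous",
        set(),
        VUS,
        consequence=Consequence.MISSENSE,
        aa=1500,
        annotations=AnnotationEvidence(splice_no_impact_not_conserved=True),
    ),
    # --- combinations reaching each tier, and conflicts ---
    _scenario(
        "combo_pathogenic",
        {"PM2", "PS4", "PP1_Moderate", "PM1"},
        Tier.PATHOGENIC,
        freq="pm2",
        probands=15,
        meioses=[5],
        aa=500,
    ),
    _scenario(
        "combo_likely_pathogenic_denovo",
        {"PM2", "PS2", "PP1_Moderate"},
        Tier.LIKELY_PATHOGENIC,
        freq="pm2",
        meioses=[5],
        de_novo=[_denovo(True)],
    ),
    _scenario(
        "combo_likely_pathogenic_counts",
        {"PM2", "PS4_Moderate", "PP1", "PP3"},
        Tier.LIKELY_PATHOGENIC,
        freq="pm2",
        probands=11,
        meioses=[3],
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.PATHOGENIC_SUPPORTING
        ),
    ),
    _scenario(
        "combo_benign_two_strong",
        {"BS3", "BS4"},
        Tier.BENIGN,
        meioses=[4],
        nonsegregation=True,
        functional=[FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.BENIGN)],
    ),
    _scenario(
        "combo_likely_benign_strong_supporting",
        {"BS4", "BP4"},
        Tier.LIKELY_BENIGN,
        meioses=[2],
        nonsegregation=True,
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.BENIGN_SUPPORTING
        ),
    ),
    _scenario(
        "combo_likely_benign_two_supporting",
        {"BP4", "BP5"},
        Tier.LIKELY_BENIGN,
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.BENIGN_SUPPORTING,
            alternate_molecular_basis=True,
        ),
    ),
    _scenario(
        "conflict_pm2_vs_bs3",
        {"PM2", "BS3"},
        VUS,
        freq="pm2",
        functional=[FunctionalEvidence(AssayClass.MAMMALIAN_KNOCK_IN, AssayDirection.BENIGN)],
    ),
    _scenario(
        "conflict_bs1_vs_pp3",
        {"BS1", "PP3"},
        VUS,
        freq="bs1",
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.PATHOGENIC_SUPPORTING
        ),
    ),
    _scenario(
        "override_recorded",
        {"PM2", "PS4_Moderate", "PP3"},
        VUS,
        freq="pm2",
        probands=11,
        annotations=AnnotationEvidence(
            computational_consensus=ComputationalConsensus.PATHOGENIC_SUPPORTING
        ),
        override=ExpertOverride(
            classification=Tier.LIKELY_PATHOGENIC,
            justification="synthetic override: expert judgment upgrade",
        ),
    ),
    _scenario("no_evidence", set(), VUS, freq="none"),
]


@dataclass
class FixtureSet:
    seed: int
    bundles: list[EvidenceBundle] = field(default_factory=list)
    manifest: list[dict] = field(default_factory=list)


def generate_fixtures(
    seed: int, n_per_scenario: int = 1, out_dir: Optional[str | Path] = None
) -> FixtureSet:
    """Generate the scenario bundles and their expected-outcome manifest.

    With ``out_dir`` set, writes ``evidence.json`` (all bundles) and
    ``manifest.json`` (seed, intended rule sets and tiers); both are
    byte-identical across runs with the same seed.
    """
    rng = np.random.default_rng(seed)
    fixture = FixtureSet(seed=seed)
    for scenario in SCENARIOS:
        for k in range(n_per_scenario):
            bundle_id = scenario.name if n_per_scenario == 1 else f"{scenario.name}-r{k + 1}"
            bundle = scenario.build(rng, bundle_id)
            fixture.bundles.append(bundle)
            entry = {
                "bundle_id": bundle_id,
                "scenario": scenario.name,
                "intended_rules": sorted(scenario.intended_rules),
                "intended_tier": scenario.intended_tier.value,
            }
            if bundle.expert_override is not None:
                entry["intended_override"] = bundle.expert_override.classification.value
            fixture.manifest.append(entry)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        evidence_payload = {
            "schema_version": 1,
            "seed": seed,
            "bundles": [bundle_to_dict(b) for b in fixture.bundles],
        }
        (out / "evidence.json").write_text(
            json.dumps(evidence_payload, indent=2, sort_keys=True) + "\n"
        )
        (out / "manifest.json").write_text(
            json.dumps({"seed": seed, "bundles": fixture.manifest}, indent=2, sort_keys=True)
            + "\n"
        )
    return fixture
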