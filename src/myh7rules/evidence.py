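"""Structured evidence model for MYH7 variant classification.

All evidence consumed by the rules engine is *declarative*: every boolean
(e.g. "parents phenotype-negative after clinical evaluation") is a curator
assertion taken at face value, never inferred from free text. The engine's
sole input is an :class:`EvidenceBundle` aggregating population frequency
records, proband observations, family segregation records, de novo
observations, functional-assay annotations and in-silico/annotation
verdicts for one variant in one disease context (HCM, DCM or RCM).

Validation is total: :func:`validate_bundle` never raises on arbitrary
field values; it returns a list of :class:`Violation` naming the offending
field and record index, and an empty list iff every invariant holds.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Any, Optional

SCHEMA_VERSION = 1

DEFAULT_GENE = "MYH7"
DEFAULT_TRANSCRIPT = "NM_000257.3"


class Consequence(str, enum.Enum):
    """Molecular consequence classes recognised by the rule set."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical-splice"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "in-frame-indel"
    STOP_LOSS = "stop-loss"
    OTHER = "other"


#: Loss-of-function consequence classes routed to PVS1_Moderate.
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)


class Phenotype(str, enum.Enum):
    """Phenotype tags attached to case-level observations.

    ``DCM_WITH_PRIOR_HCM`` marks end-stage HCM that now presents as DCM:
    such cases count as HCM evidence because earlier clinical evidence
    supported the HCM phenotype. ``LVNC_ISOLATED`` (isolated left
    ventricular noncompaction, with no accompanying cardiomyopathy) is
    excluded from HCM and DCM evidence counts because the disease status
    of isolated LVNC is debated. Unknown tags map to ``OTHER`` on input
    and are never counted.
    """

    HCM = "HCM"
    DCM = "DCM"
    RCM = "RCM"
    LVNC_ISOLATED = "LVNC-isolated"
    DCM_WITH_PRIOR_HCM = "DCM-with-prior-HCM"
    OTHER = "other"


class DiseaseContext(str, enum.Enum):
    HCM = "HCM"
    DCM = "DCM"
    RCM = "RCM"


class ComputationalConsensus(str, enum.Enum):
    """Aggregate in-silico prediction verdict (curator-supplied)."""

    PATHOGENIC_SUPPORTING = "pathogenic-supporting"
    BENIGN_SUPPORTING = "benign-supporting"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


class AssayClass(str, enum.Enum):
    """Functional-assay classes; only variant-specific mammalian knock-in
    models carry strong weight (PS3/BS3)."""

    MAMMALIAN_KNOCK_IN = "mammalian-variant-specific-knock-in"
    TRANSGENIC_DOSAGE = "transgenic-dosage-model"
    KNOCKOUT = "knockout"
    IN_VITRO = "in-vitro"
    OTHER = "other"


class AssayDirection(str, enum.Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    INCONCLUSIVE = "inconclusive"


class Tier(str, enum.Enum):
    """Five-tier clinical classification."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely pathogenic"
    UNCERTAIN = "uncertain significance"
    LIKELY_BENIGN = "likely benign"
    BENIGN = "benign"


#: Benign-to-pathogenic ordering used by monotonicity checks and reports.
TIER_ORDER = [
    Tier.BENIGN,
    Tier.LIKELY_BENIGN,
    Tier.UNCERTAIN,
    Tier.LIKELY_PATHOGENIC,
    Tier.PATHOGENIC,
]


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass
class VariantIdentity:
    """Identity of the variant under curation.

    ``aa_position`` is the 1-based position on the protein (reference
    transcript NM_000257.3); absent for non-coding effects. It drives the
    PM1 critical-domain check (myosin head region, aa 181-937).
    """

    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER
    aa_position: Optional[int] = None
    in_repeat_region: bool = False
    gene: str = DEFAULT_GENE
    transcript: str = DEFAULT_TRANSCRIPT

    def label(self) -> str:
        return self.hgvs_p or self.hgvs_c or "<unnamed variant>"


@dataclass
class PopulationFrequencyRecord:
    """Allele count / allele number for one reference-population cohort.

    ``deeply_characterized`` marks populations where enough probands have
    been deeply analysed for the BS1 frequency threshold to be trusted
    (the BS1 safeguard); BS1 never fires on other populations.
    """

    population: str
    ac: int
    an: int
    deeply_characterized: bool = False


@dataclass
class ProbandObservation:
    """One independently ascertained index case carrying the variant.

    ``duplicate_of`` optionally names another proband identifier this
    record may duplicate (cases known or suspected to be part of more
    than one cohort); linked records count once.
    """

    proband_id: str
    cohort_id: str = ""
    phenotype: Phenotype = Phenotype.OTHER
    duplicate_of: Optional[str] = None


@dataclass
class SegregationRecord:
    """Co-segregation evidence from one family.

    Exactly one of ``meioses`` (a direct informative-meiosis count) or
    ``pedigree_ref`` (key of a parsed pedigree, see the PED reader) must
    be supplied. ``nonsegregation`` asserts that at least one affected
    noncarrier was observed in this family; such families contribute no
    meioses and raise BS4.
    """

    family_id: str
    meioses: Optional[int] = None
    pedigree_ref: Optional[str] = None
    nonsegregation: bool = False


@dataclass
class DeNovoObservation:
    """One documented de novo occurrence.

    All fields are mandatory curator assertions (no implicit defaults for
    evidence). Maternity confirmation is recorded for the audit trail but
    is not required by the rules: only paternity confirmation separates
    PS2 from PM6. ``family_history_negative`` asserts absence of disease
    or suspicious findings in a three-generation pedigree;
    ``parents_phenotype_negative`` asserts both parents are phenotype
    negative after thorough clinical evaluation (ECG plus echo or cardiac
    MRI).
    """

    paternity_confirmed: bool
    maternity_confirmed: bool
    parents_genotype_negative: bool
    parents_phenotype_negative: bool
    family_history_negative: bool


@dataclass
class FunctionalEvidence:
    assay_class: AssayClass
    direction: AssayDirection


@dataclass
class AnnotationEvidence:
    """Curator-asserted annotation facts feeding the lookup-style rules."""

    computational_consensus: ComputationalConsensus = ComputationalConsensus.ABSENT
    #: same amino-acid change as a known pathogenic variant via a different
    #: nucleotide change (PS1)
    same_aa_known_pathogenic: bool = False
    #: different missense change at a residue with an established
    #: pathogenic missense variant (PM5)
    different_change_at_pathogenic_residue: bool = False
    #: observed in trans / double het without increased severity (BP2)
    in_trans_without_increased_severity: bool = False
    #: observed in cis with a pathogenic variant (BP2)
    in_cis_with_pathogenic: bool = False
    #: carrier case has an alternate molecular basis for disease (BP5)
    alternate_molecular_basis: bool = False
    #: splice predictors see no impact and the nucleotide is not highly
    #: conserved (BP7; requires a synonymous variant)
    splice_no_impact_not_conserved: bool = False


@dataclass
class ExpertOverride:
    """Expert-panel override of the rule-based classification.

    Records the judgment without modeling it: reports always show both
    the rule-based tier and the override, clearly labelled.
    """

    classification: Tier
    justification: str = ""


@dataclass
class EvidenceBundle:
    """All evidence for one variant in one disease context."""

    variant: VariantIdentity
    disease_context: DiseaseContext
    population_frequencies: list[PopulationFrequencyRecord] = field(default_factory=list)
    probands: list[ProbandObservation] = field(default_factory=list)
    segregations: list[SegregationRecord] = field(default_factory=list)
    de_novo: list[DeNovoObservation] = field(default_factory=list)
    functional: list[FunctionalEvidence] = field(default_factory=list)
    annotations: AnnotationEvidence = field(default_factory=AnnotationEvidence)
    expert_override: Optional[ExpertOverride] = None
    bundle_id: str = ""
    schema_version: int = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    """One invariant violation, naming the field and record index."""

    field: str
    message: str
    index: Optional[int] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = self.field if self.index is None else f"{self.field}[{self.index}]"
        return f"{where}: {self.message}"


def _is_int(x: Any) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


def _is_bool(x: Any) -> bool:
    return isinstance(x, bool)


def _check_enum(value: Any, enum_cls: type[enum.Enum]) -> bool:
    return isinstance(value, enum_cls)


def validate_bundle(bundle: EvidenceBundle) -> list[Violation]:
    """Check every type invariant; return violations instead of raising.

    Total on arbitrary field values: wrong types are reported as
    violations, never propagated as exceptions.
    """
    v: list[Violation] = []

    var = getattr(bundle, "variant", None)
    if not isinstance(var, VariantIdentity):
        v.append(Violation("variant", "missing or not a VariantIdentity"))
    else:
        if not _check_enum(var.consequence, Consequence):
            v.append(Violation("variant.consequence", "not a recognised consequence class"))
        pos = var.aa_position
        if pos is not None and (not _is_int(pos) or pos < 1):
            v.append(Violation("variant.aa_position", "must be an integer >= 1 when present"))
        if not _is_bool(var.in_repeat_region):
            v.append(Violation("variant.in_repeat_region", "must be a boolean"))

    if not _check_enum(getattr(bundle, "disease_context", None), DiseaseContext):
        v.append(Violation("disease_context", "must be one of HCM, DCM, RCM"))

    for i, rec in enumerate(getattr(bundle, "population_frequencies", []) or []):
        if not isinstance(rec, PopulationFrequencyRecord):
            v.append(Violation("population_frequencies", "not a PopulationFrequencyRecord", i))
            continue
        if not _is_int(rec.an) or rec.an <= 0:
            v.append(Violation("population_frequencies.an", "AN must be a positive integer", i))
        if not _is_int(rec.ac) or rec.ac < 0:
            v.append(Violation("population_frequencies.ac", "AC must be a non-negative integer", i))
        elif _is_int(rec.an) and rec.an > 0 and rec.ac > rec.an:
            v.append(Violation("population_frequencies.ac", "AC must satisfy AC <= AN", i))

    for i, obs in enumerate(getattr(bundle, "probands", []) or []):
        if not isinstance(obs, ProbandObservation):
            v.append(Violation("probands", "not a ProbandObservation", i))
            continue
        if not _check_enum(obs.phenotype, Phenotype):
            v.append(Violation("probands.phenotype", "not a recognised phenotype tag", i))
        if not obs.proband_id:
            v.append(Violation("probands.proband_id", "must be non-empty", i))

    for i, seg in enumerate(getattr(bundle, "segregations", []) or []):
        if not isinstance(seg, SegregationRecord):
            v.append(Violation("segregations", "not a SegregationRecord", i))
            continue
        has_count = seg.meioses is not None
        has_ped = seg.pedigree_ref is not None
        if has_count == has_ped:
            v.append(
                Violation(
                    "segregations",
                    "exactly one of {meioses, pedigree_ref} must be supplied",
                    i,
                )
            )
        if has_count and (not _is_int(seg.meioses) or seg.meioses < 0):
            v.append(Violation("segregations.meioses", "must be a non-negative integer", i))
        if not _is_bool(seg.nonsegregation):
            v.append(Violation("segregations.nonsegregation", "must be a boolean", i))

    for i, dn in enumerate(getattr(bundle, "de_novo", []) or []):
        if not isinstance(dn, DeNovoObservation):
            v.append(Violation("de_novo", "not a DeNovoObservation", i))
            continue
        for name in (
            "paternity_confirmed",
            "maternity_confirmed",
            "parents_genotype_negative",
            "parents_phenotype_negative",
            "family_history_negative",
        ):
            if not _is_bool(getattr(dn, name, None)):
                v.append(Violation(f"de_novo.{name}", "must be explicitly set to a boolean", i))

    for i, fx in enumerate(getattr(bundle, "functional", []) or []):
        if not isinstance(fx, FunctionalEvidence):
            v.append(Violation("functional", "not a FunctionalEvidence", i))
            continue
        if not _check_enum(fx.assay_class, AssayClass):
            v.append(Violation("functional.assay_class", "not a recognised assay class", i))
        if not _check_enum(fx.direction, AssayDirection):
            v.append(Violation("functional.direction", "not a recognised direction", i))

    ann = getattr(bundle, "annotations", None)
    if not isinstance(ann, AnnotationEvidence):
        v.append(Violation("annotations", "missing or not an AnnotationEvidence"))
    else:
        if not _check_enum(ann.computational_consensus, ComputationalConsensus):
            v.append(Violation("annotations.computational_consensus", "not a recognised verdict"))
        for name in (
            "same_aa_known_pathogenic",
            "different_change_at_pathogenic_residue",
            "in_trans_without_increased_severity",
            "in_cis_with_pathogenic",
            "alternate_molecular_basis",
            "splice_no_impact_not_conserved",
        ):
            if not _is_bool(getattr(ann, name, None)):
                v.append(Violation(f"annotations.{name}", "must be explicitly set to a boolean"))

    ov = getattr(bundle, "expert_override", None)
    if ov is not None:
        if not isinstance(ov, ExpertOverride) or not _check_enum(ov.classification, Tier):
            v.append(Violation("expert_override", "override classification must be a valid tier"))

    return v


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def bundle_to_dict(bundle: EvidenceBundle) -> dict:
    """Serialize a bundle to plain JSON-compatible types."""
    d = asdict(bundle)

    def _conv(obj: Any) -> Any:
        if isinstance(obj, enum.Enum):
            return obj.value
        if isinstance(obj, dict):
            return {k: _conv(x) for k, x in obj.items()}
        if isinstance(obj, list):
            return [_conv(x) for x in obj]
        return obj

    return _conv(d)


def _enum_from(value: Any, enum_cls: type[enum.Enum], fallback: Any = None) -> Any:
    try:
        return enum_cls(value)
    except ValueError:
        return fallback if fallback is not None else value


def bundle_from_dict(d: dict) -> EvidenceBundle:
    """Reconstruct a bundle from its JSON form.

    Unknown phenotype tags map to ``other`` (conservatively excluded from
    all counting); other unknown enum values are preserved verbatim so
    that :func:`validate_bundle` reports them.
    """
    var = d.get("variant") or {}
    variant = VariantIdentity(
        hgvs_c=var.get("hgvs_c", ""),
        hgvs_p=var.get("hgvs_p", ""),
        consequence=_enum_from(var.get("consequence", "other"), Consequence),
        aa_position=var.get("aa_position"),
        in_repeat_region=var.get("in_repeat_region", False),
        gene=var.get("gene", DEFAULT_GENE),
        transcript=var.get("transcript", DEFAULT_TRANSCRIPT),
    )
    pops = [
        PopulationFrequencyRecord(
            population=p.get("population", ""),
            ac=p.get("ac"),
            an=p.get("an"),
            deeply_characterized=p.get("deeply_characterized", False),
        )
        for p in d.get("population_frequencies", [])
    ]
    probands = [
        ProbandObservation(
            proband_id=p.get("proband_id", ""),
            cohort_id=p.get("cohort_id", ""),
            phenotype=_enum_from(p.get("phenotype", "other"), Phenotype, Phenotype.OTHER),
            duplicate_of=p.get("duplicate_of"),
        )
        for p in d.get("probands", [])
    ]
    segs = [
        SegregationRecord(
            family_id=s.get("family_id", ""),
            meioses=s.get("meioses"),
            pedigree_ref=s.get("pedigree_ref"),
            nonsegregation=s.get("nonsegregation", False),
        )
        for s in d.get("segregations", [])
    ]
    denovo = [
        DeNovoObservation(
            paternity_confirmed=dn.get("paternity_confirmed"),
            maternity_confirmed=dn.get("maternity_confirmed"),
            parents_genotype_negative=dn.get("parents_genotype_negative"),
            parents_phenotype_negative=dn.get("parents_phenotype_negative"),
            family_history_negative=dn.get("family_history_negative"),
        )
        for dn in d.get("de_novo", [])
    ]
    functional = [
        FunctionalEvidence(
            assay_class=_enum_from(f.get("assay_class", "other"), AssayClass),
            direction=_enum_from(f.get("direction", "inconclusive"), AssayDirection),
        )
        for f in d.get("functional", [])
    ]
    a = d.get("annotations") or {}
    annotations = AnnotationEvidence(
        computational_consensus=_enum_from(
            a.get("computational_consensus", "absent"), ComputationalConsensus
        ),
        same_aa_known_pathogenic=a.get("same_aa_known_pathogenic", False),
        different_change_at_pathogenic_residue=a.get(
            "different_change_at_pathogenic_residue", False
        ),
        in_trans_without_increased_severity=a.get("in_trans_without_increased_severity", False),
        in_cis_with_pathogenic=a.get("in_cis_with_pathogenic", False),
        alternate_molecular_basis=a.get("alternate_molecular_basis", False),
        splice_no_impact_not_conserved=a.get("splice_no_impact_not_conserved", False),
    )
    ov = d.get("expert_override")
    override = (
        ExpertOverride(
            classification=_enum_from(ov.get("classification"), Tier),
            justification=ov.get("justification", ""),
        )
        if ov
        else None
    )
    return EvidenceBundle(
        variant=variant,
        disease_context=_enum_from(d.get("disease_context"), DiseaseContext),
        population_frequencies=pops,
        probands=probands,
        segregations=segs,
        de_novo=denovo,
        functional=functional,
        annotations=annotations,
        expert_override=override,
        bundle_id=d.get("bundle_id", ""),
        schema_version=d.get("schema_version", SCHEMA_VERSION),
    )


def bundle_to_json(bundle: EvidenceBundle, **kwargs: Any) -> str:
    kwargs.setdefault("indent", 2)
    kwargs.setdefault("sort_keys", True)
    return json.dumps(bundle_to_dict(bundle), **kwargs)


def bundle_from_json(text: str) -> EvidenceBundle:
    return bundle_from_dict(json.loads(text))
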