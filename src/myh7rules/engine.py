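"""Rule registry and per-criterion evaluation.

The registry is data, not logic: every ACMG/AMP criterion is a
:class:`RuleSpec` carrying its direction, strength as applied, MYH7
specification type (no-change / disease-gene / modified-strength /
removed) and gating requirements (PS4 and PP1 tiers require PM2).
Removed rules are registered for the audit trail but never evaluated.
:func:`evaluate_all` runs every evaluable criterion on an
:class:`~myh7rules.evidence.EvidenceBundle` and returns one
:class:`AppliedRule` per base criterion with a deterministic,
human-readable evidence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from . import cases, frequency
from .evidence import (
    LOF_CONSEQUENCES,
    AnnotationEvidence,
    AssayClass,
    AssayDirection,
    ComputationalConsensus,
    Consequence,
    EvidenceBundle,
    FunctionalEvidence,
    VariantIdentity,
    validate_bundle,
)

__all__ = [
    "RuleSpec",
    "AppliedRule",
    "Registry",
    "EngineConfig",
    "build_registry",
    "load_default_config",
    "evaluate_pm1",
    "evaluate_pvs1_moderate",
    "evaluate_functional",
    "evaluate_annotation_rules",
    "evaluate_all",
    "RuleEvaluationError",
]

STRENGTHS = ("standalone", "very-strong", "strong", "moderate", "supporting")
SPECIFICATION_TYPES = ("no-change", "disease-gene", "modified-strength", "removed")

#: Default strength implied by a code prefix when no suffix modifies it.
_PREFIX_STRENGTH = {
    "PVS": "very-strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "standalone",
    "BS": "strong",
    "BP": "supporting",
}
_SUFFIX_STRENGTH = {
    "_Strong": "strong",
    "_Moderate": "moderate",
    "_Supporting": "supporting",
}


def _expected_strength(code: str) -> Optional[str]:
    for suffix, strength in _SUFFIX_STRENGTH.items():
        if code.endswith(suffix):
            return strength
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_STRENGTH[prefix]
    return None


class RuleEvaluationError(ValueError):
    """Input error raised by a sub-evaluator, tagged with the rule code."""


@dataclass
class RuleSpec:
    code: str
    direction: str  # pathogenic | benign
    strength: str
    specification: str
    base: str = ""
    gating: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        self.base = self.base or self.code
        if self.direction not in ("pathogenic", "benign"):
            raise ValueError(f"{self.code}: bad direction {self.direction!r}")
        if self.strength not in STRENGTHS:
            raise ValueError(f"{self.code}: bad strength {self.strength!r}")
        if self.specification not in SPECIFICATION_TYPES:
            raise ValueError(f"{self.code}: bad specification {self.specification!r}")
        expected = _expected_strength(self.code)
        if expected is not None and expected != self.strength:
            raise ValueError(
                f"{self.code}: strength {self.strength!r} inconsistent with code (expected {expected!r})"
            )


@dataclass
class AppliedRule:
    """Evaluated activation of one criterion."""

    code: str
    base: str
    direction: str
    strength: str
    met: bool
    summary: str = ""
    inputs: dict = field(default_factory=dict)


class Registry:
    """Ordered collection of rule specifications."""

    def __init__(self, specs: Iterable[RuleSpec]):
        self.specs: dict[str, RuleSpec] = {}
        for spec in specs:
            if spec.code in self.specs:
                raise ValueError(f"duplicate rule code {spec.code!r}")
            self.specs[spec.code] = spec
        for spec in self.specs.values():
            for gate in spec.gating:
                if gate not in self.specs:
                    raise ValueError(f"{spec.code}: unknown gating rule {gate!r}")
            if spec.specification == "removed" and spec.base != spec.code:
                raise ValueError(f"{spec.code}: removed rules must be base rules")

    def __getitem__(self, code: str) -> RuleSpec:
        return self.specs[code]

    def __contains__(self, code: str) -> bool:
        return code in self.specs

    def base_rules(self) -> list[RuleSpec]:
        return [s for s in self.specs.values() if s.base == s.code]

    def audit(self) -> dict[str, int]:
        """Counts by specification type over base rules, plus the
        modified-strength additions."""
        base = self.base_rules()
        return {
            "base_rules": len(base),
            "removed": sum(s.specification == "removed" for s in base),
            "disease_gene": sum(s.specification == "disease-gene" for s in base),
            "no_change": sum(s.specification == "no-change" for s in base),
            "modified_strength": sum(
                s.specification == "modified-strength" for s in self.specs.values()
            ),
        }

    def to_yaml(self) -> str:
        rows = []
        for s in self.specs.values():
            row = {
                "code": s.code,
                "direction": s.direction,
                "strength": s.strength,
                "specification": s.specification,
                "description": s.description,
            }
            if s.base != s.code:
                row["base"] = s.base
            if s.gating:
                row["gating"] = list(s.gating)
            rows.append(row)
        return yaml.safe_dump({"rules": rows}, sort_keys=False)


def build_registry(config: Optional[dict] = None) -> Registry:
    """Build the rule registry from a mapping (default: shipped MYH7 set)."""
    if config is None:
        text = resources.files("myh7rules.data").joinpath("registry.yaml").read_text()
        config = yaml.safe_load(text)
    specs = [
        RuleSpec(
            code=row["code"],
            direction=row["direction"],
            strength=row["strength"],
            specification=row["specification"],
            base=row.get("base", ""),
            gating=tuple(row.get("gating", ())),
            description=row.get("description", ""),
        )
        for row in config["rules"]
    ]
    return Registry(specs)


@dataclass
class EngineConfig:
    """Everything the engine needs: thresholds, registry, cohort model."""

    frequency: frequency.FrequencyRuleConfig = field(
        default_factory=frequency.FrequencyRuleConfig
    )
    derivation: dict[str, frequency.ThresholdDerivationParams] = field(default_factory=dict)
    ps4_thresholds: tuple[int, int, int] = cases.PS4_THRESHOLDS
    pp1_thresholds: tuple[int, int, int] = cases.PP1_THRESHOLDS
    de_novo_strong_count: int = cases.DE_NOVO_STRONG_COUNT
    pm1_range: tuple[int, int] = (181, 937)
    registry: Registry = field(default_factory=build_registry)
    cohort_model: Optional[cases.CohortModel] = None


def load_default_config() -> EngineConfig:
    """Load the shipped MYH7 defaults (thresholds, registry, cohorts)."""
    data = resources.files("myh7rules.data")
    th = yaml.safe_load(data.joinpath("thresholds.yaml").read_text())
    co = yaml.safe_load(data.joinpath("cohorts.yaml").read_text())
    freq = th.get("frequency", {})
    ce = th.get("case_evidence", {})
    dom = th.get("domain", {})
    return EngineConfig(
        frequency=frequency.FrequencyRuleConfig(
            ba1=float(freq.get("ba1", 1e-3)),
            bs1=float(freq.get("bs1", 2e-4)),
            pm2=float(freq.get("pm2", 4e-5)),
            confidence=float(freq.get("confidence", 0.95)),
            min_an=int(freq.get("min_an", 2000)),
            method=freq.get("method", "poisson"),
            bs1_eligible_populations=tuple(freq.get("bs1_eligible_populations", ())),
        ),
        derivation={
            code: frequency.ThresholdDerivationParams(
                prevalence=float(p["prevalence"]),
                contribution=float(p["contribution"]),
                penetrance=float(p["penetrance"]),
            )
            for code, p in th.get("derivation", {}).items()
        },
        ps4_thresholds=tuple(ce.get("ps4_thresholds", cases.PS4_THRESHOLDS)),
        pp1_thresholds=tuple(ce.get("pp1_thresholds", cases.PP1_THRESHOLDS)),
        de_novo_strong_count=int(ce.get("de_novo_strong_count", 3)),
        pm1_range=(int(dom.get("pm1_start", 181)), int(dom.get("pm1_end", 937))),
        registry=build_registry(),
        cohort_model=cases.CohortModel(
            ancestries={
                label: cases.CohortSizes(cases=int(v["cases"]), controls=int(v["controls"]))
                for label, v in co.get("ancestries", {}).items()
            },
            assumed_control_carriers=int(co.get("assumed_control_carriers", 2)),
        ),
    )


# ---------------------------------------------------------------------------
# Individual evaluators
# ---------------------------------------------------------------------------


def _applied(registry: Registry, code: str, met: bool, summary: str, **inputs) -> AppliedRule:
    spec = registry[code]
    return AppliedRule(
        code=code,
        base=spec.base,
        direction=spec.direction,
        strength=spec.strength,
        met=met,
        summary=summary,
        inputs=inputs,
    )


def evaluate_pm1(
    variant: VariantIdentity,
    registry: Optional[Registry] = None,
    domain: tuple[int, int] = (181, 937),
) -> AppliedRule:
    """PM1: missense variant in the myosin head domain (aa 181-937).

    Restricted to missense because missense variants are the predominant
    pathogenic class in this gene; truncating variants route to
    PVS1_Moderate instead, avoiding double counting.
    """
    registry = registry or build_registry()
    lo, hi = domain
    pos = variant.aa_position
    met = (
        variant.consequence == Consequence.MISSENSE
        and pos is not None
        and lo <= pos <= hi
    )
    summary = (
        f"missense at aa {pos} within head domain {lo}-{hi}"
        if met
        else f"consequence {getattr(variant.consequence, 'value', variant.consequence)} at aa {pos} outside head-domain criterion"
    )
    return _applied(registry, "PM1", met, summary, aa_position=pos, domain=list(domain))


def evaluate_pvs1_moderate(
    variant: VariantIdentity, registry: Optional[Registry] = None
) -> AppliedRule:
    """PVS1_Moderate: loss-of-function variant at moderate weight."""
    registry = registry or build_registry()
    met = variant.consequence in LOF_CONSEQUENCES
    summary = (
        f"loss-of-function consequence ({variant.consequence.value}) at moderate weight"
        if met
        else "not a loss-of-function consequence"
    )
    return _applied(
        registry,
        "PVS1_Moderate",
        met,
        summary,
        consequence=getattr(variant.consequence, "value", str(variant.consequence)),
    )


def evaluate_functional(
    evidence: list[FunctionalEvidence], registry: Optional[Registry] = None
) -> tuple[AppliedRule, AppliedRule]:
    """PS3/BS3: only mammalian variant-specific knock-in models qualify."""
    registry = registry or build_registry()
    knockin = [e for e in evidence if e.assay_class == AssayClass.MAMMALIAN_KNOCK_IN]
    ps3 = any(e.direction == AssayDirection.DAMAGING for e in knockin)
    bs3 = any(e.direction == AssayDirection.BENIGN for e in knockin)
    other = len(evidence) - len(knockin)
    note = f"; {other} non-qualifying assay(s) ignored" if other else ""
    ps3_summary = ("mammalian knock-in model, damaging" if ps3 else "no qualifying damaging knock-in evidence") + note
    bs3_summary = ("mammalian knock-in model, no damaging effect" if bs3 else "no qualifying benign knock-in evidence") + note
    return (
        _applied(registry, "PS3", ps3, ps3_summary, n_assays=len(evidence)),
        _applied(registry, "BS3", bs3, bs3_summary, n_assays=len(evidence)),
    )


def evaluate_annotation_rules(
    annotation: AnnotationEvidence,
    variant: VariantIdentity,
    registry: Optional[Registry] = None,
) -> list[AppliedRule]:
    """Lookup-style rules: PS1, PM4, PM5, PP3, BP2, BP4, BP5, BP7."""
    registry = registry or build_registry()
    out: list[AppliedRule] = []
    out.append(
        _applied(
            registry,
            "PS1",
            annotation.same_aa_known_pathogenic,
            "same amino acid change as a known pathogenic variant"
            if annotation.same_aa_known_pathogenic
            else "no matching known pathogenic amino acid change",
        )
    )
    pm4 = (
        variant.consequence == Consequence.INFRAME_INDEL and not variant.in_repeat_region
    ) or variant.consequence == Consequence.STOP_LOSS
    out.append(
        _applied(
            registry,
            "PM4",
            pm4,
            "protein-length change (in-frame indel in non-repeat region or stop-loss)"
            if pm4
            else "no qualifying protein-length change",
            consequence=getattr(variant.consequence, "value", str(variant.consequence)),
            in_repeat_region=variant.in_repeat_region,
        )
    )
    out.append(
        _applied(
            registry,
            "PM5",
            annotation.different_change_at_pathogenic_residue,
            "different missense change at a residue with an established pathogenic variant"
            if annotation.different_change_at_pathogenic_residue
            else "no known pathogenic missense at this residue",
        )
    )
    consensus = annotation.computational_consensus
    out.append(
        _applied(
            registry,
            "PP3",
            consensus == ComputationalConsensus.PATHOGENIC_SUPPORTING,
            f"computational consensus: {getattr(consensus, 'value', consensus)}",
        )
    )
    bp2 = annotation.in_trans_without_increased_severity or annotation.in_cis_with_pathogenic
    out.append(
        _applied(
            registry,
            "BP2",
            bp2,
            "observed in trans/double het without increased severity or in cis with a pathogenic variant"
            if bp2
            else "no qualifying trans/cis observation",
        )
    )
    out.append(
        _applied(
            registry,
            "BP4",
            consensus == ComputationalConsensus.BENIGN_SUPPORTING,
            f"computational consensus: {getattr(consensus, 'value', consensus)}",
        )
    )
    out.append(
        _applied(
            registry,
            "BP5",
            annotation.alternate_molecular_basis,
            "alternate molecular basis for disease in a carrier case"
            if annotation.alternate_molecular_basis
            else "no alternate molecular basis reported",
        )
    )
    bp7 = (
        variant.consequence == Consequence.SYNONYMOUS
        and annotation.splice_no_impact_not_conserved
    )
    out.append(
        _applied(
            registry,
            "BP7",
            bp7,
            "synonymous variant, no predicted splice impact, nucleotide not conserved"
            if bp7
            else "BP7 requires a synonymous variant with asserted splice/conservation evidence",
            consequence=getattr(variant.consequence, "value", str(variant.consequence)),
        )
    )
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def evaluate_all(
    bundle: EvidenceBundle,
    config: Optional[EngineConfig] = None,
    pedigrees: Optional[Mapping[str, cases.Pedigree]] = None,
) -> list[AppliedRule]:
    """Evaluate every applicable criterion on a validated bundle.

    Frequency rules run first so that PM2 gating for PS4 and PP1 is
    resolved before case-level evidence is tiered. Removed rules are
    never evaluated and never appear in the output. The result is
    deterministic for identical input.
    """
    config = config or load_default_config()
    registry = config.registry
    violations = validate_bundle(bundle)
    if violations:
        raise ValueError(
            "bundle does not validate: " + "; ".join(str(v) for v in violations)
        )

    applied: list[AppliedRule] = []

    # --- frequency rules (BA1 / BS1 / PM2), resolving the PM2 gate ---
    if bundle.population_frequencies:
        freq = frequency.evaluate_frequency_rules(
            bundle.population_frequencies, config.frequency
        )
    else:
        freq = frequency.FrequencyOutcome(rule=None)
    pm2_met = freq.rule == "PM2"
    faf_desc = (
        f"max filtering AF {freq.max_faf:.3g} in {freq.max_faf_population}"
        if freq.max_faf is not None
        else ("no population passed the minimum-AN gate" if freq.low_an_warning else "no population data")
    )
    for code in ("BA1", "BS1", "PM2"):
        applied.append(
            _applied(
                registry,
                code,
                freq.rule == code,
                faf_desc,
                faf_by_population={k: float(v) for k, v in sorted(freq.faf_by_population.items())},
                low_an_warning=freq.low_an_warning,
            )
        )

    # --- PS4 tiers from eligible proband count (PM2-gated) ---
    count, proband_trace = cases.count_eligible_probands(
        bundle.probands, bundle.disease_context
    )
    ps4_code = cases.tier_ps4(count, pm2_met, config.ps4_thresholds)
    ps4_inputs: dict = {"eligible_probands": count, "pm2_met": pm2_met, "trace": proband_trace}
    if config.cohort_model is not None and count > 0:
        stats_by_ancestry = {}
        for label in sorted(config.cohort_model.ancestries):
            try:
                res = cases.quasi_case_control(count, config.cohort_model, label)
            except ValueError:
                continue
            stats_by_ancestry[label] = {
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        ps4_inputs["quasi_case_control"] = stats_by_ancestry
    applied.append(
        _applied(
            registry,
            ps4_code or "PS4",
            ps4_code is not None,
            f"{count} eligible proband(s); PM2 {'met' if pm2_met else 'not met'}",
            **ps4_inputs,
        )
    )

    # --- PP1 tiers and BS4 from segregation (PM2-gated) ---
    try:
        seg = cases.count_informative_meioses(bundle.segregations, pedigrees)
    except (cases.PedigreeError, ValueError) as exc:
        raise RuleEvaluationError(f"PP1/BS4: {exc}") from exc
    pp1_code, bs4 = cases.tier_pp1(seg, pm2_met, config.pp1_thresholds)
    applied.append(
        _applied(
            registry,
            pp1_code or "PP1",
            pp1_code is not None,
            f"{seg.meioses} informative meioses (LOD {seg.lod:.2f}); PM2 {'met' if pm2_met else 'not met'}"
            + ("; nonsegregation observed" if seg.nonsegregation else ""),
            meioses=seg.meioses,
            lod=seg.lod,
            per_family=seg.per_family,
            pm2_met=pm2_met,
        )
    )
    applied.append(
        _applied(
            registry,
            "BS4",
            bs4,
            "affected noncarrier observed (nonsegregation)"
            if bs4
            else "no nonsegregation observed",
        )
    )

    # --- de novo (PS2 / PM6, mutually exclusive) ---
    dn_code = cases.evaluate_de_novo(bundle.de_novo, config.de_novo_strong_count)
    n_dn = len(bundle.de_novo)
    applied.append(
        _applied(
            registry,
            "PS2",
            dn_code == "PS2",
            f"{n_dn} de novo observation(s); qualifies at strong"
            if dn_code == "PS2"
            else f"{n_dn} de novo observation(s); strong criteria not met",
            n_observations=n_dn,
        )
    )
    applied.append(
        _applied(
            registry,
            "PM6",
            dn_code == "PM6",
            "qualifying de novo occurrence without confirmed paternity"
            if dn_code == "PM6"
            else "no qualifying unconfirmed de novo occurrence",
            n_observations=n_dn,
        )
    )

    # --- domain, LOF, functional, annotation rules ---
    applied.append(evaluate_pm1(bundle.variant, registry, config.pm1_range))
    applied.append(evaluate_pvs1_moderate(bundle.variant, registry))
    applied.extend(evaluate_functional(bundle.functional, registry))
    applied.extend(evaluate_annotation_rules(bundle.annotations, bundle.variant, registry))

    order = {code: i for i, code in enumerate(registry.specs)}
    applied.sort(key=lambda r: order.get(r.code, len(order)))
    return applied
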