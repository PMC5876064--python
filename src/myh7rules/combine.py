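"""Evidence combination: applied rules -> five-tier classification.

Implements the parent ACMG/AMP combining table over strengths *as
applied* (a criterion applied at modified strength counts at that
strength), with the expert-panel modifications: BA1 is standalone and
absolute, and BS1 alone -- with no pathogenic-direction rule met --
suffices for likely benign. Mixed-direction evidence resolves to
uncertain significance with a conflict flag so curators see it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .evidence import EvidenceBundle, ExpertOverride, Tier
from .engine import AppliedRule, EngineConfig, evaluate_all, load_default_config

__all__ = ["Classification", "VariantReport", "combine", "classify_bundle"]


@dataclass
class Classification:
    tier: Tier
    criterion: str
    conflict: bool
    rules: list[AppliedRule] = field(default_factory=list)

    def met_codes(self) -> list[str]:
        return [r.code for r in self.rules if r.met]


def _tally(rules: list[AppliedRule], direction: str) -> dict[str, int]:
    counts = {"standalone": 0, "very-strong": 0, "strong": 0, "moderate": 0, "supporting": 0}
    for r in rules:
        if r.direction == direction:
            counts[r.strength] += 1
    return counts


def combine(rules: Iterable[AppliedRule]) -> Classification:
    """Combine met rules into a five-tier classification.

    Pathogenic requires one of: 1 very-strong with (>=1 strong | >=2
    moderate | 1 moderate + 1 supporting | >=2 supporting); >=2 strong;
    or 1 strong with (>=3 moderate | >=2 moderate + >=2 supporting |
    >=1 moderate + >=4 supporting). Likely pathogenic: 1 very-strong +
    >=1 moderate; 1 strong + >=1 moderate; 1 strong + >=2 supporting;
    >=3 moderate; >=2 moderate + >=2 supporting; >=1 moderate + >=4
    supporting. Benign: BA1 standalone, or >=2 strong benign. Likely
    benign: 1 strong benign + >=1 supporting benign; >=2 supporting
    benign; or BS1 alone with no pathogenic-direction rule met.
    """
    all_rules = list(rules)
    met = [r for r in all_rules if r.met]
    bases = [r.base for r in met]
    if len(bases) != len(set(bases)):
        dup = sorted({b for b in bases if bases.count(b) > 1})
        raise ValueError(f"duplicate base rule codes in met set: {', '.join(dup)}")

    path = [r for r in met if r.direction == "pathogenic"]
    benign = [r for r in met if r.direction == "benign"]
    p = _tally(met, "pathogenic")
    b = _tally(met, "benign")

    def result(tier: Tier, criterion: str, conflict: bool = False) -> Classification:
        return Classification(tier=tier, criterion=criterion, conflict=conflict, rules=all_rules)

    if b["standalone"] >= 1:
        return result(Tier.BENIGN, "BA1 standalone", conflict=bool(path))

    if path and benign:
        return result(
            Tier.UNCERTAIN, "conflicting pathogenic and benign evidence", conflict=True
        )

    if benign:
        if b["strong"] >= 2:
            return result(Tier.BENIGN, ">=2 strong benign")
        if b["strong"] >= 1 and b["supporting"] >= 1:
            return result(Tier.LIKELY_BENIGN, "1 strong + >=1 supporting benign")
        if b["supporting"] >= 2:
            return result(Tier.LIKELY_BENIGN, ">=2 supporting benign")
        if len(benign) == 1 and benign[0].code == "BS1":
            return result(Tier.LIKELY_BENIGN, "BS1 alone, no conflicting information")
        return result(Tier.UNCERTAIN, "insufficient benign evidence")

    vs, s, m, sup = p["very-strong"], p["strong"], p["moderate"], p["supporting"]
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and sup >= 1) or sup >= 2):
        return result(Tier.PATHOGENIC, "very-strong combination")
    if s >= 2:
        return result(Tier.PATHOGENIC, ">=2 strong pathogenic")
    if s >= 1 and (m >= 3 or (m >= 2 and sup >= 2) or (m >= 1 and sup >= 4)):
        return result(Tier.PATHOGENIC, "1 strong + moderate/supporting combination")
    if vs >= 1 and m >= 1:
        return result(Tier.LIKELY_PATHOGENIC, "1 very-strong + 1 moderate")
    if s >= 1 and (m >= 1 or sup >= 2):
        return result(Tier.LIKELY_PATHOGENIC, "1 strong + moderate/supporting combination")
    if m >= 3 or (m >= 2 and sup >= 2) or (m >= 1 and sup >= 4):
        return result(Tier.LIKELY_PATHOGENIC, "moderate/supporting combination")
    if met:
        return result(Tier.UNCERTAIN, "criteria not met for any stronger tier")
    return result(Tier.UNCERTAIN, "no criteria met")


@dataclass
class VariantReport:
    """Rule-based classification plus any recorded expert override.

    The override never alters the rule-based tier: both are carried,
    clearly labelled, and ``final_tier`` applies the override when set.
    """

    variant_label: str
    disease_context: str
    classification: Classification
    override: Optional[ExpertOverride] = None
    bundle_id: str = ""

    @property
    def final_tier(self) -> Tier:
        if self.override is not None:
            return self.override.classification
        return self.classification.tier


def classify_bundle(
    bundle: EvidenceBundle,
    config: Optional[EngineConfig] = None,
    pedigrees: Optional[Mapping] = None,
) -> VariantReport:
    """Evaluate all rules and combine them; report overrides alongside."""
    config = config or load_default_config()
    applied = evaluate_all(bundle, config, pedigrees)
    classification = combine(applied)
    return VariantReport(
        variant_label=bundle.variant.label(),
        disease_context=getattr(bundle.disease_context, "value", str(bundle.disease_context)),
        classification=classification,
        override=bundle.expert_override,
        bundle_id=bundle.bundle_id,
    )
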