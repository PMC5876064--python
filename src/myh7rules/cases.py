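"""Case-level evidence: proband counting (PS4), segregation (PP1/BS4),
de novo occurrences (PS2/PM6) and the quasi case-control statistic.

The proband rules use conservative universal count thresholds (>= 2
supporting, >= 6 moderate, >= 15 strong) calibrated against likelihood-
ratio targets of 10/30/100 in a "quasi case-control" design that pools
probands across studies against large reference cohorts standing in for
healthy controls. Segregation uses the autosomal-dominant simplification
LOD = n * log10(2) over informative meioses between affected carriers,
with the same 10/30/100 likelihood-ratio targets (3/5/7 meioses). Both
families of rules are gated on PM2: enrichment and segregation only
count for variants absent or extremely rare in population databases.
Segregation from a single family is sufficient (the multi-family
recommendation of the parent framework is waived for this gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
from scipy import stats

from .evidence import (
    DeNovoObservation,
    DiseaseContext,
    Phenotype,
    ProbandObservation,
    SegregationRecord,
)

__all__ = [
    "CohortSizes",
    "CohortModel",
    "CaseControlResult",
    "SegregationEvidence",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "count_eligible_probands",
    "quasi_case_control",
    "tier_ps4",
    "count_informative_meioses",
    "lod_score",
    "tier_pp1",
    "evaluate_de_novo",
    "PS4_THRESHOLDS",
    "PP1_THRESHOLDS",
]

#: Minimum proband counts for PS4 at supporting / moderate / strong.
PS4_THRESHOLDS = (2, 6, 15)
#: Minimum informative meioses for PP1 at supporting / moderate / strong.
PP1_THRESHOLDS = (3, 5, 7)
#: Qualifying de novo occurrences that upgrade PM6 to PS2 without
#: paternity confirmation.
DE_NOVO_STRONG_COUNT = 3

#: Phenotype tags counted as evidence in each disease context. Isolated
#: LVNC is excluded in the HCM and DCM contexts; plain DCM is excluded
#: from HCM counts unless earlier clinical evidence supported HCM
#: (the DCM-with-prior-HCM tag).
ELIGIBLE_PHENOTYPES: dict[DiseaseContext, frozenset[Phenotype]] = {
    DiseaseContext.HCM: frozenset({Phenotype.HCM, Phenotype.DCM_WITH_PRIOR_HCM}),
    DiseaseContext.DCM: frozenset({Phenotype.DCM, Phenotype.DCM_WITH_PRIOR_HCM}),
    DiseaseContext.RCM: frozenset({Phenotype.RCM}),
}


# ---------------------------------------------------------------------------
# Proband counting and PS4
# ---------------------------------------------------------------------------


def count_eligible_probands(
    observations: Iterable[ProbandObservation], context: DiseaseContext
) -> tuple[int, list[dict]]:
    """Count independent probands eligible as evidence in ``context``.

    Phenotype filtering happens first; surviving observations are then
    collapsed into identity clusters via shared proband identifiers and
    ``duplicate_of`` links (cases known or suspected to appear in more
    than one cohort count once). Returns the cluster count and a
    per-observation trace recording eligibility, the reason for any
    exclusion, and the cluster representative.
    """
    eligible_tags = ELIGIBLE_PHENOTYPES[DiseaseContext(context)]
    trace: list[dict] = []
    kept: list[ProbandObservation] = []
    for obs in observations:
        entry = {
            "proband_id": obs.proband_id,
            "phenotype": obs.phenotype.value if isinstance(obs.phenotype, Phenotype) else str(obs.phenotype),
            "eligible": False,
            "reason": "",
            "cluster": None,
        }
        if obs.phenotype not in eligible_tags:
            if obs.phenotype == Phenotype.LVNC_ISOLATED:
                entry["reason"] = "isolated LVNC excluded from proband counts"
            elif obs.phenotype == Phenotype.DCM and context == DiseaseContext.HCM:
                entry["reason"] = "DCM case not counted for HCM without prior HCM evidence"
            else:
                entry["reason"] = f"phenotype not consistent with {DiseaseContext(context).value}"
        else:
            entry["eligible"] = True
            kept.append(obs)
        trace.append(entry)

    # union-find over proband ids and duplicate links
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for obs in kept:
        find(obs.proband_id)
        if obs.duplicate_of:
            union(obs.proband_id, obs.duplicate_of)

    clusters = {find(obs.proband_id) for obs in kept}
    by_id = {e["proband_id"]: e for e in trace}
    for obs in kept:
        by_id[obs.proband_id]["cluster"] = find(obs.proband_id)
    return len(clusters), trace


@dataclass
class CohortSizes:
    cases: int
    controls: int

    def __post_init__(self) -> None:
        if self.cases <= 0 or self.controls <= 0:
            raise ValueError("cohort sizes must be positive")


@dataclass
class CohortModel:
    """Case and control (reference-cohort proxy) sizes per ancestry.

    ``assumed_control_carriers`` is the carrier count assumed in controls
    when PM2 is met (absence / extreme rarity); the shipped default of 2
    reproduces the conventional conservative assumption.
    """

    ancestries: dict[str, CohortSizes] = field(default_factory=dict)
    assumed_control_carriers: int = 2

    def __post_init__(self) -> None:
        if self.assumed_control_carriers < 0:
            raise ValueError("assumed_control_carriers must be non-negative")


def default_cohort_model() -> CohortModel:
    """Illustrative default cohorts for the two main ancestries.

    Control sizes are the ExAC non-Finnish European and African cohorts;
    case sizes are illustrative pooled proband cohorts of the same order
    used to calibrate the count thresholds.
    """
    return CohortModel(
        ancestries={
            "NFE": CohortSizes(cases=2500, controls=33370),
            "AFR": CohortSizes(cases=500, controls=5203),
        },
        assumed_control_carriers=2,
    )


@dataclass
class CaseControlResult:
    """Fisher's exact test on the carrier-by-cohort 2x2 table."""

    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def quasi_case_control(
    case_carriers: int, cohorts: CohortModel, ancestry: str
) -> CaseControlResult:
    """Two-sided Fisher's exact test of carrier enrichment in cases.

    Builds the 2x2 table [[case carriers, case non-carriers],
    [control carriers, control non-carriers]] from the ancestry's cohort
    sizes and the assumed control carrier count. The two-sided p-value
    follows the standard convention (sum of the probabilities of all
    tables with fixed margins no more probable than the observed one).
    The sample odds ratio is +inf when controls carry no alleles but
    cases do, and reported as 1 for the empty (0 carriers anywhere)
    table by convention.
    """
    if ancestry not in cohorts.ancestries:
        raise ValueError(f"unknown ancestry label: {ancestry!r}")
    sizes = cohorts.ancestries[ancestry]
    if case_carriers < 0 or case_carriers > sizes.cases:
        raise ValueError("case_carriers must be between 0 and the case cohort size")
    a = case_carriers
    b = sizes.cases - a
    c = cohorts.assumed_control_carriers
    d = sizes.controls - c
    if d < 0:
        raise ValueError("assumed control carriers exceed the control cohort size")
    table = ((a, b), (c, d))
    if a == 0 and c == 0:
        return CaseControlResult(odds_ratio=1.0, p_value=1.0, table=table)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if a * d == 0 and b * c == 0:
        oratio = 1.0
    elif b * c == 0:
        oratio = math.inf
    else:
        oratio = (a * d) / (b * c)
    return CaseControlResult(odds_ratio=oratio, p_value=float(p), table=table)


def tier_ps4(
    proband_count: int,
    pm2_met: bool,
    thresholds: tuple[int, int, int] = PS4_THRESHOLDS,
) -> Optional[str]:
    """PS4 tier from the eligible proband count; requires PM2."""
    if proband_count < 0:
        raise ValueError("proband count must be non-negative")
    if not pm2_met:
        return None
    supporting, moderate, strong = thresholds
    if proband_count >= strong:
        return "PS4"
    if proband_count >= moderate:
        return "PS4_Moderate"
    if proband_count >= supporting:
        return "PS4_Supporting"
    return None


# ---------------------------------------------------------------------------
# Segregation: pedigrees, meiosis counting, LOD, PP1/BS4
# ---------------------------------------------------------------------------


class PedigreeError(ValueError):
    """Malformed pedigree: unknown parent reference or ancestry cycle."""


@dataclass
class Individual:
    iid: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: int = 0
    affected: Optional[bool] = None  # None = unknown affection status
    carrier: Optional[bool] = None  # None = ungenotyped


@dataclass
class Pedigree:
    family_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)

    def validate(self) -> None:
        dg = nx.DiGraph()
        for iid, ind in self.individuals.items():
            dg.add_node(iid)
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise PedigreeError(
                        f"family {self.family_id}: unknown parent {parent!r} of {iid!r}"
                    )
                dg.add_edge(parent, iid)
        if not nx.is_directed_acyclic_graph(dg):
            raise PedigreeError(f"family {self.family_id}: pedigree contains a cycle")


def _pedigree_meioses(ped: Pedigree) -> tuple[int, bool]:
    """Informative meioses and nonsegregation flag for one family.

    An affected noncarrier anywhere in the family indicates
    nonsegregation; such families contribute no meioses. Otherwise the
    informative meioses are the parent->child transmission edges on the
    minimal subgraph connecting all affected carriers: unaffected or
    ungenotyped connectors are traversed but contribute no evidence
    endpoints, and known noncarriers cannot transmit the variant and are
    excluded as connectors.
    """
    ped.validate()
    inds = ped.individuals
    if any(ind.affected is True and ind.carrier is False for ind in inds.values()):
        return 0, True
    g = nx.Graph()
    for iid, ind in inds.items():
        if ind.carrier is False:
            continue
        g.add_node(iid)
        for parent in (ind.father, ind.mother):
            if parent is not None and inds[parent].carrier is not False:
                g.add_edge(parent, iid)
    terminals = [iid for iid, ind in inds.items() if ind.affected is True and ind.carrier is True]
    total = 0
    for component in nx.connected_components(g):
        local = [t for t in terminals if t in component]
        if len(local) >= 2:
            sub = nx.algorithms.approximation.steiner_tree(g.subgraph(component), local)
            total += sub.number_of_edges()
    return total, False


@dataclass
class SegregationEvidence:
    """Pooled segregation evidence across families."""

    meioses: int
    lod: float
    nonsegregation: bool
    per_family: dict[str, dict] = field(default_factory=dict)


def lod_score(n: int) -> float:
    """LOD score for ``n`` informative meioses: log10(2**n) = n*log10(2)."""
    if n < 0:
        raise ValueError("meiosis count must be non-negative")
    return n * math.log10(2.0)


def count_informative_meioses(
    records: Iterable[SegregationRecord],
    pedigrees: Optional[Mapping[str, Pedigree]] = None,
) -> SegregationEvidence:
    """Pool informative meioses across families.

    Direct counts are authoritative when supplied; pedigree-referenced
    records are resolved against ``pedigrees`` and counted by
    transmission edges (see :func:`_pedigree_meioses`). Families with an
    affected noncarrier set the nonsegregation flag and contribute zero
    meioses.
    """
    total = 0
    nonseg = False
    per_family: dict[str, dict] = {}
    for rec in records:
        if rec.meioses is not None:
            fam_n, fam_nonseg = int(rec.meioses), bool(rec.nonsegregation)
        elif rec.pedigree_ref is not None:
            if pedigrees is None or rec.pedigree_ref not in pedigrees:
                raise PedigreeError(f"unresolvable pedigree reference {rec.pedigree_ref!r}")
            fam_n, fam_nonseg = _pedigree_meioses(pedigrees[rec.pedigree_ref])
            fam_nonseg = fam_nonseg or bool(rec.nonsegregation)
        else:
            raise ValueError(f"family {rec.family_id}: no meiosis count or pedigree reference")
        if fam_nonseg:
            fam_n = 0
            nonseg = True
        total += fam_n
        per_family[rec.family_id] = {"meioses": fam_n, "nonsegregation": fam_nonseg}
    return SegregationEvidence(
        meioses=total, lod=lod_score(total), nonsegregation=nonseg, per_family=per_family
    )


def tier_pp1(
    evidence: SegregationEvidence,
    pm2_met: bool,
    thresholds: tuple[int, int, int] = PP1_THRESHOLDS,
) -> tuple[Optional[str], bool]:
    """PP1 tier and BS4 flag from pooled segregation evidence.

    PP1 requires PM2 and the absence of nonsegregation; meioses may come
    from a single family. BS4 is flagged whenever nonsegregation was
    observed, independently of PM2.
    """
    bs4 = evidence.nonsegregation
    if not pm2_met or bs4:
        return None, bs4
    supporting, moderate, strong = thresholds
    if evidence.meioses >= strong:
        return "PP1_Strong", bs4
    if evidence.meioses >= moderate:
        return "PP1_Moderate", bs4
    if evidence.meioses >= supporting:
        return "PP1", bs4
    return None, bs4


# ---------------------------------------------------------------------------
# De novo occurrences
# ---------------------------------------------------------------------------


def evaluate_de_novo(
    observations: Iterable[DeNovoObservation],
    strong_count: int = DE_NOVO_STRONG_COUNT,
) -> Optional[str]:
    """PS2/PM6 from documented de novo occurrences.

    An occurrence qualifies only when both parents are genotype negative
    and phenotype negative after clinical evaluation and the
    three-generation family history is negative. PS2 (strong) needs one
    qualifying occurrence with confirmed paternity, or at least
    ``strong_count`` qualifying occurrences regardless of paternity
    confirmation; otherwise any qualifying occurrence yields PM6
    (moderate). Maternity confirmation is not required.
    """
    qualifying = [
        o
        for o in observations
        if o.parents_genotype_negative
        and o.parents_phenotype_negative
        and o.family_history_negative
    ]
    if not qualifying:
        return None
    if any(o.paternity_confirmed for o in qualifying) or len(qualifying) >= strong_count:
        return "PS2"
    return "PM6"
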