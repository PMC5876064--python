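"""File I/O: evidence JSON/TSV, PED pedigrees, classification reports,
and VCF annotation of classified variants.

Evidence bundles travel as versioned JSON (one bundle, or a
``{"schema_version": .., "bundles": [..]}`` collection). A flat TSV
dialect carries one bundle per row for batch work; it is lossy (scalar
evidence and counts only) and documented in the README. All frequencies
are proportions internally; percent appears only at presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .combine import VariantReport
from .cases import Individual, Pedigree, PedigreeError
from .evidence import (
    SCHEMA_VERSION,
    EvidenceBundle,
    Violation,
    bundle_from_dict,
    bundle_to_dict,
    validate_bundle,
)

__all__ = [
    "ReadResult",
    "read_evidence",
    "write_evidence",
    "read_ped",
    "report_to_dict",
    "write_report_json",
    "write_report_tsv",
    "write_vcf_annotations",
]


@dataclass
class ReadResult:
    """Validated bundles plus an error report for malformed records."""

    bundles: list[EvidenceBundle] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.bundles)

    def __len__(self) -> int:
        return len(self.bundles)


def _ingest(record: dict, where: str, result: ReadResult) -> None:
    bundle = bundle_from_dict(record)
    violations: list[Violation] = validate_bundle(bundle)
    if violations:
        for v in violations:
            result.errors.append(f"{where}: {v}")
    else:
        result.bundles.append(bundle)


def read_evidence(path: str | Path) -> ReadResult:
    """Read evidence bundles from a JSON or TSV file.

    Returns validated bundles; malformed records are collected into the
    error report with record references rather than raised. A schema
    version newer than the library's raises immediately.
    """
    path = Path(path)
    result = ReadResult()
    if path.suffix.lower() in (".tsv", ".txt"):
        return _read_evidence_tsv(path)
    text = path.read_text()
    if not text.strip():
        result.errors.append(f"{path.name}: empty file")
        return result
    data = json.loads(text)
    if isinstance(data, dict) and "bundles" in data:
        version = data.get("schema_version", SCHEMA_VERSION)
        if version > SCHEMA_VERSION:
            raise ValueError(
                f"{path.name}: schema_version {version} newer than supported {SCHEMA_VERSION}"
            )
        records = data["bundles"]
    elif isinstance(data, list):
        records = data
    else:
        records = [data]
    for i, record in enumerate(records):
        _ingest(record, f"{path.name} record {i}", result)
    return result


_TSV_COLUMNS = [
    "bundle_id",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "aa_position",
    "in_repeat_region",
    "disease_context",
    "population",
    "ac",
    "an",
    "deeply_characterized",
    "n_probands",
    "proband_phenotype",
    "n_meioses",
    "nonsegregation",
    "computational_consensus",
]


def _read_evidence_tsv(path: Path) -> ReadResult:
    """Flat batch dialect: one bundle per row, scalar evidence only."""
    result = ReadResult()
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty:
        result.errors.append(f"{path.name}: empty file")
        return result
    for i, row in df.iterrows():
        where = f"{path.name} line {i + 2}"
        record: dict = {
            "bundle_id": row.get("bundle_id", ""),
            "variant": {
                "hgvs_c": row.get("hgvs_c", ""),
                "hgvs_p": row.get("hgvs_p", ""),
                "consequence": row.get("consequence", "other") or "other",
                "aa_position": int(row["aa_position"]) if row.get("aa_position") else None,
                "in_repeat_region": row.get("in_repeat_region", "").lower() == "true",
            },
            "disease_context": row.get("disease_context", ""),
        }
        if row.get("an"):
            record["population_frequencies"] = [
                {
                    "population": row.get("population", ""),
                    "ac": int(row["ac"]) if row.get("ac") else 0,
                    "an": int(row["an"]),
                    "deeply_characterized": row.get("deeply_characterized", "").lower() == "true",
                }
            ]
        n_probands = int(row["n_probands"]) if row.get("n_probands") else 0
        if n_probands:
            phenotype = row.get("proband_phenotype", "") or row.get("disease_context", "")
            record["probands"] = [
                {
                    "proband_id": f"{record['bundle_id'] or i}-P{k + 1}",
                    "phenotype": phenotype,
                }
                for k in range(n_probands)
            ]
        if row.get("n_meioses") or row.get("nonsegregation", "").lower() == "true":
            record["segregations"] = [
                {
                    "family_id": f"{record['bundle_id'] or i}-F1",
                    "meioses": int(row["n_meioses"]) if row.get("n_meioses") else 0,
                    "nonsegregation": row.get("nonsegregation", "").lower() == "true",
                }
            ]
        if row.get("computational_consensus"):
            record["annotations"] = {
                "computational_consensus": row["computational_consensus"]
            }
        _ingest(record, where, result)
    return result


def write_evidence(bundles: Iterable[EvidenceBundle], path: str | Path) -> None:
    """Write bundles as a versioned JSON collection (deterministic form)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "bundles": [bundle_to_dict(b) for b in bundles],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# PED pedigrees
# ---------------------------------------------------------------------------


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Parse a 7-column PED file into pedigrees keyed by family id.

    Columns (tab-delimited): family, individual, father, mother, sex,
    affection (1 unaffected, 2 affected, 0/-9 unknown) and carrier
    status (0 unknown, 1 noncarrier, 2 carrier). ``0`` denotes a
    missing parent. Pedigrees are validated (parent references resolve,
    no ancestry cycles) on parse.
    """
    pedigrees: dict[str, Pedigree] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise PedigreeError(f"line {lineno}: expected 7 tab-delimited columns")
        fam, iid, father, mother, sex, affection, carrier = parts[:7]
        ped = pedigrees.setdefault(fam, Pedigree(family_id=fam))
        ped.individuals[iid] = Individual(
            iid=iid,
            father=None if father == "0" else father,
            mother=None if mother == "0" else mother,
            sex=int(sex) if sex.lstrip("-").isdigit() else 0,
            affected={"1": False, "2": True}.get(affection),
            carrier={"1": False, "2": True}.get(carrier),
        )
    for ped in pedigrees.values():
        ped.validate()
    return pedigrees


# ---------------------------------------------------------------------------
# Classification reports
# ---------------------------------------------------------------------------


def report_to_dict(report: VariantReport) -> dict:
    c = report.classification
    return {
        "bundle_id": report.bundle_id,
        "variant": report.variant_label,
        "disease_context": report.disease_context,
        "rule_based_tier": c.tier.value,
        "criterion": c.criterion,
        "conflict": c.conflict,
        "met_rules": c.met_codes(),
        "override_tier": report.override.classification.value if report.override else None,
        "override_justification": report.override.justification if report.override else None,
        "final_tier": report.final_tier.value,
        "applied_rules": [
            {
                "code": r.code,
                "base": r.base,
                "direction": r.direction,
                "strength": r.strength,
                "met": r.met,
                "summary": r.summary,
                "inputs": r.inputs,
            }
            for r in c.rules
        ],
    }


def write_report_json(reports: Iterable[VariantReport], path: str | Path) -> None:
    payload = [report_to_dict(r) for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_report_tsv(reports: Iterable[VariantReport], path: str | Path) -> None:
    """One line per variant; tier assignments identical to the JSON report."""
    rows = []
    for r in reports:
        d = report_to_dict(r)
        rows.append(
            {
                "bundle_id": d["bundle_id"],
                "variant": d["variant"],
                "disease_context": d["disease_context"],
                "rule_based_tier": d["rule_based_tier"],
                "met_rules": ",".join(d["met_rules"]),
                "conflict": d["conflict"],
                "override_tier": d["override_tier"] or "",
                "final_tier": d["final_tier"],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

_INFO_HEADERS = [
    ("MYH7_CLASS", "1", "String", "Rule-based classification tier"),
    ("MYH7_RULES", ".", "String", "Met rule codes"),
    ("MYH7_CONFLICT", "0", "Flag", "Pathogenic and benign evidence both present"),
]


def write_vcf_annotations(
    reports: Iterable[VariantReport],
    template_vcf: str | Path,
    out_path: str | Path,
) -> int:
    """Annotate a VCF with classification INFO keys; return matches.

    Records are matched to reports by variant descriptor: the VCF ID
    column must equal the report's bundle id or its coding/protein
    descriptor. Unmatched records pass through untouched. Tier values
    use underscores in place of spaces (VCF INFO fields cannot contain
    spaces).
    """
    by_key: dict[str, VariantReport] = {}
    for r in reports:
        for key in (r.bundle_id, r.variant_label):
            if key:
                by_key[key] = r
    matched = 0
    with pysam.VariantFile(str(template_vcf)) as vin:
        header = vin.header.copy()
        for name, number, vtype, desc in _INFO_HEADERS:
            if name not in header.info:
                header.info.add(name, number, vtype, desc)
        with pysam.VariantFile(str(out_path), "w", header=header) as vout:
            for rec in vin:
                report = by_key.get(rec.id or "")
                if report is not None:
                    rec.translate(header)
                    rec.info["MYH7_CLASS"] = report.classification.tier.value.replace(" ", "_")
                    met = report.classification.met_codes()
                    if met:
                        rec.info["MYH7_RULES"] = ",".join(met)
                    if report.classification.conflict:
                        rec.info["MYH7_CONFLICT"] = True
                    matched += 1
                else:
                    rec.translate(header)
                vout.write(rec)
    return matched
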