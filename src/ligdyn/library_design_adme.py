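"""Combinatorial R-group library enumeration and drug-likeness filtering.

Compounds are named "{r2}.{r1}" (tail index dot head index).  The filtering
cascade evaluates five physicochemical rule sets (thresholds live in
``data/rules.yaml``, not in code), a consensus-logP CNS window, and optional
transporter/metabolism flag screens.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, StructureError

__all__ = [
    "CompoundId",
    "DescriptorRecord",
    "RuleReport",
    "enumerate_library",
    "parse_compound_name",
    "consensus_logp",
    "evaluate_rules",
    "filter_library",
    "load_rule_config",
    "read_descriptor_table",
]

RULE_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")
CYP_ISOFORMS = ("1A2", "2C19", "2C9", "2D6", "3A4")

_OPS = {"<=": operator.le, ">=": operator.ge, "<": operator.lt, ">": operator.gt}


@dataclass(frozen=True)
class CompoundId:
    r1: int
    r2: int

    def __post_init__(self) -> None:
        if self.r1 < 1 or self.r2 < 1:
            raise StructureError("R-group indices start at 1")

    @property
    def name(self) -> str:
        return f"{self.r2}.{self.r1}"


def parse_compound_name(name: str) -> CompoundId:
    """Inverse of ``CompoundId.name``: "9.7" -> CompoundId(r1=7, r2=9)."""
    try:
        r2_s, r1_s = name.split(".")
        return CompoundId(r1=int(r1_s), r2=int(r2_s))
    except (ValueError, TypeError) as exc:
        raise StructureError(f"cannot parse compound name {name!r}") from None


def enumerate_library(n_r1: int = 12, n_r2: int = 15) -> list[CompoundId]:
    """All (r2, r1) combinations, r2-major: 1.1, 1.2, ... up to n_r2.n_r1."""
    if n_r1 < 1 or n_r2 < 1:
        raise StructureError("R-group counts must be >= 1")
    return [CompoundId(r1=r1, r2=r2) for r2 in range(1, n_r2 + 1) for r1 in range(1, n_r1 + 1)]


@dataclass
class DescriptorRecord:
    """Per-compound physicochemical descriptors (externally computed)."""

    compound: CompoundId | None = None
    mw: float | None = None
    logp_estimates: dict[str, float] = field(default_factory=dict)
    consensus_logp_value: float | None = None  # used verbatim when provided
    hbd: int | None = None
    hba: int | None = None
    tpsa: float | None = None
    rotatable_bonds: int | None = None
    molar_refractivity: float | None = None
    atom_count: int | None = None
    ring_count: int | None = None
    carbon_count: int | None = None
    heteroatom_count: int | None = None
    pgp_substrate: bool | None = None
    cyp_inhibition: dict[str, bool] = field(default_factory=dict)
    gi_absorption: str | None = None

    def __post_init__(self) -> None:
        for name in ("hbd", "hba", "rotatable_bonds", "atom_count", "ring_count",
                     "carbon_count", "heteroatom_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise StructureError(f"{name} must be non-negative")

    def descriptor(self, key: str) -> float | None:
        """Resolve a rule-config descriptor key; logP methods fall back to
        the generic estimate when a method-specific value is absent."""
        if key in ("wlogp", "xlogp3", "mlogp", "ilogp", "logp"):
            if key in self.logp_estimates:
                return self.logp_estimates[key]
            if "logp" in self.logp_estimates:
                return self.logp_estimates["logp"]
            if self.logp_estimates:
                return consensus_logp(self)
            return self.consensus_logp_value
        return getattr(self, key, None)


@dataclass(frozen=True)
class RuleReport:
    compound: CompoundId | None
    violations: dict[str, int]          # evaluable rules only
    not_evaluable: tuple[str, ...]      # rules lacking required descriptors
    consensus_logp: float | None
    cns_pass: bool
    overall_pass: bool


def consensus_logp(record: DescriptorRecord) -> float:
    """Arithmetic mean of the available logP estimates; a precomputed
    consensus value, when supplied, is used verbatim."""
    if record.consensus_logp_value is not None:
        return record.consensus_logp_value
    if not record.logp_estimates:
        raise StructureError("no logP estimates available")
    values = list(record.logp_estimates.values())
    return sum(values) / len(values)


def load_rule_config(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("ligdyn.data").joinpath("rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if "rules" not in cfg or "cns_logp_window" not in cfg:
        raise SchemaError("rule config needs 'rules' and 'cns_logp_window'")
    return cfg


def evaluate_rules(record: DescriptorRecord, config: dict | None = None) -> RuleReport:
    """Count per-rule violations; rules with missing descriptors are reported
    as not-evaluable, never silently zero."""
    cfg = config if config is not None else load_rule_config()
    violations: dict[str, int] = {}
    not_evaluable: list[str] = []
    for rule, conditions in cfg["rules"].items():
        count = 0
        evaluable = True
        for key, op, bound in conditions:
            value = record.descriptor(key)
            if value is None:
                evaluable = False
                break
            if not _OPS[op](value, bound):
                count += 1
        if evaluable:
            violations[rule] = count
        else:
            not_evaluable.append(rule)

    try:
        clogp = consensus_logp(record)
    except StructureError:
        clogp = None
    lo, hi = cfg["cns_logp_window"]
    cns = clogp is not None and lo <= clogp <= hi
    overall = (
        bool(violations)
        and not not_evaluable
        and all(v == 0 for v in violations.values())
        and cns
    )
    return RuleReport(
        compound=record.compound,
        violations=violations,
        not_evaluable=tuple(not_evaluable),
        consensus_logp=clogp,
        cns_pass=cns,
        overall_pass=overall,
    )


def filter_library(
    records: list[DescriptorRecord],
    config: dict | None = None,
    exclude_pgp_substrates: bool = False,
    max_cyp_inhibitions: int | None = None,
) -> tuple[list[CompoundId], dict[str, RuleReport]]:
    """Apply the full cascade; returns (pass list, per-compound reports).

    Pass requires zero violations on every rule, cns_pass, and — when the
    optional screens are enabled — non-Pgp-substrate status and at most
    ``max_cyp_inhibitions`` inhibited CYP isoforms.  Output is ordered by
    compound id (r2, then r1).
    """
    seen: set[str] = set()
    for rec in records:
        if rec.compound is None:
            raise StructureError("filter_library requires records with compound ids")
        if rec.compound.name in seen:
            raise StructureError(f"duplicate compound id {rec.compound.name}")
        seen.add(rec.compound.name)

    ordered = sorted(records, key=lambda r: (r.compound.r2, r.compound.r1))
    reports: dict[str, RuleReport] = {}
    passed: list[CompoundId] = []
    for rec in ordered:
        rep = evaluate_rules(rec, config)
        reports[rec.compound.name] = rep
        ok = rep.overall_pass
        if ok and exclude_pgp_substrates and rec.pgp_substrate:
            ok = False
        if ok and max_cyp_inhibitions is not None:
            n_inhib = sum(1 for v in rec.cyp_inhibition.values() if v)
            if n_inhib > max_cyp_inhibitions:
                ok = False
        if ok:
            passed.append(rec.compound)
    return passed, reports


# --- descriptor table ingestion ----------------------------------------------

_COLUMN_ALIASES = {
    "mw": ("MW", "Molecular weight", "mw"),
    "tpsa": ("TPSA", "tpsa"),
    "hbd": ("HBD", "Num. H-bond donors", "hbd"),
    "hba": ("HBA", "Num. H-bond acceptors", "hba"),
    "rotatable_bonds": ("Rotatable bonds", "Num. rotatable bonds", "rotatable_bonds"),
    "molar_refractivity": ("Molar Refractivity", "molar_refractivity", "MR"),
    "atom_count": ("Atoms", "Num. heavy atoms", "atom_count"),
    "ring_count": ("Rings", "Num. rings", "ring_count"),
    "carbon_count": ("Carbons", "carbon_count"),
    "heteroatom_count": ("Heteroatoms", "heteroatom_count"),
}
_LOGP_COLUMNS = {
    "ilogp": ("iLOGP",), "xlogp3": ("XLOGP3",), "wlogp": ("WLOGP",),
    "mlogp": ("MLOGP",), "logp": ("LogP", "logp"),
}


def read_descriptor_table(path: str | Path) -> list[DescriptorRecord]:
    """Read a descriptor TSV with Table-style column names.

    Requires a ``Molecule`` column holding "{r2}.{r1}" names; recognised
    descriptor columns are mapped, "Consensus Log P" is used verbatim,
    Yes/No columns feed the Pgp/CYP flags.
    """
    df = pd.read_csv(path, sep="\t")
    if "Molecule" not in df.columns:
        raise SchemaError(f"{path}: missing 'Molecule' column")

    def pick(row, aliases):
        for col in aliases:
            if col in df.columns and pd.notna(row[col]):
                return row[col]
        return None

    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for attr, aliases in _COLUMN_ALIASES.items():
            v = pick(row, aliases)
            kwargs[attr] = None if v is None else (
                int(v) if attr in ("hbd", "hba", "rotatable_bonds", "atom_count",
                                   "ring_count", "carbon_count", "heteroatom_count")
                else float(v)
            )
        logp = {m: float(pick(row, cols)) for m, cols in _LOGP_COLUMNS.items()
                if pick(row, cols) is not None}
        cons = pick(row, ("Consensus Log P", "consensus_logp"))
        cyp = {iso: str(row[f"CYP{iso} inhibitor"]).strip().lower() == "yes"
               for iso in CYP_ISOFORMS if f"CYP{iso} inhibitor" in df.columns}
        pgp = None
        if "Pgp substrate" in df.columns and pd.notna(row["Pgp substrate"]):
            pgp = str(row["Pgp substrate"]).strip().lower() == "yes"
        records.append(DescriptorRecord(
            compound=parse_compound_name(str(row["Molecule"])),
            logp_estimates=logp,
            consensus_logp_value=None if cons is None else float(cons),
            pgp_substrate=pgp,
            cyp_inhibition=cyp,
            gi_absorption=str(row["GI absorption"]) if "GI absorption" in df.columns else None,
            **kwargs,
        ))
    return records
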