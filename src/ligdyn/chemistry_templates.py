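"""Residue chemical-role templates.

Each template names, per residue type, which atoms act as hydrogen-bond
donors (heavy atom plus the hydrogen names that may sit on it), acceptors,
charged groups, aromatic rings and apolar contacts.  Apolar membership
follows the rule "carbon not bonded to N/O, or sulfur", pre-resolved per
residue so no bond perception is needed at annotation time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError

__all__ = ["ResidueTemplate", "DEFAULT_TEMPLATES", "load_templates_tsv", "write_templates_tsv"]


@dataclass(frozen=True)
class ResidueTemplate:
    """Chemical roles of one residue type, keyed by atom name."""

    donors: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (heavy, H names)
    acceptors: tuple[str, ...] = ()
    cation_groups: tuple[tuple[str, ...], ...] = ()
    anion_groups: tuple[tuple[str, ...], ...] = ()
    rings: tuple[tuple[str, ...], ...] = ()
    apolar: tuple[str, ...] = ()


_BB_DONOR = (("N", ("H", "HN", "H1")),)
_BB_ACC = ("O", "OXT")


def _aa(
    donors=(),
    acceptors=(),
    cations=(),
    anions=(),
    rings=(),
    apolar=(),
    backbone_donor=True,
) -> ResidueTemplate:
    d = (_BB_DONOR if backbone_donor else ()) + tuple(donors)
    return ResidueTemplate(
        donors=d,
        acceptors=_BB_ACC + tuple(acceptors),
        cation_groups=tuple(cations),
        anion_groups=tuple(anions),
        rings=tuple(rings),
        apolar=tuple(apolar),
    )


#: Role tables for the 20 standard amino acids.
DEFAULT_TEMPLATES: dict[str, ResidueTemplate] = {
    "ALA": _aa(apolar=("CB",)),
    "ARG": _aa(
        donors=(("NE", ("HE",)), ("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))),
        cations=(("NE", "NH1", "NH2", "CZ"),),
        apolar=("CB", "CG"),
    ),
    "ASN": _aa(donors=(("ND2", ("HD21", "HD22")),), acceptors=("OD1",), apolar=("CB",)),
    "ASP": _aa(acceptors=("OD1", "OD2"), anions=(("OD1", "OD2"),), apolar=("CB",)),
    "CYS": _aa(apolar=("CB", "SG")),
    "GLN": _aa(donors=(("NE2", ("HE21", "HE22")),), acceptors=("OE1",), apolar=("CB", "CG")),
    "GLU": _aa(acceptors=("OE1", "OE2"), anions=(("OE1", "OE2"),), apolar=("CB", "CG")),
    "GLY": _aa(),
    "HIS": _aa(
        donors=(("ND1", ("HD1",)), ("NE2", ("HE2",))),
        acceptors=("ND1", "NE2"),
        rings=(("CG", "ND1", "CE1", "NE2", "CD2"),),
        apolar=("CB",),
    ),
    "ILE": _aa(apolar=("CB", "CG1", "CG2", "CD1")),
    "LEU": _aa(apolar=("CB", "CG", "CD1", "CD2")),
    "LYS": _aa(
        donors=(("NZ", ("HZ1", "HZ2", "HZ3")),),
        cations=(("NZ",),),
        apolar=("CB", "CG", "CD"),
    ),
    "MET": _aa(apolar=("CB", "CG", "SD", "CE")),
    "PHE": _aa(
        rings=(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
        apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ),
    "PRO": _aa(backbone_donor=False, apolar=("CB", "CG")),
    "SER": _aa(donors=(("OG", ("HG",)),), acceptors=("OG",)),
    "THR": _aa(donors=(("OG1", ("HG1",)),), acceptors=("OG1",), apolar=("CG2",)),
    "TRP": _aa(
        donors=(("NE1", ("HE1",)),),
        rings=(
            ("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
        ),
        apolar=("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
    "TYR": _aa(
        donors=(("OH", ("HH",)),),
        acceptors=("OH",),
        rings=(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
        apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    ),
    "VAL": _aa(apolar=("CB", "CG1", "CG2")),
}

_ROLES = {"donor", "acceptor", "cation", "anion", "ring", "apolar"}


def load_templates_tsv(path: str | Path) -> dict[str, ResidueTemplate]:
    """Read user role templates from TSV.

    Columns: ``resname``, ``role``, ``atoms``.  ``atoms`` is space separated;
    donor entries use ``HEAVY:H1|H2`` syntax, group roles (cation/anion/ring)
    give all member atoms of one group per row.
    """
    path = Path(path)
    acc: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"resname", "role", "atoms"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: template TSV needs columns resname, role, atoms")
        for lineno, row in enumerate(reader, start=2):
            role = row["role"].strip()
            if role not in _ROLES:
                raise ParseError(f"{path}:{lineno}: unknown role {role!r}")
            entry = acc.setdefault(
                row["resname"].strip(),
                {"donors": [], "acceptors": [], "cations": [], "anions": [], "rings": [], "apolar": []},
            )
            atoms = row["atoms"].split()
            if role == "donor":
                for spec in atoms:
                    heavy, _, hs = spec.partition(":")
                    entry["donors"].append((heavy, tuple(hs.split("|")) if hs else ()))
            elif role == "acceptor":
                entry["acceptors"].extend(atoms)
            elif role == "cation":
                entry["cations"].append(tuple(atoms))
            elif role == "anion":
                entry["anions"].append(tuple(atoms))
            elif role == "ring":
                entry["rings"].append(tuple(atoms))
            else:
                entry["apolar"].extend(atoms)
    return {
        name: ResidueTemplate(
            donors=tuple(e["donors"]),
            acceptors=tuple(e["acceptors"]),
            cation_groups=tuple(e["cations"]),
            anion_groups=tuple(e["anions"]),
            rings=tuple(e["rings"]),
            apolar=tuple(e["apolar"]),
        )
        for name, e in acc.items()
    }


def write_templates_tsv(templates: dict[str, ResidueTemplate], path: str | Path) -> None:
    """Inverse of :func:`load_templates_tsv`."""
    with Path(path).open("w", newline="") as fh:
        fh.write("resname\trole\tatoms\n")
        for resname, tmpl in templates.items():
            if tmpl.donors:
                specs = " ".join(
                    f"{heavy}:{'|'.join(hs)}" if hs else heavy for heavy, hs in tmpl.donors
                )
                fh.write(f"{resname}\tdonor\t{specs}\n")
            if tmpl.acceptors:
                fh.write(f"{resname}\tacceptor\t{' '.join(tmpl.acceptors)}\n")
            for grp in tmpl.cation_groups:
                fh.write(f"{resname}\tcation\t{' '.join(grp)}\n")
            for grp in tmpl.anion_groups:
                fh.write(f"{resname}\tanion\t{' '.join(grp)}\n")
            for ring in tmpl.rings:
                fh.write(f"{resname}\tring\t{' '.join(ring)}\n")
            if tmpl.apolar:
                fh.write(f"{resname}\tapolar\t{' '.join(tmpl.apolar)}\n")
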