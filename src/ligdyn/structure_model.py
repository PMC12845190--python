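"""Domain model for multi-frame molecular structures.

Coordinates are stored in Angstrom throughout (PDB native); reporting layers
convert to nm where needed.  A :class:`MolecularFrameSeries` couples a static
topology (atoms, residues, chemical roles) with a ``T x N x 3`` coordinate
block, one frame per PDB ``MODEL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chemistry_templates import DEFAULT_TEMPLATES, ResidueTemplate
from .errors import AnnotationError, ParseError, SelectionError, StructureError

__all__ = [
    "Atom",
    "MolecularFrameSeries",
    "AtomSelection",
    "read_frame_series",
    "write_frame_series",
    "annotate_chemistry",
    "select_atoms",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}

#: Residue names dropped on read unless explicitly kept (solvent / counterions).
DEFAULT_DROP_RESNAMES = frozenset({"HOH", "WAT", "NA", "CL", "SOD", "CLA"})

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """One atom of the topology; ``coords`` mirror frame 0."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    mass: float
    roles: set[str] = field(default_factory=set)
    is_ligand: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} ({self.name}): non-finite or malformed coords")
        if self.mass <= 0:
            raise StructureError(f"atom {self.serial} ({self.name}): mass must be positive")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)

    @property
    def residue_label(self) -> str:
        return f"{self.residue_name}{self.residue_index}"


@dataclass
class MolecularFrameSeries:
    """Topology plus T coordinate frames (Angstrom).

    ``donor_pairs``/``acceptors``/``charged_groups``/``rings`` are filled by
    :func:`annotate_chemistry`; geometric detectors require them.
    """

    atoms: list[Atom]
    frames: np.ndarray                      # (T, N, 3), Angstrom
    frame_times: np.ndarray                 # (T,), ns
    ligand_mask: np.ndarray                 # (N,), bool
    rings: list[tuple[int, ...]] = field(default_factory=list)
    donor_pairs: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    charged_groups: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    annotated: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        n = len(self.atoms)
        if self.frames.ndim != 3 or self.frames.shape[1] != n or self.frames.shape[2] != 3:
            raise StructureError(
                f"frames shape {self.frames.shape} inconsistent with {n} atoms"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("a frame series needs at least one frame")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise StructureError("frame_times length must equal frame count")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise StructureError("frame_times must be strictly increasing")
        if self.ligand_mask.shape != (n,):
            raise StructureError("ligand_mask length must equal atom count")
        for ring in self.rings:
            if len(ring) < 5:
                raise StructureError(f"aromatic ring {ring} has fewer than 5 atoms")
        if self.ligand_mask.any():
            lig_keys = {self.atoms[i].residue_key for i in np.flatnonzero(self.ligand_mask)}
            seqs = sorted(k[1] for k in lig_keys)
            if seqs != list(range(seqs[0], seqs[0] + len(seqs))):
                raise StructureError("ligand must span contiguous residue indices")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique residue keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def copy(self) -> "MolecularFrameSeries":
        return MolecularFrameSeries(
            atoms=[replace(a, coords=a.coords.copy(), roles=set(a.roles)) for a in self.atoms],
            frames=self.frames.copy(),
            frame_times=self.frame_times.copy(),
            ligand_mask=self.ligand_mask.copy(),
            rings=list(self.rings),
            donor_pairs=list(self.donor_pairs),
            acceptors=list(self.acceptors),
            charged_groups=list(self.charged_groups),
            annotated=self.annotated,
        )


@dataclass
class AtomSelection:
    """Predicate over atoms plus its resolved index list."""

    chain: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None
    ligand: bool | None = None
    indices: np.ndarray | None = None

    def resolve(self, series: MolecularFrameSeries) -> np.ndarray:
        if self.indices is not None:
            idx = np.asarray(self.indices, dtype=int)
        else:
            keep = []
            for i, a in enumerate(series.atoms):
                if self.chain is not None and a.chain_id != self.chain:
                    continue
                if self.residue_range is not None and not (
                    self.residue_range[0] <= a.residue_index <= self.residue_range[1]
                ):
                    continue
                if self.atom_names is not None and a.name not in self.atom_names:
                    continue
                if self.ligand is not None and a.is_ligand != self.ligand:
                    continue
                keep.append(i)
            idx = np.array(keep, dtype=int)
        if idx.size == 0:
            raise SelectionError(f"selection {self!r} resolved to no atoms")
        if idx.size != np.unique(idx).size:
            raise SelectionError("selection indices must be unique")
        idx = np.sort(idx)
        if idx[0] < 0 or idx[-1] >= series.n_atoms:
            raise SelectionError("selection indices out of range")
        return idx


_NAMED_SELECTIONS = ("backbone", "calpha", "ligand", "protein", "all", "heavy")


def select_atoms(series: MolecularFrameSeries, query: AtomSelection | str) -> np.ndarray:
    """Resolve a selection to sorted unique atom indices.

    String shortcuts: ``backbone`` (N/CA/C/O of protein), ``calpha``,
    ``ligand``, ``protein``, ``heavy`` (non-hydrogen), ``all``.
    Raises :class:`SelectionError` when nothing matches — never silent.
    """
    if isinstance(query, str):
        if query not in _NAMED_SELECTIONS:
            raise SelectionError(f"unknown named selection {query!r}; expected one of {_NAMED_SELECTIONS}")
        if query == "backbone":
            query = AtomSelection(atom_names=BACKBONE_ATOMS, ligand=False)
        elif query == "calpha":
            query = AtomSelection(atom_names=("CA",), ligand=False)
        elif query == "ligand":
            query = AtomSelection(ligand=True)
        elif query == "protein":
            query = AtomSelection(ligand=False)
        elif query == "heavy":
            idx = np.array([i for i, a in enumerate(series.atoms) if a.element != "H"], dtype=int)
            return AtomSelection(indices=idx).resolve(series)
        else:
            query = AtomSelection()
    return query.resolve(series)


# -----------------------------------------------------------------------------
# Multi-model PDB I/O (fixed columns, wwPDB v3.3)
# -----------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].upper() in ATOMIC_MASSES and not stripped[0].isdigit():
        two = stripped[:2].upper()
        # two-letter symbols only when the name is genuinely two-letter (CL, BR ...)
        if two in {"CL", "BR", "NA", "MG", "ZN", "FE"} and len(stripped) <= 2:
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ParseError(f"cannot infer element from atom name {name!r}")


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise ParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    if icode.strip():
        raise ParseError(f"line {lineno}: insertion codes are not supported (found {icode!r})")
    if altloc.strip() not in ("", "A"):
        raise ParseError(f"line {lineno}: alternate locations other than 'A' unsupported")
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return {
        "serial": serial, "name": name, "resname": resname, "chain": chain,
        "resseq": resseq, "xyz": (x, y, z), "element": element,
        "het": line.startswith("HETATM"),
    }


def read_frame_series(
    path: str | Path,
    ligand_codes: Sequence[str] = ("LIG",),
    drop_resnames: Iterable[str] = DEFAULT_DROP_RESNAMES,
    frame_times: np.ndarray | None = None,
    time_step_ns: float = 1.0,
) -> MolecularFrameSeries:
    """Read a (multi-model) PDB file into a :class:`MolecularFrameSeries`.

    One frame per ``MODEL`` block; a file without MODEL records yields a
    single frame.  HETATM records whose residue name is in ``ligand_codes``
    become ligand atoms; residues in ``drop_resnames`` are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    ligand_codes = tuple(ligand_codes)
    drop = frozenset(drop_resnames)

    models: list[list[dict]] = []
    current: list[dict] | None = None
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed["resname"] in drop:
                    continue
                if current is None:
                    if saw_model:
                        raise ParseError(f"line {lineno}: atom record outside MODEL block")
                    current = []
                current.append(parsed)
    if current:
        models.append(current)
    if not models or not models[0]:
        raise ParseError(f"{path}: no atom records found")

    ref = models[0]
    for m, model in enumerate(models[1:], start=2):
        if len(model) != len(ref):
            raise StructureError(
                f"{path}: model {m} has {len(model)} atoms, model 1 has {len(ref)}"
            )
        for a, b in zip(ref, model):
            if (a["name"], a["resname"], a["chain"], a["resseq"]) != (
                b["name"], b["resname"], b["chain"], b["resseq"]
            ):
                raise StructureError(
                    f"{path}: model {m} atom order differs from model 1 "
                    f"(first mismatch at serial {b['serial']})"
                )

    atoms: list[Atom] = []
    for rec in ref:
        is_lig = rec["resname"] in ligand_codes
        mass = ATOMIC_MASSES.get(rec["element"])
        if mass is None:
            raise StructureError(f"unknown element {rec['element']!r} for atom {rec['serial']}")
        atoms.append(
            Atom(
                serial=rec["serial"], name=rec["name"], element=rec["element"],
                residue_index=rec["resseq"], residue_name=rec["resname"],
                chain_id=rec["chain"], coords=np.array(rec["xyz"]), mass=mass,
                is_ligand=is_lig,
            )
        )
    frames = np.array([[rec["xyz"] for rec in model] for model in models])
    if frame_times is None:
        frame_times = np.arange(len(models), dtype=float) * time_step_ns
    ligand_mask = np.array([a.is_ligand for a in atoms])
    return MolecularFrameSeries(
        atoms=atoms, frames=frames, frame_times=np.asarray(frame_times, float),
        ligand_mask=ligand_mask,
    )


def write_frame_series(series: MolecularFrameSeries, path: str | Path) -> None:
    """Write all frames as a multi-model PDB (fixed columns, 3-decimal coords)."""
    path = Path(path)
    with path.open("w") as fh:
        for t in range(series.n_frames):
            fh.write(f"MODEL {t + 1:>8d}\n")
            for i, atom in enumerate(series.atoms):
                x, y, z = series.frames[t, i]
                record = "HETATM" if atom.is_ligand else "ATOM  "
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{atom.serial % 100000:>5d} {name}"
                    f" {atom.residue_name:>3s} {atom.chain_id}{atom.residue_index:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# -----------------------------------------------------------------------------
# Chemical-role annotation
# -----------------------------------------------------------------------------

def annotate_chemistry(
    series: MolecularFrameSeries,
    templates: dict[str, ResidueTemplate] | None = None,
    require_hydrogens: bool = True,
) -> MolecularFrameSeries:
    """Populate donor/acceptor/charged-group/ring/apolar annotations in place.

    ``templates`` extends/overrides the built-in amino-acid role tables; the
    ligand's residue name must appear there (or in the defaults).  A donor
    heavy atom present without any of its template hydrogens raises
    :class:`AnnotationError` unless ``require_hydrogens`` is False.
    """
    table = dict(DEFAULT_TEMPLATES)
    if templates:
        table.update(templates)

    unknown = sorted({a.residue_name for a in series.atoms if a.residue_name not in table})
    if unknown:
        raise AnnotationError(
            f"no role template for residue(s): {', '.join(unknown)}; "
            "supply a template table for non-standard residues"
        )

    donor_pairs: list[tuple[int, int]] = []
    acceptors: list[int] = []
    charged: list[tuple[int, tuple[int, ...]]] = []
    rings: list[tuple[int, ...]] = []
    missing_h: list[str] = []

    for key, idx in series.residue_atom_indices().items():
        res_atoms = {series.atoms[i].name: i for i in idx}
        tmpl = table[series.atoms[idx[0]].residue_name]
        label = series.atoms[idx[0]].residue_label

        for heavy, h_names in tmpl.donors:
            if heavy not in res_atoms:
                continue
            hs = [res_atoms[h] for h in h_names if h in res_atoms]
            if not hs:
                missing_h.append(f"{label}.{heavy}")
                continue
            series.atoms[res_atoms[heavy]].roles.add("donor-heavy")
            for h in hs:
                series.atoms[h].roles.add("polar-hydrogen")
                donor_pairs.append((res_atoms[heavy], h))
        for name in tmpl.acceptors:
            if name in res_atoms:
                series.atoms[res_atoms[name]].roles.add("acceptor")
                acceptors.append(res_atoms[name])
        for group in tmpl.cation_groups:
            members = tuple(res_atoms[n] for n in group if n in res_atoms)
            if members:
                for i in members:
                    series.atoms[i].roles.add("cation-group-member")
                charged.append((+1, members))
        for group in tmpl.anion_groups:
            members = tuple(res_atoms[n] for n in group if n in res_atoms)
            if members:
                for i in members:
                    series.atoms[i].roles.add("anion-group-member")
                charged.append((-1, members))
        for ring in tmpl.rings:
            members = tuple(res_atoms[n] for n in ring if n in res_atoms)
            if len(members) == len(ring):
                for i in members:
                    series.atoms[i].roles.add("aromatic-ring-member")
                rings.append(members)
        for name in tmpl.apolar:
            if name in res_atoms:
                series.atoms[res_atoms[name]].roles.add("apolar")

    if missing_h and require_hydrogens:
        raise AnnotationError(
            "declared donor heavy atoms lack hydrogens: " + ", ".join(sorted(missing_h))
        )

    series.donor_pairs = sorted(set(donor_pairs))
    series.acceptors = sorted(set(acceptors))
    series.charged_groups = charged
    series.rings = rings
    series.annotated = True
    return series


def derive_ligand_template(series: MolecularFrameSeries) -> dict[str, ResidueTemplate]:
    """Reconstruct the ligand's role template from an annotated series.

    Lets a synthetic complex's chemistry round-trip through PDB + TSV files.
    Assumes the ligand is a single residue type.
    """
    if not series.annotated:
        raise AnnotationError("series must be annotated to derive a template")
    lig_idx = np.flatnonzero(series.ligand_mask)
    if lig_idx.size == 0:
        return {}
    resname = series.atoms[lig_idx[0]].residue_name
    lig = set(lig_idx.tolist())
    name = lambda i: series.atoms[i].name
    donors = tuple(
        (name(d), (name(h),)) for d, h in series.donor_pairs if d in lig
    )
    acceptors = tuple(name(i) for i in series.acceptors if i in lig)
    cations = tuple(tuple(name(i) for i in grp) for sign, grp in series.charged_groups
                    if sign > 0 and grp[0] in lig)
    anions = tuple(tuple(name(i) for i in grp) for sign, grp in series.charged_groups
                   if sign < 0 and grp[0] in lig)
    rings = tuple(tuple(name(i) for i in ring) for ring in series.rings if ring[0] in lig)
    apolar = tuple(name(i) for i in lig_idx if "apolar" in series.atoms[i].roles)
    return {resname: ResidueTemplate(
        donors=donors, acceptors=acceptors, cation_groups=cations,
        anion_groups=anions, rings=rings, apolar=apolar,
    )}
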