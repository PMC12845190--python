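"""Seeded generators for every fixture the pipeline needs.

No force field, solvent or thermostat: these generators mimic the
*statistical* structure of folded-protein trajectories (prescribed
per-residue fluctuation amplitudes, planted interaction geometries,
Gaussian energy-component series) so every downstream contract can be
exercised at desk scale with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry_templates import ResidueTemplate
from .errors import ConstructionError, StructureError
from .structure_model import (
    ATOMIC_MASSES,
    Atom,
    MolecularFrameSeries,
    annotate_chemistry,
)
from .energetics_bookkeeping import COMPONENTS, EnergyComponentSeries
from .trajectory_descriptors import RMSFProfile

__all__ = [
    "LigandSpec",
    "FluctuationSpec",
    "PlantedInteraction",
    "make_toy_complex",
    "make_fluctuation_trajectory",
    "plant_interaction_snapshot",
    "plant_interaction_trajectory",
    "make_energy_series",
    "make_rmsf_pair",
]

_ANG_PER_NM = 10.0


# -----------------------------------------------------------------------------
# Toy protein-ligand complex
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandSpec:
    """How many of each chemical feature the toy ligand carries."""

    n_rings: int = 1
    n_donors: int = 1
    n_acceptors: int = 1
    n_cation_groups: int = 0
    n_anion_groups: int = 0
    n_apolar: int = 2

    def __post_init__(self) -> None:
        if min(self.n_rings, self.n_donors, self.n_acceptors,
               self.n_cation_groups, self.n_anion_groups, self.n_apolar) < 0:
            raise ConstructionError("ligand feature counts must be non-negative")
        if (self.n_rings + self.n_donors + self.n_acceptors + self.n_cation_groups
                + self.n_anion_groups + self.n_apolar) == 0:
            raise ConstructionError("ligand spec declares no atoms at all")


def _mass(element: str) -> float:
    return ATOMIC_MASSES[element]


def _hexagon(center: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    return [
        center + radius * np.array([math.cos(k * math.pi / 3), math.sin(k * math.pi / 3), 0.0])
        for k in range(6)
    ]


def make_toy_complex(
    n_residues: int,
    ligand_spec: LigandSpec | None = LigandSpec(),
    seed: int = 0,
    chain: str = "A",
    ligand_resname: str = "LIG",
    ligand_resseq: int = 386,
) -> MolecularFrameSeries:
    """Deterministic single-frame protein-ligand complex.

    The protein is a glycine chain laid along a smooth helical curve; the
    ligand (if any) sits in a cleft ~6 A off the chain midpoint with the
    requested chemical features.  Chemistry is annotated before returning.
    """
    if n_residues < 5:
        raise ConstructionError("need at least 5 residues for a toy protein")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    serial = 1

    def add(name, element, resseq, resname, xyz, is_ligand=False):
        nonlocal serial
        atoms.append(Atom(
            serial=serial, name=name, element=element, residue_index=resseq,
            residue_name=resname, chain_id=chain, coords=np.asarray(xyz, float),
            mass=_mass(element), is_ligand=is_ligand,
        ))
        serial += 1

    # Backbone along a gentle helix; ~3.5 A residue spacing.
    for i in range(n_residues):
        t = i * 0.25
        c = np.array([3.0 * i, 9.0 * math.sin(t), 9.0 * math.cos(t)])
        add("N", "N", i + 1, "GLY", c + (-0.7, -0.8, 0.0))
        add("H", "H", i + 1, "GLY", c + (-0.7, -1.8, 0.0))
        add("CA", "C", i + 1, "GLY", c)
        add("C", "C", i + 1, "GLY", c + (0.9, 0.7, 0.0))
        add("O", "O", i + 1, "GLY", c + (0.9, 0.7, 1.23))

    ligand_template = None
    if ligand_spec is not None:
        mid = n_residues // 2
        t = mid * 0.25
        pocket = np.array([3.0 * mid, 9.0 * math.sin(t), 9.0 * math.cos(t)]) + (0.0, 0.0, -6.0)
        cursor = 0.0

        donors, acceptors, cations, anions, rings, apolar = [], [], [], [], [], []
        for r in range(ligand_spec.n_rings):
            names = [f"CR{r + 1}{k + 1}" for k in range(6)]
            for name, xyz in zip(names, _hexagon(pocket + (cursor, 0.0, 0.0))):
                add(name, "C", ligand_resseq, ligand_resname, xyz, is_ligand=True)
            rings.append(tuple(names))
            cursor += 5.0
        for i in range(ligand_spec.n_donors):
            hvy, hyd = f"ND{i + 1}", f"HD{i + 1}"
            base = pocket + (cursor, 0.0, 0.0)
            add(hvy, "N", ligand_resseq, ligand_resname, base, is_ligand=True)
            add(hyd, "H", ligand_resseq, ligand_resname, base + (1.0, 0.0, 0.0), is_ligand=True)
            donors.append((hvy, (hyd,)))
            cursor += 4.0
        for i in range(ligand_spec.n_acceptors):
            name = f"OA{i + 1}"
            add(name, "O", ligand_resseq, ligand_resname, pocket + (cursor, 0.0, 0.0), is_ligand=True)
            acceptors.append(name)
            cursor += 4.0
        for g in range(ligand_spec.n_cation_groups):
            base = pocket + (cursor, 0.0, 0.0)
            names = (f"CC{g + 1}", f"NC{g + 1}A", f"NC{g + 1}B", f"NC{g + 1}C")
            offsets = [(0, 0, 0), (1.33, 0, 0), (-0.665, 1.15, 0), (-0.665, -1.15, 0)]
            for name, off in zip(names, offsets):
                add(name, "N" if name.startswith("N") else "C",
                    ligand_resseq, ligand_resname, base + np.array(off, float), is_ligand=True)
            cations.append(names)
            cursor += 5.0
        for g in range(ligand_spec.n_anion_groups):
            base = pocket + (cursor, 0.0, 0.0)
            names = (f"CX{g + 1}", f"OX{g + 1}A", f"OX{g + 1}B")
            offsets = [(0, 0, 0), (1.10, 0.6, 0), (1.10, -0.6, 0)]
            for name, off in zip(names, offsets):
                add(name, "O" if name.startswith("O") else "C",
                    ligand_resseq, ligand_resname, base + np.array(off, float), is_ligand=True)
            anions.append(names)
            cursor += 4.5
        for i in range(ligand_spec.n_apolar):
            name = f"CM{i + 1}"
            add(name, "C", ligand_resseq, ligand_resname, pocket + (cursor, 0.0, 0.0), is_ligand=True)
            apolar.append(name)
            cursor += 3.5

        ligand_template = ResidueTemplate(
            donors=tuple(donors), acceptors=tuple(acceptors),
            cation_groups=tuple(tuple(c) for c in cations),
            anion_groups=tuple(tuple(a) for a in anions),
            rings=tuple(tuple(r) for r in rings), apolar=tuple(apolar),
        )

    frames = np.array([[a.coords for a in atoms]])
    series = MolecularFrameSeries(
        atoms=atoms, frames=frames, frame_times=np.array([0.0]),
        ligand_mask=np.array([a.is_ligand for a in atoms]),
    )
    templates = {ligand_resname: ligand_template} if ligand_template else None
    return annotate_chemistry(series, templates=templates)


# -----------------------------------------------------------------------------
# Fluctuation trajectories
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationSpec:
    """Per-residue per-axis Gaussian amplitude (nm) for synthetic motion.

    Each residue moves rigidly (all its atoms share one displacement per
    frame), so the expected Calpha RMSF of residue r is sigma_r * sqrt(3).
    """

    sigma_nm: np.ndarray          # per protein residue, nm
    n_frames: int
    seed: int = 0
    rigid_rotation_deg: float = 0.0     # optional global motion per frame
    rigid_translation_ang: float = 0.0
    time_step_ns: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_nm", np.asarray(self.sigma_nm, float))
        if np.any(self.sigma_nm < 0):
            raise ConstructionError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ConstructionError("need at least one frame")


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = math.radians(rng.normal(0.0, angle_deg))
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)


def make_fluctuation_trajectory(
    complex_series: MolecularFrameSeries,
    spec: FluctuationSpec,
) -> MolecularFrameSeries:
    """Reference frame + per-residue rigid Gaussian jitter (+ optional global
    rigid motion).  The ligand, if present, is kept rigid at sigma = 0."""
    rng = np.random.default_rng(spec.seed)
    ref = complex_series.frames[0]
    res_idx = complex_series.residue_atom_indices()
    protein_keys = [k for k, idx in res_idx.items()
                    if not complex_series.atoms[idx[0]].is_ligand]
    if spec.sigma_nm.size not in (1, len(protein_keys)):
        raise ConstructionError(
            f"sigma length {spec.sigma_nm.size} does not match {len(protein_keys)} protein residues"
        )
    sigma_ang = np.broadcast_to(spec.sigma_nm * _ANG_PER_NM, (len(protein_keys),))

    # residue-rigid displacements: one 3-vector per (frame, protein residue)
    disp = rng.standard_normal((spec.n_frames, len(protein_keys), 3)) * sigma_ang[None, :, None]
    atom_res = np.full(complex_series.n_atoms, -1)
    for r, key in enumerate(protein_keys):
        atom_res[res_idx[key]] = r
    frames = np.broadcast_to(ref, (spec.n_frames,) + ref.shape).copy()
    moving = atom_res >= 0
    frames[:, moving, :] += disp[:, atom_res[moving], :]

    if spec.rigid_rotation_deg > 0 or spec.rigid_translation_ang > 0:
        for t in range(spec.n_frames):
            rot = _random_rotation(rng, spec.rigid_rotation_deg)
            shift = rng.normal(0.0, spec.rigid_translation_ang or 1e-12, size=3)
            center = frames[t].mean(axis=0)
            frames[t] = (frames[t] - center) @ rot.T + center + shift

    out = complex_series.copy()
    out.frames = frames
    out.frame_times = np.arange(spec.n_frames, dtype=float) * spec.time_step_ns
    return out


# -----------------------------------------------------------------------------
# Planted interaction snapshots
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One protein-ligand contact to be built at an exact geometry.

    ``geometry`` keys by type:
      hbond        -> h_a, d_a (Angstrom); D-H bond fixed at 1.0 A
      salt_bridge  -> min_distance
      pi_stacking  -> centroid_distance, offset
      hydrophobic  -> distance
    """

    type: str
    geometry: dict
    donor_side: str = "protein"      # hbond only: which side donates
    residue_name: str = ""           # protein probe residue; default per type
    residue_seq: int = 0             # 0 -> auto-numbered
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in ("hbond", "salt_bridge", "pi_stacking", "hydrophobic"):
            raise ConstructionError(f"unknown interaction type {self.type!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ConstructionError("occupancy must lie in [0, 1]")
        if self.type == "hbond":
            h_a, d_a = self.geometry["h_a"], self.geometry["d_a"]
            if not (abs(d_a - h_a) <= 1.0 <= d_a + h_a):
                raise ConstructionError(
                    f"hbond geometry h_a={h_a}, d_a={d_a} violates the D-H-A triangle "
                    "inequality with a 1.0 A D-H bond"
                )
        if self.type == "pi_stacking":
            if self.geometry["offset"] > self.geometry["centroid_distance"]:
                raise ConstructionError("pi-stacking offset cannot exceed centroid distance")


_DEFAULT_PROBE = {"hbond": "GLY", "salt_bridge": "ASP", "pi_stacking": "PHE",
                  "hydrophobic": "ALA"}


def _probe_ring_names(residue_name: str) -> list[str]:
    # TRP's aromatic 6-ring uses different atom names than PHE/TYR
    if residue_name == "TRP":
        return ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
    return ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
_SLOT_SPACING = 25.0
_MIN_HEAVY_CLEARANCE = 1.5
_GEOM_TOL = 0.01


def _build_slot(inter: PlantedInteraction, origin: np.ndarray):
    """Return (protein atom specs, ligand atom specs, per-slot geometry checker).

    Atom specs are (name, element, xyz) tuples; roles come from templates.
    """
    prot: list[tuple[str, str, np.ndarray]] = []
    lig: list[tuple[str, str, np.ndarray]] = []
    if inter.type == "hbond":
        h_a, d_a = float(inter.geometry["h_a"]), float(inter.geometry["d_a"])
        d = origin
        h = origin + (1.0, 0.0, 0.0)
        ax = (d_a ** 2 - h_a ** 2 + 1.0) / 2.0
        ay2 = d_a ** 2 - ax ** 2
        if ay2 < -1e-9:
            raise ConstructionError(f"unrealizable hbond geometry h_a={h_a}, d_a={d_a}")
        a = origin + (ax, math.sqrt(max(ay2, 0.0)), 0.0)
        if inter.donor_side == "protein":
            prot = [("N", "N", d), ("H", "H", h)]
            lig = [("OA9", "O", a)]
        else:
            lig = [("ND9", "N", d), ("HD9", "H", h)]
            prot = [("O", "O", a)]
    elif inter.type == "salt_bridge":
        dist = float(inter.geometry["min_distance"])
        lig = [
            ("CC9", "C", origin),
            ("NC9A", "N", origin + (1.33, 0.0, 0.0)),
            ("NC9B", "N", origin + (-0.665, 1.15, 0.0)),
            ("NC9C", "N", origin + (-0.665, -1.15, 0.0)),
        ]
        od1 = origin + (1.33 + dist, 0.0, 0.0)
        prot = [
            ("OD1", "O", od1),
            ("CG", "C", od1 + (1.10, 0.60, 0.0)),
            ("OD2", "O", od1 + (2.20, 0.0, 0.0)),
        ]
    elif inter.type == "pi_stacking":
        cen = float(inter.geometry["centroid_distance"])
        off = float(inter.geometry["offset"])
        h = math.sqrt(cen ** 2 - off ** 2)
        lig_names = [f"CR9{k + 1}" for k in range(6)]
        lig = [(n, "C", xyz) for n, xyz in zip(lig_names, _hexagon(origin))]
        prot_names = _probe_ring_names(inter.residue_name)
        prot_center = origin + (off, 0.0, h)
        prot = [(n, "C", xyz) for n, xyz in zip(prot_names, _hexagon(prot_center))]
    else:  # hydrophobic
        dist = float(inter.geometry["distance"])
        prot = [("CB", "C", origin)]
        lig = [("CM9", "C", origin + (dist, 0.0, 0.0))]
    return prot, lig


def _measure_slot(inter: PlantedInteraction, prot_xyz: dict, lig_xyz: dict) -> dict:
    if inter.type == "hbond":
        if inter.donor_side == "protein":
            d, h, a = prot_xyz["N"], prot_xyz["H"], lig_xyz["OA9"]
        else:
            d, h, a = lig_xyz["ND9"], lig_xyz["HD9"], prot_xyz["O"]
        return {"h_a": float(np.linalg.norm(h - a)), "d_a": float(np.linalg.norm(d - a))}
    if inter.type == "salt_bridge":
        cat = np.array([lig_xyz[n] for n in ("CC9", "NC9A", "NC9B", "NC9C")])
        ani = np.array([prot_xyz[n] for n in ("OD1", "OD2")])
        dmat = np.linalg.norm(cat[:, None] - ani[None, :], axis=2)
        return {"min_distance": float(dmat.min())}
    if inter.type == "pi_stacking":
        lig_c = np.mean([lig_xyz[f"CR9{k + 1}"] for k in range(6)], axis=0)
        prot_c = np.mean([prot_xyz[n] for n in _probe_ring_names(inter.residue_name)], axis=0)
        vec = prot_c - lig_c
        cen = float(np.linalg.norm(vec))
        normal = np.array([0.0, 0.0, 1.0])
        off = float(np.linalg.norm(vec - np.dot(vec, normal) * normal))
        return {"centroid_distance": cen, "offset": off}
    return {"distance": float(np.linalg.norm(prot_xyz["CB"] - lig_xyz["CM9"]))}


def plant_interaction_snapshot(
    complex_series: MolecularFrameSeries | None,
    interactions: list[PlantedInteraction],
    chain: str = "A",
    ligand_resname: str = "LIG",
    ligand_resseq: int = 386,
) -> MolecularFrameSeries:
    """Single-frame series whose contacts match the requested geometries.

    Each interaction is built in its own spatial slot (25 A apart) from a
    minimal protein probe residue plus ligand atoms; planted geometry is
    re-measured after construction and must agree within 0.01 A.  With an
    empty interaction list the input complex is returned unchanged (copy).
    """
    if not interactions:
        if complex_series is None:
            raise ConstructionError("no interactions and no base complex given")
        return complex_series.copy()
    if complex_series is not None:
        ligand_resname = next(
            (a.residue_name for a in complex_series.atoms if a.is_ligand), ligand_resname
        )

    atoms: list[Atom] = []
    lig_atoms: list[Atom] = []
    serial = 1
    ligand_template_parts = {
        "donors": [], "acceptors": [], "cations": [], "rings": [], "apolar": [],
    }
    slot_lig_names: list[list[str]] = []
    errors: list[str] = []
    auto_seq = 0

    for s, inter in enumerate(interactions):
        origin = np.array([s * _SLOT_SPACING, 0.0, 0.0])
        prot, lig = _build_slot(inter, origin)
        auto_seq += 1
        resseq = inter.residue_seq or auto_seq
        resname = inter.residue_name or _DEFAULT_PROBE[inter.type]
        for name, element, xyz in prot:
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_index=resseq, residue_name=resname,
                              chain_id=chain, coords=np.asarray(xyz, float),
                              mass=_mass(element)))
            serial += 1
        # Ligand atoms get slot-unique names (suffix = slot number).
        renamed = []
        for name, element, xyz in lig:
            uname = name.replace("9", str(s + 1)) if "9" in name else f"{name}{s + 1}"
            renamed.append((uname, name))
            lig_atoms.append(Atom(serial=0, name=uname, element=element,
                                  residue_index=ligand_resseq, residue_name=ligand_resname,
                                  chain_id=chain, coords=np.asarray(xyz, float),
                                  mass=_mass(element), is_ligand=True))
        slot_lig_names.append([u for u, _ in renamed])
        mapping = dict(renamed)
        if inter.type == "hbond" and inter.donor_side == "ligand":
            ligand_template_parts["donors"].append(
                (next(u for u, n in mapping.items() if n == "ND9"),
                 (next(u for u, n in mapping.items() if n == "HD9"),))
            )
        if inter.type == "hbond" and inter.donor_side == "protein":
            ligand_template_parts["acceptors"].append(slot_lig_names[-1][0])
        if inter.type == "salt_bridge":
            ligand_template_parts["cations"].append(tuple(slot_lig_names[-1]))
        if inter.type == "pi_stacking":
            ligand_template_parts["rings"].append(tuple(slot_lig_names[-1]))
        if inter.type == "hydrophobic":
            ligand_template_parts["apolar"].append(slot_lig_names[-1][0])

    for a in lig_atoms:
        a.serial = serial
        serial += 1
    atoms = atoms + lig_atoms

    frames = np.array([[a.coords for a in atoms]])
    series = MolecularFrameSeries(
        atoms=atoms, frames=frames, frame_times=np.array([0.0]),
        ligand_mask=np.array([a.is_ligand for a in atoms]),
    )
    lig_template = ResidueTemplate(
        donors=tuple(ligand_template_parts["donors"]),
        acceptors=tuple(ligand_template_parts["acceptors"]),
        cation_groups=tuple(ligand_template_parts["cations"]),
        rings=tuple(ligand_template_parts["rings"]),
        apolar=tuple(ligand_template_parts["apolar"]),
    )
    annotate_chemistry(series, templates={ligand_resname: lig_template},
                       require_hydrogens=False)

    # steric clearance between heavy atoms of different sides
    heavy = [a for a in series.atoms if a.element != "H"]
    for i, a in enumerate(heavy):
        for b in heavy[i + 1:]:
            if a.is_ligand == b.is_ligand:
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d < _MIN_HEAVY_CLEARANCE:
                errors.append(f"{a.residue_label}.{a.name} vs ligand {b.name}: {d:.2f} A")
    if errors:
        raise ConstructionError("steric overlap < 1.5 A: " + "; ".join(errors))

    # post-construction verification of every requested geometry
    by_name = {(a.residue_key, a.name): a.coords for a in series.atoms}
    auto_seq = 0
    for s, inter in enumerate(interactions):
        auto_seq += 1
        resseq = inter.residue_seq or auto_seq
        prot_xyz = {a.name: a.coords for a in series.atoms
                    if not a.is_ligand and a.residue_index == resseq}
        lig_xyz = {a.name.replace(str(s + 1), "9", 1) if str(s + 1) in a.name else a.name: a.coords
                   for a in series.atoms if a.is_ligand and a.name in
                   set(slot_lig_names[s])}
        measured = _measure_slot(inter, prot_xyz, lig_xyz)
        for key, want in inter.geometry.items():
            got = measured[key]
            if abs(got - float(want)) > _GEOM_TOL:
                errors.append(f"slot {s} {inter.type} {key}: wanted {want}, measured {got:.4f}")
    if errors:
        raise ConstructionError("planted geometry verification failed: " + "; ".join(errors))
    return series


def plant_interaction_trajectory(
    complex_series: MolecularFrameSeries | None,
    interactions: list[PlantedInteraction],
    n_frames: int,
    **kwargs,
) -> MolecularFrameSeries:
    """Multi-frame version honouring each interaction's ``occupancy``.

    In frames where an interaction is absent its ligand atoms are displaced
    far from the probe; present frames are spread evenly so the persistence
    equals floor(occupancy * n_frames) / n_frames exactly (0.5 alternates).
    """
    snap = plant_interaction_snapshot(complex_series, interactions, **kwargs)
    if not interactions:
        return snap
    name_to_idx = {a.name: i for i, a in enumerate(snap.atoms) if a.is_ligand}
    frames = np.repeat(snap.frames, n_frames, axis=0)
    t_idx = np.arange(n_frames)
    for s, inter in enumerate(interactions):
        occ = inter.occupancy
        present = np.floor((t_idx + 1) * occ) - np.floor(t_idx * occ) >= 1.0
        slot_atoms = [name_to_idx[n] for n in _slot_ligand_names(snap, s)]
        for t in np.flatnonzero(~present):
            frames[t, slot_atoms, 2] += 50.0
    out = snap.copy()
    out.frames = frames
    out.frame_times = np.arange(n_frames, dtype=float)
    return out


def _slot_ligand_names(series: MolecularFrameSeries, slot: int) -> list[str]:
    lo = slot * _SLOT_SPACING - _SLOT_SPACING / 2
    hi = slot * _SLOT_SPACING + _SLOT_SPACING / 2
    return [a.name for a in series.atoms
            if a.is_ligand and lo < a.coords[0] < hi]


# -----------------------------------------------------------------------------
# Energy series and RMSF profile pairs
# -----------------------------------------------------------------------------

def make_energy_series(
    means: dict[str, float],
    sds: dict[str, float],
    n_frames: int,
    seed: int = 0,
) -> EnergyComponentSeries:
    """Independent Gaussian per-frame components with the given means/SDs."""
    if n_frames < 1:
        raise ConstructionError("need at least one frame")
    missing = [c for c in COMPONENTS if c not in means or c not in sds]
    if missing:
        raise ConstructionError(f"means/sds must name all of {COMPONENTS}; missing {missing}")
    if any(sds[c] < 0 for c in COMPONENTS):
        raise ConstructionError("sds must be non-negative")
    rng = np.random.default_rng(seed)
    draws = {c: means[c] + sds[c] * rng.standard_normal(n_frames) for c in COMPONENTS}
    return EnergyComponentSeries(
        vdwaals=draws["VDWAALS"], eel=draws["EEL"],
        epb=draws["EPB"], enpolar=draws["ENPOLAR"],
    )


def make_rmsf_pair(
    length: int,
    baseline: float = 0.08,
    bump_range: tuple[int, int] = (159, 168),
    bump_delta: float = 0.3,
    seed: int = 0,
    jitter_max: float = 0.04,
) -> tuple[RMSFProfile, RMSFProfile]:
    """Profile pair (A, B) with B = A + ``bump_delta`` on ``bump_range``
    (inclusive residue ids) and |B - A| < ``jitter_max`` elsewhere."""
    lo, hi = bump_range
    if not (1 <= lo <= hi <= length):
        raise ConstructionError(f"bump range {bump_range} outside profile 1..{length}")
    rng = np.random.default_rng(seed)
    ids = np.arange(1, length + 1)
    a = np.full(length, baseline, float)
    jitter = rng.uniform(-jitter_max, jitter_max, size=length)
    b = a + jitter
    in_bump = (ids >= lo) & (ids <= hi)
    b[in_bump] = a[in_bump] + bump_delta
    b = np.clip(b, 0.0, None)
    return (
        RMSFProfile(residue_ids=ids, rmsf=a),
        RMSFProfile(residue_ids=ids.copy(), rmsf=b),
    )
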