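"""Geometric protein-ligand interaction detection and trajectory fingerprints.

Four detectors (hydrogen bond, salt bridge, pi-stacking, hydrophobic contact)
operate on single frames across the protein-ligand interface; the trajectory
fingerprint runs all of them per frame and records per-(residue, type)
presence plus persistence.  All thresholds are inclusive and every emitted
event stores the geometry that satisfied them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, SelectionError, StructureError
from .structure_model import MolecularFrameSeries

__all__ = [
    "InteractionEvent",
    "FingerprintMatrix",
    "HBondPairStat",
    "DetectorConfig",
    "detect_hbonds_frame",
    "detect_salt_bridges_frame",
    "detect_pi_stacking_frame",
    "detect_hydrophobic_frame",
    "detect_all_frame",
    "fingerprint_trajectory",
    "hbond_distance_table",
    "contact_class_map",
]

_ANG_PER_NM = 10.0


@dataclass(frozen=True)
class DetectorConfig:
    """All geometric thresholds (Angstrom / degrees), inclusive."""

    hbond_h_a_max: float = 3.0
    hbond_d_a_max: float = 4.0
    hbond_dha_min: float = 120.0
    salt_bridge_max: float = 5.5
    pi_centroid_max: float = 5.5
    pi_offset_max: float = 2.0
    pi_planarity_max: float = 35.0
    hydrophobic_max: float = 4.5


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    type: str                      # hbond | salt_bridge | pi_stacking | hydrophobic
    protein_residue: str           # e.g. "GLY74"
    ligand_atoms: tuple[int, ...]  # atom indices on the ligand side
    geometry: dict = field(default_factory=dict)  # distances (A) and angles (deg)
    detail: dict = field(default_factory=dict)    # atom names etc. for reporting


@dataclass(frozen=True)
class HBondPairStat:
    donor_residue: str
    donor_atom: str
    acceptor_residue: str
    acceptor_atom: str
    mean_distance_nm: float

    def __post_init__(self) -> None:
        if self.mean_distance_nm <= 0:
            raise StructureError("mean donor-acceptor distance must be positive")


@dataclass
class FingerprintMatrix:
    """frames x (residue, type) boolean presence with per-key persistence."""

    keys: list[tuple[str, str]]        # (protein residue label, interaction type)
    matrix: np.ndarray                 # (T, K) bool
    events: list[list[InteractionEvent]]  # per frame

    @property
    def n_frames(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def persistence(self) -> dict[tuple[str, str], float]:
        t = self.matrix.shape[0]
        return {
            key: float(self.matrix[:, k].sum()) / t
            for k, key in enumerate(self.keys)
        }


def _require_annotation(series: MolecularFrameSeries) -> None:
    if not series.annotated:
        raise AnnotationError("series is not chemistry-annotated; call annotate_chemistry first")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b (degrees)."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds_frame(
    series: MolecularFrameSeries,
    frame: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> list[InteractionEvent]:
    """Cross-interface hydrogen bonds in one frame.

    Criteria (all inclusive): d(H, A) <= ``hbond_h_a_max``,
    d(D, A) <= ``hbond_d_a_max``, angle D-H-A >= ``hbond_dha_min``.
    Both directions (protein donor -> ligand acceptor and vice versa).
    """
    _require_annotation(series)
    if not series.donor_pairs and any("donor-heavy" in a.roles for a in series.atoms):
        raise AnnotationError("declared donors carry no hydrogens")
    coords = series.frames[frame]
    lig = series.ligand_mask
    events = []
    for d_idx, h_idx in series.donor_pairs:
        for a_idx in series.acceptors:
            if lig[d_idx] == lig[a_idx]:
                continue  # same side of the interface
            d_a = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            if d_a > config.hbond_d_a_max:
                continue
            h_a = float(np.linalg.norm(coords[h_idx] - coords[a_idx]))
            if h_a > config.hbond_h_a_max:
                continue
            dha = _angle_deg(coords[d_idx], coords[h_idx], coords[a_idx])
            if dha < config.hbond_dha_min:
                continue
            prot_idx = a_idx if lig[d_idx] else d_idx
            lig_atoms = (d_idx, h_idx) if lig[d_idx] else (a_idx,)
            events.append(InteractionEvent(
                frame=frame, type="hbond",
                protein_residue=series.atoms[prot_idx].residue_label,
                ligand_atoms=lig_atoms,
                geometry={"h_a": h_a, "d_a": d_a, "dha_angle": dha},
                detail={
                    "donor_residue": series.atoms[d_idx].residue_label,
                    "donor_atom": series.atoms[d_idx].name,
                    "acceptor_residue": series.atoms[a_idx].residue_label,
                    "acceptor_atom": series.atoms[a_idx].name,
                },
            ))
    return events


def detect_salt_bridges_frame(
    series: MolecularFrameSeries,
    frame: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> list[InteractionEvent]:
    """Cation-group / anion-group contacts across the interface.

    A pair counts when the minimum inter-atom distance between the two groups
    is <= ``salt_bridge_max``; that minimum is the reported distance.
    """
    _require_annotation(series)
    coords = series.frames[frame]
    lig = series.ligand_mask
    events = []
    for sign_a, grp_a in series.charged_groups:
        for sign_b, grp_b in series.charged_groups:
            if sign_a != +1 or sign_b != -1:
                continue
            if lig[grp_a[0]] == lig[grp_b[0]]:
                continue
            dmat = np.linalg.norm(
                coords[np.array(grp_a)][:, None, :] - coords[np.array(grp_b)][None, :, :],
                axis=2,
            )
            dmin = float(dmat.min())
            if dmin > config.salt_bridge_max:
                continue
            prot_grp, lig_grp = (grp_b, grp_a) if lig[grp_a[0]] else (grp_a, grp_b)
            events.append(InteractionEvent(
                frame=frame, type="salt_bridge",
                protein_residue=series.atoms[prot_grp[0]].residue_label,
                ligand_atoms=tuple(lig_grp),
                geometry={"min_distance": dmin},
            ))
    return events


def _ring_geometry(coords: np.ndarray, ring: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Ring centroid and unit normal (best-fit plane via SVD)."""
    pts = coords[np.array(ring)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] <= 1e-8:
        raise StructureError(f"degenerate (collinear) ring: atoms {ring}")
    return centroid, vt[2]


def detect_pi_stacking_frame(
    series: MolecularFrameSeries,
    frame: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> list[InteractionEvent]:
    """Face-to-face pi-stacking between cross-interface aromatic ring pairs.

    Conditions: centroid distance <= ``pi_centroid_max``; lateral offset (the
    centroid-centroid vector projected onto the protein ring plane) <=
    ``pi_offset_max``; angle between ring normals (folded to <= 90 deg) <=
    ``pi_planarity_max``.
    """
    _require_annotation(series)
    coords = series.frames[frame]
    lig = series.ligand_mask
    prot_rings = [r for r in series.rings if not lig[r[0]]]
    lig_rings = [r for r in series.rings if lig[r[0]]]
    events = []
    for pr in prot_rings:
        c_p, n_p = _ring_geometry(coords, pr)
        for lr in lig_rings:
            c_l, n_l = _ring_geometry(coords, lr)
            vec = c_l - c_p
            dist = float(np.linalg.norm(vec))
            if dist > config.pi_centroid_max:
                continue
            offset = float(np.linalg.norm(vec - np.dot(vec, n_p) * n_p))
            if offset > config.pi_offset_max:
                continue
            ang = float(np.degrees(np.arccos(np.clip(abs(np.dot(n_p, n_l)), 0.0, 1.0))))
            if ang > config.pi_planarity_max:
                continue
            events.append(InteractionEvent(
                frame=frame, type="pi_stacking",
                protein_residue=series.atoms[pr[0]].residue_label,
                ligand_atoms=tuple(lr),
                geometry={"centroid_distance": dist, "offset": offset, "normal_angle": ang},
            ))
    return events


def detect_hydrophobic_frame(
    series: MolecularFrameSeries,
    frame: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> list[InteractionEvent]:
    """One event per protein residue with any apolar-apolar cross-interface
    pair within ``hydrophobic_max``."""
    _require_annotation(series)
    coords = series.frames[frame]
    lig = series.ligand_mask
    apolar = np.array([("apolar" in a.roles) for a in series.atoms])
    lig_idx = np.flatnonzero(apolar & lig)
    prot_idx = np.flatnonzero(apolar & ~lig)
    events = []
    if lig_idx.size == 0 or prot_idx.size == 0:
        return events
    dmat = np.linalg.norm(coords[prot_idx][:, None, :] - coords[lig_idx][None, :, :], axis=2)
    per_res: dict[str, tuple[float, int]] = {}
    for row, p in enumerate(prot_idx):
        dmin = float(dmat[row].min())
        if dmin > config.hydrophobic_max:
            continue
        label = series.atoms[p].residue_label
        best = per_res.get(label)
        if best is None or dmin < best[0]:
            per_res[label] = (dmin, int(lig_idx[int(np.argmin(dmat[row]))]))
    for label, (dmin, latom) in sorted(per_res.items()):
        events.append(InteractionEvent(
            frame=frame, type="hydrophobic", protein_residue=label,
            ligand_atoms=(latom,), geometry={"min_distance": dmin},
        ))
    return events


_DETECTORS = (
    detect_hbonds_frame,
    detect_salt_bridges_frame,
    detect_pi_stacking_frame,
    detect_hydrophobic_frame,
)


def detect_all_frame(
    series: MolecularFrameSeries,
    frame: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> list[InteractionEvent]:
    events: list[InteractionEvent] = []
    for det in _DETECTORS:
        events.extend(det(series, frame, config))
    return events


def fingerprint_trajectory(
    series: MolecularFrameSeries,
    config: DetectorConfig = DetectorConfig(),
) -> FingerprintMatrix:
    """Run all four detectors on every frame; boolean per (residue, type)."""
    _require_annotation(series)
    per_frame = [detect_all_frame(series, t, config) for t in range(series.n_frames)]
    keys = sorted({(e.protein_residue, e.type) for evs in per_frame for e in evs})
    key_pos = {k: i for i, k in enumerate(keys)}
    matrix = np.zeros((series.n_frames, len(keys)), dtype=bool)
    for t, evs in enumerate(per_frame):
        for e in evs:
            matrix[t, key_pos[(e.protein_residue, e.type)]] = True
    return FingerprintMatrix(keys=keys, matrix=matrix, events=per_frame)


def _resolve_atom(series: MolecularFrameSeries, residue_label: str, atom_name: str) -> int:
    for i, a in enumerate(series.atoms):
        if a.residue_label == residue_label and a.name == atom_name:
            return i
    raise SelectionError(f"cannot resolve atom {residue_label}.{atom_name}")


def hbond_distance_table(
    series: MolecularFrameSeries,
    pairs: list[tuple[str, str, str, str]],
) -> list[HBondPairStat]:
    """Mean donor-acceptor distance (nm) over ALL frames for each named pair.

    ``pairs`` entries are (donor residue label, donor atom name,
    acceptor residue label, acceptor atom name); e.g.
    ("GLY74", "N", "LIG386", "N24").  Means are over every frame whether or
    not the bond criteria hold in it.
    """
    stats = []
    for don_res, don_atom, acc_res, acc_atom in pairs:
        d_idx = _resolve_atom(series, don_res, don_atom)
        a_idx = _resolve_atom(series, acc_res, acc_atom)
        dists = np.linalg.norm(series.frames[:, d_idx, :] - series.frames[:, a_idx, :], axis=1)
        stats.append(HBondPairStat(
            donor_residue=don_res, donor_atom=don_atom,
            acceptor_residue=acc_res, acceptor_atom=acc_atom,
            mean_distance_nm=float(np.mean(dists)) / _ANG_PER_NM,
        ))
    return stats


def contact_class_map(
    series: MolecularFrameSeries,
    frame: int = 0,
    green_max: float = 4.0,
    yellow_max: float = 6.0,
) -> dict[str, str]:
    """Per protein residue: 'green' (< green_max), 'yellow' ([green_max,
    yellow_max]), or 'none', by minimum heavy-atom distance to the ligand."""
    if not series.ligand_mask.any():
        raise SelectionError("contact classing requires a ligand")
    coords = series.frames[frame]
    heavy = np.array([a.element != "H" for a in series.atoms])
    lig_idx = np.flatnonzero(series.ligand_mask & heavy)
    out = {}
    for key, idx in series.residue_atom_indices().items():
        atoms = [i for i in idx if heavy[i] and not series.ligand_mask[i]]
        if not atoms:
            continue
        dmin = float(np.min(np.linalg.norm(
            coords[np.array(atoms)][:, None, :] - coords[lig_idx][None, :, :], axis=2,
        )))
        label = series.atoms[atoms[0]].residue_label
        out[label] = "green" if dmin < green_max else ("yellow" if dmin <= yellow_max else "none")
    return out
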