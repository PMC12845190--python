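"""Per-frame trajectory descriptors: RMSD series, per-residue RMSF, Rg.

Internally everything is Angstrom; descriptor outputs default to nm to match
the usual reporting convention for MD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientFramesError, SelectionError, StructureError
from .structure_model import AtomSelection, MolecularFrameSeries, select_atoms
from .superposition import kabsch_fit, rmsd

__all__ = ["SeriesSummary", "RMSFProfile", "rmsd_series", "rmsf_profile", "rg_series"]

_ANG_PER_NM = 10.0


@dataclass(frozen=True)
class SeriesSummary:
    """Mean +/- sample SD of a per-frame series."""

    mean: float
    sd: float | None   # sample SD (ddof=1); None when n < 2
    n: int
    unit: str

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": self.n, "unit": self.unit}


def summarize(values: np.ndarray, unit: str) -> SeriesSummary:
    values = np.asarray(values, float)
    if values.size < 1:
        raise StructureError("cannot summarize an empty series")
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else None
    return SeriesSummary(mean=float(np.mean(values)), sd=sd, n=int(values.size), unit=unit)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue fluctuation values (nm)."""

    residue_ids: np.ndarray
    rmsf: np.ndarray          # nm
    atom_basis: str = "calpha"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, int))
        object.__setattr__(self, "rmsf", np.asarray(self.rmsf, float))
        if self.residue_ids.shape != self.rmsf.shape:
            raise StructureError("residue ids and rmsf values must align")
        if np.any(self.rmsf < 0):
            raise StructureError("RMSF values must be non-negative")

    def __len__(self) -> int:
        return int(self.rmsf.size)


def _convert(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "nm":
        return values / _ANG_PER_NM
    if unit in ("angstrom", "A"):
        return values
    raise ValueError(f"unknown unit {unit!r}")


def rmsd_series(
    series: MolecularFrameSeries,
    fit_selection: AtomSelection | str = "backbone",
    measure_selection: AtomSelection | str | None = None,
    reference: int = 0,
    unit: str = "nm",
) -> tuple[np.ndarray, np.ndarray, SeriesSummary]:
    """RMSD of each frame against a reference frame.

    Each frame is Kabsch-fit on ``fit_selection`` to the reference frame,
    then RMSD is measured on ``measure_selection`` (defaults to the fit
    selection).  Returns (times_ns, values, summary).
    """
    fit_idx = select_atoms(series, fit_selection)
    meas_idx = fit_idx if measure_selection is None else select_atoms(series, measure_selection)
    if not (0 <= reference < series.n_frames):
        raise SelectionError(f"reference frame {reference} out of range")
    ref_fit = series.frames[reference][fit_idx]
    ref_meas = series.frames[reference][meas_idx]
    values = np.empty(series.n_frames)
    for t in range(series.n_frames):
        tf = kabsch_fit(series.frames[t][fit_idx], ref_fit)
        values[t] = rmsd(tf.apply(series.frames[t][meas_idx]), ref_meas)
    values = _convert(values, unit)
    return series.frame_times.copy(), values, summarize(values, unit)


def _fit_all_frames(frames: np.ndarray, fit_idx: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        tf = kabsch_fit(frames[t][fit_idx], ref)
        out[t] = tf.apply(frames[t])
    return out


def rmsf_profile(
    series: MolecularFrameSeries,
    fit_selection: AtomSelection | str = "backbone",
    atom_basis: str = "calpha",
) -> RMSFProfile:
    """Per-residue RMSF (nm) about the time-average structure.

    Frames are first fit to frame 0 on ``fit_selection``; the time-average
    structure is computed and one refinement pass re-fits every frame to that
    average before deviations are measured.  ``atom_basis='calpha'`` uses the
    residue's CA atom; ``'heavy-mean'`` averages the mean squared deviation
    over the residue's heavy atoms.
    """
    if series.n_frames < 2:
        raise InsufficientFramesError("RMSF requires at least 2 frames")
    if atom_basis not in ("calpha", "heavy-mean"):
        raise ValueError(f"unknown atom_basis {atom_basis!r}")
    fit_idx = select_atoms(series, fit_selection)

    fitted = _fit_all_frames(series.frames, fit_idx, series.frames[0][fit_idx])
    mean_structure = fitted.mean(axis=0)
    fitted = _fit_all_frames(fitted, fit_idx, mean_structure[fit_idx])
    mean_structure = fitted.mean(axis=0)
    msf_per_atom = np.mean(np.sum((fitted - mean_structure) ** 2, axis=2), axis=0)

    residue_ids = []
    values = []
    for key, idx in series.residue_atom_indices().items():
        atoms = [series.atoms[i] for i in idx]
        if atoms[0].is_ligand:
            continue
        if atom_basis == "calpha":
            basis = [i for i, a in zip(idx, atoms) if a.name == "CA"]
            if not basis:
                continue
        else:
            basis = [i for i, a in zip(idx, atoms) if a.element != "H"]
        residue_ids.append(key[1])
        values.append(np.mean(msf_per_atom[basis]))
    if not residue_ids:
        raise SelectionError("no residues with the requested basis atoms")
    rmsf_nm = np.sqrt(np.asarray(values)) / _ANG_PER_NM
    return RMSFProfile(residue_ids=np.asarray(residue_ids), rmsf=rmsf_nm, atom_basis=atom_basis)


def rg_series(
    series: MolecularFrameSeries,
    selection: AtomSelection | str = "protein",
    mass_weighted: bool = True,
    unit: str = "nm",
) -> tuple[np.ndarray, np.ndarray, SeriesSummary]:
    """Radius of gyration per frame: sqrt(sum m_i |r_i - r_com|^2 / sum m_i)."""
    idx = select_atoms(series, selection)
    masses = series.masses()[idx] if mass_weighted else np.ones(idx.size)
    total = masses.sum()
    if total <= 0:
        raise StructureError("total mass is zero")
    coords = series.frames[:, idx, :]
    com = np.einsum("tij,i->tj", coords, masses) / total
    sq = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    values = np.sqrt(np.einsum("ti,i->t", sq, masses) / total)
    values = _convert(values, unit)
    return series.frame_times.copy(), values, summarize(values, unit)
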