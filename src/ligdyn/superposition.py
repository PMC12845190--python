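"""Rigid-body superposition: Kabsch fitting, RMSD, iterative pruned-pair RMSD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, PruningCollapseError

__all__ = ["RigidTransform", "SuperpositionResult", "kabsch_fit", "rmsd", "pruned_superpose"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile coordinates onto a reference."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), Angstrom

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise FitError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise FitError("rotation matrix is not a proper rotation (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ np.asarray(self.rotation).T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        r = np.asarray(self.rotation) @ np.asarray(other.rotation)
        t = np.asarray(self.rotation) @ np.asarray(other.translation) + self.translation
        return RigidTransform(rotation=r, translation=t)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd_all: float          # Angstrom, over all pairs under final transform
    rmsd_pruned: float       # Angstrom, over retained pairs
    retained_pairs: np.ndarray
    n_all: int
    n_retained: int


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between paired coordinate sets; no fitting performed."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise FitError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise FitError("expected non-empty (n, 3) coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Least-squares optimal rigid transform of ``mobile`` onto ``reference``.

    Minimises the (optionally weighted) sum of squared pair distances; a
    reflection solution is corrected by flipping the smallest singular
    direction, so the result is always a proper rotation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 atom pairs to fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise FitError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    p = mobile - cm
    q = reference - cr
    h = (p * w[:, None]).T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise FitError("degenerate point set (collinear or coincident); rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return RigidTransform(rotation=rot, translation=trans)


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """RMSD after an optimal Kabsch fit (convenience wrapper)."""
    tf = kabsch_fit(mobile, reference, weights)
    return rmsd(tf.apply(mobile), reference)


def pruned_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    cutoff: float = 2.0,
    max_iter: int = 50,
    min_fraction: float = 0.3,
) -> SuperpositionResult:
    """Iterative pruned-pair superposition.

    Repeats {fit on retained pairs; drop every pair whose post-fit distance
    exceeds ``cutoff``} until no pair exceeds the cutoff, ``max_iter`` is
    reached, or further pruning would retain fewer than
    ``min_fraction * n_all`` pairs (the last valid retained set is kept).
    Reports both the pruned RMSD and the all-pair RMSD under the final
    transform.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("mobile and reference must be matching (n, 3) arrays")
    n_all = mobile.shape[0]
    if n_all < 3:
        raise FitError(f"need at least 3 atom pairs, got {n_all}")

    retained = np.arange(n_all)
    min_keep = int(np.ceil(min_fraction * n_all))
    for _ in range(max_iter):
        tf = kabsch_fit(mobile[retained], reference[retained])
        dist = np.linalg.norm(tf.apply(mobile[retained]) - reference[retained], axis=1)
        keep = dist <= cutoff
        if keep.all():
            break
        candidate = retained[keep]
        if candidate.size < min_keep:
            break  # keep last valid retained set
        if candidate.size < 3:
            raise PruningCollapseError(
                f"pruning left {candidate.size} pairs; at least 3 required"
            )
        retained = candidate

    tf = kabsch_fit(mobile[retained], reference[retained])
    moved = tf.apply(mobile)
    return SuperpositionResult(
        transform=tf,
        rmsd_all=rmsd(moved, reference),
        rmsd_pruned=rmsd(moved[retained], reference[retained]),
        retained_pairs=retained,
        n_all=n_all,
        n_retained=int(retained.size),
    )
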