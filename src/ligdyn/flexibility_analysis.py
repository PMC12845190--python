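"""Three-class residue flexibility taxonomy and differential-flexibility detection.

Residues are binned on RMSF (nm): low (< 0.1), medium ([0.1, 0.3]), high
(> 0.3); both closed boundaries fall to medium.  Differential flexibility
between two systems is found by comparing sliding-window maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import StructureError
from .trajectory_descriptors import RMSFProfile

__all__ = [
    "FlexibilityClassing",
    "FlexSegment",
    "classify_flexibility",
    "flexibility_summary",
    "extrema_residues",
    "sliding_window_diff",
]

CLASS_ORDER = ("low", "medium", "high")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching printed-table style (36.455 -> 36.46)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FlexibilityClassing:
    residue_ids: np.ndarray
    labels: tuple[str, ...]            # per residue, in profile order
    low_max: float
    high_min: float

    @property
    def n_classified(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASS_ORDER}

    @property
    def percentages(self) -> dict[str, float]:
        n = self.n_classified
        return {c: round_half_up(100.0 * k / n) for c, k in self.counts.items()}


@dataclass(frozen=True)
class FlexSegment:
    """A run of residues where one system's windowed RMSF maxima dominate."""

    start_residue: int
    end_residue: int
    direction: str        # "A-higher" | "B-higher"
    peak_abs_diff: float  # nm

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise StructureError("segment start must not exceed end")
        if self.direction not in ("A-higher", "B-higher"):
            raise StructureError(f"bad direction {self.direction!r}")


def classify_flexibility(
    profile: RMSFProfile,
    low_max: float = 0.1,
    high_min: float = 0.3,
) -> FlexibilityClassing:
    """Label each residue low / medium / high by its RMSF (nm)."""
    if len(profile) == 0:
        raise StructureError("cannot classify an empty profile")
    if np.any(profile.rmsf < 0):
        raise StructureError("negative RMSF values are invalid")
    labels = tuple(
        "low" if v < low_max else ("high" if v > high_min else "medium")
        for v in profile.rmsf
    )
    return FlexibilityClassing(
        residue_ids=profile.residue_ids.copy(), labels=labels,
        low_max=low_max, high_min=high_min,
    )


def flexibility_summary(classing: FlexibilityClassing) -> list[dict]:
    """Three report rows: class, count, percentage (2 dp, half-up)."""
    counts = classing.counts
    pct = classing.percentages
    return [
        {"class": c, "count": counts[c], "percentage": pct[c]}
        for c in CLASS_ORDER
    ]


def extrema_residues(profile: RMSFProfile) -> tuple[int, float, int, float]:
    """(min residue id, min RMSF, max residue id, max RMSF); ties -> lowest id."""
    if len(profile) == 0:
        raise StructureError("empty profile")
    order = np.argsort(profile.residue_ids, kind="stable")
    ids = profile.residue_ids[order]
    vals = profile.rmsf[order]
    i_min = int(np.argmin(vals))   # argmin/argmax return first hit -> lowest id
    i_max = int(np.argmax(vals))
    return int(ids[i_min]), float(vals[i_min]), int(ids[i_max]), float(vals[i_max])


def sliding_window_diff(
    profile_a: RMSFProfile,
    profile_b: RMSFProfile,
    window: int = 5,
    min_abs_diff: float = 0.2,
) -> list[FlexSegment]:
    """Detect segments of differential flexibility between two profiles.

    Over the shared residue ids, every ``window``-residue sliding window
    (stride 1) compares the two profiles' window maxima,
    d = max(A) - max(B); windows with |d| >= ``min_abs_diff`` are flagged.
    Overlapping flagged windows of the same sign merge into one segment
    spanning their anchor (start) residues; ``peak_abs_diff`` is the largest
    |d| among the merged windows.
    """
    if window < 1:
        raise StructureError("window must be >= 1")
    shared = np.intersect1d(profile_a.residue_ids, profile_b.residue_ids)
    if shared.size == 0:
        raise StructureError("profiles share no residue ids")
    if window > shared.size:
        raise StructureError(f"window {window} exceeds shared length {shared.size}")

    a_map = dict(zip(profile_a.residue_ids.tolist(), profile_a.rmsf.tolist()))
    b_map = dict(zip(profile_b.residue_ids.tolist(), profile_b.rmsf.tolist()))
    a = np.array([a_map[r] for r in shared])
    b = np.array([b_map[r] for r in shared])

    n_windows = shared.size - window + 1
    segments: list[FlexSegment] = []
    open_seg: dict | None = None
    for s in range(n_windows):
        d = float(np.max(a[s:s + window]) - np.max(b[s:s + window]))
        flagged = abs(d) >= min_abs_diff
        sign = "A-higher" if d > 0 else "B-higher"
        if flagged and open_seg is not None and open_seg["direction"] == sign and s <= open_seg["last"] + window - 1:
            open_seg["last"] = s
            open_seg["peak"] = max(open_seg["peak"], abs(d))
        else:
            if open_seg is not None:
                segments.append(_close(open_seg, shared))
                open_seg = None
            if flagged:
                open_seg = {"first": s, "last": s, "direction": sign, "peak": abs(d)}
    if open_seg is not None:
        segments.append(_close(open_seg, shared))
    return segments


def _close(seg: dict, shared: np.ndarray) -> FlexSegment:
    return FlexSegment(
        start_residue=int(shared[seg["first"]]),
        end_residue=int(shared[seg["last"]]),
        direction=seg["direction"],
        peak_abs_diff=seg["peak"],
    )
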