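"""End-state binding-energy component bookkeeping.

Aggregates per-frame VDWAALS / EEL / EPB / ENPOLAR series (kcal/mol) into
GGAS = VDWAALS + EEL, GSOLV = EPB + ENPOLAR and TOTAL = GGAS + GSOLV, with
sample SDs computed on the per-frame derived series so the additivity
identities hold exactly at the mean level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, StructureError

__all__ = [
    "COMPONENTS",
    "EnergyComponentSeries",
    "EnergySummary",
    "summarize_energy",
    "delta_binding",
    "read_component_table",
    "write_component_table",
]

COMPONENTS = ("VDWAALS", "EEL", "EPB", "ENPOLAR")
DERIVED = ("GGAS", "GSOLV", "TOTAL")


@dataclass(frozen=True)
class EnergyComponentSeries:
    vdwaals: np.ndarray
    eel: np.ndarray
    epb: np.ndarray
    enpolar: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, f), float) for f in ("vdwaals", "eel", "epb", "enpolar")]
        n = arrays[0].size
        if n < 1:
            raise StructureError("energy series must have at least one frame")
        for name, arr in zip(COMPONENTS, arrays):
            object.__setattr__(self, name.lower(), arr)
            if arr.shape != (n,):
                raise StructureError("energy component series must share one length")
            if not np.all(np.isfinite(arr)):
                raise StructureError(f"non-finite values in {name}")

    @property
    def n_frames(self) -> int:
        return int(self.vdwaals.size)

    def component(self, name: str) -> np.ndarray:
        if name in COMPONENTS:
            return getattr(self, name.lower())
        if name == "GGAS":
            return self.vdwaals + self.eel
        if name == "GSOLV":
            return self.epb + self.enpolar
        if name == "TOTAL":
            return self.vdwaals + self.eel + self.epb + self.enpolar
        raise KeyError(name)


@dataclass(frozen=True)
class EnergySummary:
    """Mean +/- sample SD per component and derived term; kcal/mol."""

    means: dict[str, float]
    sds: dict[str, float | None]
    n: int

    def as_dict(self) -> dict:
        return {
            "n_frames": self.n,
            **{k: {"mean": self.means[k], "sd": self.sds[k]} for k in COMPONENTS + DERIVED},
        }


def summarize_energy(series: EnergyComponentSeries) -> EnergySummary:
    """Mean and sample SD for each raw component and per-frame derived term."""
    means: dict[str, float] = {}
    sds: dict[str, float | None] = {}
    for name in COMPONENTS + DERIVED:
        values = series.component(name)
        means[name] = float(np.mean(values))
        sds[name] = float(np.std(values, ddof=1)) if series.n_frames >= 2 else None
    return EnergySummary(means=means, sds=sds, n=series.n_frames)


def delta_binding(a: EnergySummary, b: EnergySummary) -> float:
    """mean(TOTAL_a) - mean(TOTAL_b), kcal/mol."""
    return a.means["TOTAL"] - b.means["TOTAL"]


def read_component_table(path: str | Path) -> EnergyComponentSeries:
    """Read a per-frame component TSV; header must name the four components.

    Extra columns (frame index, derived terms, ...) are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COMPONENTS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing component column(s): {', '.join(missing)}")
    return EnergyComponentSeries(
        vdwaals=df["VDWAALS"].to_numpy(float),
        eel=df["EEL"].to_numpy(float),
        epb=df["EPB"].to_numpy(float),
        enpolar=df["ENPOLAR"].to_numpy(float),
    )


def write_component_table(series: EnergyComponentSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(series.n_frames),
        "VDWAALS": series.vdwaals,
        "EEL": series.eel,
        "EPB": series.epb,
        "ENPOLAR": series.enpolar,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
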