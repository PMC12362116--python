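"""The T-shaped microperimetry testing grid.

The test pattern is a "T" centred on the anatomic fovea: one horizontal arm
extending temporally and two vertical arms extending superiorly and
inferiorly, with evenly spaced test loci along each arm plus a single locus
at the fovea itself.  The default geometry (15 deg temporal, 12 deg
superior, 12 deg inferior, 1 deg spacing) yields 40 loci.

Coordinates use a right-eye convention: temporal = +x, superior = +y, in
degrees of visual angle from the fovea.  Left-eye data can be mirrored at
ingest (x -> -x) before analysis; distances are mirror-invariant so the
flag only matters when axes are interpreted anatomically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "GridLocus",
    "GridGeometryError",
    "build_t_grid",
    "grid_to_frame",
    "frame_to_grid",
    "write_grid",
    "read_grid",
]

AXES = ("center", "temporal", "superior", "inferior")

#: Axis orientation used for the nesting structure of the mixed model:
#: the temporal arm (and the foveal locus lying on it) is horizontal,
#: the superior and inferior arms are vertical.
AXIS_ORIENTATION = {
    "center": "horizontal",
    "temporal": "horizontal",
    "superior": "vertical",
    "inferior": "vertical",
}


class GridGeometryError(ValueError):
    """Raised when requested grid geometry is internally inconsistent."""


@dataclass(frozen=True)
class GridLocus:
    """One microperimetry test point.

    Attributes
    ----------
    locus_id
        Deterministic integer label: 0 for the foveal locus, then temporal,
        superior and inferior arms in increasing offset.
    axis
        One of ``center``, ``temporal``, ``superior``, ``inferior``.
    offset_deg
        Distance from the fovea along the locus's own arm (>= 0).
    x_deg, y_deg
        Fovea-centred Cartesian position (temporal = +x, superior = +y).
    """

    locus_id: int
    axis: str
    offset_deg: float
    x_deg: float
    y_deg: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise GridGeometryError(f"unknown axis {self.axis!r}")
        if self.offset_deg < 0:
            raise GridGeometryError("offset_deg must be non-negative")

    @property
    def axis_orientation(self) -> str:
        return AXIS_ORIENTATION[self.axis]

    @property
    def foveal_distance_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)


def _n_steps(arm_deg: float, spacing_deg: float, name: str) -> int:
    n = arm_deg / spacing_deg
    n_round = round(n)
    if abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
        raise GridGeometryError(
            f"{name} arm length {arm_deg} is not a multiple of spacing {spacing_deg}"
        )
    return int(n_round)


def build_t_grid(
    temporal_deg: float = 15.0,
    superior_deg: float = 12.0,
    inferior_deg: float = 12.0,
    spacing_deg: float = 1.0,
) -> list[GridLocus]:
    """Construct the T-shaped grid.

    Returns the foveal locus plus ``arm/spacing`` loci per arm at offsets
    ``spacing, 2*spacing, ...``.  Arm lengths must be non-negative exact
    multiples of the (positive) spacing, otherwise a
    :class:`GridGeometryError` is raised.
    """
    if spacing_deg <= 0:
        raise GridGeometryError("spacing_deg must be positive")
    for arm, name in ((temporal_deg, "temporal"), (superior_deg, "superior"), (inferior_deg, "inferior")):
        if arm < 0:
            raise GridGeometryError(f"{name} arm length must be non-negative")

    counts = {
        "temporal": _n_steps(temporal_deg, spacing_deg, "temporal"),
        "superior": _n_steps(superior_deg, spacing_deg, "superior"),
        "inferior": _n_steps(inferior_deg, spacing_deg, "inferior"),
    }
    directions = {"temporal": (1.0, 0.0), "superior": (0.0, 1.0), "inferior": (0.0, -1.0)}

    loci = [GridLocus(0, "center", 0.0, 0.0, 0.0)]
    next_id = 1
    for axis in ("temporal", "superior", "inferior"):
        dx, dy = directions[axis]
        for i in range(1, counts[axis] + 1):
            off = i * spacing_deg
            loci.append(GridLocus(next_id, axis, off, dx * off, dy * off))
            next_id += 1
    return loci


def grid_to_frame(loci: list[GridLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "axis": [l.axis for l in loci],
            "offset_deg": [l.offset_deg for l in loci],
            "x_deg": [l.x_deg for l in loci],
            "y_deg": [l.y_deg for l in loci],
        }
    )


def frame_to_grid(frame: pd.DataFrame) -> list[GridLocus]:
    required = {"locus_id", "axis", "offset_deg", "x_deg", "y_deg"}
    missing = required - set(frame.columns)
    if missing:
        raise GridGeometryError(f"grid table missing columns: {sorted(missing)}")
    return [
        GridLocus(int(r.locus_id), str(r.axis), float(r.offset_deg), float(r.x_deg), float(r.y_deg))
        for r in frame.itertuples()
    ]


def write_grid(loci: list[GridLocus], path: str | Path) -> None:
    grid_to_frame(loci).to_csv(path, index=False)


def read_grid(path: str | Path) -> list[GridLocus]:
    return frame_to_grid(pd.read_csv(path))
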