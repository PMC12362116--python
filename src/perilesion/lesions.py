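"""Geographic-atrophy lesion masks and locus-to-lesion distances.

A lesion mask is a binary raster in the same fovea-centred frame as the
testing grid: by default a 768x768 image covering a 30 deg field, i.e. the
acquisition format of the fundus autofluorescence images on which GA is
annotated.  Distances are measured from the locus centre to the centre of
the nearest GA pixel (straight-line, Euclidean); with multifocal atrophy
the minimum over all lesions applies, and because lesions grow, distances
are recomputed against each visit's own mask.

Raster convention: pixel (row, col) with row increasing downward (image
convention), fovea at the raster centre by default.  A locus at
(x_deg, y_deg) maps to ``col = fovea_col + x/deg_per_pixel`` and
``row = fovea_row - y/deg_per_pixel`` (superior = up = smaller row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree

from .grid import GridLocus

__all__ = [
    "LesionMask",
    "EmptyMaskError",
    "OutOfFieldError",
    "MissingMaskError",
    "distance_to_ga",
    "distances_to_ga",
    "annotate_dataset",
    "write_mask",
    "read_mask",
    "read_mask_text",
]

DEFAULT_DEG_PER_PIXEL = 30.0 / 768.0


class EmptyMaskError(ValueError):
    """Raised when a distance is requested against a mask with no GA pixels."""


class OutOfFieldError(ValueError):
    """Raised when a locus falls outside the mask raster."""


class MissingMaskError(ValueError):
    """Raised when records reference a (participant, visit) without a mask."""

    def __init__(self, keys: Sequence[tuple]) -> None:
        self.keys = list(keys)
        super().__init__(f"no lesion mask for (participant, visit) keys: {self.keys}")


@dataclass
class LesionMask:
    """Binary GA raster for one eye at one visit.

    ``pixels`` is a 2-D boolean array (True = GA).  ``fovea_px`` is the
    (row, col) position of the fovea, defaulting to the raster's geometric
    centre ``((H-1)/2, (W-1)/2)``.
    """

    pixels: np.ndarray
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL
    fovea_px: tuple[float, float] | None = None
    visit_month: float = 0.0
    participant_id: str = ""
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _ga_px: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")
        h, w = self.pixels.shape
        if self.fovea_px is None:
            self.fovea_px = ((h - 1) / 2.0, (w - 1) / 2.0)
        fr, fc = self.fovea_px
        if not (0 <= fr <= h - 1 and 0 <= fc <= w - 1):
            raise ValueError("fovea_px must lie inside the raster")

    @property
    def n_ga_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_deg2(self) -> float:
        return self.n_ga_pixels * self.deg_per_pixel**2

    def ga_pixel_indices(self) -> np.ndarray:
        if self._ga_px is None:
            self._ga_px = np.argwhere(self.pixels)
        return self._ga_px

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            ga = self.ga_pixel_indices()
            if ga.shape[0] == 0:
                raise EmptyMaskError("mask contains no GA pixels")
            self._tree = cKDTree(ga)
        return self._tree

    def locus_to_pixel(self, x_deg: float, y_deg: float) -> tuple[float, float]:
        fr, fc = self.fovea_px
        return (fr - y_deg / self.deg_per_pixel, fc + x_deg / self.deg_per_pixel)


def distances_to_ga(
    loci: Sequence[GridLocus], mask: LesionMask
) -> tuple[np.ndarray, np.ndarray]:
    """Distances (degrees) from loci to the nearest GA pixel of ``mask``.

    Returns ``(distance_deg, inside_ga)``.  A locus whose containing pixel
    (nearest raster cell) is GA is *inside* the lesion and gets distance 0;
    otherwise the distance is the minimum centre-to-centre Euclidean
    distance over every GA pixel, which with multifocal lesions is
    automatically the minimum across all of them.
    """
    if mask.n_ga_pixels == 0:
        raise EmptyMaskError("mask contains no GA pixels")
    h, w = mask.pixels.shape
    pts = np.array([mask.locus_to_pixel(l.x_deg, l.y_deg) for l in loci], dtype=float)
    if pts.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    bad = (
        (pts[:, 0] < -0.5)
        | (pts[:, 0] > h - 0.5)
        | (pts[:, 1] < -0.5)
        | (pts[:, 1] > w - 0.5)
    )
    if np.any(bad):
        ids = [loci[i].locus_id for i in np.flatnonzero(bad)]
        raise OutOfFieldError(f"loci outside the imaging field: {ids}")
    rc = np.clip(np.rint(pts).astype(int), [0, 0], [h - 1, w - 1])
    inside = mask.pixels[rc[:, 0], rc[:, 1]]
    dist_px, _ = mask._kdtree().query(pts)
    dist = np.where(inside, 0.0, dist_px * mask.deg_per_pixel)
    return dist, inside


def distance_to_ga(locus: GridLocus, mask: LesionMask) -> float:
    """Euclidean distance (degrees) from one locus to the nearest GA pixel."""
    d, _ = distances_to_ga([locus], mask)
    return float(d[0])


def _mask_mapping(masks) -> Mapping[tuple, LesionMask]:
    if isinstance(masks, Mapping):
        return masks
    return {(m.participant_id, m.visit_month): m for m in masks}


def annotate_dataset(
    records: pd.DataFrame,
    masks: Mapping[tuple, LesionMask] | Iterable[LesionMask],
    grid: Sequence[GridLocus],
) -> pd.DataFrame:
    """Join sensitivity records with GA distance and foveal distance.

    ``records`` needs columns ``participant_id``, ``visit_month`` and
    ``locus_id`` (sensitivity columns are carried through untouched).
    Each (participant, visit) present in the records must have exactly one
    mask — distances are computed against that visit's own mask, so lesion
    growth between visits is reflected in the annotations.  All missing
    masks are collected and reported together in a :class:`MissingMaskError`.
    """
    loci_by_id = {l.locus_id: l for l in grid}
    unknown = set(records["locus_id"]) - set(loci_by_id)
    if unknown:
        raise KeyError(f"records reference loci absent from the grid: {sorted(unknown)}")

    masks_by_key = _mask_mapping(masks)
    out = records.copy()
    out["ga_distance_deg"] = np.nan
    out["inside_ga"] = False
    foveal = {l.locus_id: l.foveal_distance_deg for l in grid}
    out["foveal_distance_deg"] = out["locus_id"].map(foveal).astype(float)
    if "axis" not in out.columns:
        out["axis"] = out["locus_id"].map({l.locus_id: l.axis for l in grid})

    missing = []
    for key, idx in out.groupby(["participant_id", "visit_month"], sort=False).groups.items():
        mask = masks_by_key.get(key)
        if mask is None:
            missing.append(key)
            continue
        loci = [loci_by_id[i] for i in out.loc[idx, "locus_id"]]
        dist, inside = distances_to_ga(loci, mask)
        out.loc[idx, "ga_distance_deg"] = dist
        out.loc[idx, "inside_ga"] = inside
    if missing:
        raise MissingMaskError(sorted(missing))
    return out


# ---------------------------------------------------------------------------
# Mask I/O: single-channel PNG (0 background / 255 GA) + JSON sidecar, and a
# plain-text 0/1 matrix form for small fixtures.


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def write_mask(mask: LesionMask, image_path: str | Path) -> None:
    image_path = Path(image_path)
    img = Image.fromarray((mask.pixels.astype(np.uint8)) * 255, mode="L")
    img.save(image_path)
    meta = {
        "deg_per_pixel": mask.deg_per_pixel,
        "fovea_px": list(mask.fovea_px),
        "visit_month": mask.visit_month,
        "participant_id": mask.participant_id,
    }
    _sidecar_path(image_path).write_text(json.dumps(meta, indent=1))


def read_mask(image_path: str | Path) -> LesionMask:
    image_path = Path(image_path)
    pixels = np.asarray(Image.open(image_path).convert("L")) > 127
    meta = json.loads(_sidecar_path(image_path).read_text())
    return LesionMask(
        pixels=pixels,
        deg_per_pixel=float(meta["deg_per_pixel"]),
        fovea_px=tuple(meta["fovea_px"]),
        visit_month=float(meta["visit_month"]),
        participant_id=str(meta["participant_id"]),
    )


def read_mask_text(
    path: str | Path,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    fovea_px: tuple[float, float] | None = None,
    visit_month: float = 0.0,
    participant_id: str = "",
) -> LesionMask:
    """Read a whitespace-delimited 0/1 matrix as a mask (test fixtures)."""
    pixels = np.loadtxt(path, dtype=int).astype(bool)
    return LesionMask(pixels, deg_per_pixel, fovea_px, visit_month, participant_id)
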