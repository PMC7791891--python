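"""Cell morphometry and intercellular distances in physical units.

All features are computed on the rasterized instance (the same pixel set the
matching criterion sees) and converted to micrometres with the frame's pixel
size, so scaling the pixel size by ``s`` scales areas by ``s**2`` and
lengths by ``s`` exactly.

Area is the set-pixel count times the pixel area.  Perimeter is the length
of the sub-pixel iso-contour at level 0.5 of the lightly anti-aliased mask
(3x3 box smoothing before marching squares): boundary-pixel-edge counting
overestimates smooth cell perimeters by up to 4/pi, and marching squares on
the raw binary mask still overestimates a digital disk by ~5%, while the
anti-aliased contour is accurate to well under 1% at cell scales and never
undercuts the isoperimetric bound.  The estimator's values are pinned by
golden tests.  Equivalent diameter is the diameter of the circle with the
cell's area.

The minimum T-cell-to-DC distance is measured centroid-to-centroid by
default (stable for amorphous dendritic cells whose dendrites dominate a
boundary-based measure); boundary mode (minimum distance between outlines,
zero for overlapping cells) is available.  In a two-marker-panel frame the
single stained DC type is the target set; B cells are never distance
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from immunoseg.model import (
    DC_CLASSES,
    T_CELL_CLASSES,
    CellInstance,
    CohortDataset,
    ImageFrame,
    local_mask,
)

__all__ = [
    "area", "perimeter", "equivalent_diameter", "centroid_um",
    "min_distance_to_class", "cohort_features", "ProximityRecord",
    "MORPHOMETRY_COLUMNS", "PROXIMITY_COLUMNS",
]

MORPHOMETRY_COLUMNS = [
    "frame_id", "cell_id", "cell_class", "area_um2", "perimeter_um",
    "equivalent_diameter_um", "centroid_x_um", "centroid_y_um",
    "confidence", "touches_border",
]
PROXIMITY_COLUMNS = [
    "frame_id", "t_cell_id", "t_cell_class", "nearest_dc_id",
    "nearest_dc_class", "distance_um", "mode",
]


@dataclass
class ProximityRecord:
    frame_id: str
    t_cell_id: int
    t_cell_class: str
    nearest_dc_id: int
    nearest_dc_class: str
    distance_um: float
    mode: str


def _pixel_count(instance: CellInstance) -> int:
    lm = local_mask(instance)
    return int(np.count_nonzero(lm.data))


def area(instance: CellInstance, pixel_size_um: float) -> float:
    """Rasterized cell area in um^2 (set-pixel count x pixel area)."""
    n = _pixel_count(instance)
    if n == 0:
        raise ValueError(f"instance {instance.id}: empty raster")
    return n * pixel_size_um**2


def perimeter(instance: CellInstance, pixel_size_um: float) -> float:
    """Sub-pixel perimeter of the rasterized cell in um.

    Marching squares at level 0.5 on the 3x3-box-smoothed, zero-padded mask;
    lengths of all contours (including hole boundaries) are summed.  Falls
    back to the unsmoothed contour for masks too small to survive smoothing.
    """
    lm = local_mask(instance)
    if not lm.data.any():
        raise ValueError(f"instance {instance.id}: empty raster")
    padded = np.pad(lm.data.astype(float), 2)
    smoothed = ndimage.uniform_filter(padded, size=3)
    total = sum(
        float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
        for c in measure.find_contours(smoothed, 0.5)
    )
    if total == 0.0:  # e.g. a single-pixel mask averaged below the level
        total = sum(
            float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
            for c in measure.find_contours(padded, 0.5)
        )
    return total * pixel_size_um


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: sqrt(4 A / pi)."""
    if area_um2 < 0:
        raise ValueError(f"area must be nonnegative, got {area_um2}")
    return math.sqrt(4.0 * area_um2 / math.pi)


def centroid_um(instance: CellInstance, pixel_size_um: float) -> tuple[float, float]:
    """(x, y) centroid of the rasterized cell in um (mean of pixel centers)."""
    lm = local_mask(instance)
    rows, cols = np.nonzero(lm.data)
    if rows.size == 0:
        raise ValueError(f"instance {instance.id}: empty raster")
    x = (cols.mean() + lm.col0 + 0.5) * pixel_size_um
    y = (rows.mean() + lm.row0 + 0.5) * pixel_size_um
    return float(x), float(y)


def min_distance_to_class(
    cell: CellInstance,
    frame: ImageFrame,
    target_classes=None,
    mode: str = "centroid",
) -> ProximityRecord | None:
    """Distance from one cell to the nearest instance of a target class.

    Returns ``None`` when the frame contains no target instance (other than
    the cell itself).  ``mode="centroid"`` measures centroid-to-centroid;
    ``mode="boundary"`` the minimum distance between outlines (0 when they
    overlap).
    """
    if mode not in ("centroid", "boundary"):
        raise ValueError(f"unknown distance mode {mode!r}")
    if target_classes is None:
        target_classes = DC_CLASSES & set(frame.classes)
    targets = [
        s for s in frame.instances
        if s.cell_class in target_classes and s.id != cell.id
    ]
    if not targets:
        return None
    ps = frame.pixel_size_um
    if mode == "centroid":
        cx, cy = centroid_um(cell, ps)
        dists = [
            math.hypot(*(np.array(centroid_um(t, ps)) - (cx, cy))) for t in targets
        ]
    else:
        geom = cell.geometry
        dists = [geom.distance(t.geometry) * ps for t in targets]
    best = int(np.argmin(dists))
    return ProximityRecord(
        frame_id=frame.frame_id,
        t_cell_id=cell.id,
        t_cell_class=cell.cell_class,
        nearest_dc_id=targets[best].id,
        nearest_dc_class=targets[best].cell_class,
        distance_um=float(dists[best]),
        mode=mode,
    )


def cohort_features(
    cohort: CohortDataset, distance_mode: str = "centroid"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Morphometry and T-cell-to-DC proximity tables for a cohort.

    One morphometry row per cell, ordered by (frame, id); one proximity row
    per T cell in frames containing at least one DC (T cells in DC-free
    frames are skipped, not zero-filled).  Cells touching the frame border
    are flagged, not excluded.
    """
    if distance_mode not in ("centroid", "boundary"):
        raise ValueError(f"unknown distance mode {distance_mode!r}")
    morph_rows = []
    prox_rows = []
    for frame in cohort.frames:
        ps = frame.pixel_size_um
        centroids: dict[int, tuple[float, float]] = {}
        for inst in frame.instances:
            a = area(inst, ps)
            xmin, ymin, xmax, ymax = inst.bbox()
            cx, cy = centroid_um(inst, ps)
            centroids[inst.id] = (cx, cy)
            morph_rows.append(
                (
                    frame.frame_id, inst.id, inst.cell_class, a,
                    perimeter(inst, ps), equivalent_diameter(a), cx, cy,
                    inst.confidence,
                    bool(
                        xmin <= 0 or ymin <= 0
                        or xmax >= frame.width_px or ymax >= frame.height_px
                    ),
                )
            )
        dc_targets = DC_CLASSES & set(frame.classes)
        dcs = [s for s in frame.instances if s.cell_class in dc_targets]
        if not dcs:
            continue
        if distance_mode == "centroid":
            dc_xy = np.array([centroids[d.id] for d in dcs])
        for inst in frame.instances:
            if inst.cell_class not in T_CELL_CLASSES:
                continue
            if distance_mode == "centroid":
                d = np.hypot(*(dc_xy - centroids[inst.id]).T)
                best = int(np.argmin(d))
                dist = float(d[best])
            else:
                geom = inst.geometry
                d = [geom.distance(t.geometry) * ps for t in dcs]
                best = int(np.argmin(d))
                dist = float(d[best])
            prox_rows.append(
                (
                    frame.frame_id, inst.id, inst.cell_class,
                    dcs[best].id, dcs[best].cell_class, dist, distance_mode,
                )
            )
    morph = pd.DataFrame(morph_rows, columns=MORPHOMETRY_COLUMNS)
    prox = pd.DataFrame(prox_rows, columns=PROXIMITY_COLUMNS)
    return morph, prox
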