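"""Core data model: cell instances, image frames, cohorts, and the IOU primitive.

Coordinate convention
---------------------
Coordinates are 0-based.  Pixel ``(i, j)`` (row ``i``, column ``j``) occupies
the half-open unit square ``[j, j+1) x [i, i+1)`` in continuous pixel units,
so its center sits at ``(x, y) = (j + 0.5, i + 0.5)``.  Polygon vertices are
``(x, y)`` pairs in continuous pixel units.  A pixel belongs to a rasterized
instance iff its center lies inside the instance polygon (even-odd rule;
centers exactly on the boundary are excluded).

Instances carry either a polygon outline or a raster mask.  Polygons are the
canonical representation — touching cells may overlap, which a label map
cannot encode — and label-map export offers a strict mode (error on overlap)
and a precedence mode (higher confidence wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "PANELS", "T_CELL_CLASSES", "DC_CLASSES", "CELL_CLASSES",
    "InvariantError", "LocalMask", "CellInstance", "ImageFrame",
    "CohortDataset", "rasterize", "local_mask", "iou", "local_iou",
    "to_label_map", "polygonize", "mask_to_polygon",
    "validate_instance", "validate_frame", "validate_cohort",
]

#: The five cell classes: two T-lymphocyte subsets defined by CD3/CD4 surface
#: markers, two dendritic-cell subsets (myeloid and plasmacytoid), and B cells.
CELL_CLASSES = ("CD4T", "CD4negT", "mDC", "pDC", "Bcell")

T_CELL_CLASSES = frozenset({"CD4T", "CD4negT"})
DC_CLASSES = frozenset({"mDC", "pDC"})

#: Staining panels and the cell classes visible in a frame stained with each.
#: Panel 1 uses two markers per antigen-presenting cell, so a frame probes the
#: two T subsets plus a single DC type (3 classes); panel 2 uses one marker
#: per APC and adds B cells (5 classes).
PANELS = {
    "panel1-mDC": ("CD4T", "CD4negT", "mDC"),
    "panel1-pDC": ("CD4T", "CD4negT", "pDC"),
    "panel2": ("CD4T", "CD4negT", "mDC", "pDC", "Bcell"),
}

FIXATIONS = ("fresh_frozen", "FFPE")
SOURCES = ("manual", "predicted")


class InvariantError(ValueError):
    """A data-model invariant was violated; the message names the offender."""


class LocalMask(NamedTuple):
    """Boolean raster restricted to its bounding box within a frame."""

    row0: int
    col0: int
    data: np.ndarray  # 2-D bool


@dataclass
class CellInstance:
    """One segmented cell: class label, outline or mask, confidence, source.

    Parameters
    ----------
    id
        Unique within its frame; positive (label-map export uses it as the
        pixel label).
    cell_class
        One of :data:`CELL_CLASSES`.
    outline
        ``(n, 2)`` array of ``(x, y)`` vertices in continuous pixel units
        forming a simple polygon, or ``None`` for mask-backed instances.
    mask
        :class:`LocalMask` for instances defined directly by a pixel set
        (e.g. read back from a label map), or ``None``.
    confidence
        Network confidence in ``[0, 1]``; manual instances have exactly 1.0.
    source
        ``"manual"`` or ``"predicted"``.
    """

    id: int
    cell_class: str
    outline: np.ndarray | None = None
    mask: LocalMask | None = None
    confidence: float = 1.0
    source: str = "manual"
    _geometry: Polygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.outline is not None:
            self.outline = np.asarray(self.outline, dtype=float)
        if (self.outline is None) == (self.mask is None):
            raise InvariantError(
                f"instance {self.id}: exactly one of outline/mask must be set"
            )

    @property
    def geometry(self) -> Polygon:
        """Shapely polygon of the outline (built lazily; mask-backed
        instances are polygonized from their pixel boxes)."""
        if self._geometry is None:
            if self.outline is not None:
                self._geometry = Polygon(self.outline)
            else:
                self._geometry = _mask_union(self.mask)
        return self._geometry

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in continuous pixel units."""
        if self.outline is not None:
            xs, ys = self.outline[:, 0], self.outline[:, 1]
            return xs.min(), ys.min(), xs.max(), ys.max()
        m = self.mask
        return (m.col0, m.row0, m.col0 + m.data.shape[1], m.row0 + m.data.shape[0])

    def translated(self, dx: float, dy: float) -> "CellInstance":
        """Copy of this instance shifted by (dx, dy) pixels (polygon-backed only)."""
        if self.outline is None:
            raise InvariantError(f"instance {self.id}: cannot translate a mask-backed instance")
        return replace(self, outline=self.outline + np.array([dx, dy]), _geometry=None)


@dataclass
class ImageFrame:
    """One 2-D imaging field and its cell instances.

    ``pixel_size_um`` converts pixel units to micrometres; ``fixation`` and
    ``panel`` tag the tissue preparation and staining panel of the source
    section.
    """

    frame_id: str
    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.1058
    fixation: str = "FFPE"
    panel: str = "panel2"
    instances: list[CellInstance] = field(default_factory=list)

    @property
    def classes(self) -> tuple[str, ...]:
        """Classes visible in this frame's staining panel."""
        return PANELS[self.panel]


@dataclass
class CohortDataset:
    """A named collection of frames sharing fixation and pixel size."""

    name: str
    frames: list[ImageFrame] = field(default_factory=list)
    role: str = "truth"  # "truth" or "predicted"

    def all_instances(self):
        for frame in self.frames:
            for inst in frame.instances:
                yield frame, inst


# ---------------------------------------------------------------------------
# Rasterization and IOU
# ---------------------------------------------------------------------------

def _check_polygon(instance: CellInstance) -> Polygon:
    if instance.outline is not None:
        if len(instance.outline) < 3:
            raise InvariantError(
                f"instance {instance.id}: degenerate polygon with "
                f"{len(instance.outline)} vertices (need >= 3)"
            )
    geom = instance.geometry
    if geom.is_empty or geom.area <= 0:
        raise InvariantError(f"instance {instance.id}: polygon has zero area")
    if not geom.is_valid:
        raise InvariantError(f"instance {instance.id}: polygon is not simple/valid")
    return geom


def local_mask(instance: CellInstance, frame: ImageFrame | None = None) -> LocalMask:
    """Rasterize an instance onto its bounding box.

    A pixel is set iff its center ``(j + 0.5, i + 0.5)`` lies strictly inside
    the instance polygon.  Mask-backed instances return their stored pixels.
    When ``frame`` is given, the raster is clipped to the frame bounds.
    """
    if instance.mask is not None:
        return instance.mask
    geom = _check_polygon(instance)
    xmin, ymin, xmax, ymax = geom.bounds
    col0 = int(np.floor(xmin))
    row0 = int(np.floor(ymin))
    col1 = int(np.ceil(xmax))
    row1 = int(np.ceil(ymax))
    if frame is not None:
        col0, row0 = max(col0, 0), max(row0, 0)
        col1, row1 = min(col1, frame.width_px), min(row1, frame.height_px)
    if col1 <= col0 or row1 <= row0:
        raise InvariantError(f"instance {instance.id}: polygon outside frame bounds")
    cols = np.arange(col0, col1) + 0.5
    rows = np.arange(row0, row1) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not inside.any():
        raise InvariantError(
            f"instance {instance.id}: rasterizes to an empty pixel set"
        )
    return LocalMask(row0, col0, inside)


def rasterize(instance: CellInstance, frame: ImageFrame) -> np.ndarray:
    """Full-frame boolean mask of an instance (see :func:`local_mask`)."""
    lm = local_mask(instance, frame)
    out = np.zeros((frame.height_px, frame.width_px), dtype=bool)
    h, w = lm.data.shape
    out[lm.row0:lm.row0 + h, lm.col0:lm.col0 + w] = lm.data
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union (Jaccard index) of two boolean rasters.

    Returns 0.0 (with a warning) when the union is empty.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    inter = np.count_nonzero(mask_a & mask_b)
    union = np.count_nonzero(mask_a | mask_b)
    if union == 0:
        warnings.warn("IOU of two empty masks; returning 0.0 by convention")
        return 0.0
    return inter / union


def local_iou(a: LocalMask, b: LocalMask) -> float:
    """IOU of two bounding-box-local masks from the same frame.

    Equivalent to :func:`iou` on the full-frame rasters but touches only the
    overlapping window, which keeps per-frame matching cheap.
    """
    na = int(np.count_nonzero(a.data))
    nb = int(np.count_nonzero(b.data))
    r0 = max(a.row0, b.row0)
    c0 = max(a.col0, b.col0)
    r1 = min(a.row0 + a.data.shape[0], b.row0 + b.data.shape[0])
    c1 = min(a.col0 + a.data.shape[1], b.col0 + b.data.shape[1])
    if r1 <= r0 or c1 <= c0:
        inter = 0
    else:
        wa = a.data[r0 - a.row0:r1 - a.row0, c0 - a.col0:c1 - a.col0]
        wb = b.data[r0 - b.row0:r1 - b.row0, c0 - b.col0:c1 - b.col0]
        inter = int(np.count_nonzero(wa & wb))
    union = na + nb - inter
    if union == 0:
        warnings.warn("IOU of two empty masks; returning 0.0 by convention")
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Label-map conversion
# ---------------------------------------------------------------------------

def to_label_map(frame: ImageFrame, mode: str = "strict") -> tuple[np.ndarray, pd.DataFrame]:
    """Export a frame as an integer label image plus a class/confidence table.

    Background is 0 and instance ``k``'s pixels carry label ``k`` (the
    instance id).  ``mode="strict"`` raises on overlapping instances;
    ``mode="precedence"`` assigns contested pixels to the higher-confidence
    instance (ties broken by lower id).
    """
    if mode not in ("strict", "precedence"):
        raise ValueError(f"unknown label-map mode {mode!r}")
    labels = np.zeros((frame.height_px, frame.width_px), dtype=np.uint16)
    ids = [inst.id for inst in frame.instances]
    if len(set(ids)) != len(ids):
        raise InvariantError(f"frame {frame.frame_id}: duplicate instance ids")
    for inst in frame.instances:
        if not (0 < inst.id < 2**16):
            raise InvariantError(
                f"frame {frame.frame_id}: instance id {inst.id} out of uint16 label range"
            )
    # precedence: paint in increasing confidence so the strongest wins;
    # equal confidences painted in decreasing id so the lower id wins.
    order = sorted(
        frame.instances,
        key=(lambda s: (s.confidence, -s.id)) if mode == "precedence" else (lambda s: s.id),
    )
    collisions: set[tuple[int, int]] = set()
    for inst in order:
        lm = local_mask(inst, frame)
        h, w = lm.data.shape
        window = labels[lm.row0:lm.row0 + h, lm.col0:lm.col0 + w]
        if mode == "strict":
            hit = window[lm.data]
            for other in np.unique(hit[hit > 0]):
                collisions.add(tuple(sorted((int(other), inst.id))))
        window[lm.data] = inst.id
    if collisions:
        pairs = ", ".join(f"{a}&{b}" for a, b in sorted(collisions))
        raise InvariantError(
            f"frame {frame.frame_id}: overlapping instances in strict mode: {pairs}"
        )
    table = pd.DataFrame(
        {
            "label": [inst.id for inst in frame.instances],
            "class": [inst.cell_class for inst in frame.instances],
            "confidence": [inst.confidence for inst in frame.instances],
        }
    )
    return labels, table


def _mask_union(lm: LocalMask) -> Polygon:
    """Union of the unit pixel squares of a local mask (may carry holes)."""
    rows, cols = np.nonzero(lm.data)
    boxes = [
        shapely.box(c + lm.col0, r + lm.row0, c + lm.col0 + 1, r + lm.row0 + 1)
        for r, c in zip(rows, cols)
    ]
    return shapely.unary_union(boxes)


def mask_to_polygon(lm: LocalMask) -> np.ndarray | None:
    """Exterior vertex ring of a local mask, or None if the pixel set is not
    simply connected (multiple components or interior holes).

    The returned ring has vertices on the integer grid, so re-rasterizing it
    reproduces the pixel set exactly: pixel centers sit at half-integers and
    can never fall on the ring.
    """
    geom = _mask_union(lm)
    if geom.geom_type != "Polygon" or len(geom.interiors) > 0:
        return None
    return np.asarray(geom.exterior.coords[:-1], dtype=float)


def polygonize(
    label_image: np.ndarray,
    sidecar: pd.DataFrame,
    *,
    frame_id: str = "frame",
    pixel_size_um: float = 0.1058,
    fixation: str = "FFPE",
    panel: str = "panel2",
    source: str | None = None,
) -> ImageFrame:
    """Rebuild an :class:`ImageFrame` from a label image and sidecar table.

    Each nonzero label becomes one instance whose raster equals that label's
    pixel set exactly; simply connected pixel sets are stored as polygon
    outlines, others as raster masks.
    """
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer) or label_image.min() < 0:
        raise ValueError("label image must be a nonnegative integer array")
    by_label = sidecar.set_index("label")
    instances = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        if int(lab) not in by_label.index:
            raise InvariantError(f"label {int(lab)} missing from sidecar table")
        row = by_label.loc[int(lab)]
        rows, cols = np.nonzero(label_image == lab)
        r0, c0 = int(rows.min()), int(cols.min())
        data = np.zeros((int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1), dtype=bool)
        data[rows - r0, cols - c0] = True
        lm = LocalMask(r0, c0, data)
        ring = mask_to_polygon(lm)
        conf = float(row["confidence"])
        src = source if source is not None else ("manual" if conf == 1.0 else "predicted")
        instances.append(
            CellInstance(
                id=int(lab),
                cell_class=str(row["class"]),
                outline=ring,
                mask=lm if ring is None else None,
                confidence=conf,
                source=src,
            )
        )
    return ImageFrame(
        frame_id=frame_id,
        width_px=label_image.shape[1],
        height_px=label_image.shape[0],
        pixel_size_um=pixel_size_um,
        fixation=fixation,
        panel=panel,
        instances=instances,
    )


# ---------------------------------------------------------------------------
# Invariant validation
# ---------------------------------------------------------------------------

def validate_instance(instance: CellInstance, frame: ImageFrame) -> None:
    """Check all instance-level invariants; raise InvariantError naming the rule."""
    where = f"frame {frame.frame_id}, instance {instance.id}"
    if instance.cell_class not in CELL_CLASSES:
        raise InvariantError(f"{where}: unknown cell class {instance.cell_class!r}")
    if instance.cell_class not in PANELS[frame.panel]:
        raise InvariantError(
            f"{where}: class {instance.cell_class} not in panel {frame.panel}"
        )
    if not (0.0 <= instance.confidence <= 1.0):
        raise InvariantError(f"{where}: confidence {instance.confidence} outside [0, 1]")
    if instance.source not in SOURCES:
        raise InvariantError(f"{where}: unknown source {instance.source!r}")
    if instance.source == "manual" and instance.confidence != 1.0:
        raise InvariantError(
            f"{where}: manual instance must have confidence 1.0, "
            f"got {instance.confidence}"
        )
    if instance.outline is not None:
        _check_polygon(instance)
        xs, ys = instance.outline[:, 0], instance.outline[:, 1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > frame.width_px or ys.max() > frame.height_px:
            raise InvariantError(f"{where}: polygon vertices outside frame bounds")


def validate_frame(frame: ImageFrame) -> None:
    if frame.pixel_size_um <= 0:
        raise InvariantError(f"frame {frame.frame_id}: pixel_size_um must be positive")
    if frame.panel not in PANELS:
        raise InvariantError(f"frame {frame.frame_id}: unknown panel {frame.panel!r}")
    if frame.fixation not in FIXATIONS:
        raise InvariantError(f"frame {frame.frame_id}: unknown fixation {frame.fixation!r}")
    ids = [inst.id for inst in frame.instances]
    if len(set(ids)) != len(ids):
        raise InvariantError(f"frame {frame.frame_id}: duplicate instance ids")
    for inst in frame.instances:
        validate_instance(inst, frame)


def validate_cohort(cohort: CohortDataset) -> None:
    """Frames of a cohort must share fixation and pixel size."""
    if cohort.role not in ("truth", "predicted"):
        raise InvariantError(f"cohort {cohort.name}: unknown role {cohort.role!r}")
    if not cohort.frames:
        return
    fix = {f.fixation for f in cohort.frames}
    px = {f.pixel_size_um for f in cohort.frames}
    if len(fix) > 1:
        raise InvariantError(f"cohort {cohort.name}: mixed fixations {sorted(fix)}")
    if len(px) > 1:
        raise InvariantError(f"cohort {cohort.name}: mixed pixel sizes {sorted(px)}")
    for frame in cohort.frames:
        validate_frame(frame)
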