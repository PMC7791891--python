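"""Synthetic tissue cohorts and a detection-degradation model.

Ground-truth frames are generated by a cluster-then-scatter point process:
cluster centers are placed uniformly in the frame, each cell is assigned to a
random cluster and displaced from it by an isotropic Gaussian.  Each cell is
a shape-perturbed ellipse whose area is drawn from a per-class log-normal
distribution.  Formalin fixation (FFPE) contracts tissue; the simulator
models this as a single linear scale factor ``shrinkage_s`` applied to cell
linear size and to all positions about the frame center, so mean cell area
scales by ``s**2`` and every intercellular distance scales by ``s``.

The degradation model turns a truth cohort into a "predicted" cohort with
the error structure of a trained detector: per-class missed detections,
per-class false positives, class confusion, boundary jitter, and confidence
scores drawn from separate Beta distributions for correct and erroneous
cells.

Random streams are split per frame from the master seed, so changing the
frame count never reshuffles earlier frames, and ``shrinkage_s=1``
reproduces the unshrunk cohort exactly under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from immunoseg.model import (
    PANELS,
    CellInstance,
    CohortDataset,
    ImageFrame,
    validate_cohort,
)

__all__ = [
    "TissueConfig", "DegradationConfig", "generate_truth", "degrade",
    "apply_fixation_shrinkage", "dataset_config", "lognormal_mean_area",
]

N_VERTICES = 48  # boundary resolution of generated cell polygons


@dataclass(frozen=True)
class TissueConfig:
    """Parameters of one synthetic ground-truth cohort.

    ``cells_per_frame`` is a Poisson mean; ``class_mixture`` is a probability
    vector over the classes of ``panel`` (in :data:`~immunoseg.model.PANELS`
    order); ``area_um2`` maps each class to ``(median, geometric SD)`` of a
    log-normal cell-area distribution in square micrometres;
    ``shape_irregularity`` is the amplitude of a low-order random harmonic
    perturbing the cell boundary (scalar, or per-class mapping — dendritic
    cells are more amorphous than lymphocytes); ``aggregation`` is
    ``(clusters per frame, within-cluster SD in um)``; ``shrinkage_s`` in
    ``(0, 1]`` is the linear fixation-shrinkage factor.
    """

    name: str = "synthetic"
    frame_size_px: int = 1024
    pixel_size_um: float = 0.1058
    fixation: str = "FFPE"
    panel: str = "panel2"
    n_frames: int = 10
    cells_per_frame: float = 31.0
    class_mixture: tuple[float, ...] = (0.35, 0.27, 0.07, 0.08, 0.23)
    area_um2: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD4T": (80.0, 1.4),
            "CD4negT": (80.0, 1.4),
            "mDC": (110.0, 1.5),
            "pDC": (95.0, 1.5),
            "Bcell": (70.0, 1.4),
        }
    )
    shape_irregularity: float | Mapping[str, float] = field(
        default_factory=lambda: {
            "CD4T": 0.08, "CD4negT": 0.08, "mDC": 0.30, "pDC": 0.25, "Bcell": 0.08,
        }
    )
    aggregation: tuple[int, float] = (4, 12.0)
    shrinkage_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        classes = PANELS[self.panel]
        if len(self.class_mixture) != len(classes):
            raise ValueError(
                f"class_mixture has {len(self.class_mixture)} entries for panel "
                f"{self.panel} with {len(classes)} classes"
            )
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1 within 1e-9")
        if self.pixel_size_um <= 0 or self.cells_per_frame <= 0:
            raise ValueError("scale parameters must be positive")
        if not (0.0 < self.shrinkage_s <= 1.0):
            raise ValueError(f"shrinkage_s must be in (0, 1], got {self.shrinkage_s}")
        for cls in classes:
            med, gsd = self.area_um2[cls]
            if med <= 0 or gsd <= 1.0:
                raise ValueError(f"area_um2[{cls}]: median > 0 and geometric SD > 1 required")
        n_clusters, spread = self.aggregation
        if n_clusters < 1 or spread <= 0:
            raise ValueError("aggregation needs >= 1 cluster and positive spread")

    def irregularity_of(self, cell_class: str) -> float:
        if isinstance(self.shape_irregularity, Mapping):
            return float(self.shape_irregularity[cell_class])
        return float(self.shape_irregularity)


@dataclass(frozen=True)
class DegradationConfig:
    """Error structure applied to a truth cohort to emulate a detector.

    ``detect_prob`` maps class to the probability a truth cell is detected at
    all; ``fp_rate`` maps class to the expected number of spurious cells per
    frame; ``confusion`` is a row-stochastic matrix (class -> class -> prob)
    applied to detected cells, ``None`` meaning identity (no
    misclassification); ``jitter`` displaces and rescales detected outlines
    by Gaussian amounts proportional to ``jitter`` times the cell's
    equivalent radius, which controls the achieved IOU; confidence scores
    are drawn from ``Beta(*confidence_correct)`` for correctly classified
    detections and ``Beta(*confidence_error)`` for misclassified detections
    and false positives.
    """

    detect_prob: Mapping[str, float]
    fp_rate: Mapping[str, float] = field(default_factory=dict)
    confusion: Mapping[str, Mapping[str, float]] | None = None
    jitter: float = 0.0
    confidence_correct: tuple[float, float] = (8.0, 2.0)
    confidence_error: tuple[float, float] = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, p in self.detect_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"detect_prob[{cls}] = {p} outside [0, 1]")
        for cls, r in self.fp_rate.items():
            if r < 0:
                raise ValueError(f"fp_rate[{cls}] must be nonnegative")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        if self.confusion is not None:
            for cls, row in self.confusion.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"confusion row for {cls} sums to {total}, not 1 (within 1e-9)"
                    )
                if any(p < 0 for p in row.values()):
                    raise ValueError(f"confusion row for {cls} has negative entries")


def lognormal_mean_area(config: TissueConfig, cell_class: str) -> float:
    """Expected cell area in um^2 for a class, including shrinkage.

    For a log-normal with median ``m`` and geometric SD ``g`` the mean is
    ``m * exp(log(g)**2 / 2)``; shrinkage scales areas by ``s**2``.
    """
    med, gsd = config.area_um2[cell_class]
    return med * np.exp(np.log(gsd) ** 2 / 2.0) * config.shrinkage_s**2


# ---------------------------------------------------------------------------
# Shape model
# ---------------------------------------------------------------------------

def _cell_polygon(rng: np.random.Generator, area_px2: float, irregularity: float) -> np.ndarray:
    """Random star-shaped cell outline with the given continuous area (px^2).

    An ellipse with axis ratio U[0.6, 1] and uniform orientation, whose
    radius is modulated by a random harmonic of orders 2-4 normalised to
    amplitude ``irregularity`` < 1 (keeping the polygon star-shaped, hence
    simple), then rescaled to the target area.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, N_VERTICES, endpoint=False)
    axis_ratio = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    amps = rng.normal(size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    raw = sum(a * np.cos(k * phi + p) for a, k, p in zip(amps, (2, 3, 4), phases))
    denom = np.sum(np.abs(amps))
    if denom > 0:
        raw = raw / denom  # |raw| <= 1 so the radius stays positive
    r = 1.0 + min(irregularity, 0.95) * raw
    x = r * np.cos(phi)
    y = r * axis_ratio * np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    pts = np.column_stack([ct * x - st * y, st * x + ct * y])
    # shoelace area of the unit-scale outline, then rescale to target
    shoelace = 0.5 * np.abs(
        np.dot(pts[:, 0], np.roll(pts[:, 1], -1)) - np.dot(pts[:, 1], np.roll(pts[:, 0], -1))
    )
    return pts * np.sqrt(area_px2 / shoelace)


def _placement_margin_px(config: TissueConfig) -> float:
    """Conservative cell radius bound (px) used to keep placements in-frame.

    Covers areas up to three geometric SDs above the class median, the
    minimum axis ratio, and the irregularity amplitude; capped at a quarter
    of the frame so small test frames stay usable (the raster clamp catches
    the residual tail).
    """
    worst = 0.0
    for cls in PANELS[config.panel]:
        med, gsd = config.area_um2[cls]
        hi_area = med * gsd**3
        r_um = np.sqrt(hi_area / (0.6 * np.pi)) * (1.0 + config.irregularity_of(cls))
        worst = max(worst, r_um / config.pixel_size_um)
    return min(worst + 2.0, config.frame_size_px / 4.0)


def _clamp_center(cx: float, cy: float, pts: np.ndarray, size: int) -> tuple[float, float]:
    rmax_x = np.abs(pts[:, 0]).max()
    rmax_y = np.abs(pts[:, 1]).max()
    eps = 1e-6
    cx = min(max(cx, rmax_x + eps), size - rmax_x - eps)
    cy = min(max(cy, rmax_y + eps), size - rmax_y - eps)
    return cx, cy


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def generate_truth(config: TissueConfig) -> CohortDataset:
    """Generate a ground-truth cohort; deterministic given ``config.seed``."""
    classes = PANELS[config.panel]
    mixture = np.asarray(config.class_mixture, dtype=float)
    n_clusters, spread_um = config.aggregation
    spread_px = spread_um / config.pixel_size_um
    size = config.frame_size_px
    center = size / 2.0
    s = config.shrinkage_s

    margin = _placement_margin_px(config)
    frames = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_frames)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_cells = rng.poisson(config.cells_per_frame)
        cluster_xy = rng.uniform(margin, size - margin, size=(n_clusters, 2))
        instances = []
        for cid in range(1, n_cells + 1):
            # rejection-sample the unshrunk position into the margin box;
            # acceptance depends only on unshrunk draws, so the same seed
            # consumes the same stream at every shrinkage factor
            for _ in range(200):
                cl = rng.integers(n_clusters)
                offset = rng.normal(0.0, spread_px, size=2)
                pos = cluster_xy[cl] + offset
                if margin <= pos[0] <= size - margin and margin <= pos[1] <= size - margin:
                    break
            # tissue contraction: every position shrinks toward the frame
            # center by s, so intercellular distances scale exactly by s
            cx = center + s * (pos[0] - center)
            cy = center + s * (pos[1] - center)
            cls = classes[rng.choice(len(classes), p=mixture)]
            med, gsd = config.area_um2[cls]
            area = np.exp(rng.normal(np.log(med), np.log(gsd))) * s * s
            area_px2 = area / config.pixel_size_um**2
            pts = _cell_polygon(rng, area_px2, config.irregularity_of(cls))
            cx, cy = _clamp_center(cx, cy, pts, size)
            instances.append(
                CellInstance(
                    id=cid,
                    cell_class=cls,
                    outline=pts + np.array([cx, cy]),
                    confidence=1.0,
                    source="manual",
                )
            )
        frames.append(
            ImageFrame(
                frame_id=f"{config.name}-{k:04d}",
                width_px=size,
                height_px=size,
                pixel_size_um=config.pixel_size_um,
                fixation=config.fixation,
                panel=config.panel,
                instances=instances,
            )
        )
    cohort = CohortDataset(name=config.name, frames=frames, role="truth")
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def _equivalent_radius_px(outline: np.ndarray) -> float:
    x, y = outline[:, 0], outline[:, 1]
    a = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(np.sqrt(a / np.pi))


def degrade(truth: CohortDataset, config: DegradationConfig) -> CohortDataset:
    """Degrade a truth cohort into a predicted cohort.

    Each truth cell is detected independently with its class's
    ``detect_prob``; detected cells get a confusion-sampled class, a jittered
    outline, and a sampled confidence.  ``Poisson(fp_rate)`` spurious cells
    per frame and class are placed uniformly at random, borrowing the outline
    of a random truth cell of that class so false positives follow the
    class's size distribution.  Deterministic given ``config.seed``.
    """
    if truth.role != "truth":
        raise ValueError(f"expected a truth cohort, got role {truth.role!r}")
    a_ok, b_ok = config.confidence_correct
    a_err, b_err = config.confidence_error

    # shape templates for false positives, per class
    templates: dict[str, list[np.ndarray]] = {}
    for frame in truth.frames:
        for inst in frame.instances:
            if inst.outline is not None:
                templates.setdefault(inst.cell_class, []).append(inst.outline)

    frames = []
    children = np.random.SeedSequence(config.seed).spawn(len(truth.frames))
    for frame, child in zip(truth.frames, children):
        rng = np.random.default_rng(child)
        classes = PANELS[frame.panel]
        size = frame.width_px
        out = []
        next_id = 1
        for inst in frame.instances:
            if rng.random() >= config.detect_prob.get(inst.cell_class, 1.0):
                continue
            if config.confusion is None:
                new_class = inst.cell_class
            else:
                row = config.confusion[inst.cell_class]
                probs = np.array([row.get(c, 0.0) for c in classes])
                new_class = classes[rng.choice(len(classes), p=probs)]
            outline = inst.outline
            if config.jitter > 0 and outline is not None:
                r_eq = _equivalent_radius_px(outline)
                shift = rng.normal(0.0, config.jitter * r_eq, size=2)
                scale = float(np.clip(1.0 + 0.5 * config.jitter * rng.normal(), 0.5, 1.5))
                centroid = outline.mean(axis=0)
                outline = centroid + scale * (outline - centroid) + shift
                outline = _shift_into_bounds(outline, size)
            correct = new_class == inst.cell_class
            conf = rng.beta(a_ok, b_ok) if correct else rng.beta(a_err, b_err)
            out.append(
                CellInstance(
                    id=next_id,
                    cell_class=new_class,
                    outline=outline,
                    mask=inst.mask if outline is None else None,
                    confidence=float(conf),
                    source="predicted",
                )
            )
            next_id += 1
        for cls in classes:
            lam = config.fp_rate.get(cls, 0.0)
            if lam <= 0:
                continue
            for _ in range(rng.poisson(lam)):
                pool = templates.get(cls)
                if pool:
                    tmpl = pool[rng.integers(len(pool))]
                    pts = tmpl - tmpl.mean(axis=0)
                else:  # no truth cell of this class anywhere: generic round cell
                    phi = np.linspace(0, 2 * np.pi, N_VERTICES, endpoint=False)
                    r = 3.0 / frame.pixel_size_um
                    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
                cx, cy = rng.uniform(0.0, size, size=2)
                cx, cy = _clamp_center(cx, cy, pts, size)
                out.append(
                    CellInstance(
                        id=next_id,
                        cell_class=cls,
                        outline=pts + np.array([cx, cy]),
                        confidence=float(rng.beta(a_err, b_err)),
                        source="predicted",
                    )
                )
                next_id += 1
        frames.append(replace(frame, instances=out))
    cohort = CohortDataset(name=f"{truth.name}-pred", frames=frames, role="predicted")
    validate_cohort(cohort)
    return cohort


def _shift_into_bounds(outline: np.ndarray, size: int) -> np.ndarray:
    """Translate an outline the minimal amount needed to fit in the frame."""
    dx = max(0.0, -outline[:, 0].min()) - max(0.0, outline[:, 0].max() - size)
    dy = max(0.0, -outline[:, 1].min()) - max(0.0, outline[:, 1].max() - size)
    if dx or dy:
        outline = outline + np.array([dx, dy])
    return outline


def apply_fixation_shrinkage(config: TissueConfig, s: float) -> TissueConfig:
    """Return a config with fixation shrinkage ``s`` folded in.

    A linear factor ``s`` in ``(0, 1]`` multiplies ``shrinkage_s``; expected
    mean cell area then scales by ``s**2`` and expected perimeter and
    intercellular distances scale by ``s``.
    """
    if not (0.0 < s <= 1.0):
        raise ValueError(f"shrinkage factor must be in (0, 1], got {s}")
    return replace(config, shrinkage_s=config.shrinkage_s * s)


# ---------------------------------------------------------------------------
# Presets emulating the three study datasets
# ---------------------------------------------------------------------------

# Class mixtures renormalised from the manual-segmentation population tables
# of the three cohorts (a panel-1 cohort holds two T subsets plus one DC
# type; the panel-2 cohort holds all five classes).
_PRESETS = {
    # fresh-frozen, double-stain panel, ~21.5 cells/frame, 0.1413 um pixels
    "fresh_frozen_DS": dict(
        pixel_size_um=0.1413,
        fixation="fresh_frozen",
        panel="panel1-pDC",
        cells_per_frame=21.5,
        class_mixture=(0.5514, 0.2383, 0.2103),
        shrinkage_s=1.0,
    ),
    # FFPE, double-stain panel, densest cohort (~44.7 cells/frame)
    "FFPE_DS": dict(
        pixel_size_um=0.1058,
        fixation="FFPE",
        panel="panel1-pDC",
        cells_per_frame=44.7,
        class_mixture=(0.6161, 0.3064, 0.0775),
        shrinkage_s=0.667,
    ),
    # FFPE, single-stain five-class panel, ~31.0 cells/frame
    "FFPE_SS": dict(
        pixel_size_um=0.1058,
        fixation="FFPE",
        panel="panel2",
        cells_per_frame=31.0,
        class_mixture=(0.35, 0.2682, 0.0724, 0.0798, 0.2296),
        shrinkage_s=0.667,
    ),
}


def dataset_config(name: str, n_frames: int = 10, seed: int = 0, **overrides) -> TissueConfig:
    """Preset :class:`TissueConfig` emulating one of the three study cohorts.

    ``name`` is one of ``fresh_frozen_DS``, ``FFPE_DS``, ``FFPE_SS``.  Pixel
    size, fixation, panel, cell density, and class mixture follow the
    cohort's descriptors; unshrunk cell-size distributions are shared across
    presets so the FFPE presets differ from fresh-frozen by the shrinkage
    factor alone.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown dataset preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return TissueConfig(name=name, n_frames=n_frames, seed=seed, **kw)
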