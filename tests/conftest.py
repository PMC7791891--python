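"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from immunoseg.model import CellInstance, ImageFrame, local_iou, local_mask


def square_instance(
    inst_id: int,
    cell_class: str = "CD4T",
    x0: float = 0.0,
    y0: float = 0.0,
    side: float = 10.0,
    confidence: float = 1.0,
    source: str = "manual",
) -> CellInstance:
    """Axis-aligned square cell, handy for exact pixel arithmetic."""
    return CellInstance(
        id=inst_id,
        cell_class=cell_class,
        outline=[(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
        confidence=confidence,
        source=source,
    )


def disk_instance(inst_id, cell_class="CD4T", cx=60.0, cy=60.0, r=50.0, n=720, **kw):
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return CellInstance(
        id=inst_id,
        cell_class=cell_class,
        outline=np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)]),
        **kw,
    )


@pytest.fixture
def frame1024() -> ImageFrame:
    return ImageFrame(frame_id="f0", width_px=1024, height_px=1024,
                      pixel_size_um=1.0, fixation="FFPE", panel="panel2")


def brute_force_best_matching(truth: ImageFrame, pred: ImageFrame, theta: float):
    """Exhaustive search over all one-to-one same-class assignments.

    Returns (max pair count, max total IOU among maximum-cardinality
    matchings) — the independent oracle for the assignment solver.
    """
    t_masks = [local_mask(s, truth) for s in truth.instances]
    p_masks = [local_mask(s, pred) for s in pred.instances]
    admissible = []
    for i, ti in enumerate(truth.instances):
        for j, pj in enumerate(pred.instances):
            if ti.cell_class != pj.cell_class:
                continue
            v = local_iou(t_masks[i], p_masks[j])
            if v >= theta:
                admissible.append((i, j, v))
    best = (0, 0.0)

    def recurse(k, used_t, used_p, count, total):
        nonlocal best
        if (count, total) > best:
            best = (count, total)
        for idx in range(k, len(admissible)):
            i, j, v = admissible[idx]
            if i not in used_t and j not in used_p:
                recurse(idx + 1, used_t | {i}, used_p | {j}, count + 1, total + v)

    recurse(0, frozenset(), frozenset(), 0, 0.0)
    return best


def random_matching_scenario(rng: np.random.Generator, max_cells: int = 6):
    """A small truth/prediction frame pair with heavy overlaps for oracle tests."""
    size = 64
    classes = ("CD4T", "pDC")

    def random_frame(fid, n, source):
        instances = []
        for k in range(n):
            side = rng.uniform(6.0, 14.0)
            x0 = rng.uniform(0.0, size - side)
            y0 = rng.uniform(0.0, size - side)
            instances.append(
                square_instance(
                    k + 1,
                    cell_class=classes[rng.integers(2)],
                    x0=x0, y0=y0, side=side,
                    confidence=1.0 if source == "manual" else 0.9,
                    source=source,
                )
            )
        return ImageFrame(frame_id=fid, width_px=size, height_px=size,
                          pixel_size_um=1.0, fixation="FFPE", panel="panel2",
                          instances=instances)

    truth = random_frame("t", rng.integers(0, max_cells + 1), "manual")
    pred = random_frame("t", rng.integers(0, max_cells + 1), "predicted")
    return truth, pred


def brute_force_ks_d(x, y) -> float:
    """Supremum ECDF difference evaluated at every observation."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pts = np.concatenate([x, y])
    fx = np.searchsorted(x, pts, side="right") / x.size
    fy = np.searchsorted(y, pts, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def percent_change_se(a, b) -> float:
    """Delta-method SE of 100*(1 - mean(b)/mean(a))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ma, mb = a.mean(), b.mean()
    var_ratio = (mb / ma) ** 2 * (
        a.var(ddof=1) / (ma**2 * a.size) + b.var(ddof=1) / (mb**2 * b.size)
    )
    return 100.0 * float(np.sqrt(var_ratio))
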