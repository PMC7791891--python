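"""Comparative statistics: KS tests, percent change, population tables, splits.

Every fixation/panel contrast in the pipeline is a two-sample
Kolmogorov-Smirnov test on a per-cell feature (area, perimeter, equivalent
diameter, nearest-DC distance, confidence) together with the percent change
of means.  Asymptotic p-values are the default, appropriate at the sample
sizes the pipeline produces; an exact option exists for small samples.  No
multiple-testing correction is applied; reports carry the number of tests.

Population tables print total cells, images, average cells per image (1
decimal place) and per-class counts with percentage of total (2 decimal
places), rounded half-up at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from immunoseg.model import CohortDataset, T_CELL_CLASSES

__all__ = [
    "ComparisonResult", "PopulationTable", "SplitAssignment",
    "ks_two_sample", "percent_change_of_means", "population_table",
    "split_dataset", "compare_fixations", "comparison_table",
    "round_half_up",
]


@dataclass
class ComparisonResult:
    """Two-sample comparison of one feature between two groups."""

    feature: str
    cell_class: str          # a class label, "T", or "all"
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    percent_change: float    # 100 (mean_a - mean_b) / mean_a; positive = reduction
    ks_D: float
    p_value: float
    small_sample: bool       # fewer than 5 observations on either side


@dataclass
class PopulationTable:
    """Cell counts and class mixture of one cohort, at printed precision."""

    name: str
    total_cells: int
    total_images: int
    avg_cells_per_image: float           # rounded half-up, 1 dp
    class_counts: dict[str, int]
    class_percentages: dict[str, float]  # rounded half-up, 2 dp


@dataclass
class SplitAssignment:
    """Frame-level train/validation/test partition."""

    assignment: dict[str, str]
    ratios: tuple[float, ...]
    labels: tuple[str, ...]
    seed: int
    sizes: dict[str, int] = field(default_factory=dict)


def round_half_up(numerator, denominator=1, ndigits: int = 2) -> float:
    """Decimal round-half-up of numerator/denominator at ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    val = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def ks_two_sample(x, y, method: str = "asymp") -> tuple[float, float]:
    """Two-sample KS statistic D and p-value.

    D is the supremum ECDF difference; the p-value comes from the asymptotic
    two-sample Kolmogorov distribution (``method="exact"`` for small-sample
    exact p-values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires at least one observation per sample")
    res = sps.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def percent_change_of_means(reference, comparison) -> float:
    """100 x (mean(reference) - mean(comparison)) / mean(reference).

    Positive values are reductions relative to the reference group.
    """
    mr = float(np.mean(np.asarray(reference, dtype=float)))
    mc = float(np.mean(np.asarray(comparison, dtype=float)))
    if mr == 0:
        raise ValueError("reference sample has zero mean; percent change undefined")
    return 100.0 * (mr - mc) / mr


def population_table(
    source: CohortDataset | Mapping[str, int],
    total_images: int | None = None,
    name: str | None = None,
) -> PopulationTable:
    """Population table from a cohort or a per-class count mapping.

    Average cells/image is rounded half-up to 1 dp and class percentages to
    2 dp; percentages therefore sum to 100 within rounding tolerance.
    """
    if isinstance(source, CohortDataset):
        counts: dict[str, int] = {}
        for _, inst in source.all_instances():
            counts[inst.cell_class] = counts.get(inst.cell_class, 0) + 1
        total_images = len(source.frames)
        name = name or source.name
    else:
        counts = dict(source)
        if total_images is None:
            raise ValueError("total_images is required with a count mapping")
        name = name or "cohort"
    if total_images < 1:
        raise ValueError("population table requires at least one image")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("population table requires at least one cell (percentages undefined)")
    return PopulationTable(
        name=name,
        total_cells=total,
        total_images=total_images,
        avg_cells_per_image=round_half_up(total, total_images, ndigits=1),
        class_counts=counts,
        class_percentages={
            cls: round_half_up(100 * n, total, ndigits=2) for cls, n in counts.items()
        },
    )


def split_dataset(
    frames: Sequence,
    ratios: Sequence[float] = (0.90, 0.05, 0.05),
    seed: int = 0,
    labels: Sequence[str] = ("train", "validation", "test"),
) -> SplitAssignment:
    """Random frame-level partition with largest-remainder size apportionment.

    Frames are shuffled by the seed and dealt into partitions whose sizes are
    the largest-remainder apportionment of ``ratios`` x n, so each size
    differs from its exact share by less than one frame.  Deterministic given
    the seed.  (Frames from one biopsy may land in different partitions; the
    split is intentionally at the image level.)
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != len(labels):
        raise ValueError("ratios and labels must have equal length")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    ids = [f.frame_id if hasattr(f, "frame_id") else str(f) for f in frames]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate frame ids in split input")
    n = len(ids)
    exact = [r * n for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # hand leftover frames to the largest fractional remainders (ties by order)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    assignment = {}
    pos = 0
    for lab, size in zip(labels, base):
        for fid in shuffled[pos:pos + size]:
            assignment[fid] = lab
        pos += size
    return SplitAssignment(
        assignment=assignment,
        ratios=ratios,
        labels=tuple(labels),
        seed=seed,
        sizes=dict(zip(labels, base)),
    )


# ---------------------------------------------------------------------------
# Feature-table comparison (fixation / panel contrasts)
# ---------------------------------------------------------------------------

_MORPH_FEATURES = ("area_um2", "perimeter_um", "equivalent_diameter_um")


def compare_fixations(
    features_a: tuple[pd.DataFrame, pd.DataFrame],
    features_b: tuple[pd.DataFrame, pd.DataFrame],
    labels: tuple[str, str] = ("a", "b"),
    features: Sequence[str] | None = None,
    ks_method: str = "asymp",
) -> list[ComparisonResult]:
    """Compare two cohorts' feature tables group by group.

    ``features_a`` / ``features_b`` are (morphometry, proximity) table pairs
    as produced by :func:`immunoseg.features.cohort_features`.  One result is
    emitted per morphometry feature per cell class, one for the T-cell
    nearest-DC distance, and one for confidence over all cells.
    """
    morph_a, prox_a = features_a
    morph_b, prox_b = features_b
    wanted = tuple(features) if features is not None else _MORPH_FEATURES
    for col in wanted + ("cell_class", "confidence"):
        for df, side in ((morph_a, labels[0]), (morph_b, labels[1])):
            if col not in df.columns:
                raise ValueError(f"feature column {col!r} missing from {side} morphometry table")
    results = []
    classes = sorted(set(morph_a["cell_class"]) | set(morph_b["cell_class"]))
    for feat in wanted:
        for cls in classes:
            xa = morph_a.loc[morph_a["cell_class"] == cls, feat].to_numpy()
            xb = morph_b.loc[morph_b["cell_class"] == cls, feat].to_numpy()
            if xa.size == 0 or xb.size == 0:
                continue
            results.append(_compare(feat, cls, xa, xb, labels, ks_method))
    da = prox_a.loc[prox_a["t_cell_class"].isin(T_CELL_CLASSES), "distance_um"].to_numpy()
    db = prox_b.loc[prox_b["t_cell_class"].isin(T_CELL_CLASSES), "distance_um"].to_numpy()
    if da.size and db.size:
        results.append(_compare("min_distance_to_dc_um", "T", da, db, labels, ks_method))
    ca = morph_a["confidence"].to_numpy()
    cb = morph_b["confidence"].to_numpy()
    if ca.size and cb.size:
        results.append(_compare("confidence", "all", ca, cb, labels, ks_method))
    return results


def _compare(feat, cls, xa, xb, labels, ks_method) -> ComparisonResult:
    d, p = ks_two_sample(xa, xb, method=ks_method)
    return ComparisonResult(
        feature=feat,
        cell_class=cls,
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(xa.size),
        n_b=int(xb.size),
        mean_a=float(np.mean(xa)),
        mean_b=float(np.mean(xb)),
        percent_change=percent_change_of_means(xa, xb),
        ks_D=d,
        p_value=p,
        small_sample=bool(min(xa.size, xb.size) < 5),
    )


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a DataFrame (one row per feature x grouping)."""
    return pd.DataFrame([vars(r) for r in results])
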