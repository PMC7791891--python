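"""File formats: polygon JSON frames, label-map TIFFs, cohort manifests, reports.

Two interchangeable frame formats exist; polygons are canonical.

- Polygon JSON: a GeoJSON-like FeatureCollection.  Top-level ``metadata``
  carries frame_id, width/height, pixel size, fixation and panel; each
  feature's properties carry id, class, confidence and source.  Instances
  without a simple outline (mask-backed) are stored as the union of their
  pixel squares (Polygon with holes or MultiPolygon) and rasterized back on
  read, which is exact because pixel centers never fall on integer-grid
  boundaries.
- Label map: single-channel 16-bit TIFF plus a CSV sidecar with columns
  label, class, confidence.

A cohort manifest (YAML) names the cohort, role, and its frame files.  All
instance invariants are checked on load.  Writers are deterministic: the
same inputs produce byte-identical files (run-manifest timestamps live in a
separate file).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon, shape as shapely_shape

from immunoseg.model import (
    CellInstance,
    CohortDataset,
    ImageFrame,
    InvariantError,
    LocalMask,
    polygonize,
    to_label_map,
    validate_cohort,
    validate_frame,
)

__all__ = [
    "write_frame_json", "read_frame_json",
    "write_frame_labelmap", "read_frame_labelmap",
    "write_cohort", "read_cohort",
    "write_eval_summary", "write_comparison", "write_population_table",
    "write_run_manifest", "file_sha256",
]


# ---------------------------------------------------------------------------
# Polygon JSON
# ---------------------------------------------------------------------------

def _instance_geometry_json(inst: CellInstance) -> dict:
    if inst.outline is not None:
        ring = [[float(x), float(y)] for x, y in inst.outline]
        ring.append(ring[0])
        return {"type": "Polygon", "coordinates": [ring]}
    return json.loads(shapely.to_geojson(inst.geometry))


def write_frame_json(frame: ImageFrame, path) -> Path:
    path = Path(path)
    doc = {
        "type": "FeatureCollection",
        "metadata": {
            "frame_id": frame.frame_id,
            "width_px": frame.width_px,
            "height_px": frame.height_px,
            "pixel_size_um": frame.pixel_size_um,
            "fixation": frame.fixation,
            "panel": frame.panel,
        },
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "id": inst.id,
                    "class": inst.cell_class,
                    "confidence": inst.confidence,
                    "source": inst.source,
                },
                "geometry": _instance_geometry_json(inst),
            }
            for inst in frame.instances
        ],
    }
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")
    return path


def _geometry_to_instance_fields(geom) -> tuple[np.ndarray | None, LocalMask | None]:
    """Simple single-ring polygons become outlines; anything else is
    rasterized (center-in-geometry) into a mask."""
    if geom.geom_type == "Polygon" and len(geom.interiors) == 0:
        return np.asarray(geom.exterior.coords[:-1], dtype=float), None
    xmin, ymin, xmax, ymax = geom.bounds
    col0, row0 = int(np.floor(xmin)), int(np.floor(ymin))
    cols = np.arange(col0, int(np.ceil(xmax))) + 0.5
    rows = np.arange(row0, int(np.ceil(ymax))) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return None, LocalMask(row0, col0, inside)


def read_frame_json(path) -> ImageFrame:
    path = Path(path)
    doc = json.loads(path.read_text())
    meta = doc["metadata"]
    instances = []
    for feat in doc["features"]:
        props = feat["properties"]
        outline, mask = _geometry_to_instance_fields(shapely_shape(feat["geometry"]))
        instances.append(
            CellInstance(
                id=int(props["id"]),
                cell_class=str(props["class"]),
                outline=outline,
                mask=mask,
                confidence=float(props["confidence"]),
                source=str(props["source"]),
            )
        )
    frame = ImageFrame(
        frame_id=str(meta["frame_id"]),
        width_px=int(meta["width_px"]),
        height_px=int(meta["height_px"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        fixation=str(meta["fixation"]),
        panel=str(meta["panel"]),
        instances=instances,
    )
    try:
        validate_frame(frame)
    except InvariantError as exc:
        raise InvariantError(f"{path}: {exc}") from exc
    return frame


# ---------------------------------------------------------------------------
# Label-map TIFF + CSV sidecar
# ---------------------------------------------------------------------------

def write_frame_labelmap(frame: ImageFrame, tiff_path, mode: str = "strict") -> tuple[Path, Path]:
    tiff_path = Path(tiff_path)
    csv_path = tiff_path.with_suffix(".csv")
    labels, table = to_label_map(frame, mode=mode)
    tifffile.imwrite(tiff_path, labels.astype(np.uint16))
    meta = pd.DataFrame(
        {
            "label": table["label"],
            "class": table["class"],
            "confidence": table["confidence"],
        }
    )
    meta.to_csv(csv_path, index=False)
    return tiff_path, csv_path


def read_frame_labelmap(
    tiff_path, *, frame_id=None, pixel_size_um=0.1058, fixation="FFPE", panel="panel2"
) -> ImageFrame:
    tiff_path = Path(tiff_path)
    csv_path = tiff_path.with_suffix(".csv")
    if not csv_path.exists():
        raise FileNotFoundError(f"sidecar table {csv_path} not found")
    labels = tifffile.imread(tiff_path).astype(np.int64)
    sidecar = pd.read_csv(csv_path)
    frame = polygonize(
        labels,
        sidecar,
        frame_id=frame_id or tiff_path.stem,
        pixel_size_um=pixel_size_um,
        fixation=fixation,
        panel=panel,
    )
    validate_frame(frame)
    return frame


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: CohortDataset, directory, fmt: str = "json", labelmap_mode: str = "strict"
) -> Path:
    """Write every frame plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for frame in cohort.frames:
        if fmt == "json":
            p = write_frame_json(frame, directory / f"{frame.frame_id}.json")
            entries.append(p.name)
        elif fmt == "labelmap":
            p, _ = write_frame_labelmap(
                frame, directory / f"{frame.frame_id}.tif", mode=labelmap_mode
            )
            entries.append(p.name)
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
    manifest = {
        "name": cohort.name,
        "role": cohort.role,
        "fixation": cohort.frames[0].fixation if cohort.frames else None,
        "panel": cohort.frames[0].panel if cohort.frames else None,
        "pixel_size_um": cohort.frames[0].pixel_size_um if cohort.frames else None,
        "frames": entries,
    }
    mpath = directory / f"{cohort.name}.manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_cohort(manifest_path) -> CohortDataset:
    """Load and fully validate a cohort from its manifest."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    frames = []
    for entry in doc["frames"]:
        fpath = base / entry
        if not fpath.exists():
            raise FileNotFoundError(f"manifest {manifest_path} references missing file {fpath}")
        if fpath.suffix == ".json":
            frames.append(read_frame_json(fpath))
        elif fpath.suffix in (".tif", ".tiff"):
            frames.append(
                read_frame_labelmap(
                    fpath,
                    pixel_size_um=float(doc["pixel_size_um"]),
                    fixation=doc["fixation"],
                    panel=doc["panel"],
                )
            )
        else:
            raise ValueError(f"unrecognized frame file type: {fpath}")
    cohort = CohortDataset(name=doc["name"], frames=frames, role=doc.get("role", "truth"))
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_eval_summary(summary, path) -> Path:
    """Per-class and overall metrics as CSV with stable column order."""
    path = Path(path)
    rows = []
    for cls, m in summary.per_class.items():
        rows.append(
            {
                "cell_class": cls, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "n_truth": m.n_truth, "n_pred": m.n_pred,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "iou_mean": m.iou_mean, "iou_sd": m.iou_sd,
            }
        )
    rows.append(
        {
            "cell_class": "all_weighted", "tp": "", "fp": "", "fn": "",
            "n_truth": "", "n_pred": "",
            "sensitivity": summary.sensitivity,
            "specificity": summary.specificity,
            "iou_mean": summary.iou_mean, "iou_sd": "",
        }
    )
    rows.append(
        {
            "cell_class": "all_unweighted", "tp": "", "fp": "", "fn": "",
            "n_truth": "", "n_pred": "",
            "sensitivity": summary.sensitivity_unweighted,
            "specificity": summary.specificity_unweighted,
            "iou_mean": summary.iou_mean_unweighted, "iou_sd": "",
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_comparison(results, path) -> Path:
    from immunoseg.stats import comparison_table

    path = Path(path)
    comparison_table(results).to_csv(path, index=False)
    return path


def write_population_table(tables, path) -> Path:
    """Population tables in the printed layout: total cells (images), average
    cells/image, then per-class count with percentage."""
    path = Path(path)
    classes: list[str] = []
    for t in tables:
        for cls in t.class_counts:
            if cls not in classes:
                classes.append(cls)
    rows = []
    for t in tables:
        row = {
            "dataset": t.name,
            "total_cells_images": f"{t.total_cells} ({t.total_images})",
            "avg_cells_per_image": f"{t.avg_cells_per_image:.1f}",
        }
        for cls in classes:
            if cls in t.class_counts:
                row[cls] = f"{t.class_counts[cls]} ({t.class_percentages[cls]:.2f})"
            else:
                row[cls] = "N/A"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(
    path,
    command: str,
    *,
    inputs=(),
    thresholds: dict | None = None,
    seed=None,
    distance_mode=None,
    config: dict | None = None,
) -> Path:
    """JSON provenance record written next to every output."""
    from immunoseg import __version__

    path = Path(path)
    doc = {
        "command": command,
        "tool_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "thresholds": thresholds or {},
        "distance_mode": distance_mode,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "config_hash": (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None else None
        ),
    }
    path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    return path
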