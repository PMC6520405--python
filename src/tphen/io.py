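"""Plain-text readers and writers for cohorts, features and models.

Cells are stored as one CSV (case_id, stain, x_px, y_px, class), the clinical
table as CSV, annotations as GeoJSON polygons in 0-based image pixel
coordinates (x = column), per-case rigid transforms as JSON, and the
simulation configuration as YAML. Tissue masks can optionally be written as
single-channel TIFF label images.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .registration import TransformGrid
from .synthetic import CaseAnnotations, SimulationConfig
from .types import CaseRecord, CellMap


def write_cohort(out_dir, cases, cellmaps, annotations, config: SimulationConfig | None = None,
                 write_masks: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cells = []
    for case_id, per_stain in cellmaps.items():
        for stain, cm in per_stain.items():
            df = cm.cells.assign(case_id=case_id, stain=stain)
            cells.append(df[["case_id", "stain", "x_px", "y_px", "cls"]])
    pd.concat(cells, ignore_index=True).rename(columns={"cls": "class"}).to_csv(
        out / "cells.csv", index=False
    )

    clin = pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "response_category": c.response_category,
                "responder": c.responder,
                "os_months": c.os_months,
                "event": c.event,
            }
            for c in cases
        ]
    )
    clin.to_csv(out / "clinical.csv", index=False)

    features = []
    transforms = {}
    for case_id, ann in annotations.items():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(ann.tumor_polygon),
                "properties": {"case_id": case_id, "kind": "tumor"},
            }
        )
        for i, poly in enumerate(ann.exclusion_polygons):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"case_id": case_id, "kind": "exclusion", "index": i},
                }
            )
        transforms[case_id] = json.loads(ann.transform_cd8_to_cd3.to_json())
    (out / "annotations.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    (out / "transforms.json").write_text(json.dumps(transforms))

    if config is not None:
        (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    meta = {}
    for case_id, per_stain in cellmaps.items():
        cm = per_stain["CD3"]
        meta[case_id] = {"image_shape": list(cm.image_shape), "pixel_size_um": cm.pixel_size_um}
    (out / "maps.json").write_text(json.dumps(meta))

    if write_masks:
        import tifffile

        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for case_id, per_stain in cellmaps.items():
            for stain, cm in per_stain.items():
                if cm.tissue_mask is not None:
                    tifffile.imwrite(
                        mask_dir / f"{case_id}_{stain}_tissue.tif",
                        cm.tissue_mask.astype(np.uint8),
                    )


def read_cohort(in_dir):
    """Inverse of :func:`write_cohort` (masks default to full-frame tissue)."""
    src = Path(in_dir)
    clin = pd.read_csv(src / "clinical.csv")
    cases = [
        CaseRecord(r.case_id, r.response_category, float(r.os_months), bool(r.event))
        for r in clin.itertuples()
    ]
    meta = json.loads((src / "maps.json").read_text())
    cells = pd.read_csv(src / "cells.csv").rename(columns={"class": "cls"})
    transforms = json.loads((src / "transforms.json").read_text())
    geo = json.loads((src / "annotations.geojson").read_text())

    cellmaps: dict[str, dict[str, CellMap]] = {}
    for (case_id, stain), df in cells.groupby(["case_id", "stain"]):
        m = meta[case_id]
        mask_file = src / "masks" / f"{case_id}_{stain}_tissue.tif"
        if mask_file.exists():
            import tifffile

            tissue = tifffile.imread(mask_file).astype(bool)
        else:
            tissue = np.ones(tuple(m["image_shape"]), dtype=bool)
        cellmaps.setdefault(case_id, {})[stain] = CellMap(
            stain=stain,
            cells=df[["x_px", "y_px", "cls"]].reset_index(drop=True),
            image_shape=tuple(m["image_shape"]),
            pixel_size_um=m["pixel_size_um"],
            tissue_mask=tissue,
        )

    annotations: dict[str, CaseAnnotations] = {}
    for case_id in cellmaps:
        tumor = None
        exclusions = []
        for feat in geo["features"]:
            if feat["properties"]["case_id"] != case_id:
                continue
            poly = shape(feat["geometry"])
            if feat["properties"]["kind"] == "tumor":
                tumor = poly
            else:
                exclusions.append(poly)
        grid = TransformGrid.from_json(json.dumps(transforms[case_id]))
        annotations[case_id] = CaseAnnotations(
            tumor_polygon=tumor,
            exclusion_polygons=exclusions,
            transform_cd8_to_cd3=grid,
            true_iti_ratio=float("nan"),
        )
    return cases, cellmaps, annotations


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Feature CSV plus a JSON sidecar describing the columns."""
    table.to_csv(path, index_label="case_id")
    sidecar = Path(str(path)).with_suffix(".meta.json")
    kinds = {}
    for name in table.columns:
        kinds[name] = name.split(":", 1)[0]
    sidecar.write_text(json.dumps({"n_features": table.shape[1], "kinds": kinds}))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="case_id")
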