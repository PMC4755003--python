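"""CSV and TIFF interfaces for catalogues, metrics and clinical tables.

Column layouts are fixed contracts shared with the CLI; missing values
serialise as empty fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import FEATURE_NAMES, ObjectCatalogue
from .spatial import METRIC_FIELDS, DensityField, SlideMetrics, metrics_to_frame

CATALOGUE_COLUMNS = (
    ["slide_id", "phase", "object_id", "x_px", "y_px", "area_px2", "a_px", "b_px", "theta_rad"]
    + [f"f{i + 1}" for i in range(len(FEATURE_NAMES))]
    + ["class_label", "density_per_mm2"]
)

CLINICAL_COLUMNS = (
    "patient_id", "age", "tumour_size_gt50", "node_positive", "grade",
    "er_positive", "her2_positive", "taxane_second", "pcr", "til_category",
)


def write_catalogue_csv(cat: ObjectCatalogue, path: str | Path,
                        densities: dict[int, float] | None = None) -> None:
    df = cat.to_frame()
    df["density_per_mm2"] = df["object_id"].map(densities) if densities else np.nan
    df.loc[df["class_label"] == "unclassified", "class_label"] = ""
    df.to_csv(path, index=False, columns=list(CATALOGUE_COLUMNS))


def read_catalogue_csv(path: str | Path, mpp: float = 0.5) -> ObjectCatalogue:
    df = pd.read_csv(path, keep_default_na=True)
    df["class_label"] = df["class_label"].fillna("")
    return ObjectCatalogue.from_frame(df, mpp=mpp)


def write_metrics_csv(metrics: list[SlideMetrics], path: str | Path) -> None:
    metrics_to_frame(metrics).to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(("id", "phase", *METRIC_FIELDS)) - set(df.columns)
    if missing:
        raise ValueError(f"metrics file lacks columns: {sorted(missing)}")
    return df


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns) - {"til_category"}
    if missing:
        raise ValueError(f"clinical file lacks columns: {sorted(missing)}")
    return df


def write_density_field(field: DensityField, tiff_path: str | Path, csv_path: str | Path) -> None:
    """Single-band float TIFF of node values plus a long-form node CSV."""
    tifffile.imwrite(tiff_path, field.values.astype(np.float32))
    ny, nx = field.values.shape
    ox, oy = field.origin_px
    s = field.spacing_px
    rows = [
        {"x_px": ox + j * s, "y_px": oy + i * s, "density_per_mm2": field.values[i, j]}
        for i in range(ny)
        for j in range(nx)
    ]
    pd.DataFrame(rows, columns=["x_px", "y_px", "density_per_mm2"]).to_csv(csv_path, index=False)
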