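"""Per-cell k-nearest like-class densities and the 15 slide metrics.

Every classified cell receives a density estimate from the distance to its
k-th nearest neighbour of the *same* class (k = 50 by default): if that
distance is d_k millimetres, the density is ``k / (pi * d_k^2)`` cells/mm^2
— the cell count inside the disc that just reaches the k-th like-class
neighbour.  A sample is then summarised by 15 metrics: per class the
absolute count, the relative fraction, and the minimum / median / maximum
of the per-cell density estimates.  Cells of a class with fewer than k
like-class companions carry no defined estimate, and the class's density
summaries are missing rather than computed at a reduced k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import CLASS_LABELS, ObjectCatalogue

#: canonical order of the 15 metric fields in tables and CSV files
METRIC_FIELDS = (
    "count_c", "count_s", "count_l",
    "frac_c", "frac_s", "frac_l",
    "dmin_c", "dmed_c", "dmax_c",
    "dmin_s", "dmed_s", "dmax_s",
    "dmin_l", "dmed_l", "dmax_l",
)

_SUFFIX = {"cancer": "c", "stromal": "s", "lymphocyte": "l"}


@dataclass(frozen=True)
class DensityEstimate:
    object_id: int
    k_used: int
    d_k_mm: float            # nan when undefined
    density_per_mm2: float   # nan when undefined
    defined: bool


@dataclass(frozen=True)
class SlideMetrics:
    """The 15 machine-derived metrics of one sample (slide or patient)."""

    slide_or_patient_id: str
    phase: str
    count_cancer: int
    count_stromal: int
    count_lymphocyte: int
    fraction_cancer: float
    fraction_stromal: float
    fraction_lymphocyte: float
    density_min: dict      # class -> float | nan
    density_median: dict
    density_max: dict
    total_cells: int

    def to_dict(self) -> dict:
        out = {"id": self.slide_or_patient_id, "phase": self.phase}
        out["count_c"] = self.count_cancer
        out["count_s"] = self.count_stromal
        out["count_l"] = self.count_lymphocyte
        out["frac_c"] = self.fraction_cancer
        out["frac_s"] = self.fraction_stromal
        out["frac_l"] = self.fraction_lymphocyte
        for cls, sfx in _SUFFIX.items():
            out[f"dmin_{sfx}"] = self.density_min[cls]
            out[f"dmed_{sfx}"] = self.density_median[cls]
            out[f"dmax_{sfx}"] = self.density_max[cls]
        out["total_cells"] = self.total_cells
        return out


def knn_density(
    cat: ObjectCatalogue,
    class_label: str,
    k: int = 50,
) -> list[DensityEstimate]:
    """k-NN like-class density for every cell of ``class_label``.

    Distances are Euclidean between centroids, converted to millimetres via
    the catalogue's microns-per-pixel, self excluded.  An estimate is
    defined only when at least k other cells of the class exist.  Distance
    ties among neighbours cannot change d_k, so no tie-break is needed for
    the density value itself.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = [o for o in cat.objects if o.class_label == class_label]
    n = len(cells)
    if n == 0:
        return []
    if n <= k:
        return [DensityEstimate(o.object_id, k, math.nan, math.nan, False) for o in cells]

    pts_mm = np.array([(o.x_px, o.y_px) for o in cells]) * (cat.mpp / 1000.0)
    tree = cKDTree(pts_mm)
    # k+1 neighbours including self; column k is the k-th true neighbour
    dists, _ = tree.query(pts_mm, k=k + 1)
    d_k = dists[:, k]
    dens = k / (math.pi * d_k**2)
    return [
        DensityEstimate(o.object_id, k, float(d), float(rho), True)
        for o, d, rho in zip(cells, d_k, dens)
    ]


def _summarise(values: np.ndarray) -> tuple[float, float, float]:
    if len(values) == 0:
        return (math.nan, math.nan, math.nan)
    return (float(values.min()), float(np.median(values)), float(values.max()))


def slide_metrics(cat: ObjectCatalogue, k: int = 50, sample_id: str | None = None) -> SlideMetrics:
    """The 15 metrics of one labelled catalogue.

    Unclassified objects are excluded from counts and fraction denominators.
    Density summaries are over the defined per-cell estimates of the class
    and are missing (NaN) when none are defined.
    """
    counts = {c: sum(1 for o in cat.objects if o.class_label == c) for c in CLASS_LABELS}
    total = sum(counts.values())
    fracs = {c: (counts[c] / total if total else 0.0) for c in CLASS_LABELS}

    dmin, dmed, dmax = {}, {}, {}
    for c in CLASS_LABELS:
        vals = np.array([e.density_per_mm2 for e in knn_density(cat, c, k) if e.defined])
        dmin[c], dmed[c], dmax[c] = _summarise(vals)

    return SlideMetrics(
        slide_or_patient_id=sample_id or cat.slide_id,
        phase=cat.phase,
        count_cancer=counts["cancer"],
        count_stromal=counts["stromal"],
        count_lymphocyte=counts["lymphocyte"],
        fraction_cancer=fracs["cancer"],
        fraction_stromal=fracs["stromal"],
        fraction_lymphocyte=fracs["lymphocyte"],
        density_min=dmin,
        density_median=dmed,
        density_max=dmax,
        total_cells=total,
    )


def aggregate_patient(
    catalogues: list[ObjectCatalogue],
    k: int = 50,
    patient_id: str | None = None,
) -> SlideMetrics:
    """Pool one patient's slides of one phase into patient-level metrics.

    Counts are summed and fractions recomputed from the pooled counts.
    Densities are computed *within* each slide — spatial context never
    crosses physical sections — and the per-cell estimates are pooled
    before taking min / median / max.
    """
    if not catalogues:
        raise ValueError("aggregate_patient needs at least one catalogue")
    phases = {c.phase for c in catalogues}
    if len(phases) != 1:
        raise ValueError(f"mixed phases in aggregation: {sorted(phases)}")

    counts = {c: 0 for c in CLASS_LABELS}
    pooled: dict[str, list[float]] = {c: [] for c in CLASS_LABELS}
    for cat in catalogues:
        for c in CLASS_LABELS:
            counts[c] += sum(1 for o in cat.objects if o.class_label == c)
            pooled[c].extend(e.density_per_mm2 for e in knn_density(cat, c, k) if e.defined)
    total = sum(counts.values())
    fracs = {c: (counts[c] / total if total else 0.0) for c in CLASS_LABELS}

    dmin, dmed, dmax = {}, {}, {}
    for c in CLASS_LABELS:
        dmin[c], dmed[c], dmax[c] = _summarise(np.array(pooled[c]))

    return SlideMetrics(
        slide_or_patient_id=patient_id or catalogues[0].slide_id,
        phase=catalogues[0].phase,
        count_cancer=counts["cancer"],
        count_stromal=counts["stromal"],
        count_lymphocyte=counts["lymphocyte"],
        fraction_cancer=fracs["cancer"],
        fraction_stromal=fracs["stromal"],
        fraction_lymphocyte=fracs["lymphocyte"],
        density_min=dmin,
        density_median=dmed,
        density_max=dmax,
        total_cells=total,
    )


@dataclass(frozen=True)
class DensityField:
    """Density evaluated on a regular grid of nodes, for contour display."""

    origin_px: tuple[float, float]
    spacing_px: float
    values: np.ndarray  # (ny, nx); empty when the class is too sparse
    empty: bool


def density_field(
    cat: ObjectCatalogue,
    class_label: str,
    grid_spacing_px: float,
    k: int = 50,
) -> DensityField:
    """Evaluate ``k / (pi d_k^2)`` at grid nodes, d_k being the distance
    from the node to the k-th nearest cell of the class."""
    cells = [o for o in cat.objects if o.class_label == class_label]
    if len(cells) < k + 1:
        return DensityField((0.0, 0.0), grid_spacing_px, np.empty((0, 0)), True)

    pts = np.array([(o.x_px, o.y_px) for o in cells])
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    xs = np.arange(x0, x1 + grid_spacing_px, grid_spacing_px)
    ys = np.arange(y0, y1 + grid_spacing_px, grid_spacing_px)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    tree = cKDTree(pts * (cat.mpp / 1000.0))
    d_k, _ = tree.query(nodes * (cat.mpp / 1000.0), k=k)
    d_k = d_k[:, -1] if k > 1 else d_k
    vals = (k / (math.pi * d_k**2)).reshape(gy.shape)
    return DensityField((float(x0), float(y0)), float(grid_spacing_px), vals, False)


def metrics_to_frame(metrics: list[SlideMetrics]) -> pd.DataFrame:
    """Metrics table matching the CSV contract (missing density summaries
    serialise as empty fields via NaN)."""
    cols = ["id", "phase", *METRIC_FIELDS, "total_cells"]
    return pd.DataFrame([m.to_dict() for m in metrics], columns=cols)
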