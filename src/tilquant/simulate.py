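"""Synthetic inputs for every pipeline stage.

No study data accompany the method, so this module generates all of it:

* spatial point patterns (homogeneous Poisson or Thomas cluster processes)
  for density-estimator checks,
* rendered H&E-like tiles — three morphologically distinct nucleus classes
  (small round dark lymphocytes, large pleomorphic cancer nuclei, pale
  elongated stromal nuclei) composited by Beer-Lambert absorption over a
  textured pink stroma with optional white space — together with the exact
  ground-truth catalogue of planted nuclei,
* labelled nuclear-feature training sets, and
* neoadjuvant-trial-like cohorts: clinical covariates drawn from the
  published trial marginals, a pre-treatment log10 median lymphocyte
  density, a paired post-treatment density, and a pCR outcome generated
  either from direction-conditional response rates (the calibration
  default) or from a logistic model with planted coefficients (for
  parameter-recovery studies).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classification import TrainingSet
from .config import PipelineConfig
from .segmentation import CLASS_LABELS

# ---------------------------------------------------------------------------
# point patterns


def simulate_point_pattern(
    class_specs: dict,
    window_mm: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate labelled points in a rectangular window.

    ``class_specs`` maps class label -> spec dict with ``process`` either
    ``"poisson"`` (key ``intensity`` per mm^2) or ``"thomas"`` (keys
    ``parent_intensity`` per mm^2, ``mean_offspring``, ``cluster_sd_mm``).
    A Thomas process with parent intensity kappa and mean offspring mu has
    expected intensity kappa * mu, matched against a Poisson process for
    clustering comparisons.  Returns columns x_mm, y_mm, class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = window_mm
    area = w * h
    frames = []
    for label, spec in class_specs.items():
        proc = spec.get("process", "poisson")
        if proc == "poisson":
            lam = float(spec["intensity"])
            if lam < 0:
                raise ValueError("intensity must be non-negative")
            n = rng.poisson(lam * area)
            xs = rng.uniform(0, w, n)
            ys = rng.uniform(0, h, n)
        elif proc == "thomas":
            kappa = float(spec["parent_intensity"])
            mu = float(spec["mean_offspring"])
            sd = float(spec["cluster_sd_mm"])
            if kappa < 0 or mu < 0 or sd < 0:
                raise ValueError("Thomas parameters must be non-negative")
            pad = 4 * sd  # parents outside the window still scatter points in
            n_par = rng.poisson(kappa * (w + 2 * pad) * (h + 2 * pad))
            px = rng.uniform(-pad, w + pad, n_par)
            py = rng.uniform(-pad, h + pad, n_par)
            counts = rng.poisson(mu, n_par)
            xs = np.repeat(px, counts) + rng.normal(0, sd, counts.sum())
            ys = np.repeat(py, counts) + rng.normal(0, sd, counts.sum())
            inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
            xs, ys = xs[inside], ys[inside]
        else:
            raise ValueError(f"unknown process {proc!r}")
        frames.append(pd.DataFrame({"x_mm": xs, "y_mm": ys, "class": label}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["x_mm", "y_mm", "class"]
    )


# ---------------------------------------------------------------------------
# tile rendering

#: default stain vectors shared with the segmentation module's deconvolution
_H_VEC = np.array([0.650, 0.704, 0.286])
_E_VEC = np.array([0.072, 0.990, 0.105])
_H_VEC = _H_VEC / np.linalg.norm(_H_VEC)
_E_VEC = _E_VEC / np.linalg.norm(_E_VEC)


@dataclass(frozen=True)
class NucleusStyle:
    """Morphology and staining of one nucleus class (pixel units)."""

    intensity_per_mm2: float
    radius_mean_px: float      # geometric mean semi-axis
    radius_sd_px: float
    ecc_range: tuple[float, float]   # ellipticity 1 - b/a
    h_od_mean: float
    h_od_sd: float
    e_od: float


#: class styles: lymphocytes small/round/dark, cancer large/pleomorphic,
#: stromal elongated/pale (pixel sizes assume ~0.5 um/px)
DEFAULT_STYLES: dict[str, NucleusStyle] = {
    "lymphocyte": NucleusStyle(250.0, 3.2, 0.25, (0.0, 0.15), 0.95, 0.06, 0.02),
    "cancer": NucleusStyle(250.0, 7.0, 0.8, (0.10, 0.45), 0.55, 0.06, 0.05),
    "stromal": NucleusStyle(250.0, 4.8, 0.4, (0.55, 0.72), 0.35, 0.04, 0.08),
}


@dataclass(frozen=True)
class TileSpec:
    """Recipe for one rendered tile."""

    width_px: int = 1024
    height_px: int = 1024
    mpp: float = 0.5
    styles: dict[str, NucleusStyle] = field(default_factory=lambda: dict(DEFAULT_STYLES))
    stroma_e_od: float = 0.25
    stroma_h_od: float = 0.05
    texture_sd: float = 0.02
    white_rects: tuple[tuple[int, int, int, int], ...] = ()
    min_gap_px: float = 2.0         # enforced between nucleus boundaries
    allow_overlap: bool = False
    max_placement_attempts: int = 40


def _place_nuclei(spec: TileSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw nucleus positions and shapes; by default dart-throwing keeps
    ellipses (approximated by their semi-major circles) non-overlapping."""
    rows = []
    area_mm2 = (spec.width_px * spec.mpp / 1000.0) * (spec.height_px * spec.mpp / 1000.0)
    for label, style in spec.styles.items():
        n = rng.poisson(style.intensity_per_mm2 * area_mm2)
        for _ in range(n):
            a = -1.0
            while a <= 0.3:
                a = rng.normal(style.radius_mean_px, style.radius_sd_px)
            ecc = rng.uniform(*style.ecc_range)
            # a is drawn as the geometric-mean semi-axis; elongate at
            # constant pixel area so the area gate behaves the same for
            # round and elongated classes
            b = a * math.sqrt(1.0 - ecc)
            a = a / math.sqrt(1.0 - ecc)
            rows.append(
                {
                    "class": label,
                    "a_px": a,
                    "b_px": b,
                    "theta_rad": rng.uniform(-math.pi / 2, math.pi / 2),
                    "h_od": max(rng.normal(style.h_od_mean, style.h_od_sd), 0.1),
                    "e_od": style.e_od,
                }
            )
    rng.shuffle(rows)

    placed_xy: list[tuple[float, float]] = []
    placed_r: list[float] = []
    out = []
    for row in rows:
        r = row["a_px"]
        pos = None
        for _ in range(spec.max_placement_attempts):
            x = rng.uniform(0, spec.width_px)
            y = rng.uniform(0, spec.height_px)
            if spec.allow_overlap or not placed_xy:
                pos = (x, y)
                break
            pts = np.asarray(placed_xy)
            dmin = np.hypot(pts[:, 0] - x, pts[:, 1] - y) - (np.asarray(placed_r) + r)
            if dmin.min() >= spec.min_gap_px:
                pos = (x, y)
                break
        if pos is None:
            continue  # crowded tile: drop rather than overlap
        placed_xy.append(pos)
        placed_r.append(r)
        clipped = not (r <= pos[0] <= spec.width_px - r and r <= pos[1] <= spec.height_px - r)
        out.append({**row, "x_px": pos[0], "y_px": pos[1], "clipped": clipped})
    truth = pd.DataFrame(
        out, columns=["class", "x_px", "y_px", "a_px", "b_px", "theta_rad", "h_od", "e_od", "clipped"]
    )
    truth.insert(0, "nucleus_id", np.arange(1, len(truth) + 1))
    return truth


def render_tile(spec: TileSpec, seed: int | np.random.Generator = 0):
    """Render a tile and return ``(rgb_uint8, ground_truth)``.

    Nuclei are anti-aliased ellipses whose haematoxylin (and a little
    eosin) optical density is composited by Beer-Lambert over the stroma
    background; white-space rectangles have zero OD.  The ground truth
    lists every planted nucleus; nuclei extending past the tile edge are
    rendered clipped and flagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    if h <= 0 or w <= 0:
        raise ValueError("tile dimensions must be positive")

    h_od = np.full((h, w), spec.stroma_h_od) + rng.normal(0, spec.texture_sd, (h, w))
    e_od = np.full((h, w), spec.stroma_e_od) + rng.normal(0, spec.texture_sd, (h, w))
    h_od = np.clip(h_od, 0, None)
    e_od = np.clip(e_od, 0, None)
    for x0, y0, x1, y1 in spec.white_rects:
        h_od[y0:y1, x0:x1] = 0.0
        e_od[y0:y1, x0:x1] = 0.0

    truth = _place_nuclei(spec, rng)
    for row in truth.itertuples():
        a, b = row.a_px, row.b_px
        cx, cy = row.x_px, row.y_px
        pad = int(math.ceil(a)) + 2
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        ct, st = math.cos(row.theta_rad), math.sin(row.theta_rad)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        rho = np.hypot(u, v)
        # soft edge ~1 px wide for anti-aliasing
        cover = np.clip((1.0 - rho) * b + 0.5, 0.0, 1.0)
        h_od[y0:y1, x0:x1] += cover * row.h_od
        e_od[y0:y1, x0:x1] += cover * row.e_od

    od_rgb = h_od[:, :, None] * _H_VEC + e_od[:, :, None] * _E_VEC
    rgb = np.clip(np.rint(256.0 * 10.0 ** (-od_rgb) - 1.0), 0, 255).astype(np.uint8)
    return rgb, truth


def match_to_truth(detected: pd.DataFrame, truth: pd.DataFrame, max_dist_px: float = 3.0):
    """Greedy one-to-one nearest-centroid matching of detections to planted
    nuclei; returns (matches, recall, precision, mean centroid error)."""
    if len(detected) == 0 or len(truth) == 0:
        return pd.DataFrame(columns=["object_id", "nucleus_id", "dist_px"]), 0.0, 0.0, math.nan
    det = detected[["x_px", "y_px"]].to_numpy()
    tru = truth[["x_px", "y_px"]].to_numpy()
    tree = cKDTree(tru)
    dists, idx = tree.query(det)
    order = np.argsort(dists)
    used_t, used_d, pairs = set(), set(), []
    for i in order:
        if dists[i] > max_dist_px:
            break
        j = idx[i]
        if j in used_t or i in used_d:
            # nearest truth taken: look for the next-nearest free one
            cand = tree.query_ball_point(det[i], max_dist_px)
            cand = [c for c in cand if c not in used_t]
            if not cand or i in used_d:
                continue
            j = min(cand, key=lambda c: np.hypot(*(det[i] - tru[c])))
        used_t.add(j)
        used_d.add(i)
        pairs.append(
            {
                "object_id": int(detected.iloc[i]["object_id"]) if "object_id" in detected else i,
                "nucleus_id": int(truth.iloc[j]["nucleus_id"]),
                "dist_px": float(np.hypot(*(det[i] - tru[j]))),
            }
        )
    matches = pd.DataFrame(pairs)
    recall = len(matches) / len(truth)
    precision = len(matches) / len(detected)
    err = float(matches["dist_px"].mean()) if len(matches) else math.nan
    return matches, recall, precision, err


def fixture_training_set(
    seed: int = 0,
    n_per_class: int = 1000,
    config: PipelineConfig | None = None,
    tile_px: int = 1600,
) -> TrainingSet:
    """Build a labelled nuclear-feature training set by rendering tiles,
    running the real segmentation/measurement stages, and transferring
    ground-truth class labels to detections by nearest-centroid match."""
    from .pyramid import load_pyramid
    from .segmentation import build_catalogue

    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    feats: list[np.ndarray] = []
    labels: list[str] = []
    while True:
        counts = {c: labels.count(c) for c in CLASS_LABELS}
        if all(v >= n_per_class for v in counts.values()):
            break
        spec = TileSpec(width_px=tile_px, height_px=tile_px, mpp=cfg.mpp)
        rgb, truth = render_tile(spec, rng)
        cat = build_catalogue(load_pyramid(rgb, mpp_L0=cfg.mpp), config=cfg)
        df = cat.to_frame()
        matches, *_ = match_to_truth(df, truth, max_dist_px=3.0)
        truth_cls = truth.set_index("nucleus_id")["class"]
        obj_feats = {o.object_id: o.features for o in cat.objects}
        for m in matches.itertuples():
            feats.append(np.asarray(obj_feats[m.object_id]))
            labels.append(str(truth_cls[m.nucleus_id]))
    return TrainingSet(np.array(feats), np.array(labels, dtype=object))


def gaussian_clouds(
    n_per_class: int,
    separation_sd: float = 10.0,
    n_features: int = 8,
    seed: int = 0,
    n_holdout_per_class: int = 0,
):
    """Three unit-variance Gaussian feature clouds with class means
    pairwise separated by ``separation_sd`` within-class standard
    deviations (classifier sanity fixtures).

    Returns ``(X, y)``; with ``n_holdout_per_class`` also
    ``(X, y, X_hold, y_hold)`` drawn from the *same* clouds.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(3, n_features))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # push apart until pairwise separation is at least the requested one
    means = dirs * separation_sd
    for _ in range(50):
        d = np.linalg.norm(means[:, None] - means[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= separation_sd:
            break
        means *= 1.2

    def draw(n):
        X = np.vstack([rng.normal(m, 1.0, size=(n, n_features)) for m in means])
        y = np.repeat(list(CLASS_LABELS), n).astype(object)
        return X, y

    X, y = draw(n_per_class)
    if n_holdout_per_class:
        Xh, yh = draw(n_holdout_per_class)
        return X, y, Xh, yh
    return X, y


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a neoadjuvant-trial-like cohort.

    Covariate marginals default to the published trial's patient table;
    the paired-change model defaults to the published conditional response
    proportions (75.6% of paired cases decrease in lymphocyte density;
    pCR in 17.0% of decreases vs 6.7% of increases).  Setting
    ``direction_conditional=False`` switches pCR generation to a logistic
    model with planted coefficients (per log10-density unit), used for
    parameter-recovery and interaction studies.
    """

    n_patients: int = 765
    # clinical covariate marginals
    p_size_gt50: float = 0.199
    p_node_positive: float = 0.493
    grade_probs: tuple[float, float, float] = (0.037, 0.412, 0.551)
    p_er_positive: float = 0.6795
    p_her2_positive: float = 0.267
    p_taxane_second: float = 0.494
    age_mean: float = 49.0
    age_sd: float = 8.0
    # pre-treatment lymphocyte density scale (log10 cells/mm^2)
    log_density_mean: float = 2.5
    log_density_sd: float = 0.4
    # paired-change model
    p_decrease: float = 0.756
    delta_sd: float = 0.35
    delta_pre_corr: float = -0.6
    # outcome: direction-conditional calibration mode ...
    direction_conditional: bool = True
    pcr_given_decrease: float = 0.170
    pcr_given_increase: float = 0.067
    # ... or logistic mode with planted effects
    pcr_baseline: float = 0.162
    beta_density: float = 0.0          # log-OR per log10 unit pre density
    beta_delta: float = 0.0            # log-OR per log10 unit density change
    beta_delta_x_taxane: float = 0.0   # extra delta effect when taxane second
    clinical_betas: tuple[tuple[str, float], ...] = ()
    # missingness (applied last)
    p_missing_pre: float = 0.186
    p_missing_post: float = 0.086
    p_missing_pcr: float = 0.013
    p_missing_grade: float = 0.222
    p_missing_receptors: float = 0.119
    p_missing_til: float = 0.395       # among patients with pre-treatment data

    def __post_init__(self):
        probs = [
            self.p_size_gt50, self.p_node_positive, self.p_er_positive,
            self.p_her2_positive, self.p_taxane_second, self.p_decrease,
            self.pcr_given_decrease, self.pcr_given_increase, self.pcr_baseline,
            self.p_missing_pre, self.p_missing_post, self.p_missing_pcr,
            self.p_missing_grade, self.p_missing_receptors, self.p_missing_til,
            *self.grade_probs,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        if not -1.0 < self.delta_pre_corr < 1.0:
            raise ValueError("delta_pre_corr must be in (-1, 1)")


@dataclass
class CohortTables:
    clinical: pd.DataFrame
    pre_metrics: pd.DataFrame
    post_metrics: pd.DataFrame


def _metric_block(rng, log_dens_l, cellularity, n):
    """The 15 metrics of one phase given each patient's lymphocyte log10
    median density and a latent cellularity factor."""
    # noise sds calibrated to the published pre-treatment correlations:
    # corr(median density, lymphocyte fraction) ~ 0.69 and a strong shared
    # cellularity component behind the absolute counts
    zl = (log_dens_l - np.nanmean(log_dens_l)) / (np.nanstd(log_dens_l) + 1e-12)
    frac_l = 1.0 / (1.0 + np.exp(-(-2.2 + 1.0 * zl + rng.normal(0, 0.85, n))))
    frac_l = np.clip(frac_l, 0.005, 0.8)
    v = np.clip(rng.normal(0.55, 0.12, n), 0.1, 0.9)
    frac_c = (1.0 - frac_l) * v
    frac_s = 1.0 - frac_l - frac_c

    total = np.rint(10 ** (3.3 + 0.65 * cellularity)).astype(int)
    count_l = np.rint(total * frac_l).astype(int)
    count_c = np.rint(total * frac_c).astype(int)
    count_s = np.maximum(total - count_l - count_c, 0)
    total = count_l + count_c + count_s

    def dens_triplet(med_log):
        med = 10.0 ** med_log
        lo = med * 10 ** (-np.abs(rng.normal(0.9, 0.25, n)))
        hi = med * 10 ** (np.abs(rng.normal(0.6, 0.20, n)))
        return lo, med, hi

    dmin_l, dmed_l, dmax_l = dens_triplet(log_dens_l)
    dmin_c, dmed_c, dmax_c = dens_triplet(rng.normal(3.0, 0.3, n) + 0.3 * cellularity)
    dmin_s, dmed_s, dmax_s = dens_triplet(rng.normal(2.8, 0.3, n) + 0.3 * cellularity)

    return pd.DataFrame(
        {
            "count_c": count_c, "count_s": count_s, "count_l": count_l,
            "frac_c": count_c / total, "frac_s": count_s / total, "frac_l": count_l / total,
            "dmin_c": dmin_c, "dmed_c": dmed_c, "dmax_c": dmax_c,
            "dmin_s": dmin_s, "dmed_s": dmed_s, "dmax_s": dmax_s,
            "dmin_l": dmin_l, "dmed_l": dmed_l, "dmax_l": dmax_l,
            "total_cells": total,
        }
    )


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> CohortTables:
    """Draw a full cohort: clinical table plus pre- and post-treatment
    metric tables, reproducible by seed."""
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(1, n + 1)],
            "age": np.clip(np.rint(rng.normal(spec.age_mean, spec.age_sd, n)), 25, 75),
            "tumour_size_gt50": (rng.random(n) < spec.p_size_gt50).astype(float),
            "node_positive": (rng.random(n) < spec.p_node_positive).astype(float),
            "grade": rng.choice([1.0, 2.0, 3.0], size=n, p=spec.grade_probs),
            "er_positive": (rng.random(n) < spec.p_er_positive).astype(float),
            "her2_positive": (rng.random(n) < spec.p_her2_positive).astype(float),
            "taxane_second": (rng.random(n) < spec.p_taxane_second).astype(float),
        }
    )

    # pre-treatment density and the paired change
    L = rng.normal(spec.log_density_mean, spec.log_density_sd, n)
    rho = spec.delta_pre_corr
    slope = rho * spec.delta_sd / spec.log_density_sd
    resid_sd = spec.delta_sd * math.sqrt(1.0 - rho**2)
    z_dec = -float(_norm_ppf(spec.p_decrease)) * spec.delta_sd  # mean shift so P(delta<0)=p_decrease
    delta = z_dec + slope * (L - spec.log_density_mean) + rng.normal(0, resid_sd, n)
    decrease = delta < 0

    if spec.direction_conditional:
        p = np.where(decrease, spec.pcr_given_decrease, spec.pcr_given_increase)
    else:
        logit = math.log(spec.pcr_baseline / (1.0 - spec.pcr_baseline))
        eta = (
            logit
            + spec.beta_density * (L - spec.log_density_mean)
            + spec.beta_delta * (delta - delta.mean())
            + spec.beta_delta_x_taxane * (delta - delta.mean()) * clinical["taxane_second"].to_numpy()
        )
        for name, beta in spec.clinical_betas:
            v = clinical[name].to_numpy(dtype=float)
            eta = eta + beta * (v - v.mean())
        p = 1.0 / (1.0 + np.exp(-eta))
    pcr = (rng.random(n) < p).astype(float)
    clinical["pcr"] = pcr

    # pathologist TIL category: noisy ordinal readout of the density scale
    til_score = L + rng.normal(0, 0.25, n)
    cuts = np.quantile(til_score, [1 / 3, 2 / 3])
    clinical["til_category"] = (1.0 + (til_score > cuts[0]) + (til_score > cuts[1])).astype(float)

    cellularity_pre = rng.normal(0, 1, n)
    cellularity_post = rng.normal(0, 1, n)
    pre = _metric_block(rng, L, cellularity_pre, n)
    post = _metric_block(rng, L + delta, cellularity_post, n)
    for df in (pre, post):
        df.insert(0, "id", clinical["patient_id"])
    pre.insert(1, "phase", "pre_treatment")
    post.insert(1, "phase", "surgical")

    # missingness, applied last
    miss_pre = rng.random(n) < spec.p_missing_pre
    miss_post = rng.random(n) < spec.p_missing_post
    value_cols = [c for c in pre.columns if c not in ("id", "phase")]
    pre.loc[miss_pre, value_cols] = np.nan
    post.loc[miss_post, value_cols] = np.nan
    clinical.loc[rng.random(n) < spec.p_missing_pcr, "pcr"] = np.nan
    clinical.loc[rng.random(n) < spec.p_missing_grade, "grade"] = np.nan
    miss_rec = rng.random(n) < spec.p_missing_receptors
    clinical.loc[miss_rec, ["er_positive", "her2_positive"]] = np.nan
    clinical.loc[miss_pre | (rng.random(n) < spec.p_missing_til), "til_category"] = np.nan

    return CohortTables(clinical, pre, post)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def build_analysis_table(tables: CohortTables) -> pd.DataFrame:
    """Merge the three tables into one analysis frame: clinical covariates,
    the 15 pre-treatment metrics under their plain names, and the paired
    pre/post median lymphocyte densities as pre_dmed_l / post_dmed_l."""
    pre = tables.pre_metrics.drop(columns=["phase"]).rename(columns={"id": "patient_id"})
    post = tables.post_metrics[["id", "dmed_l"]].rename(
        columns={"id": "patient_id", "dmed_l": "post_dmed_l"}
    )
    out = tables.clinical.merge(pre, on="patient_id", how="left").merge(
        post, on="patient_id", how="left"
    )
    out["pre_dmed_l"] = out["dmed_l"]
    return out
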