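# tilquant

Automated computational pathology for tumour-infiltrating lymphocytes:
from H&E histology tiles to single-cell object catalogues, cell-type
classification, spatial density metrics, and the cohort statistics that
link lymphocyte density to chemotherapy response.

## The problem

Pathological complete response (pCR) — the complete eradication of tumour
cells by neoadjuvant chemotherapy — predicts long-term outcome in breast
cancer, and the density of tumour-infiltrating lymphocytes in the
diagnostic biopsy is a leading candidate predictor of pCR.  Scoring
lymphocytic infiltration by eye is subjective and coarse.  `tilquant`
implements a fully automated alternative for researchers working with
digitised H&E slides:

1. **Tissue finding** — each image is held as a four-level pyramid
   (L0 full resolution … L3 coarse).  L3 is tiled into grid blocks and a
   pixel-intensity rule (luminance ≥ 220/255 *and* HSV saturation ≤ 0.08)
   flags white space; blocks with ≥ 25 % tissue pixels are mapped back to
   L0 rectangles for analysis.
2. **Nucleus segmentation** — tiles are unmixed into haematoxylin and
   eosin optical densities (Beer–Lambert, OD = −log₁₀((I+1)/256) projected
   onto fixed stain vectors); nuclei are connected regions of
   haematoxylin OD above a locally estimated background + 3σ, deblended by
   a watershed on the distance transform and gated on area (15–2000 px² at
   0.5 µm/px) and solidity (≥ 0.7).  Each nucleus becomes one row of an
   object catalogue: centroid, moment-equivalent ellipse and an 8-value
   nuclear feature vector.
3. **Cell classification** — an RBF-kernel support-vector machine
   (features standardised, C and γ chosen by 5-fold cross-validated grid
   search) labels each nucleus *cancer*, *stromal* or *lymphocyte*.
4. **Spatial metrics** — every cell receives a k-nearest like-class
   neighbour density: with d₍k₎ the distance (mm) to its k-th nearest
   same-class neighbour (k = 50 by default),

       D = k / (π · d₍k₎²)   [cells/mm²]

   A sample is summarised by **15 metrics**: per class the count, the
   fraction, and the min / median / max of the per-cell densities.
   Multiple slides of one patient pool their per-cell estimates; spatial
   context never crosses slides.
5. **Cohort statistics** — logistic regression of pCR (odds ratios with
   Wald 95 % CIs), a univariate screen over the 15 metrics (counts as
   log₁₀(x+1), densities as log₁₀), backward stepwise elimination,
   clinical adjustment (age, tumour size, nodes, grade as one ordinal
   term, ER, HER2), a likelihood-ratio test for taxane-sequence
   interaction, paired pre/post density-change analysis with waterfall
   ordering, rank-based group tests, Pearson correlation matrices, decile
   response tables and pathologist-score concordance.

Because no real trial data ship with the package, a first-class synthetic
module generates every input: rendered H&E-like tiles with three
morphologically distinct nucleus classes and exact ground truth, and
trial-like cohorts whose covariate marginals, paired-change proportions
and metric correlations are calibrated to published trial-level values.

## Worked example

Simulate a 765-patient cohort with an odds ratio of 4.5 per log₁₀ unit of
pre-treatment median lymphocyte density planted on pCR, run the
univariate screen and the clinically adjusted model:

```python
import math
import tilquant as tq

spec = tq.CohortSpec(n_patients=765, direction_conditional=False,
                     beta_density=math.log(4.5))
records = tq.build_analysis_table(tq.simulate_cohort(spec, seed=7))

screen = tq.univariate_metric_screen(records)
print(screen.sort_values("p").head(3).round(4))
print(tq.adjusted_model(records, "dmed_l").summary())
```

```
            or  ci_low  ci_high       p    n  p_bonferroni
metric
dmed_l  3.2419  1.9157   5.4864  0.0000  623        0.0002
dmax_l  2.4589  1.5404   3.9250  0.0002  623        0.0024
dmin_l  2.1211  1.3839   3.2512  0.0006  623        0.0084

Logistic regression (n = 438, 327 incomplete rows dropped)
log-likelihood = -191.129   converged = True
term                         OR               95% CI           p
const                    0.0164     (0.00107, 0.252)     0.00318
dmed_l                     3.58         (1.85, 6.93)    0.000158
age                       0.987        (0.953, 1.02)       0.475
tumour_size_gt50            1.1           (0.603, 2)       0.759
node_positive              1.18        (0.711, 1.97)       0.517
grade                     0.889        (0.572, 1.38)       0.603
er_positive               0.813        (0.481, 1.37)       0.441
her2_positive              1.73         (1.02, 2.92)      0.0417
```

Median lymphocyte density (`dmed_l`) tops the screen — its order-statistic
companions inherit part of the signal through correlation — and the
planted effect survives clinical adjustment (estimated OR 3.58, true 4.5,
attenuated by sampling noise and complete-case loss: only 438 of 765
simulated patients have every covariate, mirroring the attrition typical
of multicentre trials).

The image side runs the same way from a shell:

```bash
tilquant simulate tile --seed 7 --out tile.tiff --truth truth.csv
tilquant segment --input tile.tiff --out catalogue.csv
tilquant classify --model svm.bin --catalogue catalogue.csv --out labelled.csv
tilquant metrics --catalogue labelled.csv --k 50 --out metrics.csv
```

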