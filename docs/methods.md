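# Methods

## The analysis in one paragraph

All subject-level parameters — demographics, diet type, FFQ consumption
categories, medication flags and the seven fecal organic-acid
concentrations — are reduced to a common categorical scale: continuous
parameters are dichotomized at their sample median, categorical ones are
kept as-is. The resulting subjects × levels indicator table is analyzed
by correspondence analysis (CA); parameters poorly represented in the
first two dimensions are discarded iteratively until those two dimensions
explain at least half of the total inertia; level pairs with large
coordinates on the final plane are scored by a signed association weight;
and selected group contrasts are summarized by 2×2 odds-ratio statistics.

## Categorization rules

* **BMI** (kg/m²): underweight < 18.5; normal 18.5–24.99 (closed
  interval); excessive > 24.99.
* **Weight change** over six months (%): loss < −5, stable in [−5, +5],
  gain > +5 — a change of exactly 5% is "stable".
* **Fiber intake**: a gram-per-day figure, when available, dominates
  (< 25 g/day low, > 30 g/day high, else normal); otherwise low-fiber and
  easily-digestible diets count as low, a high-fiber diet as high,
  standard and unclassified diets as normal. The fiber class is a
  deterministic function of diet type when no numeric intake is supplied,
  i.e. perfectly collinear with it — the default parameter list therefore
  carries `diet_type` only; add `fiber` via configuration when a numeric
  intake source exists.
* **Detection limits**: LOQ 26 µg/g dry mass (equivalently 7.8 µg/mL in
  a 1 mL extract of a 0.3 g dried sample — the extract volume is not an
  assay constant and is configurable); LOD = LOQ/3. Values between LOD
  and LOQ are flagged but retained; values under the LOD are replaced by
  LOD/2, the standard non-detect substitution in analytical chemistry.
  Censoring is **off** in the default pipeline: valeric acid's typical
  median (≈5.5 µg/g) lies below the LOD, so forcing the substitution
  would collapse its median split; raw values are used for all splits,
  and `censor_concentration` is applied only when configured.

## Median dichotomization

The split uses the ordinary sample median (mean of the middle two for
even n). Ties at the median go to "under", so the "above" group is
strictly above; the rule is configurable (`tie_rule="above"`). A subject
missing a parameter contributes all-zero indicator cells for it (reduced
row mass) rather than an imputed level.

## Correspondence analysis

Textbook CA of the indicator table: standardized residuals
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, SVD S = UΣVᵀ, principal inertias
λ_k = σ_k², total inertia = χ²/n, principal coordinates
F = D_r^{-1/2}UΣ (rows), G = D_c^{-1/2}VΣ (columns). Levels' squared
χ²-distances to the centroid are computed from the profiles directly, so
the cos² decomposition summing to 1 over all dimensions is a genuine
test, not an identity of the implementation.

Numerical conventions:

* singular values below 10⁻¹² (relative to the largest) are treated as
  numerical rank deficiency and dropped; an exactly independent table
  yields a model with zero total inertia, for which "inertia explained"
  is defined as 1;
* the sign of each singular-vector pair is fixed by making the
  largest-magnitude column loading positive, so coordinates are
  bit-reproducible across runs and LAPACK builds;
* a level at the centroid (distance² ≤ 10⁻¹²) has cos² defined as 0 and
  is flagged;
* algebraic identities are tested at 10⁻¹⁰ on exact counts, transition
  formulas at 10⁻⁸.

The Burt table (cross-product of the indicator matrix) is available as an
alternative CA input. Both diagonalize the same operator: standard
coordinates agree and Burt singular values are the squares of the
indicator ones (asserted in the test suite).

### Which "percent of inertia"?

Raw indicator-matrix inertia percentages are pessimistic — with Q
parameters the leading dimension rarely exceeds a small multiple of 1/Q —
and classic MCA software instead reports percentages on the Burt scale,
where the inertias square and concentrate. `inertia_explained` exposes
both (`scale="raw"`/`"burt"`), and the pruning loop accepts a
`fraction_scale` argument. The default is the raw ratio: with a
two-dimensional stopping rule it prunes aggressively, which is what gives
the pruning step discriminating power on cohorts of this size (see the
recovery experiment below). On real, pervasively correlated cohort data
the Burt-scale fraction reaches 50% with little or no pruning — the
regime in which a final map can retain nearly all parameters.

## Parameter pruning

A parameter's quality of representation is the column-mass-weighted mean
of its levels' cos² over dimensions 1–2 (mass-weighting matches the
geometry CA itself uses for column points); `aggregate="max"` scores a
parameter by its best-represented level instead, which protects skewed
multi-level parameters whose majority level sits near the centroid. One
parameter is discarded per iteration; quality ties discard the later
parameter in configuration order (deterministic). The loop stops when the
two-dimensional fraction reaches the threshold (default 0.5) or when
`min_params` (default 4 — below that a two-dimensional map is degenerate)
parameters remain, in which case the trace is flagged "threshold unmet"
rather than raising.

## Association weights

Levels qualify when the **maximum** of their two absolute plane
coordinates exceeds 0.3 (strict, per-dimension — not the vector norm).
For qualifying levels of *different* parameters the weight is the planar
dot product w = ‖p_A‖‖p_B‖cos θ; pairs of levels of the same parameter
are excluded because their opposition is an artifact of one-level-per-
subject coding. The dot-product reading is used because it is the only
simple combination of coordinate magnitudes and the angle cosine that is
(a) negative for inversely related levels and (b) on the ~0.3–1.4
magnitude scale that principal coordinates of binary levels produce. The
alternative reading — the coordinate products scaled once more by cos θ —
is available behind `formula="product_cos"`. Weights use dimensions 1–2
only (the plotted plane), not the full space.

## 2×2 statistics

Odds ratio (a·d)/(b·c); Woolf CI exp(ln OR ± z·√Σ1/cell) with
z = Φ⁻¹(0.975) ≈ 1.959964; Fisher's exact two-sided p under the
minimum-likelihood convention (the tail-doubling convention is an
option); the Woolf z-test p is reported alongside for transparency. A
zero cell triggers the Haldane–Anscombe correction (+0.5 to every cell),
flagged in the result. `recover_table` scans all integer tables with
given row margins and positive cells for those whose OR and CI match
printed values at three decimals — the route by which unprinted published
tables are reconstructed; printed statistics that match *no* integer
table (possible under questionnaire item non-response) are reported as
non-recoverable rather than approximated.

## The synthetic cohort generator

The generator emulates the study's structure, not any real cohort's joint
distribution:

| parameter | default | rationale |
|---|---|---|
| group sizes | 43 / 18 / 16 (UC/CD/control) | study design |
| BMI | log-normal, medians 21.6/20.2/21.6, log-sd 0.25, clipped to [13.8, 37.1] | reproduces the published per-group medians and the 13.8–37.1 kg/m² extremes at n = 77 |
| age | log-normal, medians 32/30/23.5, log-sd 0.30, ≥ 18 | published medians; adult cohort |
| acid panels | log-normal, medians 1135.3 / 381.2 / 215.0 / 43.0 / 5.52 / 46.3 / 837.6 µg/g (acetic…phosphoric), log-sd 0.3, independent across acids | published medians; spread idealized (below) |
| planted effects | underweight ×0.5 on butyric, propionic, isovaleric; excessive ×2.0 on isobutyric | the qualitative association pattern under study |
| medications | group-wise Bernoulli at the published treatment frequencies; underweight raises steroid (0.75) and antibiotic (0.60) probability in IBD patients only | treatment intensity tracks disease severity |
| diet / FFQ | group-wise categorical marginals; every level has expected count ≥ ~8 or exactly 0 | near-empty indicator columns (1–3 subjects) dominate a CA map through their χ²-distances and are unidentifiable at n = 77, so the design avoids them |

**Median calibration.** Because the analysis is median-split-based,
medians (not means) are calibrated: each acid's baseline log-median is
set by a 1-D root find so that its *marginal* median — after mixing the
planted effects over the analytically computed BMI-category probabilities
— equals the configured target. Without this the ×0.5 plants would drag
the butyric marginal median ~10% under its target.

**Deliberate idealizations.** Two features of real fecal panels are
intentionally absent from the defaults, and both matter for interpreting
what passing tests show:

1. *Spread.* The default per-acid log-sd of 0.3 (CV ≈ 31%) is tighter
   than typical between-subject spreads (log-sd 0.5–1). It is chosen so
   that planted effects of the configured magnitude separate cleanly
   from sampling noise at n = 77, making recovery a sharp test of the
   pipeline rather than of the sample size.
2. *Inter-acid correlation.* Real panels are strongly correlated across
   acids (shared fermentation drivers); `acid_shared_log_sd` adds a
   subject-level common factor to emulate this, but defaults to 0. With
   a dominant common axis, the two-dimensional pruning loop can neither
   place both category-specific planted axes in the leading plane nor
   discard the (then genuinely associated) acid parameters under the
   null — recovery of *which* acids respond to *which* BMI category is
   then not identifiable from a two-dimensional map. Passing recovery
   tests therefore demonstrate correctness of the machinery under
   separable structure, not power on maximally realistic data.

**Determinism.** One `numpy` PCG64 generator seeded from the spec (or an
override) drives all draws in a fixed per-subject order, so a seed fully
determines the cohort across platforms.

## The recovery experiments

* *Pruning*: tables of 2 strongly associated binary parameters (latent
  fair coin copied with 10% flip probability) plus 10 independent fair
  coins, n = 77. Across seeds, the loop should discard only noise
  parameters and end with the two-dimensional fraction above 0.5.
* *End-to-end*: default cohorts (n = 77), 200 seeds. All four planted
  BMI–acid pairs should be reported with positive weight in ≥ 90% of
  seeds; under the null plant (all factors 1) each pair should appear in
  ≤ 20% (observed: ≤ 7%).

Problem sizes throughout (cohorts of 77, hundreds of replicate seeds,
random tables of side 2–6) keep the full test suite and the acceptance
script at about a minute each on one CPU.

## Known limitations

* The pruning loop is greedy; it does not revisit discards and offers no
  optimality guarantee over parameter subsets.
* Association weights carry no significance assessment.
* Whole parameters, not individual levels, are discarded.
* The generator's categorical dependencies are single conditional-
  probability tweaks, not a graphical model; it does not attempt the
  original cohort's unpublished joint distribution.
* No supplementary points, inertia corrections (Benzécri/Greenacre), or
  bootstrap confidence regions in the CA.
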