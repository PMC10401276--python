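# Methods

## Screening model

The screen treats yield prediction as a per-flight, per-index univariate
problem. For flight *t* and index *V*, the sample Pearson correlation
r(V_t, y) is computed across the season's subplots (n = 16 by default),
pairwise-complete over missing cells. The flight score is
1{|r| ≥ τ}, τ = 0.7 — the conventional cut-off for a "strong" correlation.
p-values from the t transform (n − 2 df, two-sided) are always reported but
never used for selection; at n = 16 the τ = 0.7 rule is close to, but not
identical with, a p < 0.005 rule, and keeping selection purely
threshold-based makes the screen deterministic and reproducible.

A VI is *stable within a season* when its cumulative score over the
season's flights reaches `min_count = 2`. Tiers (dense rank of distinct
cumulative scores, top 3 reported) are emitted alongside, so a stricter
"top tiers only" reading of the procedure can be applied downstream without
recomputation. Ties share a tier and are ordered alphabetically — a pure
determinism device, no scientific meaning.

The three seasonal stable sets are partitioned into the 7 disjoint Venn
regions; the triple intersection is the season-robust set carried into the
regression stage. `venn_partition` demands exactly three sets: the
cross-season logic is genuinely ternary here (unique / shared-by-two /
core), and generalizing it was deliberately deferred.

## Yield models and model comparison

Per (year, stage, VI): OLS of yield on the VI, R² = 1 − SSE/SST, MAPE in
percent, slope t-test with the usual star convention. Winners within a
stage are ranked by R² descending with ties broken by lower MAPE then name;
no formal MAPE-difference test is attempted — with n = 16 such a test has
essentially no power, so the deterministic rank rule is used and both
metrics are always emitted for downstream re-ranking.

Treatment comparisons use a fixed-effects RCBD ANOVA (treatment + block)
and Fisher's LSD = t(1 − α/2, df_e)·√(2·MSE/r) with a compact letter
display built from maximal runs of the descending means whose span is
below the LSD. The split-plot error strata are ignored because only one
cash crop is analyzed; with a whole-plot factor present the MSE here would
be anti-conservative. All observations identical is handled as a special
case (single letter, no t quantile).

## Random-forest ranking

The forest is a *ranker*, never the yield model. Per flight: randomized
search (default 100 candidate sets, 5-fold CV, R² scoring, bootstrap on)
over trees ∈ [100, 1000], min-split ∈ [2, 10], min-leaf ∈ [1, 5],
max-features ∈ {all, √p}; refit on all rows; permutation importance =
mean R² drop over 10 seeded shuffles per column, computed on the training
rows (no held-out set exists at n = 16). Ranking ties break alphabetically.
Rows with any missing VI are dropped per flight (tree ensembles need
complete rows); flights with fewer complete rows than CV folds are skipped
with a warning rather than fitted degenerately.

The CV scoring metric (R²) was an open choice; it matches the metric the
regression stage reports. Search-space bounds are config defaults, not
tuned values. The `analysis/03_rf_rank.py` driver defaults to 10 candidate
draws per flight purely as a convenience scale; the full protocol (100)
is one argument away and changes nothing qualitative at n = 16.

## Imagery path

Calibration is the one-point linear panel model: reflectance =
DN·(ρ_panel/DN_panel), clipped to [0, 1] — adequate when the sensor is
linear and dark current is negligible, which is the regime the calibration
tile workflow assumes. The background classifier is a linear
maximum-margin model (LinearSVC on standardized bands) behind a pluggable
fit/predict contract; the original workflow used an SVM with unstated
kernel and parameters, so the family is a contract, not a claim. Holdout
accuracy is reported from a stratified 20 % split and refers to exactly
the returned model. Pixel-in-polygon is pixel-center containment:
deterministic, unambiguous at plot scale (~4 cm pixels vs ~3.6 m plot
sides). Zonal means run over in-polygon pixels classified as the keep
class; the canopy fraction (kept/total) is reported per plot — it doubles
as the "soil cover" style structural predictor (1 − canopy fraction is the
soil fraction; both are derivable from the one number, which is labelled
canopy_fraction everywhere).

Scene I/O is plain 5-band TIFF with a JSON description tag (pixel size,
origin, units flag); polygons are GeoJSON FeatureCollections with a
`plot_id` property; labels are (x, y, class) CSV. Coordinates are
scene-local metric, origin top-left, no CRS — inputs are assumed already
stitched and registered, and mosaicking/geo-rectification are out of scope.

## Index registry

31 indices are built in. Formulas are declared as expression strings over
{B, G, R, RE, NIR} and compiled by a safe arithmetic grammar
(+ − × ÷ ** sqrt, numbers, named constants); user configs (YAML/JSON)
extend the registry through the same path. Narrowband literature
wavelengths map to sensor bands through one fixed table
(445→blue, 705/717→rededge, 750/800/842→nir, …); anything unmapped is a
configuration error, never a silent nearest-neighbour guess. Constants are
the canonical published ones (SAVI L = 0.5, OSAVI 0.16, WDRVI α = 0.2,
EVI 2.5/6/7.5/1). On a five-band sensor RIgreen and CIgreen collapse to
the same expression (NIR/G − 1); both names are kept because both
circulate in the literature. Zero denominators yield NaN ("missing"),
excluded pairwise downstream — no imputation anywhere.

Note one algebraic caveat: mND705 = (NIR − RE)/(NIR + RE − 2B) is bounded
in [−1, 1] only in the physical regime B ≤ min(RE, NIR); outside it
(non-vegetation spectra) the denominator can vanish. The tests assert the
bound in that regime and missingness outside it.

## Synthetic experiment generator

The generator emulates the design, not the radiometry, of a three-year
cover-crop trial:

* **Design**: 4 treatments × 4 blocks, 3 seasons, 7 flights per season at
  DAP 35/46/55/67/83/95/115 (V5, V7, V10, Vn, R1, R3, R5). The flight DAPs
  anchor on the mid-season values reported for the field campaign (Vn ≈ 67,
  R1 ≈ 80, R5 ≈ 110–120 DAP) and fill the rest of a weekly-ish schedule.
* **Latent vigor**: v = 0.55 + year shift (0, −0.06, +0.03) + treatment
  effect (+0.10 winter pea, −0.06 radish/mix, −0.08 rye, +0.04 no-cover)
  + block N(0, 0.03) + plot N(0, 0.05), clipped to [0, 1]. Effects sum to
  zero; their spread (σ ≈ 0.07) is the main driver of between-plot
  variance.
* **Yield link**: y = 2.0 + 12.0·v + N(0, 0.30) Mg/ha, giving season means
  of ~7.5–9.5 Mg/ha and cor(v, y) ≈ 0.96. These values were calibrated
  once so that the planted chlorophyll indices reach |r| ≥ 0.7 at R1 in
  ≥ 90 % of replicates at n = 16 — i.e. the generator encodes the study
  conditions the screen is specified against — and were fixed thereafter.
* **Reflectance**: ρ_band = (1 − c)·soil + c·leaf(chl, v) + N(0, 0.004),
  clipped to [0, 1]. Canopy cover c(t) is a logistic in DAP (midpoint 45,
  scale 8) rising to a plateau 0.55 + 0.40·v; the chlorophyll proxy
  chl(t) = v·g(t) with g Gaussian in DAP (peak 87, width 26), so chl peaks
  between R1 and R3. Leaf visible reflectance decays exponentially in chl
  (fastest in red), the red edge decays mildly, NIR increases linearly in
  v. This is the simplest generator producing the qualitative crop
  spectrum (dark visible, sharp red edge, bright NIR) and the R1 peak in
  index–yield correlation; it is *not* radiative transfer (no PROSAIL, no
  BRDF, no atmosphere) and makes no claim to spectral realism.
* **Scenes**: 16 square plots (default 90 px a side, 4 cm pixels) on a
  4 × 4 grid with soil alleys; in-plot pixels are corn (the plot's
  five-band mean + N(0, 0.012)) in a canopy-fraction share, the remainder
  and alleys soil, with 2 % of all pixels converted to weed patches —
  enough to sample 5,000 labelled pixels per class on the default scene.

A single latent factor drives everything, which has an important
consequence for interpreting tests: in the synthetic world *most* indices
correlate with yield once the canopy closes (the 02 driver finds ~30 of 31
stable per season), so passing tests demonstrate that the machinery —
screening arithmetic, stability accounting, set algebra, ranking, fitting —
is correct and that planted signal is recovered and null signal rejected;
they do not demonstrate the real-data discrimination between index
families, which depends on multi-factor field variation the generator does
not model. The null scenario (yield slope b = 0) provides the negative
control: the false-stability rate of a fixed VI is < 10 % (empirically
~0.5 %) per season-replicate.

## Problem sizes and numerical choices

Replicated checks run at the design's own scale (16 plots/season): 100
replicate experiments for screen recovery and the V5→R1 contrast, ~200
season-replicates for the null rate, 200 noise draws for (a, b) recovery,
20 seeded runs for forest-ranking recovery; formula and OLS oracles use
1,000 random inputs at 1e−12/1e−10 tolerances. All randomness flows from
`numpy.random.default_rng` seeded explicitly; scikit-learn objects receive
derived integer seeds, so the full pipeline is bit-for-bit reproducible
given (config, seed).

Known limitations: no spatial autocorrelation between plots; no
multiple-testing control across the VI × flight grid (deliberately, to
match the screening procedure as defined); single-sensor band mapping
table; LSD ignores split-plot strata; MAPE is undefined for non-positive
observations and is reported missing there (yields are always positive).
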