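# Methods

## The analysis model

A cell-painting screen produces, per imaging site, a cell count and a
vector of morphological features. The analysis treats the DMSO vehicle
wells as the null phenotype and expresses every compound as a robust
Z-score vector against it.

**Aggregation.** Feature values are aggregated as medians per well
(sites → well), then as medians over the replicate plates. Replicates
are matched by (compound, concentration) label, never by well
coordinate, because replicate layouts are cyclically shifted to
decorrelate compound position from plate effects. Missing values are
ignored within each median; a well whose feature is missing at every
site stays missing and is logged. Vehicle wells are an exception in the
replicate-aggregation step: they keep their (fixed) positions and are
aggregated per well rather than collapsed into a single DMSO profile,
because the spread *across* vehicle wells is what calibrates the
Z-score; collapsing them would leave no dispersion estimate.

**Z-scores.** For feature *f*, z_f = (x_f − median_DMSO,f) / s_DMSO,f.
The dispersion s is 1.4826 × MAD of the aggregated vehicle wells by
default — the assay literature says only "relative to the median of
DMSO controls", and a median centre pairs naturally with a robust
scale — with plain SD available via `scale_method="sd"`. Features with
zero or undefined DMSO dispersion are excluded (never given infinite
z) and logged. At least 3 vehicle profiles are required; in practice the
accuracy of the MAD is the binding constraint on null calibration (see
Limitations).

**Induction and activity.** Induction = 100 × |{f : |z_f| ≥ τ}| / F
over the F selected features. The significance threshold τ is not
specified in the assay literature we follow; τ = 3.0 (conventional for
robust Z in morphological profiling) is the default and is surfaced in
every interface and output. The activity call is strict: active ⇔
induction > 5%.

**Biosimilarity.** 100 × max(0, 1 − CD) with CD the Pearson
correlation distance (`scipy.spatial.distance.correlation`); negative
correlations clip to 0. Constant profiles have undefined correlation
and propagate as missing values with a warning — never as 0 or 100.
Cross-biosimilarity matrices are computed among fingerprints with
induction > 30% (flag-controlled); fingerprints themselves are always
computed, with activity stored as metadata rather than used to suppress
profiles.

**Robust feature selection.** Given well profiles of two biological
repeats of one reference plate, each feature's across-well value vector
is compared between repeats; the feature is kept when similarity ≥ 0.8.
"Similarity" is deliberately the same clipped-correlation measure as
biosimilarity, so one notion runs through the package. Selection runs
on raw well medians (it precedes normalization in the workflow) and
happens once per screen. Whether the original procedure Z-scored the
well vectors first is not documented; correlation is invariant to
per-feature affine rescaling, so the choice only matters through well
weighting, and raw medians are the simpler reading.

**Region partition.** Fingerprint positions are partitioned into
cell (1–229), cytoplasm (230–461) and nuclei (462–579) blocks for the
canonical 579-feature set; other fingerprint lengths are partitioned
proportionally so region summaries stay meaningful on simulated screens.

**Subprofile matching.** A cluster subprofile is the elementwise median
of member z-vectors restricted to the cluster's dominant features; a
test fingerprint is compared by biosimilarity on that restricted set,
with assignment above 85%. How dominant features were derived for the
published clusters is prior work consumed as data: the library is a
file artifact (manifest + member tables). The shipped 13-cluster
library generator is synthetic — it borrows the canonical cluster names
so reports read naturally, and claims no equivalence to the real
clusters.

**qPCR.** ΔCt per sample = Ct(target) − arithmetic mean Ct of the
reference genes. ΔΔCt subtracts the *mean* ΔCt of the control group
(per-sample pairing is not well defined when treatment and control
sample counts differ, and group-mean normalization matches "normalizing
to the vehicle control"); relative expression is 2^−ΔΔCt. Group
summaries use geometric mean and geometric SD, the natural scale for a
quantity that is lognormal under Gaussian Ct noise. Hypothesis tests
run on ΔCt: one-way ANOVA, then Dunnett many-to-one comparisons versus
control computed from the multivariate-t formulation
(`scipy.stats.dunnett`); the degenerate all-identical case returns
F = 0 and adjusted p = 1 explicitly.

## The simulator

The generator emulates the study design — 384 wells, 9 sites/well,
triplicate plates with shifted layouts, 1716 features — with a null
model of independent Gaussians per feature, location ~ N(10, 3) and
scale ~ lognormal(0, 0.4) drawn once per screen (heterogeneous scales
exercise robust normalization). Plate effects are additive per
(plate, feature) with SD 0.5 in feature-scale units, matching the
purpose of shifted layouts. Treated wells shift by
effect × concentration-multiplier × feature scale on the signature's
features; effect sizes are therefore in units of the per-site robust SD
(site_noise_sd = 1 by default). Cell counts are a separate integer
column, N(180, 15) per site, scaled down by a per-compound toxicity
fraction. A configurable fraction of features can be made
irreproducible by adding large per-(plate, well) offsets, which destroys
replicate correlation without changing marginal scales.

Plates carry three well roles: evenly spaced DMSO vehicle wells (10% of
the plate), reference wells, and treatment wells (unassigned wells are
filled with named inert compounds, giving every screen a built-in null
cohort). The 32 reference compounds receive random signatures covering
40% of features with effects ~ N(0, 6); they model the annotated
reference plate such screens include and are what give per-feature well
profiles enough structure for replicate-based feature selection — on a
plate of nulls there is nothing to correlate, and selection would
rightly return nothing.

What the simulator does **not** model: spatial (row/column/edge)
gradients, cross-feature correlation, non-Gaussian feature noise
(the empirical noise distribution of real features is uncharacterized;
Gaussian is an explicit assumption), site-level segmentation failures,
and concentration–response curves beyond a per-concentration
multiplier. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under the stated model, not that real
screens satisfy that model.

## Validation studies and problem sizes

`morphoprint.benchmarks` packages the repeated-seed studies used by the
test suite and the acceptance script. Monte-Carlo replication is run on
screens scaled below the full 384 × 1716 geometry (which remains the
generator default): null calibration uses 50 screens of 384 wells × 300
features; signature recovery uses 100 screens of 192 wells × 250
features with effect 5 on 20% of features; feature-retention rates use
96-well replicate pairs with programmed correlations 0.95 / 0; cluster
assignment uses 100 trials at 579 features with noise at 0.2 × signal
SD. These sizes are the package's standard study conditions; noise
defaults are never changed between studies. Sub-seeds derive from the
user seed as (seed × 10007 + i) mod 2³¹−1.

## Numerical choices and degenerate inputs

- Median/MAD computations delegate to pandas/numpy; no interpolation
  tweaks.
- Constant vectors: rejected (selection), missing (biosimilarity),
  error (induction on an empty set). Exact `ptp == 0` is used to detect
  constancy, immune to mean-subtraction round-off.
- top-changed ties at equal |z| break by feature position ascending
  (stable sort).
- Well labels are letter–number (A01…P24); simulated replicate pairs
  beyond 384 wells fall back to generic labels.
- All simulation randomness flows through `numpy.random.default_rng`
  seeded from the config; equal seeds give byte-identical outputs.

## Known limitations

- Null-calibration quality depends on the vehicle-well count: with only
  ~10 DMSO wells the MAD estimate is noisy enough to inflate the |z| ≥ 3
  tail to a few percent per feature. At the default 384-well geometry
  (38 vehicle wells) median null induction is ~1%.
- The full assay-scale feature count (1716) is supported but the validation
  studies run on a few hundred features for speed; the statistics scale
  with feature count only through induction granularity.
- The cluster library format stores dominant features by name; it does
  not validate that member profiles came from the same screen
  normalization.
- Dunnett p-values use numerical multivariate-t integration; equality
  with other implementations holds to ~1e-3, not machine precision.
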