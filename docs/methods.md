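# Methods

## Growth model and fitting

OD curves are fitted on the raw (not log-transformed) scale with the modified
Gompertz form, parameterized so the quantities of interest are direct
parameters:

    od(t) = y0 + A * exp(-exp((mu_m * e / A) * (lambda - t) + 1))

- `y0` — baseline OD (dimensionless absorbance), bounded >= 0;
- `A` — asymptotic OD rise above baseline, bounded >= 0;
- `mu_m` — maximum growth rate in OD/h (the slope at the inflection point);
- `lambda` — lag time in h, bounded >= 0.

Time is hours everywhere. Fitting is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, xtol/ftol/gtol
1e-12). Initialization: `A0` = curve range; `mu0` = steepest finite-difference
slope of the 5-point median-filtered curve; `lambda0` = first time the curve
exceeds min + 0.1×range; up to five starts jitter `(mu0, lambda0)` by factors
0.5 and 2, stopping early when a start reaches an SSE within 1e-4 of nothing
left to explain. A curve is a **non-grower** when the fitted `A` < 0.05 OD or
the Gompertz SSE is no better than a flat (mean) fit; non-growers report
`mu_m = 0`. The reported maximum growth rate is the fitted `mu_m` parameter
itself (for this model it equals the post-fit numerical maximum slope, a
tested identity).

Identifiability caveat: with 13-min sampling, curves combining a small rise
(`A` ≈ 0.2 OD) with a fast rate put the whole exponential phase inside one or
two sampling intervals. With 0.01 OD measurement noise the least-squares
estimate of `mu_m` for such curves can deviate more than 5% even at its global
optimum — the acceptance suite measures this directly (roughly 86–88% of
random curves within 5% under those conditions, 100% within 0.5% without
noise). This is a property of the sampling design, not of the optimizer; the
corresponding check is reported as measured.

## Quality control

- **Contamination**: onset is the first time OD exceeds the baseline-window
  (first 1 h) mean + max(0.05 OD, 5×SD); a strain is discarded when any
  sterile control of the same condition shows an onset and the strain's
  earliest onset is not strictly earlier. All-flat controls never discard.
  The 0.05 OD floor makes the rule conservative under read noise.
- **Replicate selection**: of the quadruplicate, the three retained replicates
  are the subset minimizing the sum of pairwise Euclidean distances between
  OD vectors, found by exhaustive enumeration of all C(n,3) subsets; ties
  resolve to the lexicographically smallest index set. This single mechanism
  implements "best 3 of 4".
- **Metrics**: max growth rate is the mean fitted `mu_m` over retained
  replicates; max OD is the mean over replicates of the maximum of the
  5-point median-filtered, blank-corrected curve (the filter suppresses
  single-read spikes). Normalization divides each metric by the strain's
  maximum across all its conditions, so the best condition scores 1; a strain
  growing nowhere is flagged rather than divided by zero.

## BCECF pH inference

The calibration curve is monotone piecewise-linear interpolation between the
measured (pH, ratio) knots — chosen over a parametric dye-response form
because it is invertible by construction and has no fitting hyperparameters.
Background is subtracted per timepoint from the matched dye-free sister well
(same strain and condition); gaps in the sister series fall back to its time
mean. Ratios with non-positive denominators are flagged missing, not raised.
Ratios outside the knot hull clamp to the boundary pH and carry an
out-of-range flag: extrapolating pH from a two-point calibration tail is less
defensible than an explicit flag. No spectral cross-talk or photobleaching
correction is applied.

## Featurization

Counts are over annotation table rows, not distinct PATRIC IDs: a protein
contributing two role rows counts twice for its subsystem. Values are matched
verbatim after trimming outer whitespace (the export is a controlled
vocabulary). Feature names are exactly `"<Column> = <value>"`; count and
indicator blocks are concatenated over the union of genomes with zero fill,
columns sorted for determinism, and a name collision between blocks is a hard
error. Genomes with any missing output on an axis are removed listwise from
that axis's model dataset (and listed with reasons), so the pH and osmolality
datasets can differ in size. The representation is dense; at this scale
(~10^2 genomes × ~10^4 features) sparsity optimization buys nothing.

## Decision-stump ranking

The stump threshold is chosen among midpoints of consecutive distinct sorted
feature values; the loss is the unweighted sum of squared deviations from the
leaf means over both leaves, all rows, and all four outputs (the outputs
share the normalized [0,1] scale, so no per-output reweighting). Rows with
value < threshold go left; values equal to the threshold go right. Ties in
loss resolve to the smallest threshold. A constant feature yields a
degenerate single-leaf stump predicting the grand mean. The production path
is a vectorized scan over all features at once (cumulative-sum identities);
its equivalence to the per-feature fit, and the per-feature fit's exact
agreement with brute-force enumeration, are both tested.

Cross-validation uses one shuffled K-fold partition (K = 5, explicit seed,
default 0) shared by **all** features — required for fold means to be
comparable across features. Errors are stored as squared error per row so
unequal fold sizes do not bias fold means. Features are ranked ascending by
mean train error and mean test error (ties share the minimum rank);
`worst_rank = max(train_rank, test_rank)`; the final ordering breaks ties by
test rank then feature name. Degenerate-in-fold features are retained with
grand-mean predictions rather than dropped. The threshold exported for binary
partitions is the arithmetic mean of the non-degenerate fold thresholds
(undefined, with a flag, if every fold is degenerate).

## Community correlations

Counts are converted to per-sample proportions (all-zero samples are an
error), taxa collapse to families via a lineage map tolerant of
`f__Family`-style rank prefixes (unmapped taxa pool under "Unassigned";
aggregation conserves each sample's total), and each family's proportion is
correlated with the numeric condition value by Pearson r, pooling all donors'
samples. Zeros are real observations — a family undetected in a sample enters
as 0, since sparsity across donors is part of the signal. Zero-variance
families are flagged undefined rather than producing NaN surprises. Headline
output is r only; a per-donor breakdown is emitted as a diagnostic. No
multiple-testing correction or compositional transform is applied.

## Synthetic data

The generators define the study conditions the tests run under:

- **Plate runs**: 13-min sampling; eight conditions (pH 4, 5.5, 6.9, 8;
  ~440, 890, 1176, 1800 mOsm/kg); quadruplicates with three BCECF wells and
  one dye-free sister. OD noise defaults to 0.005 OD — a fixture choice for a
  quiet modern reader, not a measured value. Fluorescence is background
  (constant per channel) plus, for dye wells, a pH-dependent 490 nm signal
  through the calibration, so the inference round trip is exact by
  construction in the noiseless case; pH trajectories outside the calibration
  range are refused to keep the simulation invertible. Contamination injected
  into sterile wells rises on a 0.5 h saturating scale so the onset is
  sharply defined.
- **Genotype–phenotype**: planted features give carriers 1–3 annotation rows
  of a named value; noise features get random carrier fractions (0.1–0.9) and
  counts independent of phenotype; outputs are baseline 0.4 + carried effects
  + Gaussian noise (SD 0.05), clipped to [0,1] to match the normalized-OD
  scale. The default recovery experiment uses 80 genomes and 500 noise
  features — the real table's shape (81 × 11,514) at reduced width, since the
  live annotation service's output cannot be regenerated offline.
- **Communities**: expected family abundance is baseline + slope × condition,
  floored at a tiny positive value, perturbed logistic-normally (multiplied
  by exp N(0, dispersion)) and renormalized per sample — compositions stay
  valid while planted correlations survive. Defaults: 6 donors, the
  eight-level fermentation osmolality gradient (472–1824 mOsm/kg),
  dispersion 0.35.

All randomness flows from one integer seed per spec through
`numpy.random.SeedSequence` spawning; there is no global RNG state, which is
what makes the end-to-end run byte-reproducible.

What passing on synthetic data does **not** show: real plates have drifting
baselines, condensation spikes, dye bleaching and well-to-well optical
variation; real annotation tables have correlated features (co-occurring
subsystems) that make "the" causal feature ambiguous; real communities
interact (competition, cross-feeding) rather than responding independently
and linearly. The generators deliberately omit these so that failures
indicate implementation defects rather than model misspecification.

## Problem sizes

The bundled analysis runs 6 strains × 8 conditions × 4 replicates (plus
sterile controls) over 24 h of simulated sampling, ranks ~600 features over
40–80 genomes, and correlates 6 families across 48 fermentation samples; the
acceptance script uses 200 random curves, 100 stump instances, and 100
ranking simulations per arm. These sizes were chosen so the full chain runs
in about a minute on one core while keeping every statistical check
well-powered.
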