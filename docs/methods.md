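# Methods

`hepazone` implements the downstream analysis of spatial single-cell
proteomics of the liver lobule: quantification of multiplexed-DIA
single-shape proteomes against a reference channel, statistics of
protein zonation along the portal-to-central axis, and an image-feature
model that predicts proteome classes and reconstructs spatial proteomes.
A synthetic zonated-lobule generator supplies ground-truth data with the
statistical structure those analyses assume.  This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Quantification model

**Reference-ratio estimation.** Each run carries a dimethyl-labelled
bulk reference proteome (Δ0) and two labelled single-shape samples
(Δ4, Δ8).  For every precursor in a run, each fragment index with
positive intensity in both target and reference yields one
target/reference ratio; the MS1 areas, when both positive, contribute
one more.  The precursor ratio is the exponentiated median of the
log-ratios.  The published reference-ratio method selects among ratio
candidates with a more elaborate rule; the median was chosen here for
robustness and testability and the estimator is a single function that
can be swapped.  Whether MS1 is pooled with the fragments is
flag-switchable (`include_ms1`, pooled by default).

**Rescaling.** A unitless ratio becomes an intensity by multiplying
with the median reference intensity of that precursor over all runs.
The per-run reference scalar is the sum of the reference fragment
intensities plus the MS1 area — one defensible scalar per run.

**Protein collapse (MaxLFQ).** Per protein, sample log2 abundances
x_s minimise Σ_{s<t} (x_s − x_t − m_st)² where m_st is the median over
shared precursors of per-precursor log-ratios.  The implementation
solves the normal equations of this objective (a graph Laplacian over
samples sharing precursors), which is algebraically identical to the
stacked pairwise system but scales to hundreds of samples; the test
suite certifies equality with a dense brute-force least-squares solve to
1e-9 on small instances.  The free additive constant per connected
component is fixed so the mean of x equals the mean log2 summed
precursor intensity over that component's samples — an absolute
anchoring in the spirit of the `iq` implementation, needed because no
cross-sample median normalisation is applied at this stage.
Disconnected components are anchored independently and logged.  Zero or
absent intensities are treated as missing throughout, never as 0.

**Report filtering.** Rows must satisfy Lib.PG.Q.Value < 0.01,
Q.Value < 0.01 and Channel.Q.Value < 0.15, all strict.

## Sample QC and normalisation

Samples are excluded when their protein-identification count falls
below median − 1.5·sd or above median + 3·sd (sd is the ordinary
standard deviation of the counts; bounds are centred on the median),
when the contour area lies outside the 135–1350 µm² segmentation
gates (inclusive), or when they are robust-z outliers (default 5 MAD
units) on PC1/PC2.  An absolute identification-count window is
available as optional configuration but is off by default: the printed
interval in the source protocol describes the realised kept range on
that study's data, not an independent rule — applied literally it would
exclude nearly everything.

Median normalisation uses the set of proteins quantified in 100% of
retained samples; each sample is shifted in log space so its median
over that set equals the global median.  When no protein is complete —
common for small cohorts — a configured completeness fallback (default
0.95) relaxes the set definition; samples observing none of the set are
left unshifted, with a warning.

**A caveat worth knowing.** The complete set is dominated by abundant
proteins and, in a small panel, its per-sample median can carry a
residual position-dependent component in addition to the intended size
effect.  On simulated data with 200 proteins this residual zonation of
the offsets is detected by the ANOVA in essentially every protein,
inflating the zonated fraction well above the constructed 40%.  The
calibration and power properties of the test are therefore certified on
the unnormalised matrix, where ground truth is exact; on real data with
a complete set of ~175 proteins the effect is correspondingly smaller
but not zero.

## Zonation statistics

**Axis and bins.** Relative position is r = d_PV / (d_PV + d_CV), 0 at
the portal vein and 1 at the central vein.  (A raw quotient d_PV/d_CV
is unbounded and cannot equal 1 at the CV, so the normalised form is
used.)  Bins split [0, 1] equidistantly; bin i covers [(i−1)/B, i/B)
with the last bin closed at 1.  B = 20 by default — roughly the number
of cells along the axis — and is a free parameter (9 and 8 bins
reproduce the cross-omics rebinnings).

**Testing.** Per protein, a one-way ANOVA across bins on observed
values, restricted to proteins observed in ≥ 50% of samples with at
least two bins holding two or more observations.  With moderation on
(default), residual variances are shrunk by empirical Bayes toward a
pooled prior: the prior degrees of freedom solve a trigamma moment
equation on the log residual variances, the posterior variance is the
prior-df-weighted combination, and the moderated F uses denominator
df (d_g + d_0).  Plain ANOVA is available by flag and is used by the
permutation oracle in the tests.  P values are BH-adjusted; FDR < 0.05
is called zonated.  The "ANOVA fold change" used for ordering is the
mean of the portal-half bin means minus the central-half mean (log2);
the source protocol does not define it, so it is kept pluggable.

**Flatness.** Following the protocol exactly, a protein is called
expressed equally in all zones when a BH-adjusted Shapiro–Wilk test
across all samples gives P > 0.05.  Normality is of course a proxy —
a flat protein with Gaussian noise passes while a hockey-stick profile
produces a skewed pooled distribution that fails — and a bin-wise
equivalence test would be the statistically natural alternative; the
proxy is implemented because it is what the protocol specifies.

**Profiles.** Bin profiles are per-bin mean linear intensities divided
by their sum (an exact simplex over observed bins).  Centre-relative
log2 fold changes divide by the median of the two mid-lobular bins'
mean intensities.  Annotation proportions sum linear intensity per
annotation set per bin and normalise within bin; unannotated proteins
pool into "other".

**Pseudo-neighbors.** Samples sorted by r are combined in
non-overlapping consecutive windows of k (sliding windows available;
the protocol's wording is ambiguous between the two), averaging
observed values per protein; a value is missing only when all k are
missing; a trailing partial window is dropped, which makes the grand
mean exactly conserved when k divides n.  PCA on the combined matrix
reports per-component variance fractions and the PC1 score IQR.

**PCA policy.** Proteins observed in < 70% of samples are dropped,
remaining missing values are imputed with the per-protein median
(logged), proteins are centred (optionally unit-scaled), and the SVD
sign convention makes each component's largest-magnitude loading
positive so output is deterministic.  The k-means clustering below
reuses exactly this missing-value policy.

## Image features and class prediction

Bounding boxes take floor/ceiling of contour extrema (degenerate axes
widened to one pixel); the optional environment crop adds 1000 px per
side with clamping.  The 17 features per shape are mean, median,
minimum and maximum intensity of the full bounding box in each of the
four stain channels (phalloidin 425, WGA 488, E-cadherin 568, Glul
647), plus the shoelace polygon area in µm².  Statistics run over the
whole box rather than the polygon mask because that is what the
protocol describes; feature order is fixed (channels ascending by
wavelength, stats in the order above, area last) since none is printed.
Contour simplification keeps every ⌈1/(1−f)⌉-th vertex (uniform
decimation, matching "removing 99% of data points"), never fewer than
three.  The pixel-to-µm calibration is a required configuration value
for real data; the simulator works in a 1 µm/px frame.

Proteome classes come from k-means (k-means++ initialisation, fixed
seed, 10 restarts, best inertia) on the z-scored completeness-filtered
matrix, with K = 5 by default; classes are relabelled 1..K by
increasing mean r of their members, which defines spatial adjacency
(|class difference| = 1).  The classifier is a random forest (200
trees) trained on a plain random 0.2 test split at seed 23.  Reported:
test accuracy, macro one-vs-rest average precision, the confusion
matrix, and the fraction of misclassified test samples whose predicted
class is spatially adjacent.  Exact tree-ensemble outputs are
implementation-dependent even at a fixed seed, so all acceptance checks
on the classifier are property-based with margins, never bit-exact.

Class probabilities weight the class mean proteomes (per-class mean of
normalised log intensities over observed values) into a predicted
proteome per cell; proteins lacking a mean in some class are predicted
over the renormalised available classes.  Prediction quality is pooled
Pearson R over overlapping protein × cell entries of a held-out
section, plus the per-protein R distribution.  The pooled R is
dominated by between-protein abundance differences and is therefore
high whenever class means capture baselines; the per-protein
distribution is the stricter view.

## Synthetic lobule generator

The generator is first-class, tested code and defines the study
conditions used throughout the tests:

* **Geometry.** One portal and one central landmark bound a 1000 µm
  field; cells sit uniformly along the axis with 20 µm transverse
  jitter, so r is approximately uniform and every one of the 20 bins is
  populated — mirroring a full portal-to-central transect.
* **Areas.** Lognormal with median 600 µm² (the study's mean shape
  size) and log-sd 0.4, truncated at the 135–1350 µm² segmentation
  gates by resampling.
* **Profiles.** Default 200 proteins, 40% zonated, split evenly over
  hockey-portal, hockey-central, linear-up and linear-down shapes with
  amplitudes uniform in [2, 4] log2 units, breakpoints in [0.3, 0.7],
  exponents in [1, 2]; baselines N(12, 2.5²) log2.  Flat profiles have
  amplitude exactly 0.  Hockey profiles rise as
  max(0, (r−r0)/(1−r0))^γ from the breakpoint.
* **Measurement.** Observed log2 intensity = profile(r) +
  log2(area/600) + Gaussian noise (sd 0.5); four designated histones
  (baseline 17, near the top of the abundance range) add 2 log2 units
  per unit nuclear fraction, and a quarter of slices are anucleate
  (nuclear fraction 0).
* **Missingness.** Detection is Bernoulli with logistic probability in
  expected intensity (midpoint 10, scale 1.5) and certain above
  midpoint + 3 — reflecting that abundant signal is always found once a
  library match exists.  This produces the two emulation targets:
  per-cell protein counts grow with log area and per-protein
  completeness grows with abundance, and it leaves a complete core of
  proteins for the 100%-rule normalisation, as in the source study.
  The baseline spread, saturation offset and q-value failure fractions
  (0.2%, 0.2%, 1% per threshold) were set so these qualitative
  relations hold and then frozen.
* **Report.** Each detected protein × cell entry is spread over 2
  precursors with Dirichlet share weights and 3 fragments each; the
  reference channel carries the bulk proteome at 4× load with 0.1
  log-sd run-to-run noise and 20% of its signal as MS1.  The true
  ratio is defined against the median realised reference level over
  runs — exactly the statistic quantification recomputes — so the
  zero-noise round trip is exact to float precision.  q-values are
  drawn independently per row (no dependence structure is described
  for the real columns).
* **Images.** Per-cell 4-channel patches: the 568 mean falls and the
  647 mean rises linearly in r (amplitude 150 over base 50), 488
  couples weakly to nuclear fraction, 425 is flat; pixel noise is
  Gaussian (sd 20) truncated at 0.  Ground-truth classes are the K
  equidistant r intervals.

What the generator does *not* emulate: peptide sequences,
chromatography or ion mobility, interference structure between
fragments, spatial correlation of neighbouring cells beyond their
shared r, batch effects between sections, or the long-tailed protein
abundance distribution of real tissue.  Tests passing on this
generator certify the pipeline's algebra and statistical calibration
under the stated structure; they do not certify performance on
deposited raw data.

## Problem sizes and determinism

Simulation-based tests use 400-cell sections with 200 proteins (2000
for the null calibration) and a 500-cell section for the
image-model properties, with a 150-cell held-out section — sizes at
which every statistical property under test is comfortably resolved.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`), k-means and forest seeds are fixed in
configuration (default 23, as in the source protocol), and every
pipeline run writes its effective configuration and a content hash into
the run manifest.

## Known limitations

* The flatness call inherits the normality-as-flatness proxy from the
  protocol; interpret "flat" accordingly.
* Power figures condition on a protein being testable (≥ 50%
  complete); low-abundance zonated proteins that are rarely detected
  are invisible to any downstream test.
* The pooled prediction R overstates per-protein predictive skill (see
  above).
* The reference-ratio estimator is the median, not the published
  candidate-selection rule; on clean data they agree, under heavy
  fragment interference they may not.
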