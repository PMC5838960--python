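# Methods

## The mixing model and what it assumes

The reference set consists of three pure total-RNA components — liver
(L), brain (B), placenta (P) — and two mixtures combined by volume as
1:1:2 and 1:2:1 (L:B:P). Stored as fractions, the design matrix Φ has
columns (0.25, 0.25, 0.5) for Mix1 and (0.25, 0.5, 0.25) for Mix2. The
core assumption is additivity and linearity of signal on the linear
scale: the signal of miRNA *i* in a mixture is the Φ-weighted sum of its
pure-component signals. Under this model:

- the between-mixture ratio of any miRNA is a ratio of convex
  combinations, so it is bounded by the largest per-component fraction
  ratio — 2-fold (|log2| ≤ 1) for the default design, attained by
  brain- or placenta-exclusive miRNAs;
- a miRNA drawn only from liver (equal fractions in both mixtures), or
  with equal brain and placenta signal, has ratio exactly 1 (log2 0);
- the fractions themselves are recoverable from genome-scale data by
  least squares.

Linearity can fail in reality (saturation, additive background,
PCR-efficiency effects); the deviation metrics are designed to *measure*
such failures, not model them.

Predicted ratios are computed by pushing the linear-scale means of the
pure replicates through the model and logging; observed ratios are
differences of means of the log2 replicate values of each mixture. This
asymmetry is deliberate: prediction is a linear-scale statement, while
observation summarizes the log-scale measurements the platform actually
produced.

## Preprocessing

Counts and intensities: rows with maximum < 1 across all samples of the
processed set are dropped (detection filter), each column is scaled so
its total equals the median column total, and values are
log2-transformed with a pseudocount of 1 (so a zero count maps to log2
signal 0; detected miRNAs can still have zeros in individual samples and
the transform must be defined there). Filtering and normalization are
computed jointly over the full processed set (15 or 6 samples), not per
sample-pair. Intensity (hybridization) tables follow the same path with
the threshold on the intensity scale; whether intensities were
background-subtracted upstream is the lab's choice and is carried in
provenance. Cq tables are only negated — one PCR cycle is one doubling,
so −Cq is already a log2-scale signal — with no filtering or
normalization.

## Selectivity classes

A miRNA is selective for a tissue when its pure-profile mean there is at
least `fold` (default 10) times its mean in each other tissue; the rule
is linear-scale and scale-free, and exclusive for fold > 1 (all-zero
rows are non-selective). Brain- and placenta-selective miRNAs are the
designed true positives. The 1-to-1 (true-negative) class combines
liver-selective miRNAs with miRNAs whose brain and placenta means are
both positive and within `equality_tol_log2` (default 0.5, ≈ 1.41-fold)
of each other. The 0.5 default is a conservative choice for
"approximately equal"; no minimum signal level is imposed beyond
detection. A miRNA that is ≥ 10× above liver in both brain and placenta
but with those two within the equality band is a 1-to-1 member — its
predicted ratio is near zero, which is what the class encodes.

## Deviation, bias, precision, reliable range

Per miRNA, D = observed M − predicted M and A = the average of the
observed and predicted mean log2 signals. Median(D) is the bias metric
and IQR(D) the precision metric (linear-interpolation quantiles),
overall and per class.

The deviation distribution along the dynamic range is modeled
empirically, with no parametric assumption: records sorted by A, sliding
windows of `window_size` consecutive records (default max(50, 5% of n)),
and within each window the central 95% interval of D as the 2.5%/97.5%
empirical quantiles. A window complies when that interval lies within
± `tolerance` (default log2(1.5) ≈ 0.585, half a fold change). For
sequencing, the lower limit is the center A of the earliest window from
which *every* higher-signal window complies — requiring the suffix, not
just one window, prevents an isolated compliant window at low signal
from defining the limit — and the upper limit is the maximum detectable
A. For hybridization platforms, which can saturate, `assess_upper`
bounds the longest contiguous compliant run on both sides. If no window
complies, or there are fewer than `min_range_records` (default 100,
which routes small PCR panels here), the range is "not determined" (ND)
with the reason recorded.

## Discrimination

ROC curves use the designed labels (true positives: brain- and
placenta-selective; true negatives: 1-to-1; non-selective miRNAs are
excluded). With replication, miRNAs are ranked by the two-sided paired
t-test of replicate-paired Mix1 vs Mix2 log2 signals; p-values are used
only as ranking scores, so no multiple-testing correction applies.
Degenerate rows are handled explicitly: paired differences with zero
variance but a nonzero mean get the machine-minimum p-value (a perfectly
consistent difference), and all-zero differences get p = 1; "zero" is
judged at an absolute tolerance of 1e-6 log2 units so numeric residue
from normalization is never mistaken for signal. Without replication the
ranking score is |observed M|. AUC equals the Mann–Whitney pairwise-win
probability; ties share midranks (diagonal ROC segments). The
"within-range" AUC restricts the *label set* to miRNAs whose observed A
falls inside the reliable range; scores are unchanged.

## Deconvolution

For each mixture, the fractions solve

    min_φ  Σ_i ( S_i,mix − Σ_c S_i,c φ_c )²   s.t.  φ ≥ 0,  Σ φ = 1

on linear-scale normalized signals (the model is linear there), using
all detected miRNAs shared between profile and mixtures. The solver
enumerates the faces of the simplex: for every nonempty support set it
solves the sum-to-one equality-constrained least squares via the KKT
system and keeps the feasible minimum. For a convex quadratic over the
simplex the optimum lies in the relative interior of some face, where
the equality-constrained solution is feasible, so the enumeration is
exact; it is practical for the ≤ 12 components any mixture design uses.
A condition number above 1e10 (collinear tissue columns) is rejected
with a diagnostic. Rows are unweighted by default; an inverse-signal
weighting could temper count heteroscedasticity but the large-signal
rows that dominate the fit are also the best measured, and the unweighted
fit recovers Φ to well under 0.01 at realistic depths.

Uncertainty: miRNA rows are resampled with replacement (replicates are
too few to resample), the fit repeated per draw, and each component's
(Mix1, Mix2) estimates summarized as an ellipse — the chi-square(2 df,
0.95) contour of the empirical 2D covariance centered at the bootstrap
mean. With noise-free data the resampling variance collapses and the
ellipse is flagged degenerate. The pairs bootstrap captures row-level
dispersion but not the errors-in-variables bias of using a noisy pure
profile as the design matrix; in calibration simulations at realistic
sequencing depth the empirical 95% coverage of the true Φ is ≈ 92%,
within the 90–99% band the tests require. The consistent tissue-specific
displacement caused by differing miRNA mass fractions per unit total RNA
is reported (segment lengths and their sum), never corrected.

## The synthetic-data generator

`mixqc.simulate` emulates the study conditions of a well-powered
sequencing site: 1000 detected miRNAs, of which 9.5% brain-selective,
9.5% placenta-selective, 2% liver-selective and 3.2% designed
brain = placenta (mirroring a deep NGS dataset with ~1130 detected and
107/105/23/36 in those classes); log-normal baseline abundance (log2
mean 6, sd 3, spanning ~18 log2 units); enrichment fold 30 for selective
miRNAs; 3 replicates of each of the 5 samples; 2 million reads per
sample.

Construction details that make the ground truth exact:

- For ordinary (non-designed) miRNAs the brain/placenta log2 gap is
  drawn from ±[0.7, 2.0] — outside the 0.5 equality band — and liver
  jitter is bounded at ±1 log2, so no miRNA satisfies the 10× rule or
  the equality rule by chance and the designed labels coincide exactly
  with `classify_selectivity` on the noise-free profile (asserted in
  tests).
- Selective rows keep the other two tissues exactly at baseline, so the
  enrichment satisfies the ≥ 10× rule by construction; liver-selective
  rows have brain = placenta exactly, making every designed true
  negative have predicted M = 0 under any rescaling.
- Tissue columns are rescaled to exactly equal totals — the equal
  miRNA-mass-fraction ideal that median-total normalization assumes —
  using one multiplicative factor per designed row-group, which
  preserves every within-row ratio; a minimum-norm solve picks factors
  closest to 1 (an iterative column-scaling fallback covers degenerate
  group structures). Per-tissue `mirna_fraction` scalars deliberately
  break the ideal to reproduce real tissue-fraction bias.

Platform noise: sequencing draws each sample as a multinomial of `depth`
total reads over the miRNA proportions (compositional, like a
sequencer's fixed read budget; preferred over independent Poisson
because the normalization step exists to handle exactly this
constraint); hybridization adds a background floor then multiplies by
log-normal noise (additive background is what produces ratio compression
at low signal); PCR reports Cq = intercept − log2(signal) + Gaussian
noise. Mixture samples are generated from the ground-truth linear
signals through the mixing equations — not by resampling pure samples —
so the in-silico-prediction-vs-physical-mixture comparison is exercised
end to end. `depth=None` yields the noise-free limit in which the
pipeline must recover every metric exactly (deviation 0, AUC 1, Φ to
1e-6).

What the generator does not emulate: sequence-level artifacts (adapter
or mapping bias), cross-hybridization structure, batch effects across
rounds, or correlated noise between replicates. Passing tests therefore
demonstrate the correctness and calibration of the metrics under the
stated noise models, not the behaviour of any particular instrument.

## Numerical choices

- Pseudocount 1 at the log2 step, applied identically to predicted
  signals so the two scales are comparable.
- Quantiles everywhere use the linear-interpolation rule.
- Loess bands (MA-plot class trends): local quadratic with tricube
  weights over the span fraction (default 0.75) of nearest neighbours;
  the pointwise 95% band is a normal approximation, fit ± z·σ̂·‖l(x)‖,
  with σ̂ from the loess residuals; fewer than 10 points yields a
  warning and no band.
- The predicted-plot A axis logs the predicted mixture signals
  themselves (not means of logged pure means).
- The simplex solver accepts support-set solutions with components down
  to −1e-10 (clipped and renormalized) to absorb KKT roundoff.
- Bootstrap draws and the pipeline are fully seeded; `run_pipeline` is
  deterministic given data, config and seed.

## Analysis modes

`full` analyses pures + mixtures of one round. `baseline` takes a banked
pure profile (e.g. from a first round) and analyses only the six mixture
samples of later rounds; with the very same samples it reproduces
full-mode metrics up to the preprocessing of the smaller sample set.
`single_replicate` restricts to replicate index 1 and switches the ROC
ranking to |observed M|; across simulations its mean AUC is below the
replicated mode's, which is why monitoring should stick to one protocol.

## Problem sizes used by the test suite

Unit and property tests run on instances of 5–2000 records. The
statistical acceptance checks use: 20 seeds at 1000 miRNAs / 1e6 reads
for Φ recovery (tolerance 0.02); 200 simulation replicates at 1000
miRNAs / 2e6 reads with 300 bootstrap draws for ellipse coverage
(90–99% band); 20 seeds at 400 miRNAs / 3e4 reads for the
replication-benefit comparison; and brute-force oracles (pairwise-win
AUC, 1e-3 simplex grid, naive window rescan) on instances small enough
to enumerate. These sizes are the package's chosen test conditions; the
library itself has no size limits beyond memory.

## Known limitations

- The reliable-range estimate is window-based and therefore quantized to
  the window spacing; very sparse panels (e.g. 32-assay PCR) report ND
  by design.
- Bootstrap ellipses ignore errors-in-variables bias from the noisy pure
  profile; coverage is slightly below nominal (≈ 92% at realistic
  depth).
- The deconvolution reports, but cannot separate, tissue miRNA-fraction
  bias from measurement bias; spike-in-based fraction assessment is out
  of scope.
- Only two-mixture comparisons are implemented end to end; the types
  admit more mixtures but the metrics are pairwise.
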