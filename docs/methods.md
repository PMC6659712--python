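# Methods

`qminet` implements the statistical pipeline of quantitative multiplex
co-immunoprecipitation (QMI): bead-level preprocessing of multiplexed
IP-FCM data, adaptive nonparametric hit calling (ANC), weighted
correlation network analysis (CNA), and the intersection of the two that
defines high-confidence changes in protein co-association networks.  A
synthetic-data generator with recorded ground truth drives all validation.

## The data model

A QMI run couples each capture (IP) antibody to a spectrally addressable
bead region and distributes the bead master mix into one well per
detection (probe) antibody.  The instrument reports one event per bead:
a doublet-discriminator value, two classification-channel intensities,
and a reporter (PE) fluorescence.  A measurement ("interaction") is the
pair `IP_Probe`; its per-well readout is the multiset of reporter values
of the beads in that well belonging to that IP's region, summarised by
the median fluorescence intensity (MFI).

The simulator (`synthdata`) emulates this layout directly:

* **Reporter noise** is lognormal *parameterised by its median*, so a
  configured MFI target is the exact population median — MFI is defined
  as a median, and this keeps planted fold changes exact at the statistic
  the pipeline uses.  The coefficient of variation defaults to 0.3,
  a typical spread for bead-level immunoassay fluorescence.
* **Detection floor**: the median entering the lognormal is clipped from
  below at 100 a.u., reproducing the assay background (IgG controls read
  out near MFI 100); sub-floor signals are therefore indistinguishable
  from background, which is why weak interactions have "no room to
  decrease".
* **Batch structure**: each experiment multiplies all baselines by
  `2^N(0, batch_sd)` (default 0.2), i.e. an additive offset on the log2
  scale — exactly the location model ComBat removes.
* **Doublets**: a configurable fraction of events (default 5%) receive a
  discriminator value outside the (5000, 25000) gate, split symmetrically
  above and below since only the gate bounds are specified.
* **Study design defaults** follow the assay as practised: 4 experiments
  (batches), technical duplicates, 300 beads per interaction per well
  (the instrument typically collects 10^2–10^3).

The matrix-level generator (`simulate_mfi_matrix`) plants co-varying
modules through a shared per-sample latent factor with loading 0.8
against unit-total noise (expected within-module correlation 0.64),
optional trait-linked log2 shifts, and additive log2 batch offsets.

What the generator does **not** model: spectral compensation, plate
spatial effects, instrument drift, antibody cross-reactivity, or
heavy-tailed outlier beads.  Passing tests therefore demonstrate that the
statistical machinery is calibrated and powerful under the assay's
nominal noise model, not that it is robust to instrument pathology.

## Preprocessing

Gating keeps events with discriminator strictly inside (5000, 25000) —
the bounds are printed as strict inequalities and boundary events are
excluded.  Bead classification assigns each event to the nearest region
centroid within 3 within-region SDs; exact ties and out-of-radius events
stay unclassified and are dropped (conservative; the dropped fraction is
logged).  Reporter pairing yields one bead distribution per
(IP, probe, well); event counts are conserved.  Medians of even-length
distributions use the midpoint of the central order statistics.

Technical replicates are **pooled at the event level** for ANC (the test
operates on bead distributions) but **averaged at the MFI level** for
CNA (whose input is the replicate-averaged matrix).  The choice of
pooling duplicates inside ANC is a declared convention of this package.

## ANC: adaptive nonparametric hit calling

Per interaction and experiment, treated and control bead distributions
are compared with a two-sample test — Kolmogorov–Smirnov by default
(sensitive to any distributional shift, matching the bead-distribution
framing), Mann–Whitney optionally.  The per-experiment cutoff is

    alpha_adj = min(alpha_family / n_interactions, alpha_empirical)

where `alpha_empirical` is calibrated on null comparisons formed from
technical replicate pairs of the same condition: it is the largest alpha
at which the expected number of null calls across the panel,
`n_interactions x (fraction of null p-values < alpha)`, stays at or
below `alpha_family` (0.05).  When a null comparison falls under the
Bonferroni cutoff, the cutoff moves strictly below it.  This is this
package's concretisation of the "empirical adjustment for technical
variation"; the original MATLAB rule is unpublished.

A hit must be individually significant with a consistent fold-change
direction in **more than 70%** of experiments — 3 of 4 qualifies, 7 of
10 does not.  Interactions whose control MFI sits at the detection floor
in every experiment are flagged `floor_limited` and excluded from
fold-change rankings.

Numerics: the panel-scale KS path computes the exact D statistic via
sorted-array search and evaluates the Kolmogorov distribution with
Stephens' small-sample correction, vectorised across the panel.  At
bead-level sample sizes (n ≈ 600 pooled) this agrees with the finite-n
asymptotic to < 0.008 absolute, and because the empirical alpha is
calibrated on null p-values from the same path, the cutoff is
self-consistent.  The scalar `distribution_test` delegates to scipy's
`ks_2samp`, which switches to the exact null for small samples.

The single-plex family (`adjusted_mannwhitney_family`) Bonferroni-divides
the family alpha across comparisons.  Note that with n=3 vs 3 the exact
two-sided Mann–Whitney p-value cannot fall below 0.1, so such families
can never reach significance — the family-wise error is controlled
trivially; the procedure only discriminates at larger replicate counts.

## CNA: correlation network analysis

The pipeline stages, in the order applied: noise filter (drop
interactions with MFI < 100 in **all** samples — the row-level reading of
the filter; partially detected interactions are kept), ComBat batch
correction with experiment as batch, log2 transform, soft-threshold
selection, unsigned power adjacency `|cor|^beta`, topological overlap,
average-linkage clustering of `1 − TOM`, static tree cut with
branch-size pruning, module eigengenes, eigengene–trait correlation, and
per-interaction module membership (kME) with Benjamini–Hochberg control
at FDR 0.05 (BH is used wherever an FDR is required without a named
method).

**ComBat** is implemented in-package as the parametric empirical-Bayes
location/scale model: per-interaction standardisation against grand mean
and pooled variance, per-batch location/scale estimates shrunk toward
across-interaction priors (normal for locations, moment-matched inverse
gamma for scales) by the standard iterative posterior solution.  A single
batch returns the input unchanged; a singleton batch falls back to
location-only adjustment for that batch.  Degenerate priors (noiseless
constructions) disable shrinkage, making the adjustment the exact
closed-form location fix.  Because EB shrinkage deliberately removes only
the shrunken part of each interaction's batch deviation, the operator is
*not* idempotent on noisy data — only the degenerate/noiseless case is.
The implementation is cross-checked against `scanpy.pp.combat` (< 1%
relative deviation, attributable to convergence thresholds).

ComBat runs on **raw MFIs with log2 afterwards**, mirroring the stated
analysis order, although the additive model is better matched on the
log scale; `log2_before_combat=True` selects the conventional order.  On
simulated data with batch effects the raw-scale order costs measurable
module-recovery accuracy (mean adjusted Rand index ~0.85 vs ~0.91
log-first over 20 seeds) — a limitation inherited with the stated order.

**Soft-threshold selection** computes, per candidate power, the signed
R² of the log–log regression of the binned connectivity distribution
(negated for a positive slope) and takes the smallest power reaching
R² ≥ 0.8.  Two guards keep the rule meaningful on small panels
(tens to hundreds of interactions, not the tens of thousands the
scale-free criterion was designed for): candidates whose mean
connectivity falls below 1% of (n−1) are excluded — past that density
any connectivity histogram looks scale-free while the topological
overlap degenerates and module detection collapses — and when no
admissible power reaches the target, the smallest power within 0.1 of
the best admissible R² is taken rather than the argmax, which
otherwise lands on the sparsest candidate by noise.  Both guards are
parameters (`min_mean_k_frac`, disable with 0).

**Tree cutting** is a static cut at 0.99 of the maximum merge height
with branches smaller than `min_size` (default 6, the middle of the 5–10
range) sent to the unassigned "grey" class; modules are named by a fixed
colour sequence, largest first.  Static cutting was chosen over dynamic
tree cut for reproducibility and testability; it reproduces planted
modules at the panel sizes this package targets.

Module eigengenes are the first right-singular vector of the
row-standardised member submatrix, sign-oriented positively with the
members' mean profile.  Trait correlations use the Pearson t-test
(trait coded 1 vs 0); p.MM is the correlation-test p-value of each
interaction against the eigengene, BH-adjusted across interactions.

## ANC ∩ CNA and summaries

The high-confidence set is the intersection: ANC hits that also belong to
a trait-associated module (eigengene p < 0.05) with adjusted p.MM < 0.05.
Counts for each criterion are reported separately, and the set is by
construction a subset of both parents.

Supporting computations mirror the publication conventions: epitope
collapse keeps, per unordered protein pair, the measurement with the
largest |log2 FC| (ties broken lexicographically and logged); the
detection mask flags |log2 FC| < log2(1.1) — changes under 10%, the
assay's lower limit of detection, with the exact boundary unmasked and
the rule symmetric under fold-change inversion; row-normalised heatmap
input is the per-row z-score of log2 data; network export writes SIF
with an attribute sidecar, GraphML, or a single CSV, all round-tripping
through the package's reader.

**Hierarchical clustering** of samples uses Ward linkage on Euclidean
distances of the log2, batch-corrected matrix.  Cluster support follows
the multiscale bootstrap: for scales r ∈ {0.5, …, 1.4}, features are
resampled with replacement at size ⌈r·p⌉ and the samples reclustered;
per original cluster, the probit of the per-scale recovery probability
is fitted to `v√r + c/√r` by weighted least squares and the
approximately unbiased support is `AU = 100·(1 − Φ(v − c))`, with
`BP = 100·(1 − Φ(v + c))` the plain bootstrap probability at r = 1;
zero curvature makes the two coincide.  Clusters recovered in every
resample are reported at AU = 100; clusters never recovered at AU = 0
with a flag.  Resampling is over features (the standard formulation for
sample clustering; the resampled axis is not otherwise specified).
Defaults: 10 scales, 1000 resamples per scale (100 in tests).

**PCA** is the SVD of the column-centred sample matrix; unit-variance
scaling is off by default (the input is already log2, batch-corrected)
and available via `scale=True`.

## Problem sizes used in validation

The global-null calibration simulates 200 panels of 378 interactions
(an 18 × 21 capture-probe grid) × 4 experiments in duplicate at 300
beads per interaction per well, and requires the fraction of panels with
any ANC hit to stay at or below 0.05.  Planted-recovery checks use
42-interaction panels with five 0.6-fold dissociations (20 seeds;
sensitivity ≥ 0.9); the Mann–Whitney family-wise error uses 2000
simulated 10-comparison families; module recovery uses 30 × 24 matrices
with three planted modules of size 8 (20 seeds; mean ARI ≥ 0.9).

## Known limitations

* The empirical-alpha rule and the ANC test statistic are this package's
  concretisation of a procedure whose original implementation is
  unpublished; both are exposed as parameters.
* The exact Mann–Whitney floor makes n=3 families uninformative (see
  above); this is a property of the test, faithfully reproduced.
* Module detection is tuned for panels of tens to hundreds of
  interactions; genome-scale inputs would warrant dynamic tree cutting
  and block-wise TOM computation.
* AU p-values inherit the usual multiscale-bootstrap caveats for small
  feature counts (p < ~20 features makes the scale grid coarse).
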