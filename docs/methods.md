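# Methods

## Study design assumed by the pipeline

One "experiment" is an inhibitor arm treated in triplicate and harvested at
3, 6 and 9 h, with triplicate time-matched DMSO solvent controls and
triplicate untreated anchors at 0 h and 9 h. The anchors exist to expose
solvent effects; by default they do not enter the treated-vs-DMSO
contrasts, with one exception: the regression detectors use the 0 h
untreated samples as a shared pre-treatment baseline (see below). A
two-arm analysis (SB = TGF-β inhibition, SU = FGF inhibition) shares the
DMSO and untreated arms.

## Synthetic data generator

The generator produces gene × sample NB counts with known ground truth:

- **Baselines.** Per-gene abundance weights are lognormal
  (`log_mean_baseline`, default μ=2.0, σ=1.5 on the natural-log scale) and
  normalized to relative abundance, so baseline CPM is the weight × 10⁶ /
  Σweights. σ=1.5 gives the 2–3 decades of expression spread typical of a
  filtered bulk matrix.
- **Depth.** Expected library size defaults to 10⁶ (a scaled-down depth
  that keeps test runs fast while leaving most genes with tens to hundreds
  of counts); per-sample sizes are jittered lognormally with 10% CV to
  exercise normalization.
- **Dispersion.** Gene-wise NB dispersion φ in Var = μ + φμ², drawn
  lognormal around 0.05 (a typical bulk tagwise value; the study itself
  reports no dispersion estimates, so this is a convention, not a measured
  value). Calibration and power suites fix φ = 0.05 exactly.
- **Effects.** A fraction `frac_de` of genes receive a treated-arm
  trajectory from the impulse family: monotone-up, monotone-down (offset
  time outside the window) or transient (onset and offset inside it), mixed
  0.4/0.4/0.2 by default. The drawn effect size is the max |log₂ fold
  change| **at the observed nonzero timepoints** — curves are exponent-scaled
  so the realized trajectory attains exactly that maximum where it can be
  seen, which makes truth directly comparable to estimated LFC tables.
- **Dual-arm mode** shares baselines, dispersions and control arms between
  SB-like and SU-like arms and forces a configurable overlap of the two DE
  gene sets (default 25%), with per-arm trajectories and signs drawn
  independently so common targets split into concordant and discordant
  cases.

What the generator does *not* emulate: batch effects, gene–gene count
correlation, compositional distortion from very large DE fractions,
length/GC biases, and outlier samples. Passing tests therefore demonstrate
statistical correctness of the machinery under a well-specified NB world,
not robustness to every artifact of real libraries.

## Preprocessing

CPM = counts/library×10⁶ (plain total-count normalization; TMM-style
scaling deliberately omitted — the emulated workflow specifies only counts
per million). The expression filter keeps genes with mean CPM ≥ 1 across
the experiment's samples (treated arm + its controls + anchors), computed
per experiment; `mode="all"`/`"any"` variants are available because "at
least 1 CPM within each experiment" admits several readings. LFC uses a
pseudocount of 0.5 on mean CPM in both numerator and denominator, keeping
LFCs finite for zero groups while leaving well-expressed genes essentially
untouched. LFCs are stored signed (treated over control); reports also
carry |LFC| and a direction column because published tables for
downregulated targets print magnitudes.

## Dispersion estimation

Per replicate group (treatment × timepoint), counts on a common library
scale give the moment estimate φ̂ = (s² − c·m)/m² (c corrects the Poisson
term for rescaling); groups pool weighted by residual df, clamp at 0, and
shrink toward the across-gene median with a prior weight of 20 df. With
~16 residual df per gene the raw tagwise values are extremely noisy;
half-shrinkage toward the common value is the same compromise count-based
DE tools make. The shrinkage target is a single common value, not a
mean-dependent trend — adequate here because simulated dispersions are not
mean-dependent; a trended prior is the natural extension for real data.

## The four detectors

All detectors are symmetric in the condition labels and were chosen to
emulate the statistical idioms of a standard tool ensemble (pairwise
count-based testing, impulse-model likelihood ratio, spline + moderated F,
two-stage polynomial regression) without attempting numerical
bit-compatibility with any of them — agreement is targeted at the level of
calibration and power.

**Pairwise NB Wald (pairwise_nb).** Per timepoint, the treated/control
difference of log mean CPM with delta-method variance
Σ(10⁶/(L·m̃) + φ)/n² per group, using the pooled mean m̃ (plus half a
count) so the statistic is exactly label-symmetric. Per-timepoint p-values
combine via the Šidák transform 1−(1−p_min)^T, which is exactly uniform
under independent null timepoints — a Bonferroni-min·T combination is not
a p-value (its null distribution is far from uniform), which matters
because downstream gates and the calibration suite consume these values as
probabilities.

**Impulse LRT (impulse_lrt).** NB likelihood with mean = impulse(t) ×
library offset, dispersion fixed at the shrunk estimate. Null: one curve
for all samples; alternative: independent curves per arm. Optimization is
deterministic multi-start Nelder–Mead (numba-compiled) from data-driven
initializations — cell-mean levels with midpoint transition times at two
slopes, plus a flat curve — and every alternative fit also starts from the
null solution, which guarantees the nesting invariant ll_alt ≥ ll_null by
construction. The reference distribution uses **df = (#condition×time
cells in the alternative) − (#time cells in the null)**, i.e. 3 for the
3/6/9 h design, not the raw parameter-count difference of 6: with three
distinct timepoints the six-parameter curve family can interpolate any
positive triple, so the extra identifiable mean dimensions — and hence the
asymptotic df — equal the number of cells, and a χ²₆ reference would be
drastically conservative (CDF error ≈ 0.25 mid-scale). The same
saturation property yields an independent test oracle: at three timepoints
the impulse LRT must equal the saturated group-means NB LRT, which has a
closed form under Poisson.

**Spline moderated F (spline_f).** log₂(CPM+0.5) is modeled as intercept +
natural-cubic-spline basis B(t) (knots at the distinct timepoints, df = 3
with the 0 h baseline included) + condition·(B(t)−B(0)). The interaction
basis vanishes at t = 0, encoding the physical constraint that arms are
identical before treatment; this also keeps the design full-rank when the
treated arm has no 0 h samples of its own, and removes the need for a
condition main effect. Residual variances are squeezed by empirical-Bayes
moment matching on log s² (prior df from a trigamma inverse), and the
condition-dependent coefficients are tested with a moderated F on
(k, d₀+d_res) df.

**Two-stage polynomial (poly_twostage).** Same response and sample set;
full model intercept + t + t² + cond·t + cond·t² (time scaled to [0,1] for
conditioning; interactions again vanish at t=0). Stage 1 is the ordinary
global F against intercept-only — significance means *any* temporal or
condition structure, which matches the two-stage idiom this detector
emulates; stage 2 backward-eliminates non-significant terms at 0.05 and
reports the surviving term set. The reported p is the stage-1 p.

**Quasi-likelihood moderation.** Both count-based tests are additionally
scaled by a per-gene quasi-dispersion: the Pearson X² of the saturated
cell-means NB fit over its residual df, EB-squeezed across genes, with the
statistic referenced against F(df, d₀+d_res). At n = 3 the unmoderated
Wald/LRT references are measurably anti-conservative (type-I error
0.07–0.09 at nominal 0.05); quasi-likelihood moderation is the standard
remedy in count-based DE analysis and brings all four detectors to
0.044–0.068 empirical type-I with KS-uniform null p-values.

## Consensus

Candidate sets per detector: BH-adjusted p < α AND max-over-timepoints
|LFC| ≥ λ (the ≥ is inclusive; the max-over-timepoints granularity is a
documented choice). The published gates (0.05 / 0.01 for the two arms) do
not state raw vs adjusted p; adjusted is the default as the field norm,
with `use_adjusted=False` available. The λ-anchoring rule — positive
control's |LFC| at its earliest timepoint exceeding a 0.1 noise floor,
rounded *down* to one decimal — is an explicit interpretation of deriving
a threshold "based on" a known target gene: applied to a control
responding (0.58, 1.24, 1.54) it returns 0.5, and to one first responding
at 0.74 it returns 0.7. It is deliberately exposed as one of several rules
(earliest, min-over-significant, manual) because the published description
fixes only the outcome, not the formula. Voting keeps genes called by ≥ k
tools (default 3 of 4); candidate lists sort by (n_tools desc, max |LFC|
desc, gene id asc) for stable output.

## Networks

Edge tables follow the STRING export dialect; `combined_score ≥ 400`
(medium confidence, the documented default of that resource) is the
default cutoff. Networks are induced subgraphs on consensus candidates
with degree-0 nodes removed; temporal annotation stores, per node, the
first timepoint with |LFC| ≥ λ and per-timepoint up/down/none segments —
the same information the original workflow encodes as node colors and
ring segments, exported here as GraphML/TSV attributes. Merging takes the
node/edge union, tags shared nodes `both` and suffixes each experiment's
annotations; conflicting edge scores resolve to the maximum. The crosstalk
network is the subgraph induced on the shared targets (intersection of the
two consensus lists) plus their depth-1 neighbors. Common targets are
classified by comparing LFC signs at each experiment's max-|LFC| timepoint
(below-threshold sides are indeterminate); the timepoint choice is a
documented convention, as the published comparison does not state one.

## Numerical choices

- Impulse optimization: θ = (log levels, t₁, t₂, log β) with box penalties
  (levels 10⁻⁴–10⁹ CPM, times −5–20 h, β 0.05–20/h) and a soft t₁ ≤ t₂
  penalty; Nelder–Mead, ≤300 iterations, relative f-tolerance 10⁻¹⁰; ties
  between starts resolve to the best likelihood, so results are
  deterministic and independent of any RNG.
- Zero-count groups: half-count pseudocounts on the CPM scale (pairwise
  test), 0.5 pseudocount on log-CPM responses, mean floors of 10⁻² CPM in
  impulse initialization.
- Degenerate inputs: zero residual variance yields F = 0 (not NaN);
  all-zero cells contribute nothing to quasi-dispersions; empty filter
  results and empty networks warn rather than fail.
- BH adjustment delegates to statsmodels (`fdr_bh`).

## Problem sizes of the bundled suites

Calibration uses 2000-gene null simulations at φ = 0.05, n = 3, over three
seeds; power/FDR uses 1000-gene simulations (10% DE, max |LFC| uniform in
[1, 3]) over five seeds — 1000 genes gives 100 true positives, enough to
estimate sensitivity to a few percent. Impulse recovery uses 100 genes at
φ = 0.01 with 6 replicates per timepoint and marker-grade expression
(500–5000 CPM-scale levels): at that noise level a cell mean is only ~4%
accurate, so the 10% recovery criterion is a meaningful check of the
optimizer precisely in the well-expressed regime where curve fits are
scientifically used.

## Known limitations

- Emulation fidelity to the original tool ensemble is statistical
  (calibration, power ordering, consensus behavior), not numerical; the
  published candidate counts depended on specific tool versions and
  external database states and are not reproduction targets here.
- The impulse df argument assumes the design's timepoint count; designs
  with ≥ 7 distinct timepoints would need the parameter-count df cap
  (min(6, cells)), which the implementation applies automatically.
- The generator's DMSO arm equals the untreated baseline unless a solvent
  shift is configured, so solvent-effect QC paths are exercised only
  synthetically.
- Identifier handling is purely string-based; mapping between gene symbols
  and database identifiers is out of scope.
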