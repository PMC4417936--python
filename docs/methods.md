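# Methods

## The model

Food level is treated as a categorical stimulus F ∈ {f₁ … f_K} (K = 6 by
default). Each animal yields a readout vector: expression intensities
x = (x_NSM, x_ADF, x_ASI), each the summed fluorescence of the two cells of a
neuron pair (AU), and/or a lifespan t (days). Encoding fidelity is measured
by generative Bayes decoding:

1. p(x | f) is modelled as a multivariate Gaussian per food level (full
   covariance by default; diagonal optional), p(t | f) as a Weibull.
2. Parameters are estimated per food on training data: sample mean and
   (n−1)-denominator covariance for the Gaussian; maximum likelihood with
   location fixed at zero for the Weibull.
3. For a held-out animal, p(f | x) ∝ π_f · p(x | f) with uniform priors π_f
   by default (food levels are treated as equally likely stimuli even when
   group sizes differ; an empirical-prior option exists). Densities are
   combined in log space and normalized with log-sum-exp.
4. The hard assignment is argmax_f p(f | x), ties broken deterministically
   toward the lower food index.

Cross-validation is 5-fold, stratified by food level so that no training
fold loses a class at small mutant sample sizes. Within each food group,
rows are first put in a canonical order (by animal id, then values) and then
permuted with a generator seeded by the run seed and dealt round-robin into
folds; this makes fold assignment — and hence every decoding output —
invariant to the row order of the input table. Subset sweeps (all seven
non-empty subsets of {NSM, ADF, ASI}) share one fold assignment so subset
accuracies are directly comparable.

Two summaries are reported per run: the probability matrix, whose row f is
the mean posterior vector over animals truly at food f, and the ML confusion
matrix, whose row f holds hard-assignment frequencies. Overall accuracy is
the event-count-weighted mean of the ML diagonal; "above chance" subtracts
1/K.

Functional masking: a mutant's reporter still fluoresces, but only readouts
whose underlying gene is intact count as physiological signals. Functional
sets are wildtype → {NSM, ADF, ASI}, *tph-1(−)* → {ASI}, *daf-7(−)* →
{NSM, ADF}, double mutant → ∅, whose accuracy is defined as the chance floor
1/K. Functional decoding uses the mutant's own data restricted to its
functional neurons, so it reflects both the masking and the mutant's altered
response statistics.

## Expression statistics

Per (genotype, neuron, food): n, mean, sample SD (n−1; this is the
variability σ), SEM = SD/√n, and the mean normalized to the highest
*wildtype* mean of that neuron when a wildtype group is present (else to the
genotype's own maximum). σ is computed on raw AU; normalization applies to
means only. Dynamic range ΔF = max_f mean − min_f mean within a genotype.
Missing neuron values are excluded pairwise for summaries; decoding drops
incomplete rows listwise.

## Survival

Kaplan–Meier estimation and the log-rank / Gehan–Breslow–Wilcoxon tests are
delegated to lifelines (the Wilcoxon variant weights event times by the
number at risk, making it sensitive to early divergence). Mean lifespans use
observed deaths only; censored animals are counted and logged. A genotype's
lifespan response is summarized by the *range* (max − min of per-food mean
lifespans) and the *baseline* (their unweighted average — not the pooled
per-animal mean, so each food level contributes equally). Decoding from
lifespan drops censored rows before the per-food Weibull fits; the shape
parameter is capped at 100 for degenerate (zero-spread) samples.

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the analysis assumes —
it is the package's study condition, not a tuning surface.

- **Food panel**: six concentrations (0, 2×10⁵, 2×10⁷, 6×10⁸, 2×10⁹, 1×10¹⁰
  cells/ml), zero food = dietary deprivation, ordered ascending.
- **Wildtype expression profiles** (AU): ADF rises strictly monotonically
  with food; NSM and ASI peak at interior foods; NSM and ADF are low at zero
  food. Per-condition SDs (75–85 AU against profile spans of ~330–470 AU)
  were chosen so that single-neuron decoding lands well between chance and
  perfect, leaving headroom for combinations to help.
- **Mutant effects** enter as two orthogonal gains applied to the wildtype
  profiles: a dynamic-range gain that scales per-food deviations from the
  profile mean, and a variability gain on the SDs. *tph-1(−)*: range ×1.4
  (serotonin signalling normally compresses the range); *daf-7(−)*: SD ×1.8
  and ASI range ×0.35 (TGF-β normally suppresses variability, and the ASI
  response collapses without its own gene product); double mutant:
  intermediate (range ×1.3 except ASI ×0.5, SD ×1.5).
- **Lifespans**: Weibull with shape 5 (a steep, ageing-type hazard typical
  of worm survival curves), scales set so the wildtype per-food mean
  lifespans are (24, 28, 30, 24, 20, 18) days: extension under moderate
  restriction, decline at deprivation and ad libitum. The wildtype range is therefore
  12 d around a 24 d baseline; mutants flatten the profile toward the
  baseline (gains 0.65 / 0.6 / 0.4), so the double mutant keeps a 4.8 d
  range — a 60% reduction — while every genotype keeps the same baseline.
- **Sampling**: 120 animals per condition by default (~720 per genotype
  across foods). Negative Gaussian draws are rejection-resampled by default
  (clipping at zero optional), keeping the Gaussian decoding model only
  mildly misspecified. Lifespans are uncensored by default; a censoring
  fraction can be switched on. All draws derive from numpy Generator streams
  keyed on (seed, stream, genotype-name hash, food index), so output is
  bitwise reproducible and independent of genotype list order.

Not emulated: developmental timing, matricide/censoring structure,
temperature, bacterial growth, any correlation between an individual's
expression and its own lifespan (expression and lifespan tables are
independent draws), and possible log-normality of real intensity
distributions. Passing tests therefore demonstrate correctness of the
machinery under the assumed model, not distributional claims about real
worms.

## Image quantification

Stacks are (z, y, x), 0-based, 2 µm z-spacing, head along x with anterior at
low x (pose is standardized by the imaging geometry; no pose estimation).
The chain: per-pixel maximum projection over z → Otsu threshold (or fixed) →
connected components, area-filtered, split by local-maxima-seeded watershed
when cells touch → red-channel candidates split by anterior–posterior order
into NSM (anterior) and ADF pairs, green-channel pair = ASI, left/right by
y, surplus candidates flagged unknown → per cell, integrate the 250
brightest voxels in a 9×15×15 (z×y×x) box (z found as the argmax along the
detected (y, x) column) → for the gut-adjacent pairs (ADF, ASI), subtract
250 × the background mode, estimated as the densest histogram bin
(Freedman–Diaconis width, floored at 1 AU) in a 9×31×31 region; NSM is far
from the gut and is not subtracted. Per-pair readouts are the summed net
intensities of the two cells.

The synthetic generator places Gaussian-blob cells (σ = 0.7/1.1/1.1 voxels
in z/y/x, small enough that 250 voxels capture >99.8% of a cell) of
1.5–2.5×10⁴ AU total on a quadratic anterior→posterior autofluorescence ramp
(0.2 → 8 AU, emulating gut autofluorescence that rises toward the posterior
pairs) with clipped Gaussian read noise (SD 0.8 AU; blob peaks ≈500+ AU, so
SNR ≫ 10). Residual round-trip error (~0.5% median) comes from order-statistic
selection of noisy voxels and mode-bin quantization.

## Numerical choices and degenerate inputs

- Covariance ridge: ε·trace/d with ε = 10⁻⁶ added to the diagonal
  unconditionally — deterministic, negligible for healthy fits, and keeps
  nearly collinear folds invertible.
- Posterior underflow (all class densities zero): uniform posterior with a
  warning rather than NaN.
- Weibull MLE needs ≥5 deaths per food; Gaussian fits need ≥ d+2 complete
  rows per food; violations raise errors naming the offending food level.
- ml_assign ties go to the lower food index; with identical class densities
  this is exercised only on sets of measure zero in practice.
- Analysis problem sizes (120 animals/condition for decoding, 500 for
  lifespan-range estimates, 50 stacks for the imaging suite) give sampling
  errors comfortably below the effect sizes under study.

## Known limitations

- The decoder assumes Gaussian/Weibull class-conditionals; no
  goodness-of-fit testing is performed before decoding.
- Functional masking restricts columns of the mutant's own data; alternative
  definitions (e.g. masking wildtype data) would isolate the masking effect
  from the mutant's distributional changes and are not implemented.
- Accuracy estimates are lower bounds in the presence of measurement noise;
  no noise-deconvolution is attempted.
- Neuron identification relies on the standardized pose; flipped or rotated
  specimens beyond a left-right mirror are out of scope.
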