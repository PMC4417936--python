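# foodcode

How accurately does an animal's nervous system represent how much food is
around? In *C. elegans*, transcription of two conserved signalling genes in
three sensory/neurosecretory neuron pairs — *tph-1* (tryptophan hydroxylase,
serotonin) in NSM and ADF, and *daf-7* (TGF-β) in ASI — responds in a graded,
neuron-specific and partly non-monotonic way to bacterial food concentration,
and lifespan itself responds non-monotonically to the same food axis. This
package treats that system as a neural code and asks, quantitatively, how
well each readout (alone or in combination) encodes the food level, and how
mutations reshape the code.

`foodcode` provides, as a tested library plus numbered analysis drivers:

- **Synthetic study data** with the assumed statistical structure: per
  (neuron, food) Gaussian expression readouts (summed per-pair intensities),
  per (genotype, food) Weibull lifespans, across six food levels from 0 to
  10¹⁰ bacterial cells/ml and four genotypes (wildtype, *tph-1(−)*,
  *daf-7(−)*, double mutant).
- **A Bayes maximum-likelihood decoder.** For readout x and food classes
  f₁…f_K, class-conditional densities p(x|f) are fitted on training folds
  (multivariate Gaussian for expression, Weibull for lifespan); held-out
  animals get posteriors p(f|x) ∝ π_f · p(x|f) and are assigned to
  argmax_f p(f|x) under stratified 5-fold cross-validation. Results are a
  probability matrix (mean posterior mass per true food), an ML confusion
  matrix (assignment frequencies), and overall accuracy relative to the
  chance floor 1/K.
- **Expression statistics**: per-condition means normalized to the highest
  wildtype mean per neuron, dynamic range ΔF = max_f mean − min_f mean, and
  inter-individual variability σ (sample SD per condition).
- **Survival analysis**: Kaplan–Meier curves, per-food mean lifespans, the
  response *range* (max − min of per-food means) and food-independent
  *baseline* (their average), log-rank and Gehan–Breslow–Wilcoxon tests.
- **Image quantification**: maximum projection → threshold/watershed cell
  detection → geometric neuron identification → integration of the 250
  brightest voxels in a box per cell → mode-based background subtraction for
  the gut-adjacent pairs (ADF, ASI), validated on synthetic ground-truth
  z-stacks.

## Worked example

```python
import foodcode as fc

cfg = fc.default_config(n_per_condition=120, seed=1)
expr = fc.generate_expression(cfg, "wildtype")
results = fc.subset_sweep(expr, k=5, seed=1)
for subset, res in results.items():
    print("+".join(subset), round(res.overall_accuracy, 3))
```

prints

```
NSM 0.461
ADF 0.524
ASI 0.483
NSM+ADF 0.743
NSM+ASI 0.704
ADF+ASI 0.693
NSM+ADF+ASI 0.821
```

Each number is the cross-validated fraction of animals whose true food level
(of six, chance ≈ 0.167) is recovered from that readout combination: no
single neuron suffices (non-monotonic profiles make foods collide), while
the three-neuron combination decodes 82% of animals correctly. The same
decoder applied to mutant data shows the two opposing regulatory effects:
*tph-1* loss widens dynamic range and raises accuracy, *daf-7* loss inflates
variability and lowers it, and with only *functional* readouts considered
(e.g. just ASI in *tph-1(−)*) every mutant encodes worse than wildtype.

The numbered scripts under `analysis/` run the full study on synthetic data
(simulation → survival profiles → expression statistics → expression and
lifespan decoding → imaging round-trip) and write their tables under
`results/`. There is also a CLI: `foodcode simulate | stats | decode |
survival | imagesim | quantify | replica`.

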