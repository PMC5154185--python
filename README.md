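# ramforage

Analysis toolkit for an open-field radial-arm-maze (RAM) assay of spatial
working memory in bumblebees (*Bombus terrestris*). In the assay a forager
must visit eight artificial flowers arranged on a vertical circle and return
to the nest; a visit to an already-emptied flower (a *revisit*) is a working-
memory error. The package answers two questions:

1. **Do bees use spatial working memory at all?** Observed performance is
   compared with Monte Carlo null models: a *chance* forager that picks every
   flower uniformly at random, and a *chance + stereotypy* forager that moves
   according to the empirical flower-to-flower transition matrix (capturing
   memory-free heuristics such as moving to the nearest neighbour or flying
   upwards) but ignores which flowers it has emptied.
2. **Does an acute pesticide dose impair that memory?** Post-exposure
   performance across four dose groups (0 / 0.091 / 0.377 / 2.5 ng
   thiamethoxam per bee) is analysed with an all-subsets AIC workflow over
   {basic, size, treatment, treatment+size, treatment×size}: a
   negative-binomial mixed model for total revisits, a Cox proportional-hazards
   model for the choice index of the first revisit, a binomial mixed model for
   per-choice success, and a Gaussian mixed model for log time per visit, with
   Akaike-weight model averaging (w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)) of all
   models within 2 AIC units of the best.

Because the original behavioural records are not public, a first-class
synthetic-experiment generator reproduces the study design (7 colonies, 61
bees, group sizes 16/14/16/15, ten training bouts to asymptote, one
post-exposure test bout) with a dose- and size-dependent working-memory
impairment, so the entire inference pipeline is exercised and tested end to
end.

## Performance metrics

For each bout the package computes:

* **total revisits** — working-memory errors (chance expectation 8·H₈ − 8 ≈ 13.74);
* **correct choices before the first revisit** — the duplicate-free prefix
  length (chance ≈ 3.25); its choice index also yields a survival record,
  right-censored at choice 8 for error-free bouts;
* **correct choices in the first eight visits** (chance 8·(1 − (7/8)⁸) ≈ 5.25);
* **time per visit** — bout duration / number of visits (modelled on the log
  scale).

## Worked example

Run the complete pipeline on a synthetic experiment:

```sh
ram-forage run --synth --seed 1 --n-iter 200000 --out-dir demo
```

The validation stage (`demo/validation_comparison.csv`) compares the final
training bout of all 61 bees with the two nulls; observed means and 95%
t-intervals versus simulated means:

```
                      metric null_model  observed_mean  ci_low  ci_high  simulated_mean
              total_revisits          C          0.623   0.330    0.916          13.748
              total_revisits        C+S          0.623   0.330    0.916          11.446
correct_before_first_revisit          C          6.721   6.237    7.205           3.241
correct_before_first_revisit        C+S          6.721   6.237    7.205           3.928
      correct_in_first_eight          C          7.459   7.247    7.671           5.253
      correct_in_first_eight        C+S          7.459   7.247    7.671           5.581
```

Both simulated means fall far outside every observed interval, i.e. the
simulated bees beat both null models on all three metrics — the behavioural
signature of spatial working memory. The inference stage then selects among
the five candidate models per response; for total revisits
(`demo/revisits_selection.csv`):

```
         model     aic  delta_aic  weight  in_best_set
treatment+size 197.629      0.000   0.886        True
     treatment 202.917      5.288   0.063       False
treatment*size 203.343      5.714   0.051       False
          size 222.985     25.355   0.000       False
         basic 225.075     27.446   0.000       False
```

A treatment-containing model dominates (Akaike weight 0.89), recovering the
dose effect built into the generator. The survival analysis
(`demo/survival_averaged.csv`) reports model-averaged hazard ratios for the
first revisit; here the high dose gives HR 2.89 with 95% CI [1.22, 6.83] —
dosed bees revisit earlier. `demo/size_split.csv` repeats the count analysis
within small (≤ 5.46 mm thorax) and large (> 5.46 mm) strata, and
`demo/km_curves.csv` holds the per-group Kaplan–Meier step functions.

All outputs carry a `# provenance:` header (seed, config hash, version); the
pipeline is byte-for-byte reproducible for a fixed seed.

## Library use

```python
from ramforage import (build_flower_array, chance_policy, monte_carlo_null,
                       generate_experiment, total_revisits)

nulls = monte_carlo_null(chance_policy(), n_iterations=1_000_000, seed=42)
print(nulls["total_revisits"].mean)   # ~13.743

dataset = generate_experiment(seed=7)  # bees / visits / bouts tables
```

Subcommands `synth`, `metrics`, `simulate`, `validate`, `analyze` and `run`
expose each stage separately (`ram-forage --help`).

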