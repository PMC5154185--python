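# Methods

## The task and its null models

The assay is an open-field radial-arm maze: eight artificial flowers on a
circle in a vertical plane, ids 1–8 clockwise from the top. A bout ends when
all eight flowers have been visited (a hard cap of 10,000 visits guarantees
termination for pathological movement rules; cap-hit bouts are flagged
incomplete). Performance is summarised per bout by total revisits, correct
choices before the first revisit, correct choices in the first eight visits,
and time per visit (duration / visits). Time per visit divides by *total
visits*; a division-by-revisits variant exists behind a flag but is undefined
for error-free bouts, which is why it is not the default.

Two memory-free null models are simulated by Monte Carlo:

* **Chance (C)** — every choice uniform over all 8 flowers, self-transitions
  allowed (the literal reading of "equal probability for every flower"). A
  no-self variant (uniform over the other 7) is available via
  `allow_self=False`; the closed-form expectations quoted below hold for the
  default. Under C the metric means have exact forms: total revisits
  8·H₈ − 8 = 13.7429, correct-in-first-eight 8·(1 − (7/8)⁸) = 5.2511, and
  correct-before-first-revisit Σₖ Πⱼ₍₀..ₖ₋₁₎ (8−j)/8 = 3.2450. These are the
  oracles the engine is tested against (3 Monte Carlo SEs at 10⁵–10⁶
  iterations).
* **Chance + stereotypy (C+S)** — the first choice is drawn from the pooled
  empirical first-choice distribution and each later choice from the row of
  the pooled empirical transition matrix (estimated from every bee's final
  training bout, optional pseudocount smoothing; zero-count rows fall back to
  uniform with a warning). Visited status never enters. A C+S simulator with a
  uniform matrix is distributionally identical to C (tested).

Observed-versus-null comparison uses the mean of the observed bees with a
two-sided 95% Student-t interval (a percentile bootstrap is available via
`method="bootstrap"`); the report states whether the simulated mean falls
inside and in which direction the observed bees deviate (fewer revisits and
more correct choices are "better"). Total revisits is compared on complete
bouts only — an incomplete bout truncates the error count — while the other
two metrics use all bouts.

Stereotypy diagnostics operate on the pooled transition counts: the
*contiguity preference* is the proportion of transitions landing on an
angularly adjacent flower (chance expectation 2/8, or 2/7 without
self-transitions), and the *vertical bias* is the Spearman rank correlation
(mid-rank ties) between each of the 16 directed neighbour-pair frequencies and
that pair's travel angle from vertical (0° up, 180° down); negative rho means
an upward flight preference. Directed pairs with proportions-of-all-transitions
frequencies are the default; undirected pairs (8, folded angles) and
row-conditional frequencies are flags, since the original construction is
under-specified. Angles are rounded at 1e-9 degrees so that geometrically
equal chords tie exactly in the ranking.

## Synthetic experiments

The generator reproduces the study design: 7 colonies (round-robin
assignment), 61 bees in dose groups control/0.091/0.377/2.5 ng of n =
16/14/16/15, thorax widths from a truncated normal (mean 5.45 mm, SD 0.35,
bounds 4.4–6.2 mm, matching the reported 4.51–6.07 mm range), ten training
bouts and one post-exposure test bout.

Behaviour comes from a *memory policy*: with probability m (working-memory
strength) the base distribution is renormalised over unvisited flowers,
otherwise the base (uniform by default, optionally a stereotyped matrix) is
used unchanged. m = 0 is chance, m = 1 perfect revisit avoidance. Training
follows a saturating trajectory m(bout) = m_max·(1 − e^(−bout/τ)) with
m_max = 0.85, τ = 3, reaching asymptote by bout ten; colony heterogeneity is a
random intercept on the logit-memory scale (SD 0.3) — the only colony effect,
matching the random-intercept structure the statistical models assume.

Exposure degrades memory on the logit scale:

    logit(m_test) = logit(m_train) − γ·log1p(dose)·(1 + δ·(size − 5.45))

with γ = 1.4, δ = 0.5. The log1p transform makes the marginal effect saturate
between 0.377 and 2.5 ng (no dose–response shape is published; this is the
package's choice), dose 0 is an exact identity, and δ > 0 makes larger bees
more impaired. The defaults were calibrated once so that high-dose bees make
roughly 3–5 times the control group's revisits — the reported effect
magnitude — giving mean test-bout memory ≈ 0.82 (control) versus ≈ 0.45
(high dose, mean-sized bee).

Bout durations are n_visits × exp(N(μ₀ + β·(size − 5.45), σ)) with
μ₀ = log 20 s, β = −0.335 (the published size effect on log time per visit)
and σ = 0.3; μ₀ and σ are unpublished and were chosen as plausible bumblebee
flower-visit times. An optional per-visit quit hazard (default 0) produces
incomplete bouts so the completeness filter has something to filter.

What the generator does **not** emulate: learning within a bout, scent marks,
inter-bout memory carry-over, pharmacokinetics (the dose acts instantaneously
through a single scalar), or any colony effect beyond an intercept. Passing
tests therefore demonstrate that the pipeline recovers effects *of the assumed
form*, not that the biological dose–response has that form.

## Inference

All four responses share the all-subsets candidate set {basic, size,
treatment, treatment+size, treatment×size} (hierarchical models only), fitted
on the test bout and ranked by AIC; models strictly within 2 units of the best
form the best set and their coefficients are averaged with renormalised Akaike
weights. Averaging is *conditional* by default (a coefficient is averaged only
over best-set models containing it); *full* averaging (absent coefficients as
zero) is a flag and outputs label which was used. The unconditional standard
error is Σ wᵢ·√(seᵢ² + (bᵢ − b̄)²); intervals are Wald with z = Φ⁻¹(0.975).

* **Total revisits** — NB2 mixed model, log link, colony random intercept.
  Fitted by direct maximum likelihood with the intercept integrated by 15-point
  Gauss–Hermite quadrature (deterministic and more accurate than a Laplace
  approximation at these group counts).
* **Per-choice success** — binomial logit mixed model with bee nested in
  colony: nested 12-point quadrature (outer colony, inner bee). Complete
  separation (e.g. an all-success response) is detected at |β| ≥ 12 with
  coefficients held at the ±15 box bound and the fit flagged non-converged.
* **Log time per visit** — Gaussian random-intercept model; the marginal
  likelihood is closed-form (compound symmetry per colony, Woodbury identity)
  and maximised by ML — not REML — so AICs are comparable across fixed-effect
  structures.
* **First-revisit choice index** — Cox proportional hazards on event times
  2–8 with Efron tie handling (times are heavily tied), right-censoring at 8,
  maximised with an analytic-gradient BFGS. Colony enters as `strata` on
  request; the default includes no colony term — with 7 colonies and ~50
  events a frailty variance is barely identifiable, and "non-parametric Cox
  proportional hazards" reads most naturally as the plain model.

AIC parameter counts: fixed effects + 1 per random-effect variance + 1 NB
dispersion or Gaussian residual variance; Cox k = number of regression
coefficients (the basic Cox model is the null partial likelihood with k = 0).
Absolute AICs are therefore not comparable with values computed under other
counting conventions — only the procedure is. Non-converged fits are excluded
from selection (never imputed), with a logged warning.

Design matrices centre bee size at its sample mean. This is a pure
reparameterisation — likelihood, AIC, slopes and interactions are unchanged —
but it removes the near-collinearity between a treatment dummy and its
size×treatment column that otherwise sends interaction fits along a flat
ridge; treatment coefficients are effects at the mean size.

The size-split re-analysis partitions bees at 5.46 mm thorax width (≤ small,
> large), refits treatment and basic count models per stratum, and reports
ΔAIC = AIC(basic) − AIC(treatment) (positive favours treatment) with Wald
intervals on the treatment coefficients. Kaplan–Meier curves per dose group
use the product-limit estimator with Greenwood standard errors.

## Numerical and reproducibility choices

* Monte Carlo bouts are simulated in vectorised batches (all active bouts
  advance one choice per step); the batch and single-bout paths are tested to
  agree in distribution, and a fixed seed gives bit-identical sequences.
* Fixed-effect standard errors are conditional on the variance parameters at
  their ML estimates (central-difference Hessian of the profile), the usual
  mixed-model convention.
* Mid-rank Spearman correlation raises an error on constant input rather than
  returning NaN; `vertical_bias` surfaces that case as a missing rho with a
  warning.
* Ties at the ΔAIC = 2 boundary are excluded from the best set (strict "< 2").
* Every output CSV begins with a `# provenance:` comment (seed, config hash,
  package version); the pipeline is a pure function of (tables, config, seed),
  and an acceptance-suite test checks byte-identical outputs across repeated
  runs.
* Seeds for the pipeline's internal stages are derived from the master seed
  via `numpy.random.SeedSequence`, so stages are independently reproducible.

### Problem sizes used by the test and acceptance suites

Monte Carlo checks run at 10⁵ iterations (2×10⁵ in the acceptance script) —
the closed-form comparisons are at 3 MC SE, so larger runs only tighten an
already-passing band. Parameter-recovery checks use 50 replicate synthetic
experiments at four-fold group sizes for the effect arm and 50 replicates at
the design size for the no-effect arm; these sizes give the selection
frequencies comfortable margins over their thresholds (≥ 80% treatment-model
selection with the effect on; basic-model plurality and < 40%
treatment-model wins with it off).

## Known limitations

* The published real-data coefficient values and absolute AICs are not
  reproducible here because the raw behavioural records are unavailable; the
  package reproduces the printed *arithmetic* (weights from ΔAICs, intervals
  and hazard ratios from coefficient/SE pairs) exactly, and the procedure on
  synthetic data.
* The published vertical-bias correlation (rho ≈ −0.87) depends on pooled
  counts that were never released; the diagnostic is validated on constructed
  counts instead.
* The binomial model's bee-level random intercept is weakly identified with
  only 8 Bernoulli draws per bee; its variance estimate is noisy (the fixed
  effects, which selection and averaging use, are well behaved).
* Gamma shared frailty for the Cox stage was considered and rejected (7
  colonies is too few to estimate a frailty variance stably); stratification
  is the supported alternative.
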