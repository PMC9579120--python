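# Methods

`circmix` models continuous-report (delayed-estimation) visual short-term
memory data, in which a participant reproduces a remembered feature value
on a circular scale and the wrapped deviation between response and target
carries the signal. This note records the models implemented, the
numerical choices behind the fitting routine, what the simulator does and
does not emulate, and the known limits of what the package's own
simulation studies can show.

## Models

All models describe the distribution of a response θ̂ given the probed
target θ and (for swap-aware models) the non-probed feature values θ*_i.
Let φ_κ denote the von Mises density with mean zero and concentration κ.

**Two-component mixture** (target + guessing):

    p(θ̂) = (1 − p_u) φ_κ(θ̂ − θ) + p_u / 2π

**Three-component mixture** (target + swap + guessing): with n non-targets,

    p(θ̂) = (1 − p_u − p_n) φ_κ(θ̂ − θ) + p_u / 2π + (p_n / n) Σ_i φ_κ(θ̂ − θ*_i)

A single κ is shared by the target and swap components: at encoding the
participant does not yet know which item will be probed, so all items are
assumed stored with the same precision. The target-response probability
is always the complement, p_t = 1 − p_u (− p_n).

**Slots**: a re-parameterisation of the two-component model in which
guessing follows from a discrete capacity K: p_u = max(0, 1 − K/N) at set
size N, with κ free.

**Slots-plus-averaging**: identical to slots for K ≤ N. For K > N every
item is stored and surplus slots duplicate items; reporting averages an
item's m copies, shrinking its circular SD by √m. The copy counts are
floor(K/N) and floor(K/N)+1, with the fraction (K mod N)/N of items
holding the larger count. The averaged concentration is obtained by the
exact Bessel-ratio round trip κ_m = A⁻¹(exp(−sd(κ)²/(2m)))… i.e.
`sd_to_kappa(kappa_to_sd(κ)/√m)`, not a small-angle approximation. K is
treated as continuous during fitting; the (K mod N)/N copy split is
already continuous in K, so no additional interpolation is needed.

## Parameter estimation

Each participant × set-size × condition cell is fitted independently by
maximum likelihood. The negative log-likelihood is minimised by the
Nelder–Mead simplex started from every permutation of a fixed grid —
κ ∈ {1, 10, 100} crossed with p_u (and p_n) ∈ {0.01, 0.1, 0.4}, or
K ∈ {1, 2, 4} for the slots family — keeping the lowest converged
optimum, ties resolved by grid order. Nine starts for two-parameter
models, twenty-seven for the three-component model.

Numerical choices:

* The search runs on an unconstrained scale: log κ, log K, and an
  additive-log-ratio transform of (p_t, p_u, p_n). The simplex therefore
  never meets a hard boundary, and p̂ values can reach 0/1 only
  asymptotically.
* Densities are evaluated in exponentially scaled form,
  exp(κ(cos x − 1))/(2π·i0e(κ)), which is overflow-free to κ well beyond
  any fitted value.
* Convergence: absolute tolerance 1e−8 on the NLL and 1e−6 on the
  transformed parameters, at most 2000 iterations per start.
* κ is searched inside (1e−3, 100) by default. The upper bound is an
  identifiability guard: the unbounded likelihood admits degenerate
  "spike" optima — a near-zero-width component capturing a handful of
  near-identical errors, the circular analogue of Gaussian-mixture
  variance collapse — which at low trial counts (≲100) occasionally beat
  the interior optimum and wreck parameter recovery. κ = 100 is a
  circular SD below 6°, more precise than any published continuous-report
  estimate (empirical κ̂ rarely exceeds ~30), so the bound is inert for
  real data; it is a constructor argument for paradigms that need more.
* Cells in which no trial has a non-target (set size 1) fit the
  three-component model with p_n fixed at 0. In cells mixing set size 1
  with larger set sizes, the swap mass degrades to guessing on the
  non-target-free trials (a pragmatic choice; such pooled cells are
  better avoided by grouping on set size).

We verified on simulated data that the multi-start search attains the
global optimum: across hundreds of datasets the fitted NLL never exceeded
the best value of an exhaustive dense grid scan over (κ, p_u), nor a
restart from the generating parameters.

Model comparison uses AIC = −2LL + 2p, AICc (AIC with penalty factor
n/(n − p − 1), undefined for n ≤ p + 1), and BIC = −2LL + p ln n, with
differences oriented two-component minus three-component so positive
values favour the three-component model. Because the models are nested,
the AIC difference is bounded below by −2 (the penalty gap when the
likelihoods tie); any smaller value indicates an optimiser failure and is
flagged.

## Summary statistics

Per participant × cell, on the wrapped errors e = θ̂ − θ:

* mean absolute error — the arithmetic mean of |e| (a linear summary of a
  quantity bounded on [0, π]);
* resultant vector length R — modulus of the mean unit vector;
* precision — 1/sd − E[1/sd | uniform responding, same n], with
  sd = √(−2 ln R). The chance term is estimated once per trial count by
  seeded Monte Carlo (10,000 replicates of n uniform angles, fixed
  internal seed) and cached; values are therefore reproducible across
  calls and sessions. An analytic form for E[1/sd] is not available; the
  Monte-Carlo estimate may differ from other implementations in the third
  decimal for small n.
* bias — circular mean of the signed errors.

For axial data declared as `degrees_180` (e.g. bar orientations), angles
are doubled onto the full circle before analysis — the standard treatment
of axial data — so κ and R live in the doubled space, while the linear
error summaries (mean absolute error, bias) are halved back to the native
scale on output.

## Simulator

`simulate_mixtur` generates stimulus displays and model-based responses:

* Feature values sit on the integer-degree grid 1–360 (colour-wheel
  convention) and by default satisfy a **20° minimum pairwise
  separation**, the conventional discriminability constraint of
  continuous-report designs. Placement policies: minimum separation d
  (default 20); exact consecutive spacing d, the array ascending from a
  random start that is itself the probed item (so non-targets sit
  one-sided of the target); or unconstrained uniform sampling without
  replacement.
* Minimum-separation displays are sampled by construction rather than
  rejection: the consecutive gaps around the circle are d plus a
  uniformly random integer composition of the slack 360 − N·d, followed
  by a random rotation and random assignment of the probed position.
  Pairwise separation ≥ d is equivalent to consecutive gaps ≥ d, so this
  draws uniformly from the admissible configurations; naive rejection is
  intractable at e.g. N = 8, d = 40° (acceptance ≈ 4 × 10⁻⁷).
* Mixture components are allocated by **stratified counts**: each
  component receives round(p·n) trials (largest-remainder rounding),
  randomly interleaved, so the realised composition matches the
  parameters exactly rather than binomially. Swap trials imitate a
  uniformly chosen non-target; responses are von Mises draws around the
  chosen item (uniform for guesses).
* With a vector of set sizes, trials are split equally (remainder to the
  earliest) and randomly interleaved, and each parameter may be a
  matching-length vector.

What the simulator does **not** emulate: sequential dependencies between
trials, response times, ensemble/configural encoding, stimulus-specific
biases (e.g. colour-category attraction), and participant-level
heterogeneity beyond what the caller scripts. Passing tests therefore
certify the estimator against its own generative assumptions, not against
the full richness of empirical data.

## Simulation-study harnesses

The recovery harnesses draw per-dataset substreams from a single master
seed (`SeedSequence.spawn`), so runs are bit-for-bit reproducible and
order-independent. Generating parameters are uniform draws: κ ∈ (1, 16)
and p_u ∈ (0, 0.4) throughout; the swap rate p_n uses (0, 0.14) for the
trial-count study and (0, 0.4) — the same span as the other mixture
probabilities — for the model-recovery, set-size and similarity studies,
where the question is swap identifiability across its plausible extent.
Recovery quality is the product–moment correlation between generating and
recovered values, labelled poor (< .5), fair, good, or excellent (≥ .9),
boundaries rounding up.

### The swap-rate identifiability ceiling

A caution that falls directly out of these studies: the precision of any
p̂_n is limited by how distinguishable swap responses are from target
responses and guesses. With κ averaging ~8 and non-targets only a few
degrees from the target, the per-trial Fisher information for p_n is tiny;
no estimator can beat it. Concretely, with p_n confined to (0, 0.14) and
200 trials at set size 4, even an oracle handed the true κ and p_u
recovers p_n only to r ≈ .8; the joint maximum-likelihood fit sits near
r ≈ .63. Swap-rate conclusions from narrow-range, moderate-trial designs
should be treated accordingly (kappa and guess-rate recovery are
unaffected: r ≈ .93 and ≈ .87 in the same design).

### Problem sizes

The packaged acceptance script (`scripts/acceptance.py`) runs each
recovery design with 500 synthetic datasets and the model-recovery study
with 200 datasets per generating model; these sizes give correlation and
percentage estimates with Monte-Carlo standard errors of roughly .01–.03
and 2–3 points respectively, and complete on a single CPU in well under
half an hour.

## Known limitations

* The slots-family start grid (K ∈ {1, 2, 4}) and the continuous-K
  allocation rule are this package's own constructions; other
  implementations may parameterise slots-plus-averaging differently.
* Hierarchical/Bayesian estimation is out of scope; every cell is fitted
  independently, so participants with few trials get noisy estimates
  rather than shrinkage.
* No standard errors or confidence intervals on fitted parameters;
  uncertainty should be assessed across participants or by simulation.
* When guessing dominates (p_u ≳ 0.5), κ estimates become unstable — a
  property of the likelihood, not the optimiser — and fitted κ for such
  cells should be interpreted with caution, or the cells excluded.
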