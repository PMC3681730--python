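# Methods

## Generative model and inversion

The environment is a one-armed bandit emitting binary outcomes u(k). The
static perceptual agent entertains a two-level generative model: at
level 1 the outcome is caused deterministically and unambiguously by a
binary state x1; at level 2 a real-valued tendency x2 sets
P(x1 = 1) = s(x2) through the logistic function s, and x2 is assumed
constant across trials, so the prior over x2 at trial k is the carried
posterior from trial k − 1. The recognition density over x2 is Gaussian,
N(μ2, σ2).

Variational inversion with the Bernoulli log-likelihood expanded to
second order around the prior mean gives the closed-form trial update

    μ̂1(k)   = s(μ2(k−1))            predicted reward probability
    σ̂1(k)   = μ̂1(k)(1 − μ̂1(k))     prediction variance
    δ1(k)   = u(k) − μ̂1(k)          first-level prediction error
    1/σ2(k) = 1/σ2(k−1) + σ̂1(k)
    μ2(k)   = μ2(k−1) + σ2(k) δ1(k)

The update pair (μ2, σ2) is the exact minimiser of that quadratic trial
objective (`quadratic_trial_objective`; the test suite verifies this
against direct numerical minimisation to 1e−3 in μ2 and 1% in σ2).
Against the *exact* level-2 free energy

    F(k) = KL[ N(μ2(k), σ2(k)) ‖ N(μ2(k−1), λ(k−1)) ]
           − E_{N(μ2(k), σ2(k))}[ log p(u(k) | x2) ]

the closed form is a Laplace-style approximation whose optimum deviates
by O(σ³) — up to ≈0.11 in μ2 and ≈10% in σ2 at σ2 ≈ 1–2 (also
tested). The valence signal is always computed from the exact F, with
the Gaussian expectation taken by 64-node Gauss–Hermite quadrature
(halving the node count changes F by < 1e−12 on visited states; an
adaptive-quadrature oracle in the tests agrees to 1e−8).

## Valence, emotions, regulation

Valence is the negative first backward difference of free energy,
V(k) = −(F(k) − F(k−1)); it therefore telescopes: ΣV = F(first) −
F(last). The discrete derivatives used for emotion classification are
F′ ≈ −V(k) and F″ ≈ V(k−1) − V(k), both backward differences. Emotions
are undefined on the first two trials (two differences needed).

Quadrants of (F′, F″) give happiness, hope, unhappiness and fear as in
the table in the README. Relief and disappointment are *transition
states*: F′ has just crossed zero and is still very close to it. How
"very close" translates to discrete data depends on the sampling
regime, and the classifier exposes it as `crossing_band`:

- on a densely sampled smooth series the crossing step always has
  |V| = O(step), so any sign change is the transition state — the
  standalone classifier and the `annotate` command default to
  `crossing_band = ∞`. This yields the transition theorem verified in
  the tests: label changes from negative to positive emotions pass
  through relief, the reverse through disappointment.
- at trial resolution with binary inputs, valence flips sign with
  magnitude O(1) at every surprise; such a crossing is nowhere near
  F′ = 0 and belongs to the fear/hope quadrants. The trial-by-trial
  agent therefore uses `crossing_band = 0`. This choice is what makes
  the epistemic emotions (hope/fear) the carriers of post-surprise
  dynamics, and it is required to reproduce the reference
  uncertainty-by-class statistics; with an infinite band nearly every
  would-be hope/fear trial is labelled relief/disappointment instead
  and the epistemic cells of that analysis are empty.

Ties: |V(k)| ≤ eps is neutral surprise regardless of F″; a nonzero F′
with |F″| ≤ eps (steady change) maps to the factive label of the same
valence sign, reading steady change as settled belief. The dead-band
defaults to eps = 0 because binary-input trials essentially never
produce exactly constant F.

Regulation multiplies the freshly updated posterior variance by
exp(−(αV + τ)) before it is carried to the next trial — equivalently
the posterior's Gaussian entropy H = ½ log(2πeσ2) is shifted by
−(αV + τ)/2. The exponent constant (1, kept as the single named
constant `REGULATION_EXPONENT`) is pinned down by the mood-only fixed
point: with τ = −0.13, α = 0 and μ2 ≈ 0 the low-volatility baseline
variance is λ* = (e^{0.13c} − 1)/σ̂1, giving ≈0.56 for c = 1 — the
observed baseline — versus ≈1.19 for c = 2. V is undefined at trial 1
and treated as 0 there, so mood acts alone (mood is referent-free and
persistent). The admissible sensitiveness interval is α ∈ [0, 1].

Per-trial event order: predict → observe u → Bayesian update (σ2_pre,
μ2) → exact F → valence → emotion label → regulate σ2_pre to σ2_post →
carry (μ2, σ2_post). The regulated variance is the one a subsequent
trial sees as its prior, which is how valence acts as a learning rate;
it is also the quantity averaged in the uncertainty-by-class analysis
("after the elicitation of the emotion, before the next input").

## The comparison volatility learner

The dynamic perceptual agent replaces the static assumption with a
Gaussian random walk on x2 whose log step size is κx3 + ω, and a random
walk with step variance ϑ on the log-volatility x3. The trial update is
the standard variational inversion of this binary hierarchical filter
(precision-weighted prediction errors at levels 2 and 3; see the module
docstring for the equations). Defaults κ = 1.4, ω = −4.0, ϑ = 0.5,
μ3(0) = 1, σ3(0) = 1 were selected so that the filter tracks the
reference scenario stably and shows its two signature behaviours:
σ2 rising smoothly across the whole run (rank correlation with trial
index ≈ 0.93) and a more variable predicted-probability trace in the
replayed third stage than in the identical first stage. The level-3
precision update of this inversion can turn non-positive under extreme
surprise (roughly 10% of outcome sequences at these settings, and
almost always with substantially larger ω); this is raised as
`HGFUpdateError` carrying the trial index rather than silently clamped.

## The scenario generator

`build_reference_schedule` defines the study conditions: 320 trials —
100 at P(u=1) = 0.5 (stage `low1`), six blocks of 20 alternating 0.9
and 0.1 starting at 0.9 (stage `high`; a flag flips the block order,
which is otherwise underdetermined), and 100 trials at 0.5 (stage
`low2`) whose *outcomes* replay stage 1 bit for bit. The replay is
implemented by copying sampled values, not re-seeding, so it holds for
any generator. Outcomes are Bernoulli draws from a seeded NumPy
generator; realization r of a batch uses seed base_seed + r.

What the generator does not emulate: continuous or ambiguous inputs,
serial dependence within a stage, reward magnitudes, and any
action-dependence of sampling (the agents are passive observers).
Passing tests therefore certify the inference and regulation machinery
under the stated schedule, not behaviour on empirical choice data.

## Reference analysis

The uncertainty-by-class experiment runs 100 seeded realizations at
α = 0.4, τ = −0.13 and, per realization, averages σ2_post over trials
labelled hope/fear (epistemic) or happiness/unhappiness (factive) —
relief/disappointment and neutral trials belong to neither class —
within the low (stages 1 and 3) and high (stage 2) volatility groups;
across-realization means and SDs are taken over these per-realization
means, never over pooled trials. Cells with no qualifying trials are
excluded from the across-statistics and counted in `missing_cells`.
The low/high *margins* are statistics over the 200 stacked
per-realization class means, so both emotion classes carry equal
weight regardless of trial counts. Typical results (base seed 1):
epistemic 0.66/1.03 (low/high), factive 0.57/0.68, margins 0.61/0.85 —
epistemic above factive in both groups and high above low, the
signature that epistemic emotions accompany high estimation
uncertainty even though they are defined purely by free-energy
dynamics.

Problem sizes throughout — 320-trial runs, 100 realizations for the
class statistics, 25 for the ordering tests, five seeds for terminal
convergence — complete in seconds and match the reference analysis
sizes where one is stated.

## Known limitations

- Strongly negative mood (τ ≲ −0.3, especially with α near 1) is a
  runaway regime: the per-trial inflation e^{−τ} outpaces the maximal
  Bayesian shrinkage, uncertainty grows without bound and the tendency
  estimate saturates. Predictions are clipped a machine-epsilon margin
  from 0/1 so the arithmetic stays finite, but trajectories in that
  regime are scientifically meaningless (the model itself predicts an
  inverted-U of tracking performance in mood).
- Valence magnitudes are tied to this model's exact free energy; a
  different (e.g. quadratic) evaluation of F shifts the class
  statistics by a few percent.
- The emotion taxonomy is per hierarchy level; no fusion of concurrent
  emotions across levels into a single experienced label is attempted.
- The volatility learner is a qualitative baseline: its update scheme
  is one of several published variants and parameter values were chosen
  for stable behaviour, not fitted.
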