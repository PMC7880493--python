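# Methods

`itdppc` simulates the classic interaural-time-difference (ITD)
localization task and asks how a neural population can represent not just
the best ITD estimate but the *momentary uncertainty* about it — the
trial-by-trial width of the Bayesian posterior. This note documents the
models, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Generative model of the stimulus

Each trial presents two-eared white noise,

    s_R(t) = σ_S s(t)     + σ_N η_R(t) + σ_0 ν_R(t)
    s_L(t) = σ_S s(t − δ) + σ_N η_L(t) + σ_0 ν_L(t),

with five independent unit-variance Gaussian white-noise processes. The
common signal `s` is delayed by the true ITD δ in the left ear. Parameters:

| parameter | meaning | default |
|---|---|---|
| σ_S, σ_N | signal / external-noise amplitude | σ_S²+σ_N²=1; σ_N ∈ {0.25, 0.77, 0.9, 0.95} |
| σ_0 | internal (cochlear) noise amplitude | 0.9 |
| δ | true ITD | grid values in [−250, 250] μs |
| sample rate | — | 48 kHz |
| low-pass cutoff | receptive band of the owl | 8 kHz |
| duration | 1 ms (posterior/decoding work), 9 ms (tuning curves) | — |

The binaural correlation BC = σ_S²/(σ_S²+σ_N²) is the experimenter's
information knob; the four standard σ_N values give BC ≈ 0.94, 0.41, 0.19,
0.10. The internal noise is excluded from BC by definition.

Implementation choices:

* **Discretization.** One sample at 48 kHz is 1e6/48000 ≈ 20.83 μs, so the
  25-point delay grid spanning [−250, 250] μs sits exactly on integer
  sample offsets. One grid serves stimuli, observers and decoder classes;
  no interpolation anywhere.
* **Circular shift and circular filtering.** The δ-shift wraps around the
  stimulus buffer, and the 8 kHz low-pass is a zero-phase brick-wall mask
  applied in the circular frequency domain. Because circular shifts commute
  with circular filtering, the covariance algebra behind the observers is
  exact rather than approximate at the edges. After filtering, channels
  are rescaled by √(full band / kept band) so the per-sample variance
  remains σ_S²+σ_N²+σ_0².
* **Band manipulations.** For "low-pass only" / "high-pass only" stimuli
  the *external* components are restricted to the requested band by
  removing out-of-band content (in-band amplitudes untouched), while the
  internal noise keeps the full 8 kHz cochlear band — it arises downstream
  of the loudspeaker. This makes band-limited stimuli genuinely less
  informative (the in-band signal competes with broadband internal noise
  over fewer effective samples) while leaving within-band correlations
  identical to the original, which is exactly the regime that separates
  the normative OT model from the descriptive one. Default cutoffs in the
  experiment runner: 2 kHz (low-pass) and 6 kHz (high-pass, the owl's best
  ITD band).

## Ideal observers

Both observers reduce the stimulus to sufficient statistics: the circular
cross-covariance profile CC(δ) = Σ_t s_R(t) s_L(t+δ), the mean channel
energy V = (s_R·s_R + s_L·s_L)/2, and the sample count T.

**Known BC (pre-marginalization).** The Gaussian log-likelihood collapses
to a fixed positive scaling of the cross-covariance,
LL(δ) = σ_S²/(σ_eff⁴ + 2σ_S²σ_eff²) · CC(δ), with the internal noise folded
into σ_eff² = σ_N² + σ_0². The unit test verifies this against a dense
2T×2T covariance evaluation to 1e-8.

**Unknown BC (post-marginalization).** Integrating the nuisance amplitudes
out under a flat improper prior on the natural Gamma parameters gives

    LM(δ) = −(T/2)·log(1 − CC²/V²) + log P(γ₊ ≥ c) + log P(c ≥ γ₋),

with γ₊ ~ Gamma(T/2, rate (V−CC)/2), γ₋ ~ Gamma(T/2, rate (V+CC)/2). The
product of tail probabilities is a lower bound on P(γ₊ ≥ γ₋) for any split
point c. We take c as the **average of the two Gamma means**,
c = T·V/(V²−CC²): direct comparison with the exact tail probability (1-D
quadrature) shows this bound is within ~1.4 nats of exact at every
cross-correlation and finite everywhere, whereas the alternative split
c = T·CC/(V²−CC²) (exposed as `split_point="printed"`) is loose by tens to
hundreds of nats at small cross-correlations and exactly −∞ for CC < 0,
which would silence the model OT population at low BC. A unit test checks
the resulting posterior against 2-D quadrature over the (σ_S, σ_N) grid
with the matching improper prior density σ_S σ_N³(σ_N²+2σ_S²): the median
KL near the posterior mode is ≈ 0 at T = 32, with a heavy-tailed minority
of weakly informative trials where the bound's mode disagrees — the
approximation is only advertised as tight where the cross-correlation is
high.

Tail probabilities are evaluated in log space; where the regularized
incomplete gamma underflows double precision, series (lower tail) and
asymptotic (upper tail) expansions take over, so log-probabilities remain
accurate down to order −1e5. Log-likelihoods are floored at −700 before
normalization; cross-correlations at |CC|/V ≥ 1 (possible only for
degenerate inputs) are clipped with a logged warning.

Priors: a flat box over [−250, 250] μs (head-range default), an unbalanced
box over [−250, 500] μs, or a zero-centered Gaussian (scale 120 μs by
default — a front-weighted prior of the population-vector literature; the
scale is a free choice, results are insensitive to it within a factor ~2).

## Population models

**IC (cross-correlator bank).** Four raised-cosine bands tile log-frequency
from 0.5 to 12 kHz with cos/sin cross-fades, so squared transfer functions
sum to one below the cutoff (self-invertibility). Consequences, both tested
to 1e-6 or better: double-filter-and-sum reconstructs any band-limited
signal, and band-wise cross-covariances sum exactly to the broadband
cross-covariance. One model unit per (band, delay) computes
Σ_t g[(F_n∗s_R)(t)·(F_n∗P_δ s_L)(t)] with g a per-sample static
nonlinearity — half-rectification by default, with sigmoid and exponential
variants (their slope/threshold defaults are free parameters, exposed in
the call signature, not fitted). Pre-rectification the population is an
exact linear probabilistic population code (lPPC): a fixed readout
(uniform band weights × the known-BC scale) reproduces the observer's
log-posterior to machine precision.

**OT (marginalization stage).** Frequency convergence (band-summed CC),
divisive normalization by V, the marginalization nonlinearity LM, then a
circular convolution along the delay axis with a self-invertible
quadrature pair (transfer cos θ_k / sin θ_k, θ_k a linear ramp to π/2 —
about a two-grid-step smoother and its power complement), and a final
half-rectification. Pre-rectification the two 25-unit sub-populations
invert exactly back to LM, making the population an invariant lPPC: one
readout, valid at every BC. The additive normalization of LM entering the
OT stage is the bound's own (no extra offset); the rectification of its
negative values is the model's main information bottleneck at low BC.

**Descriptive comparison model.** Per-band normalized cross-correlation
(band CC divided by band energy), uniformly weighted across bands (the
original band weights are not published), half-rectified. By construction
it responds only to within-band correlations, so it is insensitive to
stimulus duration — the signature that distinguishes it from the normative
OT model.

## Decoding and scoring

The decoder is multinomial logistic regression over the 25 delay classes
whose per-trial target is the observer's *full posterior*, trained by
minimizing the mean KL(true ‖ softmax(Wr+b)) full-batch with L-BFGS
(gradient tolerance 1e-6, no regularization). One class column is pinned
to zero to remove the softmax shift degeneracy, and features are
standardized internally (an invertible reparametrization folded back into
the returned weights). Dirac-target (one-hot) training is available as the
traditional baseline and never beats probabilistic targets at equal data.
IC decoders are trained per BC; the OT decoder once across all BC.
Reconstruction quality is the percent information loss,
100 · mean KL(true‖decoded) / mean KL(true‖prior), on a held-out half of
trials (50/50 split stratified by condition).

Uncertainty estimators regress the observer's posterior log-variance on
scalar response features — population-hill width and gain per frequency
sub-population, each unit's rate ("generalized gain"), optional pairwise
products (capped at 300 random pairs to keep OLS well-posed) and a
gain/width ratio — by OLS on half the trials, scored by cross-validated R²
on the other half. Trials where a feature is undefined (all-zero
sub-population rates, possible at low BC under half-rectification) are
excluded, with the exclusion count reported. The decoded posterior's
log-variance runs through the identical linear-fit machinery as the
reference estimator. Posterior entropy can replace log-variance as the
target throughout.

## Benchmark scales and what the tests show

The acceptance script reproduces the headline numbers at full scale:
3,000 training + 3,000 held-out trials per (BC, δ) condition with 1 ms
stimuli (150,000 trials for the single-BC IC benchmark, 600,000 for the
pooled OT benchmark; about 10–15 minutes on one CPU). The test suite runs
the same pipeline at 500 + 500 trials per condition, where all measured
losses are already at their large-sample plateaus. Behavioral summaries
use 500 trials per (BC, angle) at 1 ms — the duration is not stated for
the original behavioral simulations; 1 ms keeps low-BC posteriors broad
enough to exhibit the front-bias/variability regime. Tuning curves use
9 ms stimuli and 60–150 trials per point.

Measured at these conditions: the rectified-IC information loss at the
lowest BC is ≈ 1.1% (below the ≈3% originally reported for this
architecture; the loss here is essentially all rectification — the
finite-data component vanishes because the exact-lPPC readout is recovered
by full-batch optimization, cf. the < 0.01% pre-rectification loss). The
pooled OT decoder loses ≈ 2.7% at the lowest BC, somewhat above the ≈1%
reported with the original (unpublished) smoothing stage; the gap traces
to how much of LM's negative range the quadrature pair pushes into
rectification, a free design element we deliberately did not tune. The
decoded-variance R² exceeds 0.95 at every BC for both models, and every
single-feature estimator falls well short of it, with generalized gain ≥
gain — the central dissociation.

## Limitations

* White-noise stimuli with flat spectra; no head-related filtering,
  natural-sound spectra, or non-uniform receptive-field topology.
* No Poisson spiking variability — response variability is entirely
  stimulus- and internal-noise-driven, which is what induces
  information-limiting correlations; adding private spiking noise would
  average away in large populations but is not modeled.
* The marginalized observer is an analytic lower-bound approximation,
  tight near the posterior mode and at high cross-correlation; its tails
  are too light on weakly informative trials.
* The smoothing stage of the OT model and the variant-nonlinearity
  parameters are free by design and deliberately left untuned; absolute
  information-loss values (not the orderings) depend on them.
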