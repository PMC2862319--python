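# Methods

This note documents the models, the estimation procedure, every default
that matters, the numerical safeguards, and what the synthetic experiments
do and do not demonstrate.

## Generative model

A recording of `p` channels is modeled as a doubly-stochastic point process.
A stationary hidden vector autoregression of order `m`,

    x(n) = −Σₖ A(k) x(n−k) + w(n),        w(n) ~ N(0, Σ),

carries all temporal and cross-channel structure (internally the
coefficients follow this innovation-form sign convention; user-facing
generative configurations are written in propagation form,
`x(n) = Σₖ B(k) x(n−k) + w(n)`, with `B(k) = −A(k)`). Each channel's
firing rate is a memoryless transform `λᵢ(n) = f(μᵢ + σᵢ xᵢ(n))` with `f`
exponential, square, or absolute value, and spike counts are conditionally
Poisson per time bin. Conditional on the rate path counts are exactly
Poisson; unconditionally they are over-dispersed — an intrinsic property of
the model class (and a limitation when matching strongly sub-Poisson data;
see below).

Assumptions: stationarity over the analysis window; a stable hidden MVAR
(all companion eigenvalues inside the unit circle, checked with a margin of
1e−9); Gaussian innovations; a *known* nonlinearity family (exponential or
square) on the estimation side.

### Identifiability convention

The factorization `λ = f(μ + σx)` leaves the scale of `x` free. We fix
`Var(xᵢ) = 1` for every channel: all scale lives in `σᵢ`. Estimated hidden
correlations are renormalized to a unit zero-lag diagonal, and generators
absorb the model-implied stationary standard deviation of each channel into
the `σᵢ` they use. Consequently, fitted propagation matrices are reported in
the unit-variance basis, i.e. `D⁻¹ B D` with `D` the diagonal of hidden
standard deviations — off-diagonal entries differ from the generating
values by the ratio of channel scales (about 20% for the bundled
two-channel example, under 4% for the trivariate ones).

## Estimation pipeline

1. **Binning.** Spike times to counts on half-open bins.
2. **Raw correlations.** `R̂(k) = (1/(N−k)) Σₙ c(n) cᵀ(n+k)` for
   `k = 0..K`; raw (non-mean-subtracted) moments, because the inversion
   formulas consume raw second moments. Negative lags follow from
   `R(−k) = R(k)ᵀ`.
3. **Zero-lag correction.** Subtract the Poisson delta term
   `diag(E[λ])` from `R̂(0)`; the corrected diagonal is the rate second
   moment `E[λᵢ²]`.
4. **Moment inversion.** Closed forms give `(μᵢ, σᵢ)` from
   `(E[λᵢ], E[λᵢ²])` for the exponential (lognormal moments) and square
   (Gaussian fourth-moment identity) families. The absolute-value family is
   generated and characterized (folded-normal moments, quadrature
   correlations) but deliberately not inverted; data generated with it are
   analyzed under the exponential assumption — the package's
   nonlinearity-mismatch experiment.
5. **Correlation predistortion.** Each lag/pair of rate correlations maps
   back to a hidden Gaussian correlation; out-of-image values (possible in
   finite samples) are clipped to the boundary and counted in the fit
   report.
6. **Regularization** (for non-Poisson data; see below).
7. **Yule-Walker solve.** One exact stacked linear solve over the
   block-Toeplitz lagged-state covariance; no iterative fitting. The
   innovation covariance follows from the prediction-error relation and is
   projected onto the PSD cone if sampling noise leaves it marginally
   indefinite.
8. **Order selection** (optional) by BIC,
   `BIC(m) = 2·log det Σ̃(m) + 2p²m·log N / N` with `N` the number of bins,
   scanned over `m = 1..m_max`, ties toward the smaller order.

Granger indices are computed on the fitted hidden-Gaussian correlation set:
reduced models (the target channel alone, the pair, or all-but-source) are
solved from sub-blocks of the *same* correlation matrix at the same order,
so the residual variances are directly comparable. In pairwise mode the
end-to-end analysis fits each pair's bivariate model separately — including
its surrogates — because that is what makes pairwise analysis blind to the
direct/indirect distinction: a bivariate model absorbs an indirect or
common-input influence into its direct coefficient, and nullifying that
coefficient removes the correlation from the null data. Conditional
(leave-one-out) mode works entirely within the single full-model fit.

### Surrogate significance testing

For each directed edge, the fitted model is copied with the target-from-
source propagation entries zeroed at *all* lags, spike trains of the
original duration are regenerated, refitted with the identical pipeline,
and the causality index recomputed; the empirical p-value uses the add-one
convention `p = (1 + #{F_null ≥ F_obs}) / (n_surrogates + 1)`. Two
robustness rules apply:

* Zeroing one connection of a near-unit-root fit can push the spectral
  radius past 1, which would void the test. The null model is then shrunk
  by scaling lag-`k` blocks with `sᵏ` (which scales every companion
  eigenvalue by `s`) to a radius of 0.95. Pass `stabilize=False` to get an
  error instead.
* A surrogate refit whose own spectral radius lands essentially on the unit
  circle (≥ 0.97) is a failed estimation with meaningless variance ratios;
  such draws are redrawn up to three times. The same criterion is visible
  for the observed fit in its report.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| bin width (population models) | 20 ms | 0.4 events/bin at 20 Hz; the per-lag noise of the correlation estimator scales as `(T·Δ)^(−1/2)`, and below ~5 ms bins 10-minute recordings cannot support coefficient recovery |
| bin width (network motifs) | 5 ms | must resolve the 10–15 ms synaptic delays (a delay inside one bin turns causal structure into instantaneous correlation, which Granger analysis cannot use) |
| rate CV (exponential generator) | 2.0 | predistortion SNR grows with `σ² = ln(1+CV²)`; large rate fluctuations are typical of cortical recordings |
| rate CV (square / absolute) | 1.3 / 0.7 | each family bounds the attainable CV (`√2` for square, `√(π/2−1) ≈ 0.755` for absolute); defaults sit safely inside |
| correlation window `K` | max(5·m_max, 50) | covers the order scan and the PSD check |
| order scan `m_max` | 10 | configurable |
| surrogates / α | 99 / 0.05 | standard permutation practice; optional Bonferroni flag, off by default |
| impulse-response horizon | 20 steps | the bundled models' kernels decay well within it |

## Regularization for non-Poisson data

Refractory spike trains violate the model's over-dispersion in two ways:
sharp negative peaks in the auto-covariance at short lags, and a zero-lag
count dispersion at or below Poisson. With `truncate=True` the pipeline
applies:

* **Dispersion reconstruction.** The rate variance is taken as 3× the peak
  positive autocovariance over lags 1–30 (floored at a rate CV of 0.25)
  whenever that exceeds the measured count dispersion. The factor errs
  deliberately toward over-estimation: an under-estimated `σᵢ` inflates all
  predistorted correlations toward the unit circle and destabilizes every
  downstream solve, whereas over-estimation only shrinks the correlations
  through a common monotone map, which the scale-free surrogate test
  absorbs.
* **Negative-peak truncation.** Covariances dipping below independence by
  more than three standard errors of the estimator are floored at the
  independence level; noise-level negatives are left untouched (flooring
  them would bias every pair toward positive coupling).
* **Domain rescaling.** If predistorted correlations still exceed the valid
  range, every `σᵢ` is inflated by the single smallest common factor that
  brings the candidate inside (exact for the exponential family, where the
  predistorted values scale as `1/(σᵢσⱼ)`).
* **Diagonal loading.** If the block-Toeplitz matrix over the lags the
  Yule-Walker solve consumes has a negative minimum eigenvalue, `|λ_min| +
  10⁻³` is added to the zero-lag block. The loading window is restricted to
  those lags: long unused lags carry only sampling noise and would inflate
  the loading; and the margin of 10⁻³ (rather than an epsilon) keeps the
  loaded system away from exact singularity. Loading magnitude, truncation
  counts and clip counts are all reported — they are the method's
  failure-mode telemetry.

## Order selection: scope of validity

BIC with `N` = number of bins selects the true order reliably when the
correlations are measured on the hidden process itself (Gaussian-stage
realizations; verified in the suite at `N = 6·10⁵`). On *spike-derived*
correlation estimates at the 10-minute study scale, the estimator noise
contributes per-order log-det gains that decay like `1/N` — the same rate
as the penalty — at roughly ten times its size, so the scan drifts to
`m_max` regardless of duration or bin width (verified empirically across
`N = 3·10⁴..2.4·10⁵` and several discretizations, including split-half and
cross-validated variants). Automatic order selection on spike data should
therefore be treated as exploratory; the bundled experiments use the
models' known orders, consistent with the estimation algorithm's stated
assumption that the order is given.

## The synthetic experiments

**Rate calibration.** The calibrated two-channel model is simulated for ten
minutes and the empirical mean rate compared with the 20 Hz target (the
acceptance script's `t3`).

**Nonlinearity mismatch (`t1`, `t2`).** The trivariate sequential model is
simulated at 20 Hz for ten minutes with a square (or absolute-value)
nonlinearity and fitted assuming an exponential one; a matched
exponential-generated dataset is fitted the same way, and the 20-step
impulse responses of the two fits are correlated kernel-by-kernel over the
kernels that are nonzero in the generating model. To isolate the effect of
the generating nonlinearity from sampling noise, all generators for a given
repeat share the hidden Gaussian realization and the per-bin uniform
variates (Poisson counts via inverse CDF). The measured mean correlations
are ≈0.95 for both mismatches at this scale. Two regimes bound the result:
in the infinite-data limit the mismatch bias alone leaves kernel
correlations of ≈0.99 at moderate rate variability, while at 20 Hz ×
10 min the finite-sample noise of the single-lag correlation estimator
dominates and no tested configuration (bin widths 5–40 ms, rate CV
0.45–3.0, full common-random-number coupling) exceeds ≈0.96. Reference
values near 0.995 therefore appear to require either substantially more
data or estimator variance-reduction beyond the per-lag method implemented
here.

**Structure recovery, population models.** Each bundled model (pair, chain,
fork) is simulated for ten minutes at 20 Hz and analyzed end to end with 99
surrogates at α = 0.05. Conditional analysis recovers exactly the
generating graphs; pairwise analysis flags the indirect chain edge and the
common-input edges as expected. One genuine refinement: in the fork, the
exact pairwise index of the *reverse* edge between the two driven channels
is small but strictly positive (≈0.02 nats; latent common input induces
bidirectional pairwise causality), and the surrogate test reliably detects
it at this scale — pairwise analysis on the fork yields four significant
edges, not three.

**Structure recovery, spiking networks.** Three Izhikevich motifs
(unidirectional pair, chain, fork) built from regular-spiking observed
neurons with one excitatory and one inhibitory balancing neuron each.
The background drive (diffusive pulse trains plus a slow Ornstein-Uhlenbeck
excitability current, τ = 25 ms) puts the cells in a fluctuation-driven,
irregular regime at 15–25 Hz; synapses are 11 mV delta jumps at 10 ms
delays (15 ms for the fork's second branch). Conditional analysis with the
regularization path enabled recovers all three motifs. These constants are
package choices tuned for clean structural ground truth, not a reproduction
of any published network.

### What these experiments do not show

The generators match the estimator's model class (except the Izhikevich
fixtures, which probe robustness). Real recordings add nonstationarity,
common slow modulations shared across channels, electrode artifacts, and
much deeper subsampling of the underlying circuit — none of which the
synthetic suites exercise. Passing them demonstrates internal consistency
and robustness to the specific violations modeled (refractoriness,
nonlinearity mismatch), not field performance.

## Numerical choices

* Yule-Walker systems are solved directly (`numpy.linalg.solve`) with a
  condition-number guard at 10¹²; an explicit error names the condition
  number when the correlation structure is ill-conditioned.
* Model-implied correlations solve the companion-form discrete Lyapunov
  equation (SciPy) and propagate by the state recursion.
* Simulation inner loops (the MVAR recursion and the Izhikevich Euler
  integration at 0.5 ms) are numba-compiled; everything else is vectorized
  numpy/SciPy.
* Burn-in of `10·m·p` steps from a zero state is discarded before every
  Gaussian simulation.
* Per-bin Poisson means above 100 raise an error when frequent (wrong
  discretization); isolated heavy-tail bins (≤ max(0.01%, 2 bins)) are
  clipped instead, with negligible statistical effect.
* Degenerate inputs fail loudly: sub-Poisson dispersion without a floor,
  moments outside a family's domain (named inequality), unstable models
  before any simulation, too few spikes (< 100 per channel) before any fit.

## Known limitations

* The nonlinearity family must be chosen, not estimated, and only the
  exponential and square families invert in closed form.
* Coefficients are identified only up to the per-channel scale convention.
* Automatic order selection is unreliable on spike-derived correlations at
  desk scale (see above).
* The surrogate test assumes the fitted model simulates well; for data far
  from the model class (strong refractoriness) the null is generated from a
  clean doubly-stochastic process and is only an approximation to the
  pipeline's sampling distribution on such data.
* Frequency-domain causality measures (directed transfer function, partial
  directed coherence) and exogenous-input or adaptive extensions are out of
  scope.
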