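# Methods

## Model

`cernacap` models a minimal competing-endogenous-RNA (ceRNA) circuit: two
RNA species m1 (the "competitor") and m2 (the "target") are transcribed
under the control of their own transcription factors and are both targeted
by one miRNA species mu.  miRNA-ceRNA complexes c_i form at rate k_i+ mu
m_i, dissociate at k_i-, and decay either *stoichiometrically* (rate
sigma_i, the bound miRNA is destroyed with the target) or *catalytically*
(rate kappa_i, the miRNA is recycled).  Free species degrade spontaneously
(d_1, d_2, delta) and are synthesised at b_i n_i and beta n_mu, where n is
the equilibrium promoter occupancy

    n(f) = f^h / (f^h + k_out/k_in),

a cooperative Hill function of the TF copy number f.  Promoter on/off
dynamics is taken to be fast relative to transcription, so occupancies are
frozen at this equilibrium and contribute no noise; RISC loading and other
intermediate steps are not modelled.  All rates are per minute, all
abundances are absolute molecule counts — no concentration units appear
anywhere.

### Steady state

Eliminating the complexes reduces the five coupled balance equations to a
threshold-linear form

    m_i = (b_i n_i / d_i) * mu0_i / (mu0_i + mu),
    mu0_i = (d_i / k_i+) * (1 + k_i- / (sigma_i + kappa_i)),

plus a single scalar balance for the free miRNA level that is strictly
increasing in mu.  The solver brackets this monotone function on
[0, beta n_mu / delta] and applies Brent's method (xtol 1e-14), then
verifies the residuals of the full five-species system (raising if the
relative residual exceeds 1e-8).  This scalar reduction is exact, needs no
damping or Newton steps, and cannot converge to an unphysical branch.

`mu0_i` is the soft repression threshold: ceRNA_i is *free* when
mu << mu0_i, *repressed* when mu >> mu0_i, and *susceptible* in between.
The classifier uses a configurable factor-of-10 band; the regimes are
qualitative and the band is a reporting convention, not a model parameter.

Where the free-miRNA level crosses mu0_i as the competitor's TF rises, the
ceRNA transits through maximal susceptibility.  With the packaged
cross-talk parameter set the level saturates at ~51.4 molecules, just
*above* the competitor's threshold mu0_1 = 50.05, so an exact crossing
exists only for the target; the package therefore also locates
susceptibility operationally as the peak of the copy-number Fano factor
along ln f1 (`experiments.fano_peak`), which exists for both species and
sits at ln f1 ≈ 2.49 (competitor) and ≈ 2.02 (target).

### Stochastic simulation

The network is simulated exactly with the direct Gillespie method over 14
elementary reactions (3 syntheses, 3 degradations, 2 associations, 2
dissociations, 2 stoichiometric and 2 catalytic complex decays).  The
inner loop is JIT-compiled (numba) and accumulates time-weighted first and
second moments of the full state vector on the fly, so stationary means,
variances and cross-covariances are obtained without storing paths.
Trajectory storage is available separately for export and inspection.

Defaults (overridable everywhere): burn-in 10x the slowest spontaneous
relaxation time 1/min(d1, d2, delta); sampling window 100x that time;
initial state the deterministic steady state rounded to integers (unbiased
at stationarity, shortens burn-in).  Replicate chains with seeds derived
from a master seed via `numpy.random.SeedSequence` provide across-replicate
standard errors; every output table records its seed.

### Linear noise approximation

Fluctuations around the fixed point relax as d(dx)/dt = A dx + eta with A
the analytic Jacobian.  The diffusion matrix is assembled channel by
channel, Gamma = sum_r a_r s_r s_r^T over the 14 reactions (propensity a_r,
stoichiometric vector s_r), which reproduces each elementary Poisson noise
amplitude together with its cross-species sign pattern; the construction
is validated in the tests against sampled cross-covariances, not assumed.
The stationary covariance solves A C + C A^T + Gamma = 0.  Two routes are
provided: a direct Lyapunov solve (default, recommended) and a spectral
evaluation via the eigen-decomposition of A,

    C = -B [ (B^-1 Gamma B^-T)_pr / (lambda_p + lambda_r) ] B^T,

whose index convention was fixed by requiring algebraic equality with the
Lyapunov solution (the two agree to 1e-8 on randomized stable systems, a
property test).  Near-defective eigenbases fall back to the Lyapunov path
with a warning; marginal stability fails explicitly.

### Channels and capacity

A regulatory channel maps a TF copy number to the target level m2: the
*miRNA channel* is TF1 -> m1 -> (titration) -> m2, the *TF channel* is the
direct TF2 -> m2 control.  Two performance measures:

- **AOV** (amplitude of variation): mean m2 at the top of the input range
  minus at the bottom.  Noise-blind.
- **Capacity**: in the small-noise Gaussian approximation the
  capacity-achieving input density is p_opt(f) ∝ sqrt((dm/df)^2 /
  (2 pi e var(f))) and the capacity is log2 Z with Z its normalisation.
  Z counts distinguishable output levels; Z < 1 is clamped to zero bits.

Numerics that matter here:

- *Derivative of the mean response*: monotone PCHIP interpolation for
  noise-free (deterministic/LNA) curves — an ordinary cubic spline
  overshoots at the flat ends of sharp sigmoids and manufactures spurious
  slope at zero input, where the variance also vanishes.  For
  simulation-estimated curves a smoothing spline weighted by the inverse
  standard errors is used, since the squared derivative amplifies jitter.
- *Quadrature of Z*: evaluated after the change of variables to output
  space, Z = int dm / sqrt(2 pi e var(m)), on a dense uniform output grid
  with the noise weight PCHIP-interpolated between the measured points.
  Input-space quadrature of the same integral needs a much denser input
  grid wherever the response is a steep sigmoid crossed by few grid
  points; the output-space form is exact for a linear response with
  constant noise and reproduces the closed-form Poissonian-channel
  capacity to 1e-3 bits (both are tests).  Doubling the input grid moves
  Z by < 0.5 %.
- *Zero-variance grid points* (a fully decoupled channel at zero input has
  m2 = var = 0 exactly) receive zero weight: with cooperative activation
  (h >= 2) the exact integrand vanishes there.
- *Non-monotone responses* are integrated via the total variation of the
  mean with a warning: log2 Z then upper-bounds the capacity.
- *Input grids* are log-spaced in f (responses live on a log input axis)
  with the f = 0 endpoint prepended when a range starts at zero occupancy;
  40 points by default.

For a channel with Poissonian output noise the capacity has the closed
form log2[2 (sqrt(m_max) - sqrt(m_min)) / sqrt(2 pi e)]
(`poisson_limit_capacity`), the ceiling a birth-death output can reach.

Two mutual-information cross-checks accompany the headline log2 Z: a
semi-analytic Gaussian-channel integral under any supplied input density
(the input grid is internally densified until adjacent conditional means
overlap within the noise scale, otherwise the output marginal develops
comb artifacts), and a 2-D histogram plug-in on sampled (f, m2) pairs with
Freedman-Diaconis bins.  The plug-in estimator is biased upward by roughly
(Kf-1)(Km-1)/(2 N ln 2) bits and saturates near log2(bins); it is a sanity
check, not the estimator of record.

### The omega rescaling

`rescale_omega` maps delta -> omega*delta and k_i+ -> omega*k_i+.  Because
the stationary free-miRNA level scales as 1/omega while the products
k_i+ mu are invariant, the mean response m2(f1) is preserved (exactly so in
the scalar reduction whenever dissociation/complex back-fluxes are
negligible against synthesis — the packaged scenario verifies those
smallness conditions explicitly).  Shrinking omega therefore inflates the
miRNA pool and weakens individual interactions at fixed output window,
isolating the titration-noise contribution: the target Fano factor falls
to the Poisson level and the miRNA channel's capacity climbs to the direct
channel's.

## Packaged study conditions

Seven preset families (`fig2`, `fig5`, `fig6`, `fig7A`, `fig7B`, `fig8`,
`fig9`) bundle the kinetic constants, operating occupancies and input
ranges of the scenarios the sweep driver reproduces; where a scenario
distinguishes the two channels, both variants are packaged.  All share
d1 = d2 = delta = 0.1/min, h = 5, k_out/k_in = 63300 molecules^5.  Two
documented tensions in the source tables are resolved as follows:

- The tables list a TF ceiling f_max = 30 while the sweep protocol defines
  the range by occupancy 0.99, i.e. f ≈ 22.88 (n(30) ≈ 0.9974).  Presets
  store both; input grids are driven by the occupancy ranges.
- In the fixed-output-window scenario (`fig9`) the printed TF-channel
  occupancy range (0, 0.99) cannot reproduce the stated common output
  window.  The TF range is instead reconstructed at run time
  (`matched_tf_occupancy_range`): the lower endpoint maps onto the miRNA
  channel's minimal output (11.5 molecules), the upper endpoint onto its
  maximal output, clipped at occupancy 0.9995 because b2/d2 = 220 sits
  0.6 molecules below that maximum.  The resulting amplitudes (209.1 and
  208.4 molecules) agree within the stated ±1.
- In the occupancy scan (`fig7`) both n1 and n2 are listed as (0.1, 0.9)
  ranges.  These are read as the grid of *pinned* operating occupancies —
  each channel sweeps its own input over the full (0, 0.99) range while
  the other promoter is held at its grid value.  This reading reproduces
  the published sign structure of the capacity difference (the
  post-transcriptional channel wins where b2 n2 > b1 n1 under weak
  catalytic decay, and where b1 n1 < beta n_mu for a strongly catalytically
  degraded target); reading the grid values as input endpoints inverts it.

On the critical balance line b1 n1 = beta n_mu of the `fig7B` scenario the
free-miRNA level is poised and the target output is dominated by titration
noise: the direct channel can show a large AOV yet zero capacity there, so
the otherwise-observed implication "post-transcriptional wins in capacity
=> wins in AOV" holds only off that boundary.

## Desk-scale choices

Sweeps default to reduced grids (5x5 parameter points, 40-point input
grids) with the LNA capacity estimator, which is deterministic (zero
capacity standard error) and agrees with simulation-estimated variances
within 10 % away from the susceptibility peak and 25 % at it (tested).
The simulation estimator — the protocol behind the published capacities —
is available everywhere via `estimator="ga"` and is what
`scripts/acceptance.py` uses for the headline channel capacities
(25-point grids, 4 replicate chains, 3000-min windows).  Full-resolution
grids are a flag away (`reproduce --full`).

## What the generator does and does not emulate

The model's stochasticity is intrinsic reaction noise only: synthesis at
occupancy-averaged rates, and unit-stoichiometry complexes.  Real
measurements add TF-binding noise, extrinsic (cell-to-cell) variability,
multi-site miRNA binding and RISC dynamics, none of which are represented;
passing tests therefore certify the titration-channel theory and its
numerics, not agreement with any particular experiment.

## Known limitations

- Steady state only; transient cross-talk is out of scope.
- Exactly two ceRNAs and one miRNA species; no network generalisation.
- Capacity is computed in the small-noise Gaussian approximation (no
  Blahut-Arimoto over the discrete channel); for strongly non-monotone
  responses log2 Z is only an upper bound.
- The LNA misstates variances near strong susceptibility (by construction
  of the linearisation); the simulator is the arbiter there.
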