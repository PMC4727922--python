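# cernacap

Stochastic modelling of miRNA-mediated ceRNA cross-talk, and the
information capacity of post-transcriptional versus transcriptional
control of gene expression.

## The problem

According to the ceRNA ("competing endogenous RNA") picture, two RNA
species that share a miRNA regulator are effectively coupled: activating
one of them titrates the shared miRNA pool away and *derepresses* the
other.  A transcription factor for the competitor thereby controls the
target through a purely post-transcriptional channel
(TF1 → ceRNA1 → miRNA titration → ceRNA2), in parallel with the target's
own direct transcriptional channel (TF2 → ceRNA2).  This package asks, in
quantitative terms, when the indirect channel can regulate as well as — or
better than — the direct one, treating both as noisy communication
channels and computing their capacities in bits.

It is aimed at systems/computational biologists studying small-RNA
regulation, titration circuits and information flow in gene networks.

## The model and the statistic

The circuit couples five species x = (m1, m2, mu, c1, c2) through
mass-action kinetics: synthesis at Hill-occupancy-scaled rates b_i n_i(f_i)
and beta n_mu, spontaneous decay (d_1, d_2, delta), complex
association/dissociation (k_i±), and complex decay with (kappa_i) or
without (sigma_i) miRNA recycling.  At steady state the target obeys a
threshold-linear law

    m2 = (b2 n2 / d2) · mu0_2 / (mu0_2 + mu),
    mu0_i = (d_i / k_i+) (1 + k_i- / (sigma_i + kappa_i)),

so the free-miRNA level mu acts through the soft threshold mu0 separating
free, susceptible and repressed regimes.  The package provides

- an exact steady-state solver (monotone scalar reduction + Brent);
- an exact Gillespie simulator (14 reactions, numba-compiled, on-line
  moment accumulation);
- the linear noise approximation: analytic Jacobian A, diffusion matrix
  Gamma assembled from the per-reaction Poisson noise channels, and the
  stationary covariance solving A C + C Aᵀ + Gamma = 0 (Lyapunov and
  spectral routes, cross-validated);
- channel-capacity machinery in the small-noise Gaussian limit: the
  optimal input density p_opt(f) ∝ |dm̄2/df| / √(2πe σ²(f)), the capacity
  I = log₂ Z with Z its normalisation, the Poissonian-channel ceiling
  log₂[2(√m_max − √m_min)/√(2πe)], and mutual-information cross-checks;
- preset study conditions and a sweep driver over binding rates,
  recycling rates, promoter occupancies, derepression amplitude, and the
  joint rescaling delta → ω·delta, k_i+ → ω·k_i+ that tunes titration
  noise at fixed mean response.

## Worked example

```python
from cernacap import capacity, optimal_input, response_curve, steady_state
from cernacap.presets import preset, input_grid, matched_tf_occupancy_range

# post-transcriptional channel, fixed-output-window scenario
ps = preset("fig9", "miRNA", omega=1.0)
grid = input_grid(ps.params, ps.input_range, 40)
curve = response_curve(ps.params, "miRNA", grid, estimator="lna",
                       occ_base=ps.occ)
opt = optimal_input(curve)
print(f"m2 range: {curve.mean[0]:.1f} -> {curve.mean[-1]:.1f} molecules")
print(f"I_miRNA = {capacity(opt):.2f} bits (Z = {opt.Z:.2f})")

# the matched direct channel
ps_t = preset("fig9", "TF")
rng = matched_tf_occupancy_range(ps, ps_t.params)
grid_t = input_grid(ps_t.params, rng, 40)
curve_t = response_curve(ps_t.params, "TF", grid_t, estimator="lna",
                         occ_base=ps_t.occ)
print(f"I_TF = {capacity(optimal_input(curve_t)):.2f} bits")
```

prints

```
m2 range: 11.5 -> 220.6 molecules
I_miRNA = 1.91 bits (Z = 3.76)
I_TF = 2.47 bits
```

Both channels sweep the same output window (amplitude ≈ 209 molecules
above a floor of ≈ 11.5), yet the direct channel resolves ~5.5
distinguishable target levels where the miRNA-mediated one resolves ~3.8:
the difference is the extra titration noise, which vanishes in the
weak-coupling / large-miRNA-pool limit (`omega_sweep` shows I_miRNA
climbing to I_TF and the target Fano factor falling to 1 as ω → 0).

A CLI wraps the same operations:

```
cernacap capacity --preset fig9 --channel miRNA --estimator lna
cernacap simulate --preset fig2 --f1 10 --t-end 5000 --seed 1 --out traj.csv
cernacap reproduce fig6 --reduced
```

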