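# Methods

## The binding scheme

Prothymosin α (P, net charge −44) and linker histone H1.0 (H, net charge
+53) form a fully disordered 1:1 complex PH with sub-nanomolar to
nanomolar affinity (K_D ≈ 0.7–1.2 nM at 200 mM ionic strength).  Despite
the high affinity, bound and unbound molecules exchange rapidly because a
second chain can invade the complex, forming short-lived ternary
complexes:

    P + H   ⇌ PH     k_on = 1.45×10⁹ M⁻¹s⁻¹,  k_off = 1.7 s⁻¹
    P + PH  ⇌ PPH    k_on^PPH = 0.53×10⁹ M⁻¹s⁻¹,  k_off^PPH = 1.9×10³ s⁻¹
    PH + H  ⇌ PHH    K_D^PHH = 12 µM, k_on^PHH assumed equal to k_on^PPH

The PPH lifetime of ~0.5 ms opens a concentration-dependent dissociation
channel (competitive substitution): a labeled chain bound in PH can be
displaced via PPH without ever passing through the slow unimolecular
k_off.  A PPH population of only ~2% of total H1 accelerates the observed
dissociation about 30-fold at 10 nM H1 + 100 nM competitor.

These six rate coefficients are collected in `RateSet`; the defaults
(`GLOBAL_FIT_RATES`) are the globally fitted values above.

## Coupled equilibria (`equilibria`)

The five-species equilibrium (P, H, PH, PPH, PHH) is solved by a damped
alternating fixed point on the free concentrations (c_P, c_H), each step
solving the analytic conservation quadratic for one free species given
the other, followed by one bracketed root polish on the H-conservation
residual (monotone in c_H, bracketed by [0, c_H_tot]); convergence is
1e-12 relative with both conservation laws checked to 1e-9.

Closed-form isotherms cover the experimental designs: the direct
titration with ligand depletion (quadratic root), the trace-labeled
competition (coupled dimer equilibria; the labeled species depletes
nothing), and the second-H1 titration of the saturated complex (same
quadratic with K_D^PHH).  The competition closed form is 0/0 at
degenerate parameter combinations (no competitor with equal affinities);
there the analytic limit via the free-H1 root is substituted.

The competition midpoint is defined as the point where the bound fraction
is 1/2 absolute, not half of the plateau; with equal affinities of
0.73 nM and 10 nM total H1 it falls at 18.5 nM competitor.

## Kinetic generators (`rate_models`)

Generators use the column convention dp/dt = K p.  Pseudo-first-order
entries use the bulk equilibrium concentrations of unlabeled species;
the labeled molecule is infinitesimally dilute, so the generator is
independent of labeled concentrations.  PPH dissociates to either
product pair with equal likelihood (the ½ branch factors); the doubly
H1-loaded complex carries the analogous factors when labeled H is
observed.  A consequence worth noting: the stationary distribution of
the labeled-molecule chain carries a statistical factor 2 on the P*PH
state — the labeled chain can occupy either of the two equivalent P
slots — so it is not the naive thermodynamic weight vector.

Mean dwell times of the low-FRET/high-FRET aggregates are computed from
the sub-generator fundamental matrix (entry distribution × mean
absorption times), which equals occupancy/outflux in steady state; the
closed-form rational expression for the three-state bound dwell is kept
as an independent route and the two agree to 1e-10 over random draws.

Two distinct "exchange rate" notions coexist and are both exposed:

- `exchange_rate` = 1/τ_low + 1/τ_high (dwell-based; what single-molecule
  dwell analysis and the recurrence fit measure);
- `slowest_relaxation_rate` = magnitude of the smallest nonzero generator
  eigenvalue (what bulk relaxations such as stopped flow measure).

The dwell-based rate also counts fast correlated recrossings through the
~0.5 ms ternary intermediate and exceeds the bulk relaxation rate by
25–45% at the relevant concentrations.  Stopped-flow forward models and
fits therefore use the eigenvalue; dwell-derived observables use the
dwell-based rate.

The global fit of the ternary coefficients holds (k_on, k_off) fixed at
their low-concentration values, shares k_on^PHH = k_on^PPH, and minimizes
the inverse-variance-weighted residual of all observed-rate records in
log-parameter space; records without an uncertainty are weighted as 10%
relative.  Identifiability is reported via the condition number of the
scaled Jacobian.

## Photon-by-photon likelihood (`photon_ml`)

The likelihood of a photon trace under two-state switching with
state-dependent Poisson emission is the standard product of per-photon
emission operators and inter-photon propagators exp[(K − n_D − n_A)τ],
propagated left to right with renormalization and accumulated log-norms.
For two states the propagator uses the closed-form eigendecomposition
(both eigenvalues real and negative), evaluated in a compiled kernel
(~17 ns/photon) so that joint fits over ~2.4×10⁷ photons stay fast; a
generic dense-expm route is the reference implementation and the two are
tested against each other and against a Taylor-series oracle.

Fitting maximizes the summed log-likelihood over shared
(k_on_obs, k_off_obs) in log space (Nelder–Mead, multi-start), with
per-trace emission rates initialized from a sliding-window intensity
split and refined per trace at the current kinetics (profile
maximization).  Bootstrap uncertainties resample whole traces with
replacement (20 rounds) and refit warm-started at the optimum.  Viterbi
paths use the same per-interval propagators in max-product form; trace
selection keeps traces with more than 4 Viterbi transitions.

## Bursts and recurrence (`burst_recurrence`)

Burst selection follows the two-pass protocol with strict thresholds:
photons separated by less than 30 µs merge into bursts; bursts with more
than 100 photons are cut into half-open 100 µs slices and slices with
more than 50 photons are kept.

Recurrence analysis (RASP) scans all burst pairs (not only adjacent)
whose start-to-start delay falls in a half-open window.  p_same(t), the
probability that the second burst comes from the same molecule, is
estimated from the excess of the observed pair rate over the stationary
Poisson background rate fitted from long delays, p_same = 1 − λ/ρ(t);
it is validated against ground-truth molecule labels in simulation
(agreement within ±0.1 across the delay grid).

The relaxation observable ⟨E⟩(t) is the area-weighted mean position of a
global two-Gaussian fit of the second-burst histograms (positions and
widths shared across delays, amplitudes free, restricted to the FRET
range so the asymmetric donor-only population does not interfere).  This
weighted mean is linear in the state populations, so it relaxes exactly
at the exchange rate; a single-Gaussian position on a bimodal blend is
biased low (by ~2× in our labeled simulations) and is retained only as
an option for the merged-peak regime.  ⟨E⟩(t) from bound-start and
unbound-start ranges is fit globally with one shared k_ex:

    ⟨E⟩(t) = (1 − p_same) ⟨E⟩_eq + p_same [⟨E⟩_eq + (⟨E⟩(0) − ⟨E⟩_eq) e^(−k_ex t)]

## Ensemble observables (`bulk_observables`)

FCS curves are fit with the 3-D Gaussian-focus diffusion model with
triplet blinking; the focal aspect ratio s can be fixed (calibrated) or
fitted.  Hydrodynamic radii scale linearly with diffusion time against a
reference complex.  Stopped-flow traces are fit single-exponentially
after max–min normalization and dead-time exclusion; degenerate
(offset-only) traces are flagged rather than fit.  Pulsed-field-gradient
decays use the Stejskal–Tanner attenuation with δ = 3 ms, Δ = 250 ms,
γ = 26752 rad G⁻¹s⁻¹, and R_H follows from the ratio against the
1,4-dioxane internal reference (R_H = 2.12 Å).

## NMR lineshapes (`nmr_lineshape`)

The transverse magnetization of one ¹⁵N resonance distributed over
(P, PH, PPH, PHH) evolves under (−iΩ − R₂ + K)·M with M(0) ∝ p_eq; the
FID 1ᵀM(t) is evaluated by complex diagonalization (expm fallback for
near-defective matrices) and Fourier-transformed by trapezoidal
quadrature with a Nyquist check.  The sign of the relaxation term is
chosen so relaxation damps the signal.  Frequencies are stored as
offsets from a carrier; the FID duration is 5/min(R₂) with 4×
oversampling.

Peak centers and widths come from Lorentzian fits of volume-normalized
projections after constant-background removal; bimodality (slow
exchange) is detected by prominent-peak counting and the single-peak fit
is then restricted to the dominant peak.  Bound-state shifts are
estimated by linear least squares of measured centers against the
population-weighted model with the free-state shift pinned to the
zero-titrant measurement; R₂ of all bound states is approximated by half
the saturating-titrant linewidth (backbone dynamics, not global size,
dominate the linewidth in these disordered complexes).

The central spectroscopic contrast is reproduced by construction: at
20 µM concentrations, dimer-only kinetics leave free H1 near K_D so
exchange is slow on the chemical-shift timescale (two static peaks),
while the ternary pathways push the exchange rate to ~10³–10⁴ s⁻¹
(one population-averaged peak).  The synthetic residue uses offsets
(0, 200, 150, 250) rad/s and R₂ = (8, 12, 12, 12) s⁻¹, representative of
¹⁵N shift changes of a fraction of a ppm; the experimental residue set
is not enumerated in the source data, so no attempt is made to
reproduce specific residues.

## PMF post-processing (`pmf_rates`)

1-D WHAM iterates the self-consistent histogram equations over harmonic
windows (overlap of adjacent windows is checked; the profile is anchored
to zero at the largest sampled separation).  The effective two-body
potential removes the radial volume entropy, F(r) = W(r) + 2k_BT ln r,
and is zeroed over the outer 10% of the range, which makes the derived
constants invariant to the arbitrary offset of W.

K_D and k_on follow by quadrature (trapezoid on an 8× locally refined
grid) of the association-volume integral and of the steady-state flux
onto an absorbing boundary at radius b with constant relative diffusion
coefficient D (sum of the monomer translational coefficients).  The
capture radius is the largest b at which |d ln k_on/d ln b| < 1% —
for a flat potential this sensitivity is 1 everywhere (k_on ∝ b,
Smoluchowski), so no plateau is reported, while an attractive funnel
plateaus at its outer edge.

## Synthetic data (`synthetic`)

Every consuming module has a generator with known ground truth and a
mandatory seed: exact Gillespie state paths; per-state Poisson photon
emission (15/5 kHz donor/acceptor unbound, 5/15 kHz bound by default for
surface-trace ensembles, with ~10% log-normal trace-to-trace brightness
jitter); free-diffusion burst experiments with Poisson molecule arrivals,
fixed 1 ms transits (100 µs in slice-resolved recurrence settings),
within-burst state averaging, binomial or Gaussian shot noise on E, an
optional donor-only (bleached-acceptor) population, and retained
same-molecule labels; stopped-flow relaxations from expm population
dynamics plus Gaussian noise; NMR titration projections from the
lineshape forward model; and umbrella windows sampled by inverse-CDF
from exp[−β(W + bias)] on a fine grid.  The umbrella sampler draws from
the biased density of the distance coordinate itself — W already
contains the radial volume entropy, which is why WHAM recovers W and the
2k_BT ln r term is added only afterwards.

Deliberate simplifications: no focal intensity profile (burst brightness
is piecewise constant), no detector dead time or afterpulsing, no
donor/acceptor photophysics beyond the static donor-only population, and
molecule re-entry statistics are exponential.  Passing recovery tests
therefore demonstrates estimator correctness under the stated noise
models, not robustness to instrument-specific artifacts.

## Problem sizes and tolerances

Recovery experiments run at the scale of the corresponding measurement
where that is tractable on a workstation: 40 traces × 30 s × 20 kHz for
the surface-kinetics recovery (≈2.4×10⁷ photons), 3000 bursts × 8
concentrations for the histogram titration, 12-point rate curves with 5%
noise for the global kinetic fit, 31 umbrella windows × 4000 samples for
WHAM.  Equilibrium solves are converged to 1e-12 relative; lineshape
quadrature is Nyquist-checked; WHAM iterates to 1e-8 in the window
offsets.

## Known limitations

- Oligomers beyond ternary complexes are not modeled.
- The two-state photon likelihood has a compiled fast path; ≥3-state
  likelihoods use the dense-expm reference route and are slower.
- The p_same estimator is a Poisson-background construction validated on
  synthetic ground truth; it is not a reimplementation of any specific
  published recurrence toolchain.
- Ionic-strength dependence enters only through user-supplied K_D values
  per condition; no activity-coefficient model.
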