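# Methods

This note describes the models implemented in `seepfate`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic environment does and does not emulate.

## Problem setting

A seafloor seep releases methane bubbles at a steady rate. Three
pathways compete for the methane:

1. **direct bubble transport** — gas still inside the bubble when it
   surfaces (minutes);
2. **ventilation** — dissolved methane mixed up to the surface and
   transferred to the atmosphere (days to months);
3. **biodegradation** — dissolved methane oxidised to CO2 and water by
   methanotrophic bacteria (days to years, depending on conditions).

Because the governing transport equation is linear in concentration,
the model works throughout with *fractions* of the released methane
rather than physical concentrations: the fate split of one bubble is
the fate split of the seep. Bubbles are assumed independent (small
seeps); plume effects, hydrate shells, horizontal transport and
atmospheric back-pressure are out of scope.

## Single-bubble model

State: moles of CH4, N2 and O2 in one bubble, integrated over depth as
the bubble rises (LSODA, relative tolerance 1e-10, with an event at the
0.05 mm diameter floor — below this the residual moles are deposited in
the current cell, which keeps the end-game integration non-stiff and
the mole balance exactly closed).

- **Gas density**: Peng-Robinson cubic equation of state, van der Waals
  mixing with zero binary-interaction parameters (acceptable for
  CH4/N2/O2 at shelf pressures), Peneloux volume translation from the
  Rackett compressibility. Vapor root of the cubic.
- **Solubility**: modified Henry's law. Temperature dependence by a
  van't Hoff factor; salting-out by a Setschenow factor with sea salt
  treated as NaCl-equivalent molarity. The driving concentration uses
  the component's partial pressure; at ≤ 300 m depth fugacity
  coefficients are within a few percent of one, so fugacity ≈ partial
  pressure. Ambient N2/O2 are at equilibrium with a moist atmosphere
  at surface pressure, applied uniformly over depth; ambient CH4 is
  zero (which, like the clean-bubble assumption, maximises
  dissolution).
- **Shape**: Eotvos-number thresholds — spherical below Eo = 0.25,
  spherical-cap above Eo = 40, ellipsoidal between. A 4.5 mm bubble in
  cold seawater is ellipsoidal (Eo ≈ 2.7).
- **Rise velocity**: Fan-Tsuchiya unified equation with the
  aqueous-solution coefficients (c = 1.4, Kb0 = 14.7, n = 1.6) for
  spherical and ellipsoidal bubbles — one formula across both regimes,
  so the regime boundary is exactly continuous and the small-diameter
  limit is the buoyancy-viscous closed form u = g Δρ d²/(Kb μ);
  Davies-Taylor for caps (≈ 6% jump at the cap boundary, bounded by a
  tested tolerance of 10%). At 4.5 mm, 7 °C, 34 ppt this gives
  0.258 m/s.
- **Mass transfer**: clean-bubble coefficients — a Johnson-type
  correlation for ellipsoidal bubbles, a potential-flow (Boussinesq)
  form with the Sh = 2 diffusive floor otherwise. Molecular
  diffusivities are 25 °C references scaled by Stokes-Einstein
  (D μ / T constant). The bubble is assumed thermally equilibrated
  with the ambient water (millimetre bubbles equilibrate in seconds).
- **Seawater properties**: EOS-80 surface density polynomial,
  Sharqawy-type viscosity and surface tension fits.

The deposition profile is binned by evaluating the dense ODE solution
at the transport grid's cell edges, so the per-cell fractions telescope
and (dissolved + surfaced) − released vanishes identically.

## Biodegradation kinetics

The tracer experiment adds tritium-labelled methane to natural
seawater; oxidation produces labelled water, measured after sparging.
The data model is first-order decay with no lag phase:

    C(t; T) = Ctot + (Cb − Ctot) · 2^(−t / t12(T)),
    t12(T) = t12_ref · Q10^(−(T − T_ref)/10),   Q10 = 2, T_ref = 5 °C.

Sterile controls observe Cb, pre-incubation samples observe Ctot, and
all observations share one Gaussian noise scale s_n = exp(ln σ).
Activities are normalised by the mean sterile-control background,
which provably does not affect the fitted half-life (tested).

- **MLE**: staged — bounded least squares over (t12, Cb, Ctot), noise
  scale from the residual variance, then a joint L-BFGS-B polish of the
  full negative log-likelihood. Standard errors from a
  finite-difference Hessian at the optimum; a singular Hessian (e.g.
  signal-free data) yields NaN standard errors rather than a silent
  number.
- **MCMC**: emcee's affine-invariant ensemble sampler, vectorised
  likelihood, uniform priors — t12 ∈ [0.25, 100] d; Cb, Ctot ∈ [0, 10×
  the largest observed activity] (the non-negativity prior needs finite
  upper bounds to be proper); ln σ ∈ [−10, 5]. Defaults: 32 walkers,
  5000 steps, 1000 burn-in, fixed seed. Convergence is reported (mean
  acceptance fraction, integrated autocorrelation time, a boolean
  flag), never silently ignored.

Simulation tests calibrate the machinery: noise-free data are recovered
to 1e-6, the 16-84 credible interval covers the truth in ≈ 68% of
repeated synthetic experiments, and a prior-only run returns the
uniform prior.

## Transport

Finite-volume discretisation of ∂C/∂t = ∂z(K ∂z C) − k1 C on 1 m
cells (matching the per-metre deposition reporting), diffusivity on
interior faces by linear interpolation of cell-centre values, zero-flux
seabed, surface flux j = kw C0 with

    kw = a U10² (Sc/660)^(−1/2),  a = 6.97e-7 s/m,  Sc = 677.

The atmospheric equilibrium concentration is set to zero: the
atmospheric methane partial pressure is assumed too small to retard
escape.

Numerics, in the order they matter:

- **Crank-Nicolson** (θ = 1/2) for diffusion + surface flux: second
  order in space and time (verified orders 2.00 ± 0.01 on an analytic
  decaying-cosine problem; a θ = 1 harness run is detected as first
  order), unconditionally stable, tridiagonal solves via LAPACK.
- **Decay by exact integrating factor**, applied symmetrically around
  the diffusion step. Because k1 is spatially constant the decay
  operator commutes exactly with diffusion, so this "splitting" has
  zero splitting error; decay-only problems are exact to round-off at
  any step size.
- **Exact discrete closure**: the step returns its biodegraded and
  ventilated masses using the same θ-averages as the update, so
  dissolved + biodegraded + ventilated + bubble = 1 telescopes to
  machine precision (observed ~1e-12 over 10^4 steps; the tested
  guarantee is 1e-9).
- **Rannacher start-up** (4 backward-Euler half-steps) damps the
  ringing Crank-Nicolson would exhibit on the sharply bottom-peaked
  deposition at diffusion numbers K dt/Δz² ~ 10². Residual negative
  values (if any) are clipped with a multiplicative rescaling that
  preserves the total exactly.
- **Time step** 0.01 d, with automatic sub-stepping if
  kw dt/Δz exceeds 0.5 (not reached at realistic winds).
- **Runs to depletion**: the environment's K and U10 are interpolated
  linearly in time between daily snapshots and wrap periodically past
  the end of the year; a run ends when the dissolved fraction falls
  below 1e-7 (then essentially everything is biodegraded or vented),
  and a configurable horizon turns non-termination into an error that
  reports the remaining fraction.

## Fate ensemble and diagnostics

A continuous seep is represented by 36 start dates at 365/36-day
intervals from 1 January, each run to depletion and averaged with
equal weights. The half-life sweep repeats this on a log-spaced grid
(default 25 points, 1-1000 d); the sub-criterion dissolved residue
(< 1e-7) is folded into the ventilated/biodegraded split pro rata so
the three reported fractions close exactly. The direct-bubble fraction
is constant across the sweep by construction.

The normalised ventilation rate v = Ṁ_atm / M (masked where the
dissolved inventory is below 1e-9) has the units of k1, and the
branching between ventilation and biodegradation is governed by their
ratio. For a permanently well-mixed column of depth H this reduces to
the closed form ventilated share = (kw/H)/((kw/H) + k1), which the full
solver reproduces within 0.2% across half-lives of 1-1000 d whenever
the mixing time H²/K is much shorter than both 1/k1 and H/kw — the
independent oracle used in the acceptance tests.

## Synthetic environment

The generator produces what the analysis consumes — K(z,t), T(z,t),
S(z,t), U10(t) on 1 m × 1 day grids — with the seasonal structure of a
mid-latitude shelf, not the turbulence physics that creates it:

- **Diffusivity**: a parametric two-layer field. Winter: homogenised at
  ~0.1 m²/s (to a finite winter mixed depth at the deep station, which
  is never fully homogenised). Summer (smooth ramps around days 120
  and 300): a mixed layer (~0.03 m²/s) whose base deepens from 15 m
  toward autumn, over an interior (~3e-3 m²/s shallow, ~3e-4 m²/s
  deep), separated by a flat-bottomed low-diffusivity band at
  1e-5 m²/s — the background internal-wave level. Two construction
  details matter and are deliberate: the seasonal blend is geometric
  (log-space), because an arithmetic blend lets the winter magnitude
  leak into and erase the pycnocline minimum; and the band is
  flat-bottomed over several metres, because a sub-grid dip would be
  short-circuited by face averaging. Values are capped at 0.2 m²/s.
- **Temperature/salinity**: deep values 7 °C / 34 ppt; surface 6-14 °C
  seasonal cycle and ~1 ppt summer freshening confined to the mixed
  layer.
- **Wind**: clipped AR(1), mean 8 m/s, standard deviation 3 m/s,
  day-to-day correlation 0.7 — only the magnitude and variability of
  kw matter to the fate split.
- **Station presets** at 65, 106 and 303 m span the shelf-depth range;
  the 303 m preset keeps a weakly mixed interior year-round (winter
  mixed depth 130 m, interior K an order of magnitude below the
  shallow stations).
- **Tracer simulator**: flasks at days 2, 4, 13, 17, 27 and 5 / 8.5 °C,
  truth at the laboratory posterior medians (t12 = 11.622 d,
  Cb = 0.461, Ctot = 3.883, ln σ = −0.133), Gaussian noise, plus
  sterile-control and pre-incubation samples.

**What passing tests do and do not show.** The synthetic fields
reproduce the *structure* that drives the fate split (seasonal
stratification, wind-driven exchange, depth), so qualitative and
structural results — conservation, branching logic, seasonal contrast,
near-total biodegradation at the deep stratified station — carry over.
They are not reanalyses of any real station: real diffusivity fields
have storm events, internal-wave intermittency and interannual
variability that the smooth parametric fields lack, so station-specific
percentages computed here are illustrative, not predictions.

## Problem sizes used

Unit and acceptance tests run the chain at the study configuration
(1 m cells, 0.01 d steps, 36-member ensembles) for the single deep
station, and on reduced configurations (25 m well-mixed column, few
members, small half-life grids) where a closed-form oracle or a
structural property is being checked and the full grid would add
nothing. The statistical calibrations use 50-100 simulated experiments
with shortened but convergence-checked chains.

## Known limitations

- First-order biodegradation with fixed k1: no coupling to bacterial
  abundance, no lag phase, no substrate limitation.
- Clean-bubble correlations overestimate dissolution; surfactant-coated
  ("dirty") bubbles would carry more methane to the surface. A dirty
  flag is reserved but unimplemented.
- No horizontal transport, upwelling or dilution feedback; Ceq = 0
  removes any atmospheric back-pressure.
- The Setschenow/NaCl-equivalent treatment of sea salt is adequate for
  fate fractions but not for high-precision solubility work.
- Single synthetic year; no climatological averaging.
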