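# Model and methods

## Membrane kinetics

Human atrial electrophysiology follows the Courtemanche–Ramirez–Nattel (CRN)
formulation: 12 sarcolemmal currents, 15 Hodgkin–Huxley-type gates, and
intracellular Na⁺/K⁺/Ca²⁺ handling with SR uptake, transfer and
Ca²⁺-induced release (21 state variables per node).  Two variants ship:

* **healthy** — the published 1998 parameter set with one adjustment,
  G_K1 = 0.117 nS/pF (up from 0.09), which tunes the working-myocardium
  action potential; the package's implementation reproduces the published
  model closely (steady 1 Hz APD90 = 297.6 ms with the original G_K1,
  vs ≈300 ms reported for the original).
* **cAF** — chronic-AF electrical remodelling layered onto healthy as
  explicit records: G_to ×0.15, G_CaL ×0.26, G_K1 ×3.5, I_CaL activation
  τ ×1.62, I_to activation shifted +16 mV, I_CaL activation −5.4 mV, I_Na
  inactivation +1.6 mV.  "G_K1 increased by 250%" is read as ×3.5 of the
  healthy 0.117 baseline (increase = addition of 250%); the multiplier is an
  ordinary config field, so ×2.5 or original-0.09 readings are one-line
  changes.  Voltage shifts act on steady-state curves only (V → V − shift in
  the gate's ∞-curve); time constants are untouched except the stated I_CaL
  τ scaling.  The −5.4 mV shift is applied to I_CaL *activation* (the plain
  reading of the remodelling recipe); the I_Na shift is applied to both
  inactivation gates (h, j) since they share one steady-state curve.

Known deviations of this faithful implementation from some quoted values
(all verified insensitive to stimulus protocol and to dt halving):

* healthy 1 Hz APD90 is 270–280 ms in 0D (steady state vs first beat) and
  ≈282 ms for a propagating wave, not 284 ms; the recalibration that the
  G_K1 change was part of appears to contain further unpublished
  adjustments.
* the cAF 1 Hz APD90 is ≈105 ms, hence a wavelength of ≈7 cm rather than
  ≈5 cm; a ≈5 cm wavelength would require APD90 ≈72 ms, unreachable with
  the printed modifiers under any G_K1 reading.

## ChR2 photocycle

Four states (C1, C2 closed; O1, O2 open), conductance g_ChR2·(O1 + γO2)
with inward rectification G(V) = (10.6408 − 14.6408 e^{−V/42.7671})/V
(voltage sensitivity lives only here), fixed closing/recovery rates
G_d1 = 0.1, G_d2 = 0.05, G_r = 0.004 ms⁻¹, light-driven openings
k1 = 0.8535·F·p and k2 = 0.14·F·p, open-state exchange
e12 = 0.011 + 0.005 ln(E_e/0.024), e21 = 0.008 + 0.004 ln(E_e/0.024)
(clamped ≥0, defined 0 in the dark), and adaptation
dp/dt = (S0(E_e) − p)/τ_ChR2 with S0 = ½(1 + tanh[120(E_e − 0.1)]).
Externally sourced constants (γ = 0.1, E_ChR2 = 0 mV, τ_ChR2 = 1.3 ms,
w_loss = 1.3) are flagged as such in the config provenance table.

**Photon-flux unit reconstruction.**  The flux F = 6×10⁻⁵·E_e·λ/w_loss
(per ms, λ in nm) is the standard retinal-cross-section × photon-flux
construction, and the numeric prefactor fixes the irradiance unit inside
the formula.  Taken literally in mW/mm² the photocurrents are two orders of
magnitude too small to produce *any* sub-threshold electrophysiology
(no resting-potential elevation, no APD modulation, and no stimulation
threshold below 1 mW/mm²); in W/m² the quoted working irradiances become
supra-threshold.  E_e entering the flux in mW/cm² — the conventional
optogenetics irradiance unit — is the only reading consistent with a
sub/supra-threshold boundary near 0.095 mW/mm², and is the default
(`irradiance_unit_scale = 100`, exposed in `ChR2Params`).  With it the
bisected threshold of the resting cAF cell computes to 0.096 mW/mm².
All other E_e-dependences (S0, e12, e21) use mW/mm² as printed.

With C_m = 1 μF/cm² the photocurrent density (mS/cm²·mV = μA/cm²) is
numerically the pA/pF current the ionic model consumes; the cylindrical
cell surface (100 μm × 16 μm, lateral area 5.03×10⁻⁵ cm²) is retained only
for whole-cell-current reporting.

## Numerics

Explicit monodomain integration at fixed dt = 0.02 ms: forward Euler for
voltage, concentrations and the photocycle, Rush–Larsen exponential updates
for all Hodgkin–Huxley gates, 5-point Laplacian (dx = dy = 0.022 cm,
D = 0.0023 cm²/ms, stability number D·dt/dx² = 0.095 ≤ ¼) with no-flux
(mirror) boundaries at edges and mask borders.  Reaction and diffusion are
summed in a single step (no operator splitting).  The production kernels
interpolate all voltage-dependent gate and current factors from tables
(0.05 mV spacing) built from the reference formulas, so the fast path and
the reference implementation cannot drift apart; a test bounds their
voltage discrepancy below 0.5 mV over an AP.  Reversal potentials are
refreshed every 0.5 ms (concentrations drift far slower).  Degenerate
formula points (removable singularities of α_m, α/β_xr, α/β_xs, τ_d, τ_w at
isolated voltages) use their analytic limits.  Integration aborts with the
offending node if V leaves [−150, 150] mV.

Convergence at the fixed step: halving dt changes the single-cell APD90 by
<1 ms but shifts cable CV by ≈1.5% — first-order stepping at dt = 0.02 ms
does not reach the sub-1% CV regime, which is worth knowing when comparing
CV values across steps.

Pacing stimuli default to 2 ms pulses at twice the diastolic capture
threshold (measured by bisection per parameter set; ≈25 pA/pF healthy,
≈33 pA/pF cAF); edge pacing uses the x < 4 node band.  2D point stimuli
need a supra-liminal nucleus (≈11×11 nodes at default D).

## Protocols and measurements

* **APD_X** uses the relative threshold V_th = V_max − X/100·(V_max − V_min)
  per beat window (windows split at the diastolic minimum between
  upstrokes), with linear sub-sample interpolation — hence invariance under
  affine rescaling of V.  Activation times are −40 mV upstroke crossings;
  CV is measured mid-cable between interior sites.
* **Wavelength** is CV × APD90 (the spatial excited extent behind a front is
  available as a cross-check estimator).
* **Optical threshold**: bisection on a 0.001 mW/mm² grid; "fires" means V
  crosses 0 mV within 500 ms of constant light from the dark-adapted rest.
* **S1–S2 restitution**: 10 S1 beats at 1 Hz, a state snapshot before the
  last S1, then one branch per S2; S2 placement targets diastolic intervals
  50–1000 ms (CI = APD90(S1) + DI).  The restitution slope is the maximum
  adjacent-point finite difference of APD90 vs DI; failed captures are
  flagged and excluded.  Reported slope values depend visibly on the DI
  grid spacing at the short-DI end, which likely explains the ≈2× spread
  against some published slope numbers (0.10 here vs 0.05 at
  E_e = 0.085 mW/mm²; the monotone increase with E_e is reproduced).
* **Phase scan**: the cell is paced to steady state in the dark, the
  unperturbed AP of a twin run defines both A0 and the repolarisation-level
  trigger times, then each branch applies one light pulse at its level.
  A1 is the Eq-style APD90 of the perturbed beat with V_max/V_min taken over
  the full paced cycle.  Under this convention the maximal prolongation of a
  100 ms, 0.092 mW/mm² pulse sits at ≈46% repolarisation (A1/A0 ≈ 1.55) and
  no shortening regime exists; a shortening minimum near 90% repolarisation
  can only arise from a V_min convention that includes the light-elevated
  post-AP baseline (a pulse arriving after 90% repolarisation cannot move an
  already-past threshold crossing physically).  The package keeps the plain
  convention and documents the difference rather than tuning to match.
* **Spiral tips** are intersections of the V = −40 mV isoline with the
  dV/dt = 0 isoline (frame differencing), merged within 3 nodes, linked by
  nearest neighbour; chirality is the sign of ∇V × ∇(dV/dt).  The core
  diameter is the minimum enclosing circle (Welzl) of the tip trajectory.
* **Conduction block**: per beat window, nodes that never cross −40 mV while
  ≥2 of their 4-neighbours activate within 50 ms of each other; contiguous
  nodes form one block line.  **Vulnerable window**: in 1D profile stacks, a
  window opens when one excited segment splits (a recovered gap bounded by
  excitation on both sides) and closes when the gap disappears; re-excitation
  of the gap marks direction reversal (re-entry).

## Reduced problem sizes

The full-scale experiments (512×512 sheet, 5 s; 512×512 + 1536×30 hybrid)
are expressed as shipped example configs but are multi-hour runs; the test
suite and the reproduction script work at sizes a workstation core handles
in minutes, chosen to preserve the physics being asserted:

* cable CV on the 512×10 cable exactly as specified (a single paced wave);
  wavelengths on a 1200×3 cable (26.4 cm ≥ the healthy wavelength), two
  beats approximating the 1 Hz steady state;
* the wavebreak-mechanism test runs on a 128×128 cAF sheet with D/2
  (halving D shrinks wavelength, core and front width by √2 while leaving
  0D kinetics — thresholds, APDs, photocurrents — untouched), where an
  S1–S2 cross-field spiral rotates stably in the dark at ≈11.3 Hz dominant
  frequency, matching the full-scale spiral's ≈11.5 Hz.

What desk scale does *not* show: the spiral-core diameter grows sharply as
E_e approaches the stimulation threshold, and in a domain of ~1 wavelength
illumination at 0.092 mW/mm² (pulsed at any width tried, or constant)
expands the core beyond the boundary and terminates the spiral within
~100 ms of light onset — before any wavebreak can form.  The
pulsed-light fragmentation (phase-singularity count rising above one)
observed at full scale therefore does not reproduce below roughly a
256–360-node domain at reduced D, which is outside a minutes-scale compute
budget; the corresponding suite check runs at the feasible scale and fails,
and is kept as a documented negative result rather than weakened.
Likewise the synthetic fixtures used by
the analysis tests (ideal square/triangle APs, rigid Archimedean spirals,
rectangular plane waves) validate the measurement operators' arithmetic,
not the PDE dynamics; passing them says nothing about real optical-mapping
data with noise, baseline drift or motion artefacts.

## Limitations

* Isotropic D, no fibre architecture, no 3D wall or depth-dependent light
  attenuation — the sheet stands for a layer inside the atrial wall
  receiving attenuated (hence sub-threshold) light.
* ChR2 kinetic rates are voltage independent by design (only G(V) senses V);
  no temperature dependence; single opsin.
* Deterministic membrane — no channel noise, so sub-threshold responses are
  sharp rather than probabilistic.
* The irradiance-unit reconstruction above is the package's choice; its
  justification is phenomenological consistency, and all light-dependent
  results inherit it.
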