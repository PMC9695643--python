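# Methods

## Scope and model

`phototherm` simulates photothermal therapy of a superficial squamous
cell carcinoma: a 1064 nm top-hat laser (radius 5 mm, normal incidence)
heats a four-layer skin phantom whose tumor (cylinder, radius 5 mm,
depth 2 mm, top face 0.1 mm below the surface) has been loaded with
gold nanorods. The computation has three coupled stages — nanorod
optics, Monte Carlo light transport, explicit finite-difference heat
diffusion — followed by volumetric dose metrics and a grid search over
treatment conditions.

The domain is a tissue cylinder of radius 15 mm and depth 20 mm,
voxelized on a Cartesian grid; voxels whose centers fall outside the
cylinder are inactive (no conduction across their faces). z increases
downward from the surface; each voxel owns the half-open box
[i·d, (i+1)·d) per axis and takes the properties of the layer
containing its center. Layer boundaries sit at cumulative depths 0.08,
0.58, 1.18 and 20.0 mm (epidermis, papillary dermis, reticular dermis,
subcutaneous fat); thermal properties of the tumor never depend on the
nanorod loading.

## Nanorod optics

For a dilute suspension the particles add

    mu_a,np = 0.75 f_v Q_a / r_eff,   mu_s,np = 0.75 f_v Q_s / r_eff

to the host coefficients; the composite medium is the element-wise sum
and keeps the host anisotropy g = 0.8 (loadings of 1e-6..1e-3 are far
too dilute to reshape the phase function). The efficiencies of the
default rod (r_eff = 20 nm, aspect ratio 6.67, 1064 nm) are not
computed electromagnetically; they are back-derived from the published
loaded-tumor coefficient table by a least-squares fit through the
origin, giving Q_a = 14.86 and Q_s = 3.14. A single pair reproduces
all four tabulated loadings to well under 2 % (the residual is printed
rounding); the 1e-6 column alone implies Q_a ≈ 14.75, which we treat
as rounding noise. The inline published form of the loading relation is
typographically ambiguous between multiplying and dividing by r_eff;
only division yields the tabulated magnitudes, so division is used.

## Monte Carlo light transport

Classic hop/drop/spin packet transport:

* hop: optical depth tau = −ln xi is walked voxel-by-voxel, each voxel
  consuming mu_tot × (path inside it), so heterogeneous media need no
  re-drawing at interfaces; a 1e-9 mm nudge avoids sticking on faces.
* drop: at an interaction the packet deposits ΔW = W mu_a/mu_tot into
  the local voxel.
* spin: azimuth psi = 2 pi xi; deflection cosine by the
  Henyey–Greenstein inverse transform (isotropic closed form at g = 0);
  the direction rotation is the standard norm-preserving form, with the
  degenerate polar branch for |mu_z| > 0.99999.

Termination is unbiased Russian roulette (threshold 1e-4, survival
probability 0.1, survivor weight ×10). The tally records the roulette
net (weight destroyed minus created, zero in expectation) so that
absorbed + escaped + roulette net = launched exactly — conservation is
an identity of the bookkeeping, not an approximation. Boundaries are
matched: no Fresnel or specular physics (the governing equations carry
no refractive indices); a configurable specular fraction exists as a
hook and defaults to zero.

Randomness comes from a stateless splitmix64-style counter generator
keyed on (seed, packet index, draw counter): bit-reproducible for a
fixed seed on any platform, trivially stream-parallel, and every
sampler consumes sequential draws.

### Two-grid transport

Transport runs on a 0.1 mm grid and the absorbed-fraction map is
block-summed onto the thermal grid (absorbed energy is extensive, so
the reduction conserves it exactly). This matters physically: the
0.08 mm epidermis scatters strongly (mu_s = 45/mm, g = 0.8), and on a
0.5–1.0 mm grid the surface voxel in the beam column is labelled tumor,
silently deleting that layer. Resolving it changes the picture
qualitatively — at f_v = 1e-6 the diffusely reflected fraction rises
from ~4 % to ~28 % and the tumor-absorbed fraction falls from 0.77 to
0.54. A thickness-weighted property-blending mode for the surface voxel
is available (`blend_surface`) but recovers only about half of the
backscatter, because mixing an absorber and a scatterer in one voxel is
not the same as stratifying them; it is kept as an option, default off.

## Heat diffusion

Pure heat conduction with the laser source,
rho c_v dT/dt = div(k grad T) + q; no blood perfusion (a known
limitation of this phantom model — in vivo, perfusion would sink
significant heat at these time scales). The explicit seven-point update
uses harmonic-mean face conductivities 2 k k_n/(k + k_n), which keep
fluxes continuous across layer interfaces. The source in a voxel is
A · P_l / (rho c_v V) with A the absorbed fraction and P_l the
instantaneous laser power; the pulsed schedule toggles it with heating
time tau_h = 30 s, cooling interval phi_c · tau_h, and total time 900 s.

Numerical choices:

* Time step: "auto" takes the explicit stability bound
  min rho c_v / (2k Σ 1/d²) over voxels, scaled by a safety factor of
  0.5, then rounded down so an integer number of steps fits each 1 s
  snapshot (0.5 s at 1 mm voxels, 0.125 s at 0.5 mm). The bound with
  the voxel's own k is conservative for harmonic-mean faces.
* Initial and far-field temperature 37 °C (body temperature; the
  published baseline traces make any other choice implausible).
* Boundaries: top surface adiabatic (air is a poor conductor and no
  convection coefficient is specified); lateral and bottom far
  boundaries clamped at 37 °C, approximating semi-infinite tissue. An
  all-adiabatic mode exists for energy-budget verification, where the
  total enthalpy gain must equal power × absorbed fraction × on-time
  to 1e-6 relative. A clamped (cooled) top surface was examined and
  rejected: it suppresses heating of the 0.1 mm-deep tumor so strongly
  that the published monitored-point traces become unreproducible.
* Temperatures stay in °C (diffusion is offset-invariant); material
  properties are SI internally; no phase change or property
  temperature-dependence — temperatures above 100 °C would be reported
  as computed.

Monitored points (on the beam axis, trilinear interpolation, clamped at
the surface): tumor at 0.1 mm depth, normal tissue at 2.5 mm depth
(0.4 mm beneath the tumor). The published phrasing is ambiguous between
depth below the surface and distance from the tumor center; with the
two-grid optics the below-surface reading reproduces the published
in-band interval (~20–70 s at f_v = 1e-3, 200 mW continuous; this
implementation gives 19–84 s on the 0.5 mm grid) and is adopted.

## Dose metrics

* theta_A(t): fraction of tumor volume with 43 °C ≤ T < 50 °C. The
  band is half-open: 50 °C is necrotic, not apoptotic. The denominator
  is the whole tumor volume. theta_A* is the trapezoidal time average
  over the treatment.
* theta_H(t): band-weighted mean damage indicator over normal tissue;
  theta_H* its time average. Weightings are named, versioned objects.
  The default, `graded-v1`, weights 37.5–39 °C at 0.05, 39–41 °C at
  0.1, 41–43 °C at 0.3, the apoptosis band at 1 and ≥50 °C at 2. The
  coarser `band-v1` (0 below 43, 1 in band, 2 above 50) ships as an
  alternative. Both are declared stand-ins for a tissue-response table
  that is not published with the study. `graded-v1` is the default
  because a hazard that is identically zero below 43 °C makes
  theta_eff* degenerate: over most of the power grid theta_H* is then
  exactly zero, the ratio saturates at the epsilon guard, and the
  optimum is decided by the guard rather than by any dose/hazard
  trade-off — inconsistent with the published description of a hazard
  that grows smoothly with laser power from low powers.
* theta_eff* = theta_A*/max(theta_H*, eps), eps = 1e-3.

For the sweep, metrics for all powers come from one unit-power solve:
the field at power P is baseline + P × unit rise (the PDE is linear and
the far boundary is clamped at the baseline), so each snapshot row is
sorted once and band counts for every power are binary searches. The
shortcut was spot-checked against direct solves (superposition holds to
1e-8 relative; a single-condition sweep matches a standalone pipeline
run within the float32 recording precision).

## Synthetic fixtures

`phantom.synth_temperature_series` builds deterministic fields —
baseline plus a sharp-edged spherical plateau with a piecewise temporal
profile — so every metric has an exactly countable ground truth. These
fixtures exercise the metric definitions (band edges, time averaging,
weighting bands), not the physics: they contain no diffusion, no
Monte Carlo noise and no grid-resolution effects, so passing metric
tests says nothing about transport or solver accuracy (those have their
own oracles: Beer–Lambert decay, exponential-integral quadrature, the
heat kernel, energy budgets).

## Study fidelity and reproduction

The shipped study scale (acceptance script and sweep-level tests) is:
thermal grid 0.5 mm, transport grid 0.1 mm, 1e6 packets per loading
(2e5 in the test suite), snapshots every 1 s, full condition grid
51 powers × 4 loadings × 6 duty cycles via superposition — roughly ten
minutes on one CPU. The published analysis states neither its spatial
discretization, time step nor packet count, so cell-exact agreement of
optimum coordinates is not guaranteed at any particular fidelity; at
this one the apoptosis-retention optimum lands at (180 mW, f_v = 1e-6,
phi_c = 0.5) against the published (200 mW, 1e-6, 0.5) — one 20 mW grid
cell — and the effective-ratio optimum under `graded-v1` lands at
(140 mW, 1e-5, 0.5) against the published (160 mW, 1e-5, 0.5). Under
`band-v1` the effective-ratio optimum is guard-dominated and moves to
(80 mW, 1e-3, 0), which is the main sensitivity of the pipeline to the
hazard stand-in.

## Known limitations

* No blood perfusion, metabolic heat, or temperature-dependent
  properties; no vaporization physics above 100 °C.
* No refractive-index mismatch (Fresnel/total internal reflection);
  matched boundaries likely understate fluence retention slightly.
* The hazard weighting is a stand-in; theta_eff* optima shift with it
  (theta_A* optima do not).
* Layered-slab anatomy with a cylindrical tumor; no curvature,
  vasculature or heterogeneity within layers.
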