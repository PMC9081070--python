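# Methods

This note records the physics, numerics and design choices behind the
package, at the level a maintainer or reviewer needs to judge what the
computations do and do not show.

## Geometry and discretisation

The modelled module is a monolithic CZT slab (default 39 × 39 × 5 mm,
600 V bias, relative permittivity 10.9) with a continuous cathode on the
source-facing side (depth z = 0) and a 16 × 16 array of square anode pads
(2.46 mm pitch, 1.86 mm pads) on the other. The charge-transport problems
are solved not on the whole crystal but on an odd N × N anode
neighbourhood centred on one selected anode — the anode pattern is
periodic, so the map for one central anode, translated, serves all of
them. Nodes are cell vertices with inclusive endpoints; a node belongs to
a pad when its lateral distance from the pad centre is at most half the
pad size in both axes (closed set), which makes the labelling
deterministic. The lateral step must divide the pitch exactly (no silent
snapping — an incommensurate step raises an error); the depth step is the
nearest value dividing the thickness. Since the electric potential, the
weighting potential and the CIE of the central anode are mirror-symmetric
about its two lateral mid-planes, the solves run on one quadrant
(requiring pitch/step even so the mid-plane is a node plane) and are
unfolded by reflection; the cut faces carry zero-normal-gradient
conditions, which is exact for symmetric problems and is verified against
full-grid solves in the tests.

Sign convention: the cathode is the negative electrode. We hold it at
−bias with the anodes grounded, so ∇φ points from cathode to anode and
electrons drift anode-ward with the advection signs used throughout. The
field magnitude (bias/thickness for the uniform alternative) is unchanged
by this choice.

## Potentials

With space charge taken as negligible, both the electric potential φ and
the Shockley–Ramo weighting potential φ_k are Laplace problems with a
seven-point finite-difference stencil; homogeneous Neumann faces use
mirror ghost nodes, Dirichlet rows are identity (and electrode values are
re-imposed exactly after the solve). Systems are solved directly below
40 000 unknowns and with lgmres (incomplete-LU preconditioned, relative
residual 10⁻⁸) above; the tolerance is ours.

The anode-side gaps are not specified by the hardware description, so
alternatives are provided and selected by tuning:

- **A1** — uniform field, φ linear in depth.
- **A2** — Laplace solution, zero normal gradient on gaps and on the
  lateral outer boundary of the patch (the outer-boundary condition is
  our choice, consistent with the symmetry treatment; it is not
  hardware-specified).
- **A3** — convex combination a3_weight·A1 + (1 − a3_weight)·A2, one
  tunable parameter.
- **B1** — weighting potential with zero normal gradient on gaps.
- **B2** — Dirichlet gap values from an inverse-distance-weighted
  transition between the selected pad edge (value 1) and the nearest
  other pad edge (value 0): with t the fractional position along the gap
  and u = t/b2_scale clamped to [0, 1], the gap value is
  (1−u)^p / (u^p + (1−u)^p). The power p sets the steepness of the
  lateral CIE edge and b2_scale the fraction of the gap at which the
  potential reaches zero ("width" of the sensitive area); two tunable
  parameters. This reconstruction matches the stated purposes of the
  approach; the original's exact formula was not available to us.

Both φ_k ∈ [0, 1] (discrete maximum principle, clamped at the 10⁻⁸
level) and the partition of unity (all electrodes' weighting potentials
summing to one) hold to solver tolerance and are tested.

## Charge transport and the CIE

Carrier parameters are the customary mobility (cm²/V·s) and lifetime
(µs); the diffusion constant defaults to the Einstein relation
D = μ·kT/q at 293 K (0.02525 V) and can be set to zero for closed-form
checks. Defaults: electrons μ = 1000 cm²/V·s, τ = 3 µs (μτ = 3·10⁻³
cm²/V); holes μ = 80 cm²/V·s, τ = 0.5 µs — mid-range literature-style
values for detector-grade CZT; in any real application these are tuning
parameters, not constants.

The charge induction efficiency η_k(r) is obtained from one steady-state
adjoint solve per carrier: 0 = ±μ∇φ·∇x⁺ + ∇·(D∇x⁺) + G⁺ − x⁺/τ with
G⁺ = μ∇φ·∇φ_k, advection sign positive for electrons and negative for
holes, x⁺ = 0 on absorbing electrodes, zero normal gradient on
insulating surfaces. Numerics: first-order upwind differences for the
advection with nodal coefficients (face-averaged and nodal coefficients
agree for the uniform-field alternative and differ at O(h) otherwise;
nodal keeps the operator an M-matrix), mirror-Neumann Laplacian for
diffusion, internal units mm/V/µs.

Three deliberate choices here deserve explanation:

1. **Blocked-flux source masking.** The uniform-field alternative drives
   charge into the insulating gap surfaces, where the upwind scheme
   blocks the flux and the charge parks. A parked charge induces no
   further signal, but the nodal source μ∇φ·∇φ_k keeps counting; without
   correction the gap columns accumulate a spurious lifetime-limited
   induction τ·G⁺ (an order of magnitude above 1 on coarse grids). We
   therefore zero each axis component of the source at nodes where that
   axis's upwind neighbour is missing. The direct oracle applies the
   same mask, keeping the two discretisations exact transposes of one
   another; interior nodes are unaffected.
2. **Negative lobes are clamped, not fatal.** The net induction on the
   selected anode from a charge that starts inside its
   weighting-potential spillover but is collected on a neighbouring pad
   is genuinely negative (φ_k(end) − φ_k(start) < 0, magnitudes up to a
   few times 0.01 near neighbour pads). The CIE map is defined on
   [0, 1], so negative values are clamped to zero when the map is
   formed; only values below −0.5 — beyond any weighting-potential
   spillover — are treated as a scheme failure.
3. **Electrode conditions without diffusion.** With diffusion active,
   x⁺ = 0 is imposed on all ohmic electrode surfaces. With diffusion
   disabled the pure-advection problem admits no condition on the
   adjoint outflow electrode, and imposing one there would contradict
   the nonzero Hecht value at the cathode; the zero condition is then
   applied only on the carrier's collecting electrode(s). The practical
   consequence is visible in CIE depth profiles: with diffusion on, the
   single cathode-plane node is pinned to zero (a sub-micron physical
   boundary layer that the grid cannot resolve); events generated in the
   bulk are unaffected.

Signal modes: C1 uses electrons only (two tunable parameters, μ_e and
τ_e); C2 adds the hole component with the hole μτ product tunable and
the hole mobility fixed (three parameters). The combined map is clamped
to [0, 1].

Verification is by two independent oracles. The Hecht closed form
η = (λ_e/L)(1 − e^{−(L−z)/λ_e}) + (λ_h/L)(1 − e^{−z/λ_h}), λ = μτE,
pins the parallel-plate/no-diffusion limit (the adjoint solution matches
to 0.41% at a 0.1 mm step — pure first-order upwinding error, shrinking
with the step). The direct oracle explicitly time-steps the forward
continuity equation from a point deposit (conservative upwind fluxes,
explicit Euler under a CFL check) and accumulates the Shockley–Ramo
integral; on a 21³ toy grid adjoint and direct agree to better than 1%
at sampled points. The oracle is never used in production paths.

CIE maps persist in a versioned little-endian binary container (magic
string, axis lengths, axis coordinates, C-order float64 array, JSON
metadata block with the generating parameters); the format is ours.

## Listmode data and the synthetic generator

Histories are chains of interaction events (photoelectric, Compton,
elastic; position, deposited energy, variance-reduced weight) tagged
with the emission line and a transport class (collimated primary,
phantom scatter, septal penetration, collimator scatter, collimator
x-rays, other). The binary container uses fixed 54-byte records plus a
plain-text dialect for fixtures; the reader streams and tolerates
unknown class codes (mapped to "other"). Files from an external photon
transport code can be converted to this layout.

The built-in generator is a *statistical stand-in*, not a transport
code: class mixtures, septal penetration factors and attenuation
coefficients are inputs, not predictions. Per history it draws the line
by intensity and the class by the configured mixture; collimated
primaries sample the source-disc projection thinned by the matched
collimator's hole-aperture transmission (square LEHR holes, circular
MEGP holes inscribed in the anode cell, penetration factor over septa),
other classes near-uniform over the crystal; the interaction depth is a
truncated exponential with a log-log-interpolated CZT attenuation table
(order-of-magnitude values above the Cd/Te K-edges: 7.8/mm at 40 keV
down to 0.16/mm at 250 keV); the chain is a single photoabsorption with
probability photo_fraction (default 0.85, a low-energy-weighted
compromise for the CZT photoelectric fraction over 40–250 keV), else a
Klein–Nishina Compton split whose scattered photon escapes with
probability escape_fraction (default 0.5) or is absorbed at an
exponentially sampled second position. Collimator x-rays deposit a
nominal 75 keV (lead K-shell region). Weights default to 1. The
generator is deterministic under its seed.

What it does *not* emulate: solid-angle and inverse-square distance
dependence (the distance field is metadata; rate changes with distance
must be prescribed, as the sensitivity example does), angular photon
incidence, coherent-scatter angular structure, fluorescence escape from
the crystal itself, septal ray-tracing. Tests passing on synthetic data
therefore validate the *detector* chain, not photon transport.

## Detector model

Each anode's CIE is the joint map translated to its centre, trilinearly
interpolated (scipy map_coordinates), zero beyond the map's lateral
extent — an anode more than the neighbourhood half-width away is
insensitive. Per history, E_out,k = Σ_i η_k(r_i)·E_i over all 256
anodes; the largest E_out wins the history (ties, which arise only in
degenerate synthetic maps, go to the lowest anode index), responses
below the 40 keV threshold are discarded (the camera's cutoff is only
approximately known; the value is configurable), and the winner records
one count scaled by the photon weight at bin floor(E/0.1 keV). The
vectorised accumulator evaluates only anodes whose translated map can
overlap each event and matches the per-history path exactly (up to
floating-point ties).

Energy calibration re-samples counts under E = a₀ + a₁·E_init by
fractional redistribution of each source bin over the destination bins —
chosen over interpolation because it conserves counts exactly within the
axis. The resolution step spreads each source bin with a Gaussian of
σ = FWHM(E)/2.3548, FWHM(E) = b₀ + b₁·E (initial estimates 5.64 keV,
0.00751), renormalised per source bin within the 0–250 keV axis so edge
truncation does not destroy counts; the smearing matrix is windowed at
±5σ and cached per (b₀, b₁).

Because the blur itself shifts peak positions slightly, (a₀, a₁) are
determined by fixed-point iteration: apply the current calibration and
the resolution, locate each photopeak centroid (parabolic interpolation
on the log of the three bins around the local maximum, search window
±max(2 keV, FWHM)), update (a₀, a₁) by least squares mapping the implied
uncalibrated positions onto the true energies; converged when the
largest centroid shift is below 0.05 keV (half a bin), at most 20
iterations; a single peak fixes a₀ = 0. The gain is bootstrapped from
the highest-energy peak in a wide downward window (tailing only shifts
peaks down). Calibration uses the central-14×14 anode sum, consistent
with the tuning comparison. A linear calibration cannot zero all three
peak residuals when the underlying peak shifts are nonlinear in energy
(different lines interact at different depths); on spectra with a linear
ground truth the placement is within one 0.1 keV bin, on full
physical-chain spectra residuals of a few tenths of a keV remain — an
inherent property of the two-parameter model. Separately,
`align_peaks` provides the same linear alignment *without* re-applying
the blur, for reference spectra that already contain the detector
resolution (re-blurring them inside the calibration would bias the peak
positions — measured references are aligned with this function).

Images integrate each anode's spectrum over an energy window; component
spectra route counts by the history's provenance tags (winner selection
always runs on the full history, so components sum bin-exactly to the
total). Sensitivity is the windowed full-field-of-view count rate per
activity, and the distance curve c₀ + c₁·e^(−c₂·d) is fitted with
constrained least squares (c₂ ≥ 0); when flat data make c₂
unidentifiable the degenerate flat solution with c₂ = 0 is returned.

## Tuning

Agreement per spectrum pair is D_j = Σ_W (f_j·S_sim − S_ref)² /
(Σ_W S_ref)², summed over pairs to D_tot. Spectra are compared as
central-14×14 sums, after calibration and resolution, with the simulated
counts scaled to the reference's activity × duration. f_j is unity for
collimated acquisitions; for open-field ones it is the closed-form
least-squares optimum Σ(S_sim·S_ref)/Σ(S_sim²) — the original leaves the
choice open, and the closed form is the optimum of D_j itself, so it
never scores worse than unity. The comparison window spans
[max(threshold, E_min − 3·FWHM), min(250, E_max + 3·FWHM)] — the margin
rule is ours.

The nested optimisation uses Nelder–Mead (standard coefficients) on
parameters scaled by their initial values: the inner loop over (b₀, b₁)
from the initial estimates (5.64, 0.00751), relative simplex tolerance
10⁻³ or 200 evaluations, re-determining the energy calibration for every
resolution candidate (the calibration depends on the blur) and using one
calibration — from the designated calibration dataset, by default the
first — for all pairs; the outer loop over the configuration's CIE
parameters within bounds (mobility 300–2000 cm²/V·s, lifetime 0.1–20 µs,
hole μτ 10⁻⁶–10⁻³ cm²/V, a3_weight in [0, 1], b2_power 0.5–8, b2_scale
0.2–1), failed candidates scored with a large finite penalty and logged,
the full trace recorded. Eight configurations (A1/A3 × B1/B2 × C1/C2;
A2 enters only through A3) are tuned independently and ranked by their
best score. Reference spectra can optionally be re-aligned
(`recalibrate_reference`) — appropriate for measured spectra whose peak
positions drift with detector temperature, and switched off for
closed-loop tests where the references are model-generated and already
aligned.

No numeric tuning targets exist for the physical camera inside this
package (they would require the instrument); the tuning machinery is
validated closed-loop: references generated by the model at known
parameters are recovered — the inner loop to well under 5% in both
resolution parameters, the outer loop to a score not exceeding the score
at the generating parameters. The electron mobility and lifetime trade
off along a μτ ridge in the CIE map, so individual CIE parameters are
identified only up to that ridge; the score, not the parameter vector,
is the convergence criterion.

## Problem sizes

Production-quality maps use the 5 × 5 neighbourhood at a 20.5 µm step
(the mid-plane must be a node plane, so the step is the nearest
pitch-commensurate value to 20 µm with pitch/step even). The shipped
tests and the acceptance script run desk-scale configurations chosen as
the smallest sizes that exercise every code path at meaningful accuracy:
3 × 3 neighbourhoods at 0.205–0.41 mm steps, 21³ oracle grids, 10⁴–10⁵
synthetic histories per acquisition and an outer simplex budget of 25
evaluations. First-order upwinding errors scale with the step, so map
accuracy improves roughly linearly when moving to production grids.

## Known limitations

- All anodes share one CIE map and one resolution model: per-anode
  response variation and edge-anode effects are idealised away.
- Steady-state (long-integration-time) signals only: no time-dependent
  CIE, ballistic deficit, pile-up or charge-sharing threshold noise.
- The synthetic generator's scope as described above; real transport
  effects enter only through externally supplied listmode files.
- Space charge is neglected in all field alternatives; surface
  conductivity and near-surface material changes are represented only
  implicitly through the B2 parametrisation.
- First-order upwinding is diffusive: lateral CIE edges are slightly
  smeared at coarse steps, which biases tail magnitudes low relative to
  a fine-grid solution.
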