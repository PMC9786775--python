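# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `permeapath`.  Units everywhere: length nm, time ps,
energy kJ/mol, temperature K, R = 0.0083145 kJ mol⁻¹ K⁻¹; the default
temperature is 305 K (32 °C, physiological skin).

## Synthetic umbrella windows (Brownian dynamics)

The generator propagates the reaction coordinate z (permeant
centre-of-mass distance from the bilayer midplane) by Itô–Euler
overdamped Langevin dynamics on a prescribed landscape:

    z' = z + [−βD(z)(G'(z) + k(z−z₀)) + D'(z)]·dt + √(2 D(z) dt)·η.

The explicit D'(z) drift (Itô convention) makes the stationary density
the Boltzmann weight exp(−β(G + ½k(z−z₀)²)) even when D varies with
position; the test suite verifies this by total-variation comparison
against the analytic density, with and without a position-dependent D.
Domain edges are reflecting — a stand-in for the bulk-water slab that
avoids periodic free-energy surfaces.  G' and D' are evaluated from
4096-point tables of the landscape (central differences), and `dt` is
rejected up front if the worst-case drift step could traverse the
domain.  Runs are bit-reproducible given the seed; the per-window
normals are drawn in one block from a PCG64 generator.

Defaults: dt = 0.01 ps, sampling stride chosen per study (saved spacing
0.1–8 ps; see "problem sizes" below), spring constant 500 kJ mol⁻¹ nm⁻²,
23 windows from 0.0 to 4.4 nm in 0.2 nm steps.

### Built-in landscapes

Two fixtures emulate permeation of a small polar drug and its
methyl-ester prodrug through a stratum-corneum-like bilayer.  The free
energy is a monotone cubic (PCHIP) through the landmark points
(headgroup minimum, tail-region maximum, midplane offset) with a flat
zero plateau for z ≥ 4.0 nm:

* ester-like ("me5ala"): −21.1 kJ/mol at 2.4 nm, +24.5 at 0.7, +3.4 at 0;
* acid-like ("5ala"): −23.0 kJ/mol at 2.2 nm, +30.2 at 0.7, +20.3 at 0.

Diffusivity is interpolated in log₁₀-space: ~10⁻³ nm²/ps in bulk water
(typical for a ~130–150 g/mol solute), dropping two orders of magnitude
(ester-like) or almost three (acid-like) in the dense tail region,
with a partial recovery in the low-density interdigitating region near
the midplane.  The anchor values between the landmarks are the
package's own choice of a realistic profile shape.

What the generator does *not* emulate: orientational/conformational
degrees of freedom, bilayer relaxation, water dragging, periodic
boundary artefacts and force-field detail.  Passing recovery tests
therefore demonstrate correctness of the estimators, not of any MD
force field.

## WHAM

Standard self-consistent WHAM on a shared uniform grid (default bin
width 0.02 nm — ten bins per window spacing; half-open bins, final bin
right-inclusive).  The iteration runs in log-space (logsumexp) on the
window constants fᵢ with gauge f₁ = 0, and stops when max|Δfᵢ| < tol
(default 10⁻⁸ kJ/mol).  Unoccupied bins are reported as NaN, never
extrapolated; adjacent windows without histogram overlap trigger a
warning and leave gap bins flagged.  Zero-referencing subtracts the
*mean* ΔG over z ≥ 4.0 nm (averaging rather than pinning a single
point, which halves the reference noise).

Convergence diagnostic: WHAM per sliding block [t, t+L] (the classic
choice L = 50 ns advanced by 10 ns gives 21 blocks on a 250 ns series);
convergence is declared at the earliest start time after which all
later block profiles agree pairwise within a criterion (default
1 kJ/mol).  A series whose duration equals one block yields a single
block; a block longer than the series is an error.

Errors: moving-block bootstrap over each window's *trajectory* (not
i.i.d. points), block length = one integrated autocorrelation time,
200 resamples by default, WHAM re-solved per resample, per-bin standard
deviation reported.

The solver is cross-checked in the tests against an independently
written naive direct-iteration WHAM (real-space arithmetic, explicit
loops) on two-window problems: agreement within 0.1 kJ/mol.

## Diffusivity

Per window, the restrained-fluctuation estimator D = σ²/τ with σ² the
population variance of z(t) and τ = Δt(½ + Σ_k ρ(k)) the integrated
autocorrelation time of the saved series.  The ACF is computed by FFT
(mean-removed, 1/n normalisation); the sum truncates at the first
negative ρ(k) (initial-positive-sequence rule; a Sokal self-consistent
window with c = 5 is available via `truncation="sokal"`).  If the ACF
never crosses zero before `max_lag`, the τ estimate is flagged as a
lower bound with a warning.  A sample floor (default 10⁴) rejects
windows too short to estimate τ.

The estimator assumes an unconfined harmonic well; windows centred on a
reflecting domain edge are biased low (half-well sampling).  This
affects only the two outermost synthetic windows and stays well inside
the factor-of-two end-to-end tolerance.

## Permeability

Single leaflet: 1/P = ∫_{z₁}^{z₂} e^{ΔG(z)/RT}/D(z) dz by trapezoid on
a grid at least twice as fine as either input grid (refinement changes
P by <0.5% on smooth inputs).  ΔG is interpolated linearly between
supported bins; D is interpolated linearly in ln D between window
centers because it spans orders of magnitude.  Default bounds 0–4.4 nm
follow the simulated one-leaflet reaction coordinate; whether one
should instead integrate a symmetrised full bilayer is left switchable
via (z₁, z₂).  Past the profile's last supported bin inside the
declared bulk reference region, ΔG is taken as zero.

Transdermal: P = (Σᵢ 1/Pᵢ)⁻¹ over a stack of leaflet permeabilities;
the stratum-corneum model uses 200 identical leaflets (ten corneocyte
layers × ten bilayers × two leaflets).  Lateral diffusion around
corneocytes and corneocyte-phase resistance are out of scope, which is
the main reason such one-dimensional estimates exceed measured skin
permeabilities.

## Hydrogen bonds

Geometric criterion: donor–acceptor (heavy-atom) distance ≤ 0.35 nm
AND hydrogen–donor–acceptor angle (vertex at the donor) ≤ 37°, both
boundaries inclusive so fixtures built exactly at a cutoff score
deterministically.  Bonds involving the focus species (default
`permeant`) are attributed to the partner's species — CER, CHOL, FFA,
water — or to `self` when both ends are the focus; both donation
directions are counted.  Per-window profiles report each partner plus
derived columns `lipids` (= CER+CHOL+FFA) and `total`
(= lipids + water + self, exactly).  The detector applies no
minimum-image convention: frames must be pre-wrapped, a documented
limitation for real periodic trajectories.

## Solute-tempering replica exchange

The toy model splits the potential into an unscaled environment term,
a coupling term scaled by λ ∈ (0, 1], and the umbrella bias:
U_λ = U_env + λU_int + U_bias, ladder λ₁ = 1 > λ₂ > …  Neighbour swaps
are attempted every 0.1 ps (alternating even/odd pairs) with the
Metropolis probability min(1, e^{−βΔ}), Δ = (λᵢ−λⱼ)(U_int(zⱼ)−U_int(zᵢ))
— only the scaled term survives the cancellation.  The ground replica's
trajectory is returned for downstream WHAM; its ensemble is verified to
stay Boltzmann whether or not exchanges fire.  `tune_ladder` bisects on
the rung count of a geometric λ-ladder until the *minimum* neighbour
acceptance clears the 20% floor of the 20–30% working band on short
pilot runs (weakly coupled systems that exceed the band even with two
rungs are returned flagged rather than rejected).  Campaign accounting
(`plan_campaign`) takes per-window rung counts as input and validates
replica/time totals; no force-field-level √λ charge scaling is
attempted — the machinery, not an MD engine, is the deliverable.

## Problem sizes used in validation

* WHAM recovery: 23 windows × 10⁵ samples at 8 ps spacing (window
  duration 0.8 µs-equivalent, ~1500× the slowest window's τ ≈ 500 ps);
  recovered ΔG within 1.5 kJ/mol of truth over [0, 4] nm.
* Diffusivity: 10⁶-sample restrained window, D recovered within 15%.
* End-to-end: recovered profiles integrate to within a factor of 2 of
  the exact permeability integral on the true landscape.
* Replica exchange: 4-rung ladder, 6×10⁵ steps on a fast-mixing double
  well; ground-replica TV distance from Boltzmann < 0.08; empirical
  swap rates match the mean analytic probability within 1% (10⁵ draws).

The sampling interval of the recovery study (8 ps) was set so that the
slow-diffusivity windows contribute enough effectively independent
samples; with 0.5 ps spacing at the same sample count those windows'
mean positions wander by several bin widths and the stitched profile
degrades to ~3 kJ/mol error.

## Design choices where the design was open

* Rotatable bonds: acyclic single bonds whose endpoints each carry
  another heavy neighbour; no amide/ester special-casing.  Donors are
  counted per heavy atom (an NH₂ counts once).
* The Ertl TPSA table covers the N/O environments of aliphatic
  amines/ketones/acids/esters only; unknown environments raise, never
  silently contribute zero.
* WHAM requires identical bin edges across windows (one shared grid)
  rather than per-window grids.
* The bootstrap pairs with the IACT estimator for its block length;
  zero-variance windows fall back to block length 1.
* H-bond frames carry a single role per atom; an atom that should both
  donate and accept is represented by its dominant role in fixtures.
* Single-rung replica ladders delegate to the plain integrator with an
  identical seed path, so tempered and untempered runs are directly
  comparable.

## Known limitations

One-dimensional dynamics only; no barostat/thermostat physics; the
IACT-based diffusivity assumes a harmonic restraint and equilibrated
sampling; xvg ingestion expects uniform time spacing; H-bond detection
is O(hydrogens × acceptors) per frame, adequate for labelled fixtures
but not for full solvated systems.
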