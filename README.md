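# permeapath

Umbrella-sampling permeation analysis for membrane crossing, aimed at
transdermal drug delivery studies: given per-window reaction-coordinate
time series of a permeant crossing a lipid bilayer (for example the
stratum-corneum ceramide/cholesterol/free-fatty-acid matrix that
rate-limits skin absorption), the package recovers the free-energy
profile, the position-dependent diffusivity, and the membrane and
transdermal permeability coefficients, together with the supporting
machinery such studies need: replica-exchange (solute-tempering) ladder
bookkeeping, hydrogen-bond partner profiling, and small-molecule
descriptors.

Because real umbrella-sampling campaigns cost tens of microseconds of
MD, the package ships a one-dimensional Brownian-dynamics generator
that produces umbrella-window series on a prescribed landscape
(G(z), D(z)).  Every estimator is validated by parameter recovery
against that generator's ground truth — the analysis chain is testable
end to end on a desktop.

## The model

For a permeant restrained at windows z₀ ∈ {0.0, 0.2, …, 4.4} nm from
the bilayer midplane with harmonic springs U_i(z) = ½k(z−z₀ᵢ)²
(k = 500 kJ mol⁻¹ nm⁻², T = 305 K), the analysis chain is:

1. **WHAM.**  Window histograms are reweighted into one unbiased
   profile by iterating the self-consistency equations
   P(z) ∝ Σᵢnᵢ(z) / Σᵢ Nᵢ e^{β(fᵢ−Uᵢ(z))},
   fᵢ = −RT ln Σ_z P(z)e^{−βUᵢ(z)}, giving ΔG(z) = −RT ln P(z),
   zero-referenced over bulk water (z ≥ 4.0 nm).  Convergence is
   diagnosed by WHAM on sliding trajectory blocks, and per-bin errors
   by moving-block bootstrap (200 resamples by default).
2. **Diffusivity.**  Per window, D(z₀) = var(z)/τ where τ is the
   integrated autocorrelation time of the restrained series — the
   standard restrained-fluctuation (Hummer) estimator.
3. **Permeability.**  The inhomogeneous solubility-diffusion integral
   1/P = ∫ e^{ΔG(z)/RT}/D(z) dz over one leaflet, and the transdermal
   coefficient from 200 leaflets (100 stacked bilayers) in series:
   1/P_trans = Σᵢ 1/Pᵢ.

Units are nm / ps / kJ mol⁻¹ / K throughout (P in nm/ps).

## Worked example

`examples/` holds one short script per capability.  Descriptors of the
two built-in permeants (5-aminolevulinic acid and its methyl-ester
prodrug):

```
$ python examples/01_descriptors.py
5ALA     donors=2  acceptors=4  rotatable=4  TPSA=80.4 A^2  MW=131.13 g/mol
Me-5ALA  donors=1  acceptors=4  rotatable=5  TPSA=69.4 A^2  MW=145.16 g/mol
```

The esterification removes one H-bond donor and 11 Å² of polar surface
area — the structural reason the prodrug binds the polar headgroups
more weakly and crosses the apolar core more cheaply.

Recovering a free-energy profile from synthetic umbrella windows
(23 windows, ~2×10⁴ samples each, about half a minute):

```
$ python examples/02_pmf_recovery.py
recovered minimum :   -21.5 kJ/mol at z = 2.41 nm   (truth -21.1 at 2.40)
recovered maximum :    26.7 kJ/mol at z = 0.69 nm   (truth  24.5 at 0.70)
recovered midplane:     5.6 kJ/mol at z = 0          (truth   3.4)
```

The minimum sits in the lipid-headgroup region (favourable polar
contacts), the barrier in the dense hydrophobic tail region.  Feeding
exact profiles through the permeability integral and the 200-leaflet
stack:

```
$ python examples/03_permeability.py
me5ala  leaflet P = 2.453e-09 nm/ps   transdermal P (200 leaflets) = 1.226e-11 nm/ps
5ala    leaflet P = 3.441e-11 nm/ps   transdermal P (200 leaflets) = 1.721e-13 nm/ps
```

The ester-like landscape permeates about two orders of magnitude
faster here: its tail barrier is 5.7 kJ/mol lower (a factor e^{5.7/RT}
≈ 9.5) and its core diffusivity several-fold higher.

A thin CLI mirrors the library (`permeapath plan | simulate | wham |
diff | perm | hbonds | descriptors | run`); window series are xvg-style
two-column text files listed in a YAML manifest, profiles are CSV.

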