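# Methods

## The problem

Skin pathologies such as scleroderma, aging, and invasive carcinomas
degrade the ultrastructure of the papillary dermis — a ~200 µm layer
directly beneath the epidermis — which lowers its optical scattering
coefficient. Structured light imaging mesoscopy (SLIM) asks a forward
question instead of an inverse one: at which wavelength λ and
illumination spatial frequency fx does the raw spatial-frequency-domain
(SFD) diffuse reflectance Rd(λ, fx) change *most* when scattering in
that embedded layer changes? A measurement at that (λ, fx) pair is
maximally sensitive to the pathology without any optical-property
inversion.

This package answers that question with Monte Carlo radiative transport
in a four-layer skin model, tallied directly in the spatial frequency
domain.

## Skin model

Four plane-parallel layers (epidermis 50 µm, papillary dermis 200 µm,
reticular dermis 1100 µm, subcutis 6150 µm; total 7.5 mm), with
anisotropy/index per layer g = 0.8, 0.8, 0.8, 0.75 and
n = 1.37, 1.40, 1.40, 1.44 under an n = 1 ambient.

Absorption per layer combines chromophores (all coefficients mm⁻¹
internally; the Beer–Lambert sum is evaluated in cm⁻¹ and divided
by 10):

    μa(λ) = 2.303·10⁻⁶ (C_HbO2 ε_HbO2 + C_Hb ε_Hb)
            + f_water μa,water(λ) + f_lipid μa,lipid(λ)

with hemoglobin concentrations in µM (epidermis 0/0; both dermal layers
37.21/9.30; subcutis 130.2/32.5, i.e. 15 g/dL hemoglobin at 80%
saturation scaled by blood volume fraction), water fractions
0.17/0.70/0.70/0.70 and lipid fractions 0.10/0.05/0.05/0.23. Epidermal
melanin adds a power law

    μa,mel(λ) = 1.7·10¹¹ · f_v · λ⁻³·⁴⁸   (λ in nm, result in mm⁻¹),

linear in the melanosome volume fraction f_v; f_v = 0.02 / 0.05 / 0.10
emulate light / medium / dark skin tones. By default the epidermal
water/lipid baseline is added on top of the melanin term; a
melanin-only mode exists (`epidermis_baseline_absorption=False`).

Reduced scattering follows Mie+Rayleigh power laws

    μs′_epi(λ)   = 1.08·10⁷ λ⁻²·³⁶⁴ + 13.571 λ⁻⁰·²⁶⁷
    μs′_dermis(λ) = 1.19·10⁷ λ⁻²·⁴²⁷ + 7.15 λ⁻⁰·²⁵⁸

(λ in nm, μs′ in mm⁻¹; both dermal layers share the dermal law), and
the full scattering coefficient is μs = μs′/(1−g) at each layer's fixed
anisotropy.

### Bundled chromophore and subcutis tables (synthetic stand-ins)

The exact extinction compilation behind the original supplementary
tables is not published. The bundled
`chromophores_synthetic_v1.csv` carries hemoglobin molar extinctions
and water/lipid absorption at the eight measurement wavelengths
(471–851 nm), compiled from standard visible/NIR literature magnitudes
and constrained to reproduce the model's documented dermis transport
behaviour: l* = 1/(μa+μs′) of 0.216 / 0.457 mm at 526 / 851 nm
(published values 0.21 / 0.46), an l* ratio of 2.58 between 851 and
471 nm (≈2.6), and a dermal μs′/μa span of 17.1–400 (≈17–404, minimum
at 471 nm, maximum at 691 nm). Subcutis reduced scattering is a
labelled synthetic power law 122·λ⁻⁰·⁶⁸⁵ mm⁻¹, kept below dermal μs′ at
every wavelength as adipose data require. Both tables are versioned,
carry provenance strings, and are overridable through
`SkinModelSpec.subcutis_musp_table` / `ChromophoreTable.from_csv`.
Quantities that depend on the green-band hemoglobin extinction (the
526 nm absorption, hence the shallow-depth statistics there) inherit a
~10% systematic uncertainty from this choice.

Tabulated lookups are exact-match by default; linear interpolation is
an explicit opt-in (`interpolate=True`) used only for homogeneous
sweeps.

## Transport engine

MCML-style photon transport with a pencil beam at normal incidence,
z positive downward, surface at z = 0, layers as half-open intervals.
Variance control is absorption weighting (implicit capture): steps are
sampled from the local μt = μa + μs, each collision multiplies the
weight by the albedo μs/μt and deposits the complement as absorbed.
Scattering directions come from the Henyey–Greenstein inverse CDF with
a uniform azimuth. Every index-mismatched interface (including the
interior 1.37/1.40 and 1.40/1.44 steps) applies unpolarized Fresnel
reflection/refraction; specular reflection at launch is removed
analytically (launch weight 1−R_spec) and reported separately from
diffuse reflectance. Photons crossing z = 0 upward are detected with
their full statistics regardless of exit angle (full-NA detection);
photons crossing the bottom of the 7.5 mm stack terminate as
transmitted through a matched-index exit. Russian roulette below a
weight of 10⁻⁴ (survival 0.1) is expectation-preserving; the
diagnostics ledger carries the net roulette term so that

    specular + detected + transmitted + absorbed + roulette_net = 1

holds to float accumulation accuracy (~10⁻¹⁴ relative), not merely in
expectation.

Randomness is a counter-based splitmix64 stream keyed by
(seed, photon index), so trajectories are independent of batch size and
bit-reproducible; per-study cells derive their seeds from the master
seed and the cell coordinates via SHA-256 (never Python's salted
`hash`). A step inside a transparent layer (μt = 0) flies straight to
the boundary; a boundary hit resamples the free path in the next layer,
which is statistically exact by the memorylessness of the exponential.

Each detected photon records weight, lateral exit displacement
(dx, dy), maximum depth visited z_max, and per-layer path lengths L_k
and collision counts J_k — the sufficient statistics for every
downstream tally and for perturbation reweighting.

## SFD tallies

Reflectance is tallied per photon directly in the frequency domain
(the "shortcut" route): Rd(fx) = ⟨w·cos(2π fx dx)⟩ over launched
photons, using the x-component of exit displacement (1-D sinusoidal
pattern, cosine kernel; dy is kept for diagnostics). At fx = 0 this is
exactly the detected weight fraction. The study grid is fx = 0–1 mm⁻¹
in 0.01 steps; analyses use 0–0.5.

The maximum-penetration-depth density pzmax(z) tallies each detected
photon's signed weight once, at its z_max, on 10 µm bins whose edges
are forced through the layer boundaries (0.05, 0.25, 1.35 mm) so that
layer partitioning is exact. By construction ∫ pzmax dz = Rd(fx)
exactly; small negative bins at high fx are reported as-is (clipping
would break the identity). Depth quantiles d_m solve
m = 100·P(z ≤ d_m)/Rd with piecewise-linear interpolation inside bins,
ties toward the smaller depth; they are computed only where Rd(fx)
exceeds 5 standard errors. Standard errors come from per-photon
contribution variance; any derived scalar can also be bootstrapped by
20 launch-index batches (batch means).

## Perturbation Monte Carlo

A perturbation restricted to (μa, μs) of one recorded layer reweights
each detected photon by the likelihood ratio

    (μs,p/μs,b)^J_k · exp(−(μt,p − μt,b) L_k),

exact in expectation under absorption weighting. Weight dispersion is
tracked by the effective sample size (Σw)²/Σw²; below 1% of the launch
count a warning recommends conventional re-simulation. In practice the
50% papillary-dermis scattering reduction is far outside the stable
reweighting regime for this optically thick layer (ESS collapses to
~10² of 3·10⁵ at 526 nm), so the study workflow runs *conventional*
transport for both the baseline and the perturbed scenario — with
common random numbers for variance reduction — and reserves
reweighting for the epidermal melanin variants, where only a short
path length through a 50 µm layer enters the exponent and the ratio is
well conditioned (ESS ≈ 1/3 of launches for f_v 0.02→0.10). Melanin
variants are anchored at f_v = 0.02. The "50% scattering reduction" is
applied to μs at fixed g, so μs′ scales identically. Perturbations to
g, n, or layer thickness require re-simulation and are out of scope.

## Optimization study

For each (λ, f_v), ΔRd(fx) = Rd,perturbed − Rd,baseline. Scattering
reductions lower Rd everywhere; the magnitude |ΔRd| peaks at an
intermediate fx because increasing fx first suppresses the competing
reflectance *gain* from the reticular dermis (which otherwise offsets
the papillary loss) and only later starves the papillary layer itself.
The optimum is located by a local quadratic fit over ±0.05 mm⁻¹ around
the discrete argmax (stabilizing the 0.01 grid against Monte Carlo
noise), with uncertainty from the spread of per-batch argmaxes; a curve
whose maximum is below 2 SE reports an undefined optimum, and an
edge maximum is reported at the edge unrefined.

The melanin-robust pair is defined on the per-wavelength optima: among
wavelengths whose peak |ΔRd| stays above 50% of the map-wide peak at
every melanin level, choose the one whose peak |ΔRd| varies least
across melanin levels; report the melanin-average of its optimal fx.
(A min-spread search over raw grid cells is *not* used: the spread of
ΔRd between melanin levels decreases monotonically with fx as all
signals attenuate together, so that rule degenerates to the grid edge
where the signal itself is weakest. The robustness question the method
answers is about the consistency of the achievable change.) Exact
spread ties break toward the larger signal.

The dimensionless study fixes l* = 1/(μa+μs′) = 1 mm in a homogeneous
20 l* slab (g = 0.8, n = 1.4) and sweeps μs′/μa; a −10% whole-medium
scattering perturbation (small enough that, by linearity of transport
in the optical coefficients, the optimum location is
magnitude-independent) defines fx* = fx,opt·l*. For μs′/μa ≲ 3
absorption dominates, little modulated light survives, and fx* = 0
(uniform illumination is optimal); fx* rises steeply over ratios 3–10
and plateaus near 0.06–0.07 with a slight decline toward high ratios.
Mapping dermal (μs′/μa, l*) through this curve reproduces the
decreasing trend of fx,opt with wavelength and sits uniformly below
the four-layer optima, as the layered geometry (absorbing epidermal
screen, perturbation confined to a shallow layer) shifts the optimum
upward.

A note on magnitude-invariance of the optimum: at high precision
(2·10⁶ photons) the refined argmax for a 25% papillary reduction sits
0.02–0.04 mm⁻¹ above the 50% one (621 nm: 0.345 vs 0.320; 526 nm the
peak is flat to <1% over 0.40–0.50 mm⁻¹ and its argmax is
ill-conditioned). The invariance is therefore asserted at grid
resolution and as transfer-optimality: either magnitude's optimum
retains ≥97% (measured ≥99.7%) of peak sensitivity under the other's
curve.

## Problem sizes and numerical defaults

The reference configuration (8 wavelengths × 3 melanin levels,
baseline + perturbed) defaults to 5·10⁶ photons per transport run;
the packaged acceptance recomputation uses 10⁶ per run and the test
suite 2–5·10⁵, sizes at which the Monte Carlo standard error of Rd is
below 10⁻³ and every asserted optimum is resolved well inside a grid
step on a single CPU in minutes. pzmax uses 10 µm bins
(convergence-checked at 5 µm); batch statistics use 20 batches;
roulette threshold 10⁻⁴ with survival 0.1; the engine's safety cap is
10⁶ events per photon (unreached in practice; residual weight at the
cap is booked as absorbed so the ledger still closes).

## What the model does and does not emulate

The generator reproduces layered steady-state transport with
literature-shaped chromophore spectra. It does not model instrument
response (finite projector/camera NA, demodulation of phase-shifted
frames, SNR), polarization, fluorescence, surface roughness, sublayer
heterogeneity or hydration/temperature dependence of the spectra; the
bottom boundary terminates rather than reflects. Passing tests
therefore certify the transport physics and the optimization machinery
for this model class, not agreement with any particular instrument's
measurements; absolute (λ, fx) optima inherit the ~10% systematic
uncertainty of the synthetic extinction tables, and the depth
statistics at green wavelengths are the most sensitive to that choice.

## Known limitations

* pMC reweighting is unusable for strong scattering perturbations of
  optically thick layers (by design it warns rather than silently
  degrading).
* The 0.01 mm⁻¹ fx grid bounds the precision of any reported optimum;
  quadratic refinement interpolates but cannot beat the underlying
  flatness of ΔRd near its peak (±0.02–0.04 mm⁻¹ at 526 nm).
* Wavelengths outside 400–1000 nm are outside the validity of the
  scattering power laws; the chromophore table refuses wavelengths it
  does not tabulate.
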