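# slim — structured light imaging mesoscopy toolkit

Many skin pathologies (scleroderma, aging, invasive carcinomas) alter
the optical scattering of the **papillary dermis**, a ~200 µm layer
buried under the epidermis. Recovering that layer's properties by
inverting diffuse-optics measurements is ill-posed at sub-millimeter
scales. SLIM takes the opposite route: find the wavelength λ and
illumination spatial frequency fx at which the *raw*
spatial-frequency-domain (SFD) reflectance Rd(λ, fx) is most sensitive
to a scattering change in the target layer, and just measure there.

This package is a simulator + analysis toolkit for that design
question, aimed at biomedical-optics researchers:

* **Monte Carlo photon transport** in a layered slab (pencil beam,
  Henyey–Greenstein phase function, Fresnel boundaries, implicit
  capture, Russian roulette), with a numba kernel and a counter-based
  RNG that makes every run bit-reproducible.
* **Direct SFD tallies**: each detected photon contributes
  w·cos(2π fx Δx) per spatial frequency — no Fourier/Hankel transform
  of binned reflectance — plus the maximum-penetration-depth density
  pzmax(z), whose depth integral recovers Rd(fx) *exactly*.
* **A four-layer skin model** (epidermis / papillary dermis / reticular
  dermis / subcutis) built from chromophore composition: hemoglobin,
  water, lipid via μa(λ) = 2.303·10⁻⁶(C_HbO2 ε_HbO2 + C_Hb ε_Hb) +
  f_w μa,w + f_l μa,l, epidermal melanin via
  μa,mel = 1.7·10¹¹ f_v λ⁻³·⁴⁸, and Mie+Rayleigh power laws for μs′(λ).
* **Perturbation Monte Carlo**: reweight a baseline trajectory ensemble
  by (μs,p/μs,b)^J·exp(−Δμt·L) per layer to predict reflectance under
  absorption/scattering changes without re-simulation (used for
  epidermal melanin variants, with effective-sample-size guards).
* **Depth statistics**: cumulative Pzmax(z ≤ d), quantiles d_m from
  m = 100·Pzmax(z ≤ d_m)/Rd, pzmax differences, and exact per-layer
  decomposition of reflectance changes.
* **The optimizer**: ΔRd(λ, fx) maps for a 50% papillary-dermis
  scattering reduction across melanin levels (f_v = 2/5/10%),
  per-wavelength optima with batch uncertainties, the melanin-robust
  (λ, fx) pair, and the dimensionless homogeneous study
  fx* = fx,opt·l* versus μs′/μa at fixed transport mean free path
  l* = 1/(μa+μs′).

## Worked example

Baseline vs perturbed (50% papillary scattering reduction) at 621 nm,
2% epidermal melanin, 2·10⁵ photons per run with shared random numbers:

```python
import numpy as np
from slim import *

table = load_default_chromophore_table()
spec = default_skin_spec(melanin_fv=0.02)
baseline, perturbed = make_baseline_and_perturbed(spec, 621.0, table)

cfg = TransportConfig(n_photons=200_000, seed=7)
ph_b, diag = run_transport(baseline, cfg)
ph_p, _ = run_transport(perturbed, cfg)

fx = default_fx_grid(0.5, 0.01)
rb, rp = sfd_reflectance(ph_b, fx), sfd_reflectance(ph_p, fx)
res = optimal_fx(fx, rp.rd - rb.rd, se=np.hypot(rb.se, rp.se))
print(f"optimal fx = {res.fx_at_max:.3f} /mm, |dRd| = {res.max_abs_delta:.4f}")

z = default_z_edges(baseline.total_depth, baseline.boundaries)
pz = pzmax_density(ph_b, 0.0, z)
print("d50 =", round(depth_quantile(pz, 50.0), 3), "mm")
```

prints

```
optimal fx = 0.335 /mm, |dRd| = 0.0444
d50 = 0.44 mm
```

i.e. at 621 nm the reflectance change produced by the embedded
scattering drop peaks at fx ≈ 0.33 mm⁻¹ (a ~4.4 percentage-point drop
in Rd), and half of the detected DC reflectance originates above
0.44 mm depth. The same workflow over all 8 wavelengths × 3 melanin
levels (`slim.cli_io.run_study`) shows the optimum shifting to
fx ≈ 0.2 mm⁻¹ in the NIR and identifies (851 nm, fx ≈ 0.22 mm⁻¹) as
the pair whose peak reflectance change is most consistent across skin
tones.

The command line mirrors the library:

```
$ slim simulate --wavelength 621 --photons 200000 --seed 7 --out rd.csv
Rd(0) = 0.47815  detected 0.4781  absorbed 0.4922
$ slim fxstar --ratios 1,3,30 --photons 100000 --seed 7
musp/mua =    1.000  fx* = 0.000
musp/mua =    3.000  fx* = 0.015
musp/mua =   30.000  fx* = 0.066
$ slim map --photons 500000 --seed 1 --out study/     # full study
$ slim fixtures --out fixtures/                       # bundled tables
```

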