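"""Perturbation Monte Carlo: reweight a baseline photon set.

Under absorption weighting, a photon that made J collisions and
travelled a path length L inside a perturbed layer carries a likelihood
ratio (mus_p / mus_b)^J * exp(-(mut_p - mut_b) L) between the perturbed
and baseline media, where mut = mua + mus.  Multiplying each detected
weight by this ratio turns the baseline trajectory ensemble into an
unbiased estimator for the perturbed medium, at the cost of increased
weight dispersion (tracked via the effective sample size).

This is exact in expectation for any perturbation confined to mua and
mus of recorded layers; changes to g, n or layer thickness require
re-simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .mc_engine import DetectedPhotonSet
from .skin_optics import (
    ChromophoreTable,
    LayeredMedium,
    SkinModelSpec,
    build_skin_medium,
    melanin_absorption,
    scale_layer_scattering,
)

__all__ = [
    "PerturbationSpec",
    "reweight",
    "make_baseline_and_perturbed",
    "melanin_variant",
    "LowEffectiveSampleSizeWarning",
]


class LowEffectiveSampleSizeWarning(UserWarning):
    """Reweighted ensemble is dominated by few photons; re-simulate."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Layer-restricted change: multiplicative on mus, additive on mua."""

    layer_name: str
    mus_scale: float = 1.0
    mua_delta: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.mus_scale <= 0:
            raise ValueError("mus_scale must be positive")


def reweight(
    photons: DetectedPhotonSet,
    medium: LayeredMedium,
    pert: PerturbationSpec,
    ess_warn_fraction: float = 0.01,
) -> DetectedPhotonSet:
    """Apply the pMC likelihood ratio for one perturbed layer.

    Trajectory geometry (dx, z_max, L, J) is unchanged; only weights are
    scaled.  Warns if the effective sample size drops below
    ``ess_warn_fraction`` of the launched count.
    """
    k = medium.layer_index(pert.layer_name)
    if photons.L.shape[1] != len(medium.layers):
        raise ValueError(
            "photon set does not carry per-layer records matching this medium"
        )
    lay = medium.layers[k]
    mua_p = lay.mua + pert.mua_delta
    if mua_p < 0:
        raise ValueError("perturbed mua would be negative")
    mus_b = lay.mus
    mus_p = mus_b * pert.mus_scale
    dmut = (mua_p + mus_p) - (lay.mua + mus_b)

    J = photons.J[:, k].astype(float)
    L = photons.L[:, k]
    log_ratio = -dmut * L
    if pert.mus_scale != 1.0:
        if mus_b <= 0:
            raise ValueError("cannot scale scattering of a non-scattering layer")
        log_ratio = log_ratio + J * np.log(pert.mus_scale)
    w_new = photons.w * np.exp(log_ratio)

    out = dc_replace(
        photons,
        w=w_new,
        provenance=photons.provenance
        + (
            f"pMC[{pert.layer_name}: mus x{pert.mus_scale:g}, "
            f"mua {pert.mua_delta:+g}/mm]",
        ),
    )
    ess = out.effective_sample_size()
    if ess < ess_warn_fraction * photons.n_launched:
        warnings.warn(
            f"effective sample size {ess:.0f} below "
            f"{ess_warn_fraction:.0%} of {photons.n_launched} launched "
            "photons; consider a conventional re-run",
            LowEffectiveSampleSizeWarning,
        )
    return out


def make_baseline_and_perturbed(
    spec: SkinModelSpec,
    wavelength_nm: float,
    table: ChromophoreTable,
    mus_scale: float = 0.5,
    layer_name: str = "papillary_dermis",
) -> tuple[LayeredMedium, LayeredMedium]:
    """Baseline skin medium and a copy with papillary-dermis mus scaled.

    The default halves the papillary-dermis scattering coefficient at
    fixed anisotropy, so the reduced scattering musp scales identically.
    """
    baseline = build_skin_medium(spec, wavelength_nm, table)
    if mus_scale == 1.0:
        return baseline, baseline
    return baseline, scale_layer_scattering(baseline, layer_name, mus_scale)


def melanin_variant(
    photons: DetectedPhotonSet,
    medium: LayeredMedium,
    spec: SkinModelSpec,
    new_fv: float,
    table: ChromophoreTable | None = None,
) -> DetectedPhotonSet:
    """Reweight a baseline run to a different epidermal melanin content.

    Only the epidermal absorption changes (by the difference of the
    melanin power law between the two volume fractions), so the ratio is
    a pure exp(-dmua * L_epidermis) factor — well conditioned because
    epidermal path lengths are short.
    """
    if medium.wavelength_nm is None:
        raise ValueError("medium must carry its wavelength")
    dmua = melanin_absorption(new_fv, medium.wavelength_nm) - melanin_absorption(
        spec.melanin_fv, medium.wavelength_nm
    )
    pert = PerturbationSpec(
        layer_name="epidermis",
        mus_scale=1.0,
        mua_delta=dmua,
        description=f"melanin fv {spec.melanin_fv:g} -> {new_fv:g}",
    )
    return reweight(photons, medium, pert)
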