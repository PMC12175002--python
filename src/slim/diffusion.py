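"""Diffusion-approximation SFD reflectance for a semi-infinite medium.

Standard-diffusion forward model for sinusoidally structured
illumination of a homogeneous half-space: the modulated fluence decays
with an effective attenuation mueff' = sqrt(3 mua mutr + (2 pi fx)^2)
and the diffuse reflectance follows

    Rd(fx) = 3 A a' / [(mueff'/mutr + 1) (mueff'/mutr + 3 A)]

with mutr = mua + musp, a' = musp / mutr, and A the internal-reflection
parameter from the effective reflection coefficient

    Reff = 0.0636 n + 0.668 + 0.710 / n - 1.440 / n^2,
    A = (1 - Reff) / (2 (1 + Reff)).

Accurate to a few percent for musp/mua >> 1 and fx l* <~ 1; used here as
an independent closed-form cross-check of the transport engine, never as
its implementation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["effective_reflection_coefficient", "diffusion_rd"]


def effective_reflection_coefficient(n_rel: float) -> float:
    """Empirical internal-reflection coefficient for relative index n."""
    if n_rel <= 0:
        raise ValueError("relative refractive index must be positive")
    if abs(n_rel - 1.0) < 1e-12:
        return 0.0
    return 0.0636 * n_rel + 0.668 + 0.710 / n_rel - 1.440 / n_rel**2


def diffusion_rd(mua: float, musp: float, n_rel: float = 1.4, fx=0.0):
    """Semi-infinite diffuse SFD reflectance Rd(fx).

    Parameters are mm^-1 (fx as well); ``n_rel`` is tissue index over
    ambient index.  Accepts scalar or array fx.
    """
    if mua < 0 or musp <= 0:
        raise ValueError("need mua >= 0 and musp > 0")
    fx = np.asarray(fx, dtype=float)
    mutr = mua + musp
    a_prime = musp / mutr
    reff = effective_reflection_coefficient(n_rel)
    big_a = (1.0 - reff) / (2.0 * (1.0 + reff))
    mueff_prime = np.sqrt(3.0 * mua * mutr + (2.0 * np.pi * fx) ** 2)
    ratio = mueff_prime / mutr
    rd = 3.0 * big_a * a_prime / ((ratio + 1.0) * (ratio + 3.0 * big_a))
    return rd if rd.ndim else float(rd)
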