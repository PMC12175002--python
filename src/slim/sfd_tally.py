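"""Per-photon (shortcut) tallies in the spatial frequency domain.

Instead of binning spatially resolved reflectance and transforming it,
each detected photon contributes w * cos(2 pi fx dx) directly at every
spatial frequency of interest (1-D sinusoidal illumination, cosine
kernel on the x-component of the exit displacement).  The same signed
kernel tallies the maximum-penetration-depth density pzmax(z), whose
integral over depth recovers Rd(fx) exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc_engine import DetectedPhotonSet
from .skin_optics import LayeredMedium

__all__ = [
    "SFDReflectance",
    "PzmaxDistribution",
    "sfd_reflectance",
    "pzmax_density",
    "layer_partitioned_reflectance",
    "mc_standard_error",
    "default_fx_grid",
    "default_z_edges",
]


def default_fx_grid(fx_max: float = 1.0, step: float = 0.01) -> np.ndarray:
    """Study grid of spatial frequencies, 0 to fx_max in steps of 0.01/mm."""
    n = int(round(fx_max / step))
    return np.linspace(0.0, fx_max, n + 1)


def default_z_edges(
    total_depth: float,
    layer_boundaries=None,
    bin_width: float = 0.010,
) -> np.ndarray:
    """Depth-bin edges (default 10 um) forced through layer boundaries.

    Aligning edges with the layer interfaces makes layer partitioning of
    pzmax exact rather than approximate.
    """
    interior = [] if layer_boundaries is None else [
        b for b in np.asarray(layer_boundaries, float) if 0.0 < b < total_depth
    ]
    pieces = []
    lo = 0.0
    for hi in sorted(interior) + [total_depth]:
        nbins = max(1, int(round((hi - lo) / bin_width)))
        pieces.append(np.linspace(lo, hi, nbins + 1)[:-1])
        lo = hi
    edges = np.concatenate(pieces + [[total_depth]])
    return edges


@dataclass
class SFDReflectance:
    """Diffuse SFD reflectance Rd(fx) with Monte Carlo standard errors."""

    fx_grid: np.ndarray
    rd: np.ndarray
    se: np.ndarray
    n_launched: int
    wavelength_nm: float | None = None
    medium_fingerprint: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fx": self.fx_grid, "rd": self.rd, "se": self.se})

    def at(self, fx: float) -> float:
        idx = np.argmin(np.abs(self.fx_grid - fx))
        if abs(self.fx_grid[idx] - fx) > 1e-9:
            raise KeyError(f"fx = {fx} not on the tally grid")
        return float(self.rd[idx])


@dataclass
class PzmaxDistribution:
    """Signed-weight density of maximum penetration depth at one fx.

    density integrates (sum density * bin width) to Rd(fx) exactly;
    negative bins can occur at fx > 0 and are reported as-is, since
    clipping would break the integral identity.
    """

    z_edges: np.ndarray
    density: np.ndarray
    fx: float
    rd: float
    n_launched: int
    wavelength_nm: float | None = None

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def bin_masses(self) -> np.ndarray:
        """Per-bin detected weight fraction (density * width)."""
        return self.density * self.bin_widths

    def integral(self) -> float:
        return float(self.bin_masses.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_lo": self.z_edges[:-1],
                "z_hi": self.z_edges[1:],
                "density": self.density,
            }
        )


def _signed_weights(photons: DetectedPhotonSet, fx: float) -> np.ndarray:
    if fx == 0.0:
        return photons.w
    return photons.w * np.cos(2.0 * np.pi * fx * photons.dx)


def sfd_reflectance(photons: DetectedPhotonSet, fx_grid) -> SFDReflectance:
    """Shortcut tally: Rd(fx) = mean over launched photons of w cos(2 pi fx dx).

    Standard errors use the per-launched-photon variance of the summand
    (undetected photons contribute zero).
    """
    fx_grid = np.atleast_1d(np.asarray(fx_grid, dtype=float))
    if fx_grid.size == 0:
        raise ValueError("fx_grid must be nonempty")
    if np.any(fx_grid < 0):
        raise ValueError("spatial frequencies must be >= 0")
    n = photons.n_launched
    rd = np.empty(fx_grid.size)
    se = np.empty(fx_grid.size)
    for j, fx in enumerate(fx_grid):
        c = _signed_weights(photons, fx)
        total = float(c.sum())
        rd[j] = total / n
        var = float((c * c).sum()) / n - rd[j] ** 2
        se[j] = np.sqrt(max(var, 0.0) / n)
    return SFDReflectance(
        fx_grid=fx_grid,
        rd=rd,
        se=se,
        n_launched=n,
        wavelength_nm=photons.wavelength_nm,
        medium_fingerprint=photons.medium_fingerprint,
    )


def pzmax_density(photons: DetectedPhotonSet, fx: float, z_edges) -> PzmaxDistribution:
    """Tally each detected photon's signed weight at its maximum depth.

    Each photon is tallied exactly once, so the depth integral of the
    density equals Rd(fx).
    """
    z_edges = np.asarray(z_edges, dtype=float)
    if z_edges.ndim != 1 or z_edges.size < 2 or np.any(np.diff(z_edges) <= 0):
        raise ValueError("z_edges must be strictly increasing with >= 2 entries")
    if fx < 0:
        raise ValueError("fx must be >= 0")
    zmax = photons.z_max
    if photons.n_detected and (
        zmax.min() < z_edges[0] - 1e-9 or zmax.max() > z_edges[-1] + 1e-9
    ):
        raise ValueError(
            "z_max outside the z_edges range: tally does not cover the medium"
        )
    c = _signed_weights(photons, fx)
    mass, _ = np.histogram(np.clip(zmax, z_edges[0], z_edges[-1]), bins=z_edges, weights=c)
    widths = np.diff(z_edges)
    n = photons.n_launched
    density = mass / widths / n
    return PzmaxDistribution(
        z_edges=z_edges,
        density=density,
        fx=float(fx),
        rd=float(c.sum()) / n,
        n_launched=n,
        wavelength_nm=photons.wavelength_nm,
    )


def layer_partitioned_reflectance(
    pz: PzmaxDistribution, medium: LayeredMedium
) -> dict[str, float]:
    """Integrate pzmax over each layer's depth interval.

    Requires bin edges aligned with the layer boundaries (use
    :func:`default_z_edges`); the shares sum to Rd(fx) exactly.
    """
    edges = pz.z_edges
    shares: dict[str, float] = {}
    for k, lay in enumerate(medium.layers):
        lo_idx = np.searchsorted(edges, lay.z_top)
        hi_idx = np.searchsorted(edges, lay.z_bottom)
        if (
            lo_idx >= edges.size
            or hi_idx >= edges.size
            or abs(edges[lo_idx] - lay.z_top) > 1e-9
            or abs(edges[hi_idx] - lay.z_bottom) > 1e-9
        ):
            raise ValueError(
                f"bin edges not aligned with boundaries of layer "
                f"{lay.name or k}; re-bin with default_z_edges(..., "
                "layer_boundaries=medium.boundaries)"
            )
        name = lay.name or f"layer{k}"
        shares[name] = float(pz.bin_masses[lo_idx:hi_idx].sum())
    return shares


def mc_standard_error(
    photons: DetectedPhotonSet,
    statistic,
    n_batches: int = 20,
):
    """Batch-means standard error of any per-photon-set scalar statistic.

    ``statistic`` maps (photons, detected-photon indices, n_launched in
    that subset) -> float; photons are split into ``n_batches`` equal
    launch-index batches.  Returns (estimate over all photons, SE).
    """
    if photons.n_launched < n_batches:
        raise ValueError("fewer launched photons than batches")
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    per_batch = photons.n_launched / n_batches
    batch_of = np.minimum(
        (photons.photon_index / per_batch).astype(np.int64), n_batches - 1
    )
    launched = np.diff(
        np.floor(np.arange(n_batches + 1) * per_batch).astype(np.int64)
    )
    values = np.empty(n_batches)
    for b in range(n_batches):
        sel = np.nonzero(batch_of == b)[0]
        values[b] = statistic(photons, sel, int(launched[b]))
    est = statistic(photons, np.arange(photons.n_detected), photons.n_launched)
    se = float(values.std(ddof=1) / np.sqrt(n_batches))
    return est, se


def batch_rd_curves(
    photons: DetectedPhotonSet, fx_grid, n_batches: int = 20
) -> np.ndarray:
    """Rd(fx) per launch-index batch, shape (n_batches, n_fx).

    Each batch is normalized by its own launched-photon count, so the
    batch mean estimates the same quantity as the full tally.
    """
    fx_grid = np.atleast_1d(np.asarray(fx_grid, dtype=float))
    if photons.n_launched < n_batches:
        raise ValueError("fewer launched photons than batches")
    per_batch = photons.n_launched / n_batches
    batch_of = np.minimum(
        (photons.photon_index / per_batch).astype(np.int64), n_batches - 1
    )
    counts = np.diff(
        np.floor(np.arange(n_batches + 1) * per_batch).astype(np.int64)
    )
    curves = np.zeros((n_batches, fx_grid.size))
    for j, fx in enumerate(fx_grid):
        c = _signed_weights(photons, fx)
        curves[:, j] = np.bincount(batch_of, weights=c, minlength=n_batches)
    curves /= counts[:, None]
    return curves
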