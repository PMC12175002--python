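"""Penetration-depth statistics of detected reflectance.

Built on the maximum-penetration-depth density pzmax(z): the cumulative
distribution Pzmax(z <= d), the depth quantiles dm defined by
m = 100 * Pzmax(z <= dm) / Rd (d50 is the median sampling depth), the
difference of pzmax between a perturbed and a baseline scenario, and the
per-layer decomposition of the reflectance change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfd_tally import PzmaxDistribution, layer_partitioned_reflectance
from .skin_optics import LayeredMedium

__all__ = [
    "DepthQuantiles",
    "DeltaPzmax",
    "cumulative_pzmax",
    "depth_quantile",
    "depth_quantiles",
    "delta_pzmax",
    "delta_layer_contributions",
]


@dataclass
class DepthQuantiles:
    """Depths dm enclosing m percent of the detected reflectance at one fx."""

    fx: float
    levels: np.ndarray  # percent, e.g. 10, 25, 50, 75, 90
    dm: np.ndarray      # mm, same shape as levels
    rd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fx": self.fx, "m": self.levels, "dm_mm": self.dm})


@dataclass
class DeltaPzmax:
    """Bin-wise pzmax difference (perturbed minus baseline) at one fx."""

    z_edges: np.ndarray
    delta_density: np.ndarray
    fx: float
    delta_rd: float

    @property
    def bin_masses(self) -> np.ndarray:
        return self.delta_density * np.diff(self.z_edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_lo": self.z_edges[:-1],
                "z_hi": self.z_edges[1:],
                "delta_density": self.delta_density,
            }
        )


def cumulative_pzmax(pz: PzmaxDistribution, d: float) -> float:
    """Pzmax(z <= d): detected weight with maximum depth not exceeding d.

    Piecewise linear within bins; at d = total depth this returns Rd(fx)
    exactly (same tallies, no re-normalization).
    """
    edges = pz.z_edges
    if d < edges[0] - 1e-12 or d > edges[-1] + 1e-12:
        raise ValueError(
            f"depth d = {d} mm outside the tallied range "
            f"[{edges[0]}, {edges[-1]}] mm"
        )
    d = min(max(d, edges[0]), edges[-1])
    masses = pz.bin_masses
    idx = np.searchsorted(edges, d, side="right") - 1
    if idx >= masses.size:  # d exactly at the bottom edge
        return float(masses.sum())
    total = float(masses[:idx].sum())
    frac = (d - edges[idx]) / (edges[idx + 1] - edges[idx])
    return total + float(masses[idx]) * frac


def depth_quantile(pz: PzmaxDistribution, m: float) -> float:
    """Smallest depth dm with 100 * Pzmax(z <= dm) / Rd >= m.

    Linear interpolation within the crossing bin; ties break toward the
    smaller depth.  Undefined (raises) when Rd(fx) <= 0, as happens for
    signed tallies at high fx.
    """
    if not 0.0 < m < 100.0:
        raise ValueError("quantile level m must lie in (0, 100)")
    if pz.rd <= 0.0:
        raise ValueError(
            "depth quantiles undefined: Rd(fx) <= 0 for this signed tally"
        )
    target = m / 100.0 * pz.rd
    masses = pz.bin_masses
    cum = np.cumsum(masses)
    # first bin whose cumulative mass reaches the target
    idx = int(np.searchsorted(cum, target, side="left"))
    if idx >= masses.size:
        return float(pz.z_edges[-1])
    below = cum[idx] - masses[idx]
    if masses[idx] <= 0:
        return float(pz.z_edges[idx])
    frac = (target - below) / masses[idx]
    frac = min(max(frac, 0.0), 1.0)
    return float(pz.z_edges[idx] + frac * (pz.z_edges[idx + 1] - pz.z_edges[idx]))


def depth_quantiles(
    pz: PzmaxDistribution, levels=(10.0, 25.0, 50.0, 75.0, 90.0)
) -> DepthQuantiles:
    """dm for a set of percentage levels (default d10 ... d90)."""
    levels = np.asarray(levels, dtype=float)
    dm = np.array([depth_quantile(pz, m) for m in levels])
    return DepthQuantiles(fx=pz.fx, levels=levels, dm=dm, rd=pz.rd)


def delta_pzmax(
    baseline: PzmaxDistribution, perturbed: PzmaxDistribution
) -> DeltaPzmax:
    """Perturbed-minus-baseline pzmax difference on a shared binning."""
    if baseline.z_edges.shape != perturbed.z_edges.shape or np.any(
        np.abs(baseline.z_edges - perturbed.z_edges) > 1e-12
    ):
        raise ValueError("pzmax distributions must share identical z bins")
    if abs(baseline.fx - perturbed.fx) > 1e-12:
        raise ValueError("pzmax distributions must share the same fx")
    return DeltaPzmax(
        z_edges=baseline.z_edges.copy(),
        delta_density=perturbed.density - baseline.density,
        fx=baseline.fx,
        delta_rd=perturbed.rd - baseline.rd,
    )


def delta_layer_contributions(
    baseline_pz: PzmaxDistribution,
    perturbed_pz: PzmaxDistribution,
    medium: LayeredMedium,
) -> dict[str, float]:
    """Per-layer integrals of the pzmax difference at one fx.

    The values sum to Delta Rd(fx) exactly (difference of two exact
    layer partitions).
    """
    base = layer_partitioned_reflectance(baseline_pz, medium)
    pert = layer_partitioned_reflectance(perturbed_pz, medium)
    return {name: pert[name] - base[name] for name in base}
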