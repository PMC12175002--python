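"""Sensitivity-optimal measurement design for SLIM.

Builds the decision surface Delta Rd(lambda, fx) between a baseline and
a perturbed scenario, extracts per-wavelength optima (the spatial
frequency maximizing |Delta Rd| and its value), finds the
melanin-robust (lambda, fx) pair, and runs the dimensionless
homogeneous-medium study fx* = fx_opt * l* versus musp/mua.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc_engine import DetectedPhotonSet, TransportConfig, run_transport
from .sfd_tally import SFDReflectance, default_fx_grid, sfd_reflectance
from .skin_optics import LayeredMedium, OpticalLayer, transport_mfp

__all__ = [
    "DeltaReflectanceMap",
    "OptimalPair",
    "FxStarCurve",
    "delta_reflectance_map",
    "delta_reflectance_correlated",
    "optimal_fx",
    "max_delta_spectrum",
    "melanin_uniform_pair",
    "homogeneous_fx_star",
    "fx_opt_spectrum_homogeneous",
    "homogeneous_medium",
    "derive_seed",
]


def derive_seed(master_seed: int, *coords) -> int:
    """Stable per-cell seed below 2**31 from a master seed and coordinates.

    Cells (wavelength, scenario, ...) get independent streams regardless
    of execution order.
    """
    import hashlib

    # stable across processes (never Python's salted hash())
    payload = repr((int(master_seed),) + tuple(str(c) for c in coords)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


@dataclass
class DeltaReflectanceMap:
    """Delta Rd = Rd_perturbed - Rd_baseline over a (lambda, fx) grid."""

    wavelengths: np.ndarray          # (n_wl,)
    fx_grid: np.ndarray              # (n_fx,)
    delta_rd: np.ndarray             # (n_wl, n_fx)
    se: np.ndarray                   # (n_wl, n_fx)
    melanin_fv: float
    description: str = ""
    batch_curves: np.ndarray | None = None  # (n_wl, n_batches, n_fx)

    def __post_init__(self) -> None:
        if self.delta_rd.shape != (self.wavelengths.size, self.fx_grid.size):
            raise ValueError("delta_rd shape must match (wavelengths, fx_grid)")
        if self.se.shape != self.delta_rd.shape:
            raise ValueError("se shape must match delta_rd")
        if np.any(~np.isfinite(self.delta_rd)):
            raise ValueError("delta map has missing cells")

    def row(self, wavelength_nm: float) -> int:
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength_nm} nm not in map")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, wl in enumerate(self.wavelengths):
            for j, fx in enumerate(self.fx_grid):
                rows.append(
                    (self.melanin_fv, wl, fx, self.delta_rd[i, j], self.se[i, j])
                )
        return pd.DataFrame(
            rows, columns=["melanin_fv", "wavelength_nm", "fx", "delta_rd", "se"]
        )


@dataclass
class OptimalPair:
    """Per-wavelength optimum of |Delta Rd| over spatial frequency."""

    wavelength_nm: float
    fx_at_max: float
    max_abs_delta: float
    fx_uncertainty: float
    defined: bool = True


@dataclass
class FxStarCurve:
    """Dimensionless optimal spatial frequency versus musp/mua at fixed l*."""

    ratio_grid: np.ndarray
    fx_star: np.ndarray
    l_star: float
    pert_magnitude: float

    def interpolate(self, ratio: float) -> float:
        lo, hi = self.ratio_grid.min(), self.ratio_grid.max()
        if not lo <= ratio <= hi:
            raise ValueError(
                f"musp/mua ratio {ratio:.3g} outside the simulated range "
                f"[{lo:.3g}, {hi:.3g}]; extrapolation refused"
            )
        # ratios span decades: interpolate on log-ratio
        return float(
            np.interp(np.log(ratio), np.log(self.ratio_grid), self.fx_star)
        )


def delta_reflectance_map(
    baseline_runs: list[SFDReflectance],
    perturbed_runs: list[SFDReflectance],
    melanin_fv: float,
    description: str = "",
    batch_curves: np.ndarray | None = None,
) -> DeltaReflectanceMap:
    """Cell-wise differences of matched baseline/perturbed Rd curves.

    Standard errors combine in quadrature, which is conservative when
    the runs share random numbers; use
    :func:`delta_reflectance_correlated` when the perturbed set is a
    pMC reweighting of the same trajectories.
    """
    if len(baseline_runs) != len(perturbed_runs) or not baseline_runs:
        raise ValueError("need matched, nonempty baseline and perturbed runs")
    fx = baseline_runs[0].fx_grid
    wavelengths, delta, se = [], [], []
    for b, p in zip(baseline_runs, perturbed_runs):
        if b.fx_grid.shape != p.fx_grid.shape or np.any(b.fx_grid != p.fx_grid):
            raise ValueError("baseline and perturbed fx grids differ")
        if (b.wavelength_nm is None) != (p.wavelength_nm is None) or (
            b.wavelength_nm is not None
            and not np.isclose(b.wavelength_nm, p.wavelength_nm)
        ):
            raise ValueError("baseline and perturbed wavelengths differ")
        wavelengths.append(np.nan if b.wavelength_nm is None else b.wavelength_nm)
        delta.append(p.rd - b.rd)
        se.append(np.hypot(b.se, p.se))
    return DeltaReflectanceMap(
        wavelengths=np.asarray(wavelengths, float),
        fx_grid=fx.copy(),
        delta_rd=np.asarray(delta),
        se=np.asarray(se),
        melanin_fv=melanin_fv,
        description=description,
        batch_curves=batch_curves,
    )


def delta_reflectance_correlated(
    baseline: DetectedPhotonSet, perturbed: DetectedPhotonSet, fx_grid
) -> tuple[np.ndarray, np.ndarray]:
    """Delta Rd(fx) and SE from a shared trajectory ensemble.

    Requires the perturbed set to be a reweighting of the identical
    trajectories (same photon indices); the per-photon weight difference
    then gives the exact correlated-difference variance.
    """
    if baseline.n_detected != perturbed.n_detected or np.any(
        baseline.photon_index != perturbed.photon_index
    ):
        raise ValueError("photon sets do not share trajectories")
    fx_grid = np.atleast_1d(np.asarray(fx_grid, float))
    n = baseline.n_launched
    dw = perturbed.w - baseline.w
    delta = np.empty(fx_grid.size)
    se = np.empty(fx_grid.size)
    for j, fx in enumerate(fx_grid):
        c = dw if fx == 0 else dw * np.cos(2.0 * np.pi * fx * baseline.dx)
        delta[j] = float(c.sum()) / n
        var = float((c * c).sum()) / n - delta[j] ** 2
        se[j] = np.sqrt(max(var, 0.0) / n)
    return delta, se


def optimal_fx(
    fx_grid,
    delta_rd,
    se=None,
    fx_max: float = 0.5,
    window: float = 0.05,
    batch_curves: np.ndarray | None = None,
    wavelength_nm: float = np.nan,
) -> OptimalPair:
    """Locate the spatial frequency maximizing |Delta Rd|.

    A local quadratic fit over +/- ``window`` around the discrete argmax
    stabilizes the estimate against grid-level Monte Carlo noise; the
    uncertainty is the spread of per-batch argmax positions when batch
    curves are available.  A curve that is flat relative to its noise
    (max |Delta Rd| < 2 SE) yields an undefined optimum.
    """
    fx_grid = np.asarray(fx_grid, float)
    delta_rd = np.asarray(delta_rd, float)
    mask = fx_grid <= fx_max + 1e-12
    fx_g = fx_grid[mask]
    mag = np.abs(delta_rd[mask])
    i0 = int(np.argmax(mag))

    if se is not None:
        se_g = np.asarray(se, float)[mask]
        if mag[i0] < 2.0 * se_g[i0]:
            return OptimalPair(wavelength_nm, np.nan, float(mag[i0]), np.nan, False)

    fx_hat = float(fx_g[i0])
    if 0 < i0 < fx_g.size - 1:
        win = (fx_g >= fx_g[i0] - window - 1e-12) & (fx_g <= fx_g[i0] + window + 1e-12)
        if win.sum() >= 3:
            coeff = np.polyfit(fx_g[win], mag[win], 2)
            if coeff[0] < 0:
                vertex = -coeff[1] / (2.0 * coeff[0])
                lo, hi = fx_g[win].min(), fx_g[win].max()
                fx_hat = float(min(max(vertex, lo), hi))

    unc = np.nan
    if batch_curves is not None:
        bc = np.abs(np.asarray(batch_curves, float)[:, mask])
        arg = fx_g[np.argmax(bc, axis=1)]
        unc = float(arg.std(ddof=1) / np.sqrt(bc.shape[0]))
    return OptimalPair(wavelength_nm, fx_hat, float(mag[i0]), unc, True)


def max_delta_spectrum(
    dmap: DeltaReflectanceMap, fx_max: float = 0.5, window: float = 0.05
) -> list[OptimalPair]:
    """Per-wavelength optimal_fx plus |Delta Rd| at the optimum."""
    out = []
    for i, wl in enumerate(dmap.wavelengths):
        bc = None if dmap.batch_curves is None else dmap.batch_curves[i]
        out.append(
            optimal_fx(
                dmap.fx_grid,
                dmap.delta_rd[i],
                se=dmap.se[i],
                fx_max=fx_max,
                window=window,
                batch_curves=bc,
                wavelength_nm=float(wl),
            )
        )
    return out


def melanin_uniform_pair(
    maps: dict[float, DeltaReflectanceMap],
    floor_fraction: float = 0.5,
    fx_max: float = 0.5,
) -> tuple[float, float, float]:
    """(lambda, fx) with the most melanin-consistent reflectance change.

    Candidates are the per-wavelength optima of each melanin level (the
    spread of Delta Rd between melanin levels shrinks monotonically as
    fx attenuates all signals together, so comparing raw grid cells
    would always run to the grid edge where the signal itself is weak;
    the useful robustness question is how consistent the *achievable*
    reflectance change is).  Wavelengths where any level's peak
    |Delta Rd| falls below ``floor_fraction`` of that level's map-wide
    peak are excluded; among the rest the wavelength minimizing the
    range of peak |Delta Rd| across melanin levels wins, and the
    reported fx is the melanin-average of the optimal fx there.
    Returns (wavelength, fx, spread of peak |Delta Rd|).
    """
    if len(maps) < 2:
        raise ValueError("need at least two melanin levels")
    fvs = sorted(maps)
    ref = maps[fvs[0]]
    n_wl = ref.wavelengths.size
    peak = np.empty((len(fvs), n_wl))
    fx_at = np.empty((len(fvs), n_wl))
    for a, fv in enumerate(fvs):
        m = maps[fv]
        if m.delta_rd.shape != ref.delta_rd.shape:
            raise ValueError("maps must share the (lambda, fx) grid")
        for i, pair in enumerate(max_delta_spectrum(m, fx_max=fx_max)):
            peak[a, i] = pair.max_abs_delta
            fx_at[a, i] = pair.fx_at_max if pair.defined else np.nan
    feasible = np.all(
        peak >= floor_fraction * peak.max(axis=1, keepdims=True), axis=0
    ) & np.all(np.isfinite(fx_at), axis=0)
    if not feasible.any():
        raise ValueError(
            "no wavelength keeps its peak |Delta Rd| above "
            f"{floor_fraction:.0%} of the map-wide peak at every melanin "
            "level; lower floor_fraction"
        )
    spread = peak.max(axis=0) - peak.min(axis=0)
    spread_masked = np.where(feasible, spread, np.inf)
    best = spread_masked.min()
    # exact ties (e.g. identical maps) break toward the strongest signal
    tied = np.nonzero(spread_masked == best)[0]
    i = int(tied[np.argmax(peak.mean(axis=0)[tied])])
    return (
        float(ref.wavelengths[i]),
        float(fx_at[:, i].mean()),
        float(spread[i]),
    )


def homogeneous_medium(
    ratio: float,
    l_star: float = 1.0,
    g: float = 0.8,
    n: float = 1.4,
    slab_lstar: float = 20.0,
) -> LayeredMedium:
    """Thick homogeneous slab with musp/mua = ratio at fixed l*.

    mua = 1 / ((1 + ratio) l*), musp = ratio / ((1 + ratio) l*); the slab
    spans ``slab_lstar`` transport mean free paths, effectively
    semi-infinite for reflectance.
    """
    if ratio <= 0 or l_star <= 0:
        raise ValueError("ratio and l_star must be positive")
    mua = 1.0 / ((1.0 + ratio) * l_star)
    musp = ratio / ((1.0 + ratio) * l_star)
    layer = OpticalLayer(
        z_top=0.0,
        z_bottom=slab_lstar * l_star,
        mua=mua,
        mus=musp / (1.0 - g),
        g=g,
        n=n,
        name="homogeneous",
    )
    return LayeredMedium(layers=(layer,))


def homogeneous_fx_star(
    ratio_grid,
    l_star: float = 1.0,
    pert_magnitude: float = -0.10,
    n_photons: int = 200_000,
    seed: int = 0,
    g: float = 0.8,
    n: float = 1.4,
    fx_grid=None,
    fx_max: float | None = None,
) -> FxStarCurve:
    """Dimensionless optimal spatial frequency versus musp/mua.

    For each ratio, a baseline run and a whole-medium scattering
    perturbation of relative size ``pert_magnitude`` (default -10%,
    small enough that the optimum location is perturbation-size
    independent by transport linearity) share random numbers; fx* is the
    fx maximizing |Delta Rd|, scaled by l*.  A curve whose maximum
    change sits at fx = 0 reports fx* = 0 (no refinement past the grid
    edge).
    """
    ratio_grid = np.asarray(ratio_grid, float)
    if np.any(ratio_grid <= 0):
        raise ValueError("ratios must be positive")
    if fx_grid is None:
        fx_grid = default_fx_grid(1.0 / l_star, 0.01 / l_star)
    if fx_max is None:
        fx_max = float(np.max(fx_grid))
    fx_star = np.empty(ratio_grid.size)
    for k, ratio in enumerate(ratio_grid):
        base_med = homogeneous_medium(ratio, l_star, g, n)
        pert_med = LayeredMedium(
            layers=(
                OpticalLayer(
                    z_top=0.0,
                    z_bottom=base_med.layers[0].z_bottom,
                    mua=base_med.layers[0].mua,
                    mus=base_med.layers[0].mus * (1.0 + pert_magnitude),
                    g=g,
                    n=n,
                    name="homogeneous",
                ),
            )
        )
        cfg = TransportConfig(
            n_photons=n_photons, seed=derive_seed(seed, "fxstar", round(ratio, 9))
        )
        base_ph, _ = run_transport(base_med, cfg)
        pert_ph, _ = run_transport(pert_med, cfg)
        rb = sfd_reflectance(base_ph, fx_grid)
        rp = sfd_reflectance(pert_ph, fx_grid)
        opt = optimal_fx(
            fx_grid,
            rp.rd - rb.rd,
            se=np.hypot(rb.se, rp.se),
            fx_max=fx_max,
            window=0.05 / l_star,
        )
        fx_star[k] = 0.0 if not opt.defined else opt.fx_at_max * l_star
    return FxStarCurve(
        ratio_grid=ratio_grid,
        fx_star=fx_star,
        l_star=l_star,
        pert_magnitude=pert_magnitude,
    )


def fx_opt_spectrum_homogeneous(
    optical_properties: dict[float, tuple[float, float]],
    curve: FxStarCurve,
) -> dict[float, float]:
    """Map per-wavelength (mua, musp) to physical fx_opt via the fx* curve.

    fx_opt(lambda) = fx*(musp/mua) / l*(lambda); refuses ratios outside
    the simulated curve range.
    """
    out = {}
    for wl, (mua, musp) in sorted(optical_properties.items()):
        ratio = musp / mua
        out[wl] = curve.interpolate(ratio) / transport_mfp(mua, musp)
    return out
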