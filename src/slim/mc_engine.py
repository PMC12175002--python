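"""Photon transport in a layered slab.

Pencil beam at normal incidence, Henyey-Greenstein scattering,
unpolarized Fresnel reflection/refraction at every index-mismatched
interface, absorption weighting (implicit capture) and Russian roulette.
Photons leaving through the top surface are detected with their current
weight and sufficient statistics (lateral displacement, maximum depth
visited, per-layer path lengths and collision counts), which feed every
downstream tally and the perturbation reweighting.

Conventions: z increases downward, surface at z = 0, layers are
half-open intervals [z_top, z_bottom); specular reflection is removed
analytically at launch and reported separately from diffuse reflectance.
Each photon draws from its own counter-derived random substream, so
trajectories are independent of batching and bit-reproducible for a
given (seed, medium, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit

from .skin_optics import LayeredMedium

__all__ = [
    "TransportConfig",
    "DetectedPhotonSet",
    "RunDiagnostics",
    "run_transport",
    "sample_free_path",
    "sample_hg_cosine",
    "fresnel_unpolarized",
    "roulette",
]

_U64_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _photon_state(seed, index):
    # independent substream per photon index: mix the seed and the
    # counter so trajectories do not depend on batch boundaries
    return _mix64((seed + np.uint64(1)) * _U64_GAMMA ^ _mix64(np.uint64(index) + _U64_GAMMA))


@njit(cache=True, inline="always")
def _next_uniform(state):
    """Advance the splitmix64 stream; returns (new_state, u in (0, 1])."""
    state = state + _U64_GAMMA
    x = _mix64(state)
    return state, ((x >> np.uint64(11)) + np.uint64(1)) * _INV_2_53


@njit(cache=True, inline="always")
def _hg_cosine(g, u):
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, inline="always")
def _fresnel(n1, n2, ci):
    if n1 == n2:
        return 0.0
    if ci > 1.0:
        ci = 1.0
    sin_i = np.sqrt(max(0.0, 1.0 - ci * ci))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * ci - n2 * cos_t) / (n1 * ci + n2 * cos_t)
    rp = (n1 * cos_t - n2 * ci) / (n1 * cos_t + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport_kernel(
    zb,          # (nl+1,) layer boundaries, zb[0] = 0
    mua,         # (nl,)
    mus,         # (nl,)
    gg,          # (nl,)
    nn,          # (nl,) refractive indices
    n_ambient,
    n_photons,
    seed,        # uint64
    rt,          # roulette threshold
    ps,          # roulette survival probability
    max_events,
    det_w, det_dx, det_dy, det_zmax, det_L, det_J, det_idx,
):
    nl = mua.shape[0]
    r_spec = ((n_ambient - nn[0]) / (n_ambient + nn[0])) ** 2
    w0 = 1.0 - r_spec

    detected_sum = 0.0
    transmitted_sum = 0.0
    absorbed_sum = 0.0
    roulette_loss = 0.0
    roulette_gain = 0.0
    total_events = 0
    roulette_kills = 0
    ndet = 0

    L_loc = np.zeros(nl)
    J_loc = np.zeros(nl, np.int64)

    for i in range(n_photons):
        state = _photon_state(seed, i)
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        layer = 0
        zmax = 0.0
        for k in range(nl):
            L_loc[k] = 0.0
            J_loc[k] = 0
        events = 0
        absorbed_loc = 0.0
        alive = True

        while alive and events < max_events:
            mut = mua[layer] + mus[layer]
            if mut > 0.0:
                state, u = _next_uniform(state)
                s = -np.log(u) / mut
            else:
                s = 1e30  # transparent layer: fly to the boundary

            if uz > 0.0:
                db = (zb[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[layer] - z) / uz
            else:
                db = 1e30

            if s < db:
                # collide inside the current layer
                x += ux * s
                y += uy * s
                z += uz * s
                if z > zmax:
                    zmax = z
                L_loc[layer] += s
                J_loc[layer] += 1
                events += 1
                absorbed_loc += w * mua[layer] / mut
                w *= mus[layer] / mut

                state, u = _next_uniform(state)
                cost = _hg_cosine(gg[layer], u)
                state, u = _next_uniform(state)
                phi = 2.0 * np.pi * u
                sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    tx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    ty = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    tz = -den * sint * cosp + uz * cost
                    ux = tx
                    uy = ty
                    uz = tz
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm

                if w < rt:
                    state, u = _next_uniform(state)
                    if u <= ps:
                        roulette_gain += w / ps - w
                        w /= ps
                    else:
                        roulette_loss += w
                        roulette_kills += 1
                        alive = False
            else:
                # advance to the boundary and resolve the interface
                x += ux * db
                y += uy * db
                going_down = uz > 0.0
                z = zb[layer + 1] if going_down else zb[layer]
                if z > zmax:
                    zmax = z
                L_loc[layer] += db

                n1 = nn[layer]
                if going_down:
                    # matched exit at the bottom: deep photons terminate
                    n2 = nn[layer + 1] if layer + 1 < nl else nn[layer]
                else:
                    n2 = nn[layer - 1] if layer > 0 else n_ambient
                ci = abs(uz)
                refl = _fresnel(n1, n2, ci)
                crossed = True
                if refl > 0.0:
                    state, u = _next_uniform(state)
                    if u <= refl:
                        uz = -uz
                        crossed = False
                if crossed:
                    if n1 != n2:
                        ratio = n1 / n2
                        sin_i2 = max(0.0, 1.0 - ci * ci)
                        cos_t = np.sqrt(max(0.0, 1.0 - ratio * ratio * sin_i2))
                        ux *= ratio
                        uy *= ratio
                        uz = cos_t if going_down else -cos_t
                    if going_down:
                        if layer + 1 >= nl:
                            transmitted_sum += w
                            alive = False
                        else:
                            layer += 1
                    else:
                        if layer == 0:
                            detected_sum += w
                            det_w[ndet] = w
                            det_dx[ndet] = x
                            det_dy[ndet] = y
                            det_zmax[ndet] = zmax
                            for k in range(nl):
                                det_L[ndet, k] = L_loc[k]
                                det_J[ndet, k] = J_loc[k]
                            det_idx[ndet] = i
                            ndet += 1
                            alive = False
                        else:
                            layer -= 1

        absorbed_sum += absorbed_loc
        if events >= max_events and alive:
            # safety cap: book remaining weight as absorbed so the
            # ledger still closes
            absorbed_sum += w
        total_events += events

    diag = np.zeros(8)
    diag[0] = detected_sum
    diag[1] = transmitted_sum
    diag[2] = absorbed_sum
    diag[3] = roulette_loss
    diag[4] = roulette_gain
    diag[5] = float(total_events)
    diag[6] = float(roulette_kills)
    diag[7] = r_spec
    return ndet, diag


@dataclass(frozen=True)
class TransportConfig:
    """Engine settings; the photon budget and seed live here."""

    n_photons: int
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_events: int = 1_000_000
    record_per_layer: bool = True

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must lie in (0, 1)")
        # a threshold of exactly 0 disables roulette entirely
        if self.roulette_threshold < 0:
            raise ValueError("roulette_threshold must be >= 0")


@dataclass
class RunDiagnostics:
    """Weight-ledger and bookkeeping summary of one transport run."""

    specular_fraction: float
    detected_weight_fraction: float
    transmitted_weight_fraction: float
    absorbed_weight_fraction: float
    roulette_loss_fraction: float
    roulette_gain_fraction: float
    roulette_kills: int
    mean_events_per_photon: float

    def conservation_residual(self) -> float:
        """Deviation of the exact weight ledger from unity.

        Includes the net roulette term, so the identity is exact (to
        floating-point accumulation) even with roulette enabled; without
        the net term conservation holds only in expectation.
        """
        total = (
            self.specular_fraction
            + self.detected_weight_fraction
            + self.transmitted_weight_fraction
            + self.absorbed_weight_fraction
            + self.roulette_loss_fraction
            - self.roulette_gain_fraction
        )
        return total - 1.0


@dataclass
class DetectedPhotonSet:
    """Sufficient statistics of every detected photon.

    ``L`` and ``J`` are per-layer path lengths (mm) and collision counts
    with shape (n_detected, n_layers); ``photon_index`` is the launch
    counter of each detected photon (used for batch-means errors and for
    reproducible sub-sampling).
    """

    w: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    z_max: np.ndarray
    L: np.ndarray
    J: np.ndarray
    photon_index: np.ndarray
    n_launched: int
    seed: int
    specular_fraction: float
    total_depth: float
    layer_boundaries: np.ndarray
    wavelength_nm: float | None = None
    medium_fingerprint: str = ""
    provenance: tuple[str, ...] = ()

    @property
    def n_detected(self) -> int:
        return self.w.shape[0]

    @property
    def n_layers(self) -> int:
        return self.L.shape[1]

    def effective_sample_size(self) -> float:
        """(sum w)^2 / sum w^2 — degrades under pMC reweighting."""
        sw = float(self.w.sum())
        sw2 = float((self.w**2).sum())
        return sw * sw / sw2 if sw2 > 0 else 0.0

    def validate(self) -> None:
        if np.any(self.w <= 0):
            raise ValueError("detected weights must be positive")
        if np.any(self.z_max < 0) or np.any(self.z_max > self.total_depth + 1e-9):
            raise ValueError("z_max outside the medium depth range")
        if np.any(self.L < 0) or np.any(self.J < 0):
            raise ValueError("negative per-layer path length or collision count")

    def save(self, path) -> None:
        """Columnar HDF5 dump with run metadata attributes."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("w", "dx", "dy", "z_max", "L", "J", "photon_index"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["n_launched"] = self.n_launched
            f.attrs["seed"] = self.seed
            f.attrs["specular_fraction"] = self.specular_fraction
            f.attrs["total_depth"] = self.total_depth
            f.attrs["layer_boundaries"] = self.layer_boundaries
            f.attrs["wavelength_nm"] = -1.0 if self.wavelength_nm is None else self.wavelength_nm
            f.attrs["medium_fingerprint"] = self.medium_fingerprint
            f.attrs["provenance"] = json.dumps(list(self.provenance))

    @classmethod
    def load(cls, path) -> "DetectedPhotonSet":
        import h5py

        with h5py.File(path, "r") as f:
            wl = float(f.attrs["wavelength_nm"])
            return cls(
                w=f["w"][:],
                dx=f["dx"][:],
                dy=f["dy"][:],
                z_max=f["z_max"][:],
                L=f["L"][:],
                J=f["J"][:],
                photon_index=f["photon_index"][:],
                n_launched=int(f.attrs["n_launched"]),
                seed=int(f.attrs["seed"]),
                specular_fraction=float(f.attrs["specular_fraction"]),
                total_depth=float(f.attrs["total_depth"]),
                layer_boundaries=np.asarray(f.attrs["layer_boundaries"]),
                wavelength_nm=None if wl < 0 else wl,
                medium_fingerprint=str(f.attrs["medium_fingerprint"]),
                provenance=tuple(json.loads(f.attrs["provenance"])),
            )

    def to_frame(self):
        import pandas as pd

        data = {
            "w": self.w,
            "dx_mm": self.dx,
            "dy_mm": self.dy,
            "z_max_mm": self.z_max,
            "photon_index": self.photon_index,
        }
        for k in range(self.n_layers):
            data[f"L{k}_mm"] = self.L[:, k]
            data[f"J{k}"] = self.J[:, k]
        return pd.DataFrame(data)


def run_transport(
    medium: LayeredMedium, config: TransportConfig
) -> tuple[DetectedPhotonSet, RunDiagnostics]:
    """Simulate photon transport; returns detected photons + diagnostics."""
    nl = len(medium.layers)
    zb = medium.boundaries.astype(float)
    mua = np.array([lay.mua for lay in medium.layers])
    mus = np.array([lay.mus for lay in medium.layers])
    gg = np.array([lay.g for lay in medium.layers])
    nn = np.array([lay.n for lay in medium.layers])
    if np.any((mua + mus) <= 0) and not np.isfinite(medium.total_depth):
        raise ValueError("zero-interaction layer of infinite extent")

    n = int(config.n_photons)
    det_w = np.empty(n)
    det_dx = np.empty(n)
    det_dy = np.empty(n)
    det_zmax = np.empty(n)
    det_L = np.empty((n, nl))
    det_J = np.empty((n, nl), np.int64)
    det_idx = np.empty(n, np.int64)

    ndet, diag = _transport_kernel(
        zb, mua, mus, gg, nn,
        float(medium.n_ambient),
        n,
        np.uint64(config.seed),
        float(config.roulette_threshold),
        float(config.roulette_survival),
        int(config.max_events),
        det_w, det_dx, det_dy, det_zmax, det_L, det_J, det_idx,
    )

    photons = DetectedPhotonSet(
        w=det_w[:ndet].copy(),
        dx=det_dx[:ndet].copy(),
        dy=det_dy[:ndet].copy(),
        z_max=det_zmax[:ndet].copy(),
        L=det_L[:ndet].copy() if config.record_per_layer else np.zeros((ndet, nl)),
        J=det_J[:ndet].copy() if config.record_per_layer else np.zeros((ndet, nl), np.int64),
        photon_index=det_idx[:ndet].copy(),
        n_launched=n,
        seed=config.seed,
        specular_fraction=float(diag[7]),
        total_depth=float(medium.total_depth),
        layer_boundaries=zb.copy(),
        wavelength_nm=medium.wavelength_nm,
        medium_fingerprint=medium.fingerprint(),
        provenance=("conventional",),
    )
    diagnostics = RunDiagnostics(
        specular_fraction=float(diag[7]),
        detected_weight_fraction=float(diag[0]) / n,
        transmitted_weight_fraction=float(diag[1]) / n,
        absorbed_weight_fraction=float(diag[2]) / n,
        roulette_loss_fraction=float(diag[3]) / n,
        roulette_gain_fraction=float(diag[4]) / n,
        roulette_kills=int(diag[6]),
        mean_events_per_photon=float(diag[5]) / n,
    )
    return photons, diagnostics


# --- transport kernels exposed for direct use and testing ---------------


def sample_free_path(mu_t: float, u: float) -> float:
    """Exponential free path s = -ln(u) / mu_t (mm)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    if not 0.0 < u <= 1.0:
        raise ValueError("u must lie in (0, 1]")
    return -np.log(u) / mu_t


def sample_hg_cosine(g: float, u: float) -> float:
    """Henyey-Greenstein inverse-CDF sample of the deflection cosine."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    return float(_hg_cosine(g, u))


def fresnel_unpolarized(n_i: float, n_t: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel reflection probability; 1 beyond critical angle."""
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_theta_i <= 1.0:
        raise ValueError("cos_theta_i must lie in [0, 1]")
    return float(_fresnel(n_i, n_t, cos_theta_i))


def roulette(weight: float, threshold: float, p_survive: float, u: float) -> float:
    """Expectation-preserving low-weight termination."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    if weight >= threshold:
        return weight
    return weight / p_survive if u <= p_survive else 0.0
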