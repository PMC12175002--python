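"""Wavelength-resolved optical properties of skin and the layered medium.

This module turns chromophore composition (hemoglobin, water, lipid,
melanin) and power-law scattering models into per-layer absorption and
scattering coefficients, and assembles the four-layer skin model
(epidermis / papillary dermis / reticular dermis / subcutis) used by the
transport engine.

Unit conventions (canonical throughout the package):

* lengths in mm, depths increase downward from the surface at z = 0;
* absorption and scattering coefficients in mm^-1;
* wavelengths in nm;
* hemoglobin concentrations in uM, molar extinctions in cm^-1 M^-1
  (the composite-absorption formula evaluates in cm^-1 and divides by 10).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "LayerComposition",
    "SkinModelSpec",
    "OpticalLayer",
    "LayeredMedium",
    "melanin_absorption",
    "composite_absorption",
    "epidermis_reduced_scattering",
    "dermis_reduced_scattering",
    "reduced_to_full_scattering",
    "transport_mfp",
    "build_skin_medium",
    "load_default_chromophore_table",
    "load_default_subcutis_musp",
    "default_skin_spec",
]

#: ln(10) x 1e-6: converts uM x (cm^-1 M^-1) products to cm^-1.
_BEER_LAMBERT_PREFACTOR = 2.303e-6

LAYER_NAMES = ("epidermis", "papillary_dermis", "reticular_dermis", "subcutis")
DEFAULT_THICKNESS_UM = (50.0, 200.0, 1100.0, 6150.0)
DEFAULT_G = (0.8, 0.8, 0.8, 0.75)
DEFAULT_N = (1.37, 1.40, 1.40, 1.44)


class WavelengthLookupError(KeyError):
    """A wavelength was requested that is not tabulated."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated chromophore data at discrete wavelengths.

    Molar extinctions for oxy/deoxy-hemoglobin are in cm^-1 M^-1; pure
    water and pure lipid absorption in cm^-1.  Lookups at wavelengths not
    in the table raise :class:`WavelengthLookupError` unless
    ``interpolate=True`` was set at construction (opt-in linear
    interpolation, used only for the homogeneous sweeps).
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mua_water: np.ndarray
    mua_lipid: np.ndarray
    provenance: str = "unspecified"
    interpolate: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a nonempty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb", "mua_water", "mua_lipid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid shape")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelength_nm", wl)

    def _column(self, name: str, wavelength_nm: float) -> float:
        wl = self.wavelength_nm
        col = getattr(self, name)
        idx = np.searchsorted(wl, wavelength_nm)
        if idx < wl.size and wl[idx] == wavelength_nm:
            return float(col[idx])
        if not self.interpolate:
            raise WavelengthLookupError(
                f"wavelength {wavelength_nm} nm not tabulated in chromophore "
                f"table ({self.provenance}); tabulated: {wl.tolist()}"
            )
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise WavelengthLookupError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, wl, col))

    @classmethod
    def from_csv(cls, path, interpolate: bool = False) -> "ChromophoreTable":
        df = pd.read_csv(path, comment="#")
        sources = df.get("source")
        provenance = str(sources.iloc[0]) if sources is not None else str(path)
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(float),
            eps_hbo2=df["eps_hbo2_cm_M"].to_numpy(float),
            eps_hb=df["eps_hb_cm_M"].to_numpy(float),
            mua_water=df["mua_water_cm"].to_numpy(float),
            mua_lipid=df["mua_lipid_cm"].to_numpy(float),
            provenance=provenance,
            interpolate=interpolate,
        )


@dataclass(frozen=True)
class LayerComposition:
    """Chromophore content of one tissue layer.

    Hemoglobin concentrations in uM; water/lipid as volume fractions.
    ``f_blood`` is informational (the hemoglobin concentrations already
    fold in the blood volume fraction).
    """

    c_hbo2: float = 0.0
    c_hb: float = 0.0
    f_water: float = 0.0
    f_lipid: float = 0.0
    f_blood: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_hbo2", "c_hb", "f_water", "f_lipid", "f_blood"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.f_water + self.f_lipid > 1.0 + 1e-12:
            raise ValueError("f_water + f_lipid must not exceed 1")


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous slab of the layered medium (all lengths in mm)."""

    z_top: float
    z_bottom: float
    mua: float
    mus: float
    g: float
    n: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if not self.z_bottom > self.z_top:
            raise ValueError("z_bottom must exceed z_top")

    @property
    def musp(self) -> float:
        """Reduced scattering mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)

    @property
    def l_star(self) -> float:
        """Transport mean free path 1 / (mua + musp), mm."""
        return transport_mfp(self.mua, self.musp)

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top


@dataclass(frozen=True)
class LayeredMedium:
    """Contiguous stack of optical layers below an ambient half-space."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float | None = None
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("medium needs at least one layer")
        if abs(layers[0].z_top) > 1e-12:
            raise ValueError("first layer must start at z = 0")
        for upper, lower in zip(layers, layers[1:]):
            if abs(upper.z_bottom - lower.z_top) > 1e-9:
                raise ValueError(
                    f"layers not contiguous at z = {upper.z_bottom} mm"
                )
        if not np.isfinite(layers[-1].z_bottom):
            raise ValueError("total depth must be finite")
        object.__setattr__(self, "layers", layers)

    @property
    def total_depth(self) -> float:
        return self.layers[-1].z_bottom

    @property
    def boundaries(self) -> np.ndarray:
        """Depth bounds (n_layers + 1,) including surface and bottom."""
        return np.array(
            [self.layers[0].z_top] + [lay.z_bottom for lay in self.layers]
        )

    def layer_index(self, name: str) -> int:
        for k, lay in enumerate(self.layers):
            if lay.name == name:
                return k
        raise KeyError(f"no layer named {name!r}")

    def fingerprint(self) -> str:
        """Short stable hash of the optical properties, for provenance."""
        import hashlib

        payload = repr(
            [
                (lay.z_top, lay.z_bottom, lay.mua, lay.mus, lay.g, lay.n)
                for lay in self.layers
            ]
            + [self.n_ambient, self.wavelength_nm]
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [lay.name for lay in self.layers],
                "z_top_mm": [lay.z_top for lay in self.layers],
                "z_bottom_mm": [lay.z_bottom for lay in self.layers],
                "mua_mm": [lay.mua for lay in self.layers],
                "mus_mm": [lay.mus for lay in self.layers],
                "g": [lay.g for lay in self.layers],
                "n": [lay.n for lay in self.layers],
            }
        )


@dataclass(frozen=True)
class SkinModelSpec:
    """Composition-level description of the four-layer skin model.

    ``melanin_fv`` is the melanosome volume fraction of the epidermis
    (0.02 / 0.05 / 0.10 emulate light / medium / dark skin tones).
    ``epidermis_baseline_absorption`` toggles whether the epidermal
    water/lipid baseline term is added on top of the melanin term
    (default) or melanin is the sole epidermal absorber.
    """

    melanin_fv: float = 0.02
    thickness_um: tuple[float, ...] = DEFAULT_THICKNESS_UM
    compositions: tuple[LayerComposition, ...] = (
        LayerComposition(0.0, 0.0, 0.17, 0.10, 0.0),
        LayerComposition(37.21, 9.30, 0.70, 0.05, 0.02),
        LayerComposition(37.21, 9.30, 0.70, 0.05, 0.02),
        LayerComposition(130.2, 32.5, 0.70, 0.23, 0.07),
    )
    g: tuple[float, ...] = DEFAULT_G
    n: tuple[float, ...] = DEFAULT_N
    subcutis_musp_table: dict[float, float] = field(default_factory=dict)
    epidermis_baseline_absorption: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.melanin_fv < 1.0:
            raise ValueError("melanin_fv must lie in [0, 1)")
        for tup in (self.thickness_um, self.compositions, self.g, self.n):
            if len(tup) != 4:
                raise ValueError("skin model requires exactly four layers")


def melanin_absorption(fv: float, wavelength_nm: float) -> float:
    """Epidermal melanin absorption, mm^-1.

    Power law 1.7e11 * fv * lambda^-3.48 with lambda in nm; linear in the
    melanosome volume fraction ``fv``.
    """
    if fv < 0:
        raise ValueError("melanosome volume fraction must be >= 0")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1.7e11 * fv * wavelength_nm ** -3.48


def composite_absorption(
    comp: LayerComposition, wavelength_nm: float, table: ChromophoreTable
) -> float:
    """Layer absorption from hemoglobin + water + lipid content, mm^-1.

    Evaluates 2.303e-6 (C_HbO e_HbO + C_HbR e_HbR) + f_water mua_water
    + f_lipid mua_lipid in cm^-1 (C in uM, e in cm^-1 M^-1) and converts
    to mm^-1.
    """
    mua_cm = (
        _BEER_LAMBERT_PREFACTOR
        * (
            comp.c_hbo2 * table._column("eps_hbo2", wavelength_nm)
            + comp.c_hb * table._column("eps_hb", wavelength_nm)
        )
        + comp.f_water * table._column("mua_water", wavelength_nm)
        + comp.f_lipid * table._column("mua_lipid", wavelength_nm)
    )
    return mua_cm / 10.0


def epidermis_reduced_scattering(wavelength_nm: float) -> float:
    """Epidermal reduced scattering (Mie + Rayleigh power laws), mm^-1."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam = wavelength_nm
    return 1.08e7 * lam ** -2.364 + 13.571 * lam ** -0.267


def dermis_reduced_scattering(wavelength_nm: float) -> float:
    """Dermal reduced scattering (Mie + Rayleigh power laws), mm^-1."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam = wavelength_nm
    return 1.19e7 * lam ** -2.427 + 7.15 * lam ** -0.258


def reduced_to_full_scattering(musp: float, g: float) -> float:
    """Recover mus from musp and anisotropy: mus = musp / (1 - g)."""
    if musp < 0:
        raise ValueError("musp must be >= 0")
    if not -1.0 < g < 1.0:
        raise ValueError("cannot convert: anisotropy g must lie in (-1, 1)")
    return musp / (1.0 - g)


def transport_mfp(mua: float, musp: float) -> float:
    """Transport mean free path l* = 1 / (mua + musp), mm."""
    total = mua + musp
    if total <= 0:
        raise ValueError("mua + musp must be positive to define l*")
    return 1.0 / total


def _default_resource(name: str):
    return importlib.resources.files("slim.data") / name


def load_default_chromophore_table(interpolate: bool = False) -> ChromophoreTable:
    """Bundled chromophore table at the eight measurement wavelengths."""
    with importlib.resources.as_file(
        _default_resource("chromophores_synthetic_v1.csv")
    ) as path:
        return ChromophoreTable.from_csv(path, interpolate=interpolate)


def load_default_subcutis_musp() -> dict[float, float]:
    """Bundled subcutis reduced-scattering table (mm^-1 per wavelength)."""
    with importlib.resources.as_file(
        _default_resource("subcutis_musp_synthetic_v1.csv")
    ) as path:
        df = pd.read_csv(path, comment="#")
    return dict(zip(df["wavelength_nm"].astype(float), df["musp_mm"].astype(float)))


def default_skin_spec(melanin_fv: float = 0.02, **kwargs) -> SkinModelSpec:
    """Default four-layer skin spec with the bundled subcutis scattering."""
    spec = SkinModelSpec(
        melanin_fv=melanin_fv,
        subcutis_musp_table=load_default_subcutis_musp(),
        **kwargs,
    )
    return spec


def build_skin_medium(
    spec: SkinModelSpec, wavelength_nm: float, table: ChromophoreTable
) -> LayeredMedium:
    """Assemble the four-layer skin medium at one wavelength.

    Epidermal absorption is the melanin power law plus (by default) the
    water/lipid baseline of the epidermis composition; both dermal layers
    share the dermal scattering power law and the dermal composition;
    subcutis reduced scattering comes from ``spec.subcutis_musp_table``.  mus is recovered from musp with each layer's anisotropy.
    """
    if wavelength_nm not in spec.subcutis_musp_table:
        raise WavelengthLookupError(
            f"no subcutis reduced-scattering entry at {wavelength_nm} nm; "
            "extend spec.subcutis_musp_table"
        )
    musp_epi = epidermis_reduced_scattering(wavelength_nm)
    musp_derm = dermis_reduced_scattering(wavelength_nm)
    musp_sub = spec.subcutis_musp_table[wavelength_nm]
    musp_by_layer = (musp_epi, musp_derm, musp_derm, musp_sub)

    mua_epi = melanin_absorption(spec.melanin_fv, wavelength_nm)
    if spec.epidermis_baseline_absorption:
        mua_epi += composite_absorption(spec.compositions[0], wavelength_nm, table)
    mua_by_layer = (
        mua_epi,
        composite_absorption(spec.compositions[1], wavelength_nm, table),
        composite_absorption(spec.compositions[2], wavelength_nm, table),
        composite_absorption(spec.compositions[3], wavelength_nm, table),
    )

    layers = []
    z = 0.0
    for k, name in enumerate(LAYER_NAMES):
        thickness_mm = spec.thickness_um[k] / 1000.0
        layers.append(
            OpticalLayer(
                z_top=z,
                z_bottom=z + thickness_mm,
                mua=mua_by_layer[k],
                mus=reduced_to_full_scattering(musp_by_layer[k], spec.g[k]),
                g=spec.g[k],
                n=spec.n[k],
                name=name,
            )
        )
        z += thickness_mm
    return LayeredMedium(layers=tuple(layers), wavelength_nm=wavelength_nm)


def scale_layer_scattering(
    medium: LayeredMedium, layer_name: str, mus_scale: float
) -> LayeredMedium:
    """Return a copy with one layer's mus (hence musp, g fixed) scaled."""
    if mus_scale <= 0:
        raise ValueError("mus_scale must be positive")
    k = medium.layer_index(layer_name)
    layers = list(medium.layers)
    layers[k] = replace(layers[k], mus=layers[k].mus * mus_scale)
    return replace(medium, layers=tuple(layers))
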