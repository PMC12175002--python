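"""Shared fixtures: expensive transport runs are session-scoped.

Photon budgets here are scaled-down study conditions (a few 1e5 photons
per run) chosen so the whole suite runs on one CPU in minutes while
keeping Monte Carlo noise well below every tolerance asserted.
"""

import numpy as np
import pytest

from slim import (
    TransportConfig,
    build_skin_medium,
    default_skin_spec,
    derive_seed,
    homogeneous_medium,
    load_default_chromophore_table,
    make_baseline_and_perturbed,
    run_transport,
)


@pytest.fixture(scope="session")
def chromophore_table():
    return load_default_chromophore_table()


@pytest.fixture(scope="session")
def skin_spec():
    return default_skin_spec(melanin_fv=0.02)


@pytest.fixture(scope="session")
def homogeneous_run():
    """Diffusive homogeneous slab (musp/mua = 100, l* ~ 1 mm), 2e5 photons."""
    medium = homogeneous_medium(100.0, l_star=1.0 / 1.01, g=0.8, n=1.4,
                                slab_lstar=30.0)
    photons, diag = run_transport(
        medium, TransportConfig(n_photons=200_000, seed=101)
    )
    return medium, photons, diag


@pytest.fixture(scope="session")
def skin_run_526(chromophore_table, skin_spec):
    """Baseline + 50%-papillary-reduction pair at 526 nm, shared seed."""
    base_med, pert_med = make_baseline_and_perturbed(
        skin_spec, 526.0, chromophore_table
    )
    cfg = TransportConfig(n_photons=300_000, seed=derive_seed(7, "skin", 526.0))
    base = run_transport(base_med, cfg)
    pert = run_transport(pert_med, cfg)
    return base_med, pert_med, base, pert


@pytest.fixture(scope="session")
def skin_run_851(chromophore_table, skin_spec):
    base_med, pert_med = make_baseline_and_perturbed(
        skin_spec, 851.0, chromophore_table
    )
    cfg = TransportConfig(n_photons=300_000, seed=derive_seed(7, "skin", 851.0))
    base = run_transport(base_med, cfg)
    pert = run_transport(pert_med, cfg)
    return base_med, pert_med, base, pert


@pytest.fixture(scope="session")
def study_result():
    """Scaled full SLIM study: 8 wavelengths x 3 melanin levels, 5e5 photons."""
    from slim.cli_io import StudyConfig, run_study

    cfg = StudyConfig(n_photons=500_000, seed=20)
    return run_study(cfg)


def make_photon_set(w, dx, z_max=None, n_launched=None, dy=None, L=None, J=None,
                    total_depth=1.0, boundaries=None):
    """Hand-built DetectedPhotonSet for exact single-photon tally checks."""
    from slim import DetectedPhotonSet

    w = np.asarray(w, float)
    dx = np.asarray(dx, float)
    n = w.size
    z_max = np.zeros(n) if z_max is None else np.asarray(z_max, float)
    return DetectedPhotonSet(
        w=w,
        dx=dx,
        dy=np.zeros(n) if dy is None else np.asarray(dy, float),
        z_max=z_max,
        L=np.zeros((n, 1)) if L is None else np.asarray(L, float),
        J=np.zeros((n, 1), np.int64) if J is None else np.asarray(J, np.int64),
        photon_index=np.arange(n, dtype=np.int64),
        n_launched=n if n_launched is None else int(n_launched),
        seed=0,
        specular_fraction=0.0,
        total_depth=total_depth,
        layer_boundaries=np.array([0.0, total_depth]) if boundaries is None
        else np.asarray(boundaries, float),
    )
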