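"""Shared fixtures: small analytic grids and session-scoped simulation runs.

The heavy speckle-simulation scenarios are session-scoped so that unit,
pipeline and acceptance tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from osmoce import (
    DiffusionParams,
    OpticalParams,
    SpeckleParams,
    StrainFieldSpec,
    depth_profile,
    detect_surface,
    extrema_kinetics,
    simulate_series,
    strain_series,
    waterfall,
)


@pytest.fixture
def optics_eq() -> OpticalParams:
    """Round-number geometry for closed-form arithmetic checks."""
    return OpticalParams(lambda0_nm=1300.0, n=1.3, dz_air_um=4.0, dx_um=4.0)


@pytest.fixture
def optics_default() -> OpticalParams:
    return OpticalParams(lambda0_nm=1300.0, n=1.3)


def run_uniform_recovery(total_strain, n_frames, dt, seed, n_z=400, n_x=96,
                         reregister=False, snr_db=30.0):
    """Simulate a uniform-strain series and recover the final depth profile."""
    optics = OpticalParams()
    duration = (n_frames - 1) * dt
    rate = total_strain / duration if total_strain else 0.0
    spec = StrainFieldSpec(template="uniform", k_pos=rate,
                           diffusion=DiffusionParams())
    sp = SpeckleParams(seed=seed, n_z=n_z, n_x=n_x, snr_db=snr_db,
                       surface_um_air=200.0)
    series, truth = simulate_series(spec, sp, optics, n_frames=n_frames, dt=dt)
    cums = strain_series(series, reregister=reregister)
    surface = detect_surface(series.frames[0].amplitude)
    profile = depth_profile(cums[-1], surface, optics)
    return {
        "series": series,
        "truth": truth,
        "cums": cums,
        "surface": surface,
        "profile": profile,
        "optics": optics,
    }


@pytest.fixture(scope="session")
def uniform_run_1e2():
    """Cumulative strain 0.01 over 10 x 1 s intervals."""
    return run_uniform_recovery(0.01, n_frames=11, dt=1.0, seed=5)


@pytest.fixture(scope="session")
def uniform_run_0p3():
    """Cumulative strain 0.3 over 60 x 10 s intervals, material re-registration."""
    return run_uniform_recovery(0.3, n_frames=61, dt=10.0, seed=23, reregister=True)


@pytest.fixture(scope="session")
def small_strain_run():
    """Cumulative strain 1e-4 over 300 s plus a zero-strain noise control."""
    signal = run_uniform_recovery(1e-4, n_frames=31, dt=10.0, seed=21)
    null = run_uniform_recovery(0.0, n_frames=31, dt=10.0, seed=22)
    return {"signal": signal, "null": null}


@pytest.fixture(scope="session")
def front_tracking_run():
    """Alternating-sign osmotic front whose strain minimum deepens over 600 s.

    With k_pos=0.2, k_neg=0.8 the imposed strain minimum sits at
    z ≈ 1.26·sqrt(D·t); D = 4.7e-10 m²/s and frame times 53..653 s move it
    from ~200 to ~700 µm, emulating the migration of the dehydration front
    under concentrated osmotic agents.
    """
    optics = OpticalParams()
    spec = StrainFieldSpec(
        template="alternating_sign", k_pos=0.2, k_neg=0.8,
        diffusion=DiffusionParams(D_m2_s=4.7e-10, duration_s=600.0),
    )
    sp = SpeckleParams(seed=9, n_z=512, n_x=96, snr_db=30.0, surface_um_air=200.0)
    series, truth = simulate_series(spec, sp, optics, n_frames=61, dt=10.0, t0=53.0)
    cums = strain_series(series)
    surface = detect_surface(series.frames[0].amplitude)
    profiles = [depth_profile(c, surface, optics) for c in cums]
    w = waterfall(profiles)
    track = extrema_kinetics(w, min_prominence=0.005)
    return {
        "series": series,
        "truth": truth,
        "cums": cums,
        "surface": surface,
        "waterfall": w,
        "track": track,
        "optics": optics,
    }
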