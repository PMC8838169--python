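"""Phase-resolved axial strain estimation from complex OCT B-scans.

The chain implemented here is the core of phase-resolved optical coherence
elastography (OCE):

1. interframe phase variation via the conjugate product
   ``Φ(m, j) = arg{a2 · a1*}``;
2. axial displacement ``U = λ0·Φ / (4π·n)``, valid without wrapping only for
   |U| < λ0/(2n);
3. local axial strain ∂U/∂z from the *gradient* of Φ within a processing
   window — either by the vector method (windowed complex sum of axial
   lag products, amplitude weighting intrinsic, no unwrapping needed) or by
   an unwrap-and-least-squares slope fit kept as a cross-validation oracle;
4. cumulative strain as the running sum of interframe strain maps over the
   observation time.

Strain is returned per the optical-depth convention
``ε = (λ0/4π)·∂Φ/∂z_air``; because physical in-tissue depth is optical
depth divided by n, this value coincides with ``(λ0/4πn)·∂Φ/∂z_phys`` — the
strain itself does not depend on the refractive index, only displacement
and physical depth do.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter, uniform_filter

from .containers import (
    BScanSeries,
    ComplexBScan,
    CumulativeStrainMap,
    InterframeProduct,
    OpticalParams,
    StrainMap,
    SurfaceMap,
)

__all__ = [
    "PhaseWrapWarning",
    "interframe_product",
    "displacement_from_phase",
    "vector_axial_gradient",
    "lsq_axial_gradient",
    "accumulate",
    "detect_surface",
    "strain_series",
    "window_px",
    "strain_resolution_um",
]


class PhaseWrapWarning(UserWarning):
    """Raised when interframe phases approach ±π (wrap-ambiguous displacement)."""


def window_px(size_um: float, pitch_um: float) -> int:
    """Convert a window size in µm to an odd pixel count >= 3."""
    w = int(round(size_um / pitch_um))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def strain_resolution_um(window_um: float = 100.0) -> float:
    """Resolution of a strain map: half the processing-window size."""
    return 0.5 * window_um


def _complex_uniform(z: np.ndarray, size) -> np.ndarray:
    return uniform_filter(z.real, size) + 1j * uniform_filter(z.imag, size)


def interframe_product(scan1: ComplexBScan, scan2: ComplexBScan) -> InterframeProduct:
    """Element-wise conjugate product b = a2 · a1* of two frames.

    ``arg b`` is the interframe phase variation Φ ∈ (−π, π].
    """
    if scan1.data.shape != scan2.data.shape:
        raise ValueError(
            f"B-scan shapes differ: {scan1.data.shape} vs {scan2.data.shape}"
        )
    if scan1.optics != scan2.optics:
        raise ValueError("B-scans were acquired with different optics")
    return InterframeProduct(b=scan2.data * np.conj(scan1.data), optics=scan1.optics)


def displacement_from_phase(phase: np.ndarray, optics: OpticalParams) -> np.ndarray:
    """Axial scatterer displacement U (nm) from interframe phase Φ (rad).

    U = λ0·Φ/(4π·n).  Unambiguous only for |U| < λ0/(2n); a
    :class:`PhaseWrapWarning` is emitted when any |Φ| approaches π.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase map contains non-finite values")
    if np.any(np.abs(phase) > 0.95 * np.pi):
        warnings.warn(
            "interframe phase approaches ±π: displacement is wrap-ambiguous "
            "(uncertainty an integer multiple of λ0/2n)",
            PhaseWrapWarning,
            stacklevel=2,
        )
    return optics.lambda0_nm * phase / (4.0 * np.pi * optics.n)


def _odd(k: int) -> int:
    return k if k % 2 else k + 1


def _preavg_windows(
    wz: int, wx: int, preavg_px: int | tuple[int, int] | None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(first-pass, re-reference-pass) pre-averaging window sizes in pixels.

    The first pass keeps the axial extent short so that steep phase ramps do
    not cancel inside the complex mean; the re-reference pass, which sees an
    almost flat de-ramped phase, averages over half the processing window
    axially.  Laterally both passes extend slightly beyond the processing
    window: lateral speckle cells are statistically independent, and it is
    their number that controls the residual slope-attenuation bias of the
    lag-product estimator.
    """
    if preavg_px is None:
        first = (3, _odd(wx + 2))
    elif isinstance(preavg_px, int):
        first = (max(preavg_px, 1), max(preavg_px, 1))
    else:
        first = (max(preavg_px[0], 1), max(preavg_px[1], 1))
    second = (_odd(max(wz // 2, first[0])), first[1])
    return first, second


def vector_axial_gradient(
    prod: InterframeProduct,
    window_z_um: float = 100.0,
    window_x_um: float = 100.0,
    lag_px: int = 1,
    preavg_px: int | tuple[int, int] | None = None,
    clip_percentile: float | None = None,
    rereference: int = 1,
) -> StrainMap:
    """Vector-method axial strain from an interframe product.

    The estimator never extracts the phase of individual pixels.  Per output
    pixel it (i) pre-averages b over a small complex-mean window
    (suppresses amplitude nulls; derived from the processing window when
    ``preavg_px`` is None), (ii) forms axial lag products
    ``d(m, j) = b̃(m+lag, j)·b̃*(m, j)`` whose phase is the per-lag phase
    advance, (iii) sums d over the processing window — high-amplitude pixels
    dominate the complex sum, so amplitude weighting is intrinsic and
    isolated ~π phase outliers average out — and (iv) takes
    ``slope = arg(Σd)/lag``.  Because only phase *differences* over the lag
    enter, supra-wavelength bulk displacement never wraps the estimate; the
    result is exact for a noise-free uniform ramp with |slope·lag| < π.

    A raw lag-product estimate is attenuated by the real-valued axial
    autocorrelation of the speckle field (E[d] = |μ|²·e^{iΔΦ} + R²), so by
    default one re-referencing iteration is applied: the integrated
    first-pass slope is removed from b, the nearly flat residual is
    re-estimated with a long axial pre-average (which is now safe from ramp
    cancellation), and the two contributions are summed.

    Parameters
    ----------
    preavg_px
        Pre-averaging window, pixels; an int (isotropic), an (axial,
        lateral) pair, or None to derive from the processing window.
    clip_percentile
        If set, |d| is clipped at this percentile before summation to limit
        the dominance of specular pixels (off by default).
    rereference
        Number of re-referencing iterations (0 disables).
    """
    optics = prod.optics
    b = prod.b
    nz, nx = b.shape
    wz = window_px(window_z_um, optics.dz_air_um)
    wx = window_px(window_x_um, optics.dx_um)
    if wz > nz or wx > nx:
        raise ValueError("processing window exceeds the scan size")
    if lag_px < 1:
        raise ValueError("lag_px must be >= 1")
    if lag_px >= nz:
        raise ValueError("lag_px must be smaller than the number of rows")
    pre1, pre2 = _preavg_windows(wz, wx, preavg_px)
    # re-reference pass: the de-ramped residual slope is small, so a longer
    # lag is wrap-safe and decorrelates the speckle fluctuations that cause
    # the attenuation bias.  The de-ramp phase differs by a random constant
    # per column, so that pass must not pre-average laterally (the constants
    # cancel only in the axial lag products); the lateral averaging is moved
    # into the window sum instead.
    lag2 = min(8 * lag_px, max(wz // 2, lag_px))
    pre2 = (pre2[0], 1)
    sum2 = (wz, _odd(wx + pre1[1]))

    def _pass(
        field: np.ndarray, pre: tuple[int, int], lag: int, sum_win: tuple[int, int]
    ) -> tuple[np.ndarray, np.ndarray]:
        bt = _complex_uniform(field, pre) if max(pre) > 1 else field
        d = np.zeros_like(bt)
        d[:-lag] = bt[lag:] * np.conj(bt[:-lag])
        if clip_percentile is not None:
            mag = np.abs(d)
            pos = mag[mag > 0]
            if pos.size:
                cap = np.percentile(pos, clip_percentile)
                over = mag > cap
                d[over] *= cap / mag[over]
        S = _complex_uniform(d, sum_win)
        return np.angle(S) / lag, np.abs(S)

    slope, S_mag = _pass(b, pre1, lag_px, (wz, wx))
    for _ in range(int(rereference)):
        ramp = np.cumsum(slope, axis=0)
        resid, _ = _pass(b * np.exp(-1j * ramp), pre2, lag2, sum2)
        slope = slope + resid

    eps = (optics.lambda0_um / (4.0 * np.pi)) * slope / optics.dz_air_um

    mask = S_mag > 0.0  # all-zero windows are invalid, not NaN
    # first-pass validity margin, widened by the re-reference footprint
    mz = wz // 2 + lag_px + pre1[0] // 2
    mx = wx // 2 + pre1[1] // 2
    if rereference:
        mz += wz // 2 + pre2[0] // 2 + lag2 + 1
        mx = sum2[1] // 2 + pre1[1] // 2
    mask[:mz, :] = False
    mask[nz - mz :, :] = False
    mask[:, :mx] = False
    mask[:, nx - mx :] = False
    eps = np.where(mask, eps, 0.0)
    return StrainMap(
        eps=eps,
        mask=mask,
        window_z_um=window_z_um,
        window_x_um=window_x_um,
        depth_convention="optical",
        optics=optics,
    )


def lsq_axial_gradient(
    prod: InterframeProduct,
    window_z_um: float = 100.0,
    window_x_um: float = 100.0,
    unwrap: bool = True,
    preavg_px: int | tuple[int, int] | None = None,
) -> StrainMap:
    """Least-squares phase-slope strain estimate (cross-validation oracle).

    The interframe phase is extracted per pixel (after the same complex
    pre-averaging as the vector estimator, which keeps Rayleigh amplitude
    nulls from derailing the unwrap), unwrapped axially per column, and the
    ordinary least-squares slope of Φ versus axial pixel is computed within
    each processing window.  Pixels whose axial neighbourhood still jumps by
    more than π after unwrapping are masked invalid — the documented failure
    mode of phase-extracting estimators on steep ramps when ``unwrap=False``.
    """
    optics = prod.optics
    nz, nx = prod.b.shape
    wz = window_px(window_z_um, optics.dz_air_um)
    wx = window_px(window_x_um, optics.dx_um)
    if wz > nz or wx > nx:
        raise ValueError("processing window exceeds the scan size")

    pre1, _ = _preavg_windows(wz, wx, preavg_px)
    bt = _complex_uniform(prod.b, pre1) if max(pre1) > 1 else prod.b
    phi = np.angle(bt)
    if unwrap:
        phi = np.unwrap(phi, axis=0)

    m = np.broadcast_to(np.arange(nz, dtype=float)[:, None], phi.shape)
    size = (wz, wx)
    e_phi = uniform_filter(phi, size)
    e_m = uniform_filter(m, size)
    e_mphi = uniform_filter(m * phi, size)
    e_m2 = uniform_filter(m * m, size)
    var = e_m2 - e_m * e_m
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (e_mphi - e_m * e_phi) / var
    eps = (optics.lambda0_um / (4.0 * np.pi)) * slope / optics.dz_air_um

    mask = var > 0
    # unwrap-failure heuristic: adjacent-pixel jump > π contaminates every
    # window that touches it
    jump = np.zeros_like(phi, dtype=float)
    jump[:-1, :] = (np.abs(np.diff(phi, axis=0)) > np.pi).astype(float)
    if jump.any():
        touched = uniform_filter(jump, size) > 1e-12
        mask &= ~touched
    mz = wz // 2 + pre1[0] // 2
    mx = wx // 2 + pre1[1] // 2
    mask[:mz, :] = False
    mask[nz - mz :, :] = False
    mask[:, :mx] = False
    mask[:, nx - mx :] = False
    eps = np.where(mask, eps, 0.0)
    return StrainMap(
        eps=eps,
        mask=mask,
        window_z_um=window_z_um,
        window_x_um=window_x_um,
        depth_convention="optical",
        optics=optics,
    )


def accumulate(maps: Sequence[StrainMap], t: float | None = None) -> CumulativeStrainMap:
    """Element-wise running sum of interframe strain maps.

    The sum is taken on the intersection of the validity masks; invalid
    pixels are zeroed, never NaN.  ``t`` defaults to the number of summed
    maps (i.e. a 1 s interframe interval).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("accumulate requires at least one strain map")
    shape = maps[0].eps.shape
    conv = maps[0].depth_convention
    for sm in maps:
        if sm.eps.shape != shape:
            raise ValueError("strain maps must share a shape")
        if sm.depth_convention != conv:
            raise ValueError("strain maps must share a depth convention")
    mask = np.logical_and.reduce([sm.mask for sm in maps])
    eps = np.zeros(shape, dtype=float)
    for sm in maps:
        eps += np.where(sm.mask, sm.eps, 0.0)
    eps = np.where(mask, eps, 0.0)
    return CumulativeStrainMap(
        eps_cum=eps,
        mask=mask,
        t=float(len(maps)) if t is None else float(t),
        n_frames=len(maps),
        window_z_um=maps[0].window_z_um,
        window_x_um=maps[0].window_x_um,
        optics=maps[0].optics,
    )


def detect_surface(
    structural: np.ndarray,
    threshold_frac: float = 0.3,
    smooth_px: int = 5,
) -> SurfaceMap:
    """Per-column surface position from a structural (amplitude) image.

    The amplitude image is median-smoothed laterally over ``smooth_px``
    columns; the surface of column j is the first axial index where the
    smoothed amplitude exceeds ``threshold_frac`` times the column maximum.
    Columns that never exceed the threshold are filled from the nearest
    detected column and flagged.
    """
    amp = np.asarray(structural, dtype=float)
    if amp.ndim != 2:
        raise ValueError("structural image must be 2D")
    if np.any(amp < 0):
        raise ValueError("amplitudes must be non-negative")
    if not np.any(amp > 0):
        raise ValueError("all-zero structural image: no surface to detect")

    sm = median_filter(amp, size=(1, smooth_px), mode="nearest")
    colmax = sm.max(axis=0)
    with np.errstate(invalid="ignore"):
        above = sm >= threshold_frac * np.where(colmax > 0, colmax, np.inf)[None, :]
    hit = above.any(axis=0)
    if not hit.any():
        raise ValueError("no column exceeds the surface threshold")
    surf = np.where(hit, above.argmax(axis=0), 0)
    interpolated = ~hit
    if interpolated.any():
        valid = np.flatnonzero(hit)
        for j in np.flatnonzero(interpolated):
            surf[j] = surf[valid[np.argmin(np.abs(valid - j))]]
    return SurfaceMap(
        surf=surf,
        threshold_frac=threshold_frac,
        smooth_px=smooth_px,
        interpolated=interpolated,
    )


def strain_series(
    series: BScanSeries,
    window_z_um: float = 100.0,
    window_x_um: float = 100.0,
    lag_px: int = 1,
    preavg_px: int | tuple[int, int] | None = None,
    reregister: bool = False,
) -> list[CumulativeStrainMap]:
    """Interframe processing + accumulation over a whole B-scan series.

    For each consecutive frame pair the conjugate product is formed, the
    vector estimator applied, and the running sum updated; one cumulative
    map is returned per interframe interval, time-stamped at the later frame
    of the pair.

    By default the sum is Eulerian (fixed pixel grid).  At cumulative
    strains beyond ~0.1 the material sampled by a fixed pixel changes over
    the series, and the fixed-grid sum of engineering-strain increments
    converges to the logarithmic strain ln(1+ε) rather than ε.  With
    ``reregister=True`` each interframe map is instead sampled at the
    current position of the material initially at each pixel (axial shift
    by the accumulated displacement, integrated from the detected surface,
    which is assumed fixed), so the sum approximates the material-frame
    cumulative strain.
    """
    frames = list(series.frames)
    if len(frames) < 2:
        raise ValueError("strain_series requires at least 2 frames")
    ts = series.timestamps
    if np.any(np.diff(ts) <= 0):
        raise ValueError("frames must be in increasing time order")

    optics = series.optics
    nz, nx = frames[0].shape
    rows = np.arange(nz, dtype=float)
    if reregister:
        surf = detect_surface(frames[0].amplitude).surf
        shift_px = np.zeros((nz, nx))  # accumulated displacement, air pixels

    out: list[CumulativeStrainMap] = []
    eps_sum = np.zeros((nz, nx))
    mask_all = np.ones((nz, nx), dtype=bool)
    for k in range(len(frames) - 1):
        prod = interframe_product(frames[k], frames[k + 1])
        sm = vector_axial_gradient(
            prod,
            window_z_um=window_z_um,
            window_x_um=window_x_um,
            lag_px=lag_px,
            preavg_px=preavg_px,
        )
        if reregister:
            eps_k = np.empty((nz, nx))
            valid_k = np.empty((nz, nx), dtype=bool)
            for j in range(nx):
                src = rows + shift_px[:, j]
                eps_k[:, j] = np.interp(src, rows, np.where(sm.mask[:, j], sm.eps[:, j], 0.0))
                valid_k[:, j] = np.interp(src, rows, sm.mask[:, j].astype(float)) > 0.999
            # increments are gradients in the *current* configuration; the
            # material-frame increment carries the metric factor (1 + ε)
            growth = 1.0 + np.where(mask_all, eps_sum, 0.0)
            eps_k_material = eps_k * growth
            for j in range(nx):
                # update accumulated displacement: integrate the increment
                # from the (fixed) surface downward; above-surface rows do
                # not move.  ε per pixel equals displacement in air pixels.
                dz_step = np.where(rows > surf[j], eps_k_material[:, j], 0.0)
                shift_px[:, j] += np.cumsum(dz_step)
            eps_sum += eps_k_material
            mask_all &= valid_k
        else:
            eps_sum = eps_sum + np.where(sm.mask, sm.eps, 0.0)
            mask_all = mask_all & sm.mask
        out.append(
            CumulativeStrainMap(
                eps_cum=np.where(mask_all, eps_sum, 0.0),
                mask=mask_all.copy(),
                t=float(ts[k + 1] - ts[0]),
                n_frames=k + 1,
                window_z_um=window_z_um,
                window_x_um=window_x_um,
                optics=optics,
            )
        )
    return out
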