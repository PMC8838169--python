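"""Synthetic OCT speckle series with imposed osmotic strain fields.

The simulator provides the ground truth that makes the strain-estimation
chain testable by parameter recovery without real OCT hardware:

* a constant-source half-space diffusion solution
  ``C(z, t) = C0·erfc(z / (2·sqrt(D·t)))`` for the agent concentration,
  with penetration scale sqrt(D·t) (≈0.55 mm for D = 1e-9 m²/s at 300 s);
* strain-field templates tied to that concentration — uniform growth, a
  depth ramp, a single dilatation front, the alternating-sign profile
  characteristic of strongly hyperosmotic agents (dilatation at the
  surface, shrinkage at depth), and a thin subsurface shrinkage layer;
* cumulative axial displacement ``U(z) = ∫₀ᶻ ε dz'`` (zero at the surface);
* a point-scatterer speckle model: per lateral column, randomly placed
  sub-resolution scatterers summed with a Gaussian axial PSF and phase
  ``4πn·z/λ0``, depth attenuation, and additive circular complex noise.
  Motion is applied by displacing the (persistent) scatterers, so an
  imposed displacement U produces exactly the interframe phase
  ``4πn·U/λ0`` the phase-resolved engine inverts.

All randomness derives from one master seed; identical seeds give
bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import erfc

from .containers import BScanSeries, ComplexBScan, OpticalParams

__all__ = [
    "DiffusionParams",
    "StrainFieldSpec",
    "SpeckleParams",
    "GroundTruthBundle",
    "default_psf_fwhm_um",
    "penetration_depth_um",
    "diffusion_concentration",
    "strain_profile",
    "strain_field",
    "displacement_field",
    "speckle_scan",
    "simulate_series",
    "TEMPLATES",
]

TEMPLATES = ("uniform", "ramp", "single_front", "alternating_sign", "subsurface_layer")

#: strain magnitude above which field specs are rejected — beyond the regime
#: in which the estimator chain is validated
MAX_ABS_STRAIN = 0.5


@dataclass(frozen=True)
class DiffusionParams:
    """Agent diffusion into a half space.

    D defaults to 1e-9 m²/s (glycerol in cartilage); C0 is the normalized
    surface concentration; duration is the observation time scale used by
    the time-ramped templates.
    """

    D_m2_s: float = 1e-9
    C0: float = 1.0
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        if not self.D_m2_s > 0:
            raise ValueError("D must be positive")
        if not 0.0 < self.C0 <= 1.0:
            raise ValueError("C0 must be in (0, 1]")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")


def penetration_depth_um(D_m2_s: float, t_s: float) -> float:
    """Diffusion penetration scale sqrt(D·t) in µm."""
    return float(np.sqrt(D_m2_s * t_s) * 1e6)


def diffusion_concentration(z_um, t_s: float, p: DiffusionParams) -> np.ndarray:
    """Normalized concentration C(z, t) = C0·erfc(z/(2·sqrt(D·t))).

    Constant-source half-space solution; C(0, t) = C0 and C(z, 0⁺) = 0 for
    z > 0 (t = 0 is the limiting step function).
    """
    z = np.asarray(z_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be >= 0")
    if t_s < 0:
        raise ValueError("time must be >= 0")
    if t_s == 0:
        return np.where(z <= 0, p.C0, 0.0)
    s = penetration_depth_um(p.D_m2_s, t_s)
    return p.C0 * erfc(z / (2.0 * s))


@dataclass(frozen=True)
class StrainFieldSpec:
    """Template + coefficients defining the imposed cumulative strain field.

    Templates
    ---------
    uniform
        ε(z, t) = k_pos·t — depth-independent strain growing at k_pos per
        second (k_pos here is a rate, 1/s).
    ramp
        ε(z, t) = k_pos·t·z/ramp_depth_um — linear in depth.
    single_front
        ε(z, t) = k_pos·C(z, t) — dilatation following the diffusion front.
    alternating_sign
        ε(z, t) = C·(k_pos − k_neg·(1 − C)) — positive near the surface
        where C ≈ C0, negative deeper; sign change where C = 1 − k_pos/k_neg.
    subsurface_layer
        single_front plus a thin additive shrinkage band of thickness
        ``layer_depth_um`` at the surface, value ``layer_strain`` ramping in
        linearly over the diffusion duration.
    """

    template: str = "alternating_sign"
    k_pos: float = 0.2
    k_neg: float = 0.8
    layer_depth_um: float = 70.0
    layer_strain: float = -0.05
    ramp_depth_um: float = 1000.0
    diffusion: DiffusionParams = DiffusionParams()

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(
                f"unknown template {self.template!r}; choose from {TEMPLATES}"
            )
        if abs(self.k_pos) > 1 or abs(self.k_neg) > 1:
            raise ValueError("|k_pos| and |k_neg| must be <= 1")
        if self.layer_depth_um <= 0 or self.ramp_depth_um <= 0:
            raise ValueError("length scales must be positive")


def strain_profile(spec: StrainFieldSpec, z_um, t_s: float) -> np.ndarray:
    """Imposed cumulative strain ε(z, t) for one template at one time."""
    z = np.asarray(z_um, dtype=float)
    p = spec.diffusion
    if spec.template == "uniform":
        eps = np.full_like(z, spec.k_pos * t_s)
    elif spec.template == "ramp":
        eps = spec.k_pos * t_s * z / spec.ramp_depth_um
    elif spec.template == "single_front":
        eps = spec.k_pos * diffusion_concentration(z, t_s, p)
    elif spec.template == "alternating_sign":
        c = diffusion_concentration(z, t_s, p)
        eps = c * (spec.k_pos - spec.k_neg * (1.0 - c))
    elif spec.template == "subsurface_layer":
        eps = spec.k_pos * diffusion_concentration(z, t_s, p)
        ramp = min(t_s / p.duration_s, 1.0)
        eps = eps + spec.layer_strain * ramp * (z <= spec.layer_depth_um)
    else:  # pragma: no cover - guarded in the spec constructor
        raise ValueError(spec.template)
    if np.any(np.abs(eps) > MAX_ABS_STRAIN):
        raise ValueError(
            f"spec produces |strain| > {MAX_ABS_STRAIN}: outside the validated regime"
        )
    return eps


@dataclass
class GroundTruthBundle:
    """Imposed fields on a (time, depth) grid: concentration, strain, displacement.

    ``z_um`` is physical depth below the surface; ``U_um`` (when present) is
    the cumulative axial displacement, zero at the surface, consistent with
    ``eps`` through the trapezoid rule (forward differences of U equal
    midpoint averages of eps exactly).
    """

    z_um: np.ndarray
    t_s: np.ndarray
    C: np.ndarray
    eps: np.ndarray
    U_um: Optional[np.ndarray] = None
    surface_px: Optional[int] = None
    spec: Optional[StrainFieldSpec] = None

    def __post_init__(self) -> None:
        nt, nz = len(self.t_s), len(self.z_um)
        if self.C.shape != (nt, nz) or self.eps.shape != (nt, nz):
            raise ValueError("C and eps must have shape (n_times, n_depths)")


def strain_field(spec: StrainFieldSpec, z_um, t_s) -> GroundTruthBundle:
    """Evaluate concentration and cumulative strain on a (time, depth) grid."""
    z = np.asarray(z_um, dtype=float)
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    C = np.vstack([diffusion_concentration(z, tk, spec.diffusion) for tk in t])
    eps = np.vstack([strain_profile(spec, z, tk) for tk in t])
    return GroundTruthBundle(z_um=z, t_s=t, C=C, eps=eps, spec=spec)


def displacement_field(bundle: GroundTruthBundle) -> GroundTruthBundle:
    """Add cumulative axial displacement U(z, t) = ∫₀ᶻ ε dz' to a bundle.

    The surface (z = 0) is the fixed reference; deeper material moves
    relative to it.  U is in µm.
    """
    U = cumulative_trapezoid(bundle.eps, bundle.z_um, axis=1, initial=0.0)
    return GroundTruthBundle(
        z_um=bundle.z_um,
        t_s=bundle.t_s,
        C=bundle.C,
        eps=bundle.eps,
        U_um=U,
        surface_px=bundle.surface_px,
        spec=bundle.spec,
    )


def default_psf_fwhm_um(lambda0_nm: float = 1300.0, bandwidth_nm: float = 90.0) -> float:
    """Axial (amplitude) PSF FWHM of a Gaussian source: (2 ln2/π)·λ0²/Δλ, µm."""
    return (2.0 * np.log(2.0) / np.pi) * lambda0_nm**2 / bandwidth_nm * 1e-3


@dataclass(frozen=True)
class SpeckleParams:
    """Speckle/measurement model parameters.

    ``scatterers_per_psf`` point scatterers per axial PSF length per column
    give fully developed speckle (Rayleigh amplitude, uniform phase).
    ``psf_fwhm_um`` is the axial amplitude PSF width in air-depth µm
    (None → derived from a 1300/90 nm source, ≈8.3 µm).  ``snr_db`` sets
    additive circular complex noise relative to mean signal power below the
    surface (None → noiseless).  The grid defaults to 512 axial px over
    2 mm in air and 256 lateral px over 4 mm, with the sample surface at
    200 µm (air) below the top of the frame.
    """

    scatterers_per_psf: float = 20.0
    psf_fwhm_um: Optional[float] = None
    attenuation_per_um: float = 5e-4
    snr_db: Optional[float] = 30.0
    seed: int = 0
    n_z: int = 512
    n_x: int = 256
    surface_um_air: float = 200.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_um is not None and not self.psf_fwhm_um > 0:
            raise ValueError("psf_fwhm_um must be positive")
        if not self.scatterers_per_psf > 0:
            raise ValueError("scatterers_per_psf must be positive")
        if self.n_z < 2 or self.n_x < 2:
            raise ValueError("grid must be at least 2x2")
        if not 0 <= self.surface_um_air:
            raise ValueError("surface_um_air must be >= 0")

    def psf_fwhm(self, optics: OpticalParams) -> float:
        if self.psf_fwhm_um is not None:
            return self.psf_fwhm_um
        return default_psf_fwhm_um(optics.lambda0_nm)


@dataclass
class _Scatterers:
    """Persistent random scatterers: physical depth below surface, column, amplitude."""

    z_um: np.ndarray
    col: np.ndarray
    amp: np.ndarray


def _tissue_depth_um(sp: SpeckleParams, optics: OpticalParams) -> float:
    """Physical tissue depth covered by the grid below the surface."""
    air_below = sp.n_z * optics.dz_air_um - sp.surface_um_air
    if air_below <= 0:
        raise ValueError("surface lies below the bottom of the grid")
    return air_below / optics.n


def _make_scatterers(
    sp: SpeckleParams, optics: OpticalParams, rng: np.random.Generator
) -> _Scatterers:
    depth_phys = _tissue_depth_um(sp, optics)
    fwhm = sp.psf_fwhm(optics)
    n_per_col = int(round(sp.scatterers_per_psf * (depth_phys * optics.n) / fwhm))
    if n_per_col < 1:
        raise ValueError("zero scatterers per column: increase density or depth")
    n_total = n_per_col * sp.n_x
    z = rng.uniform(0.0, depth_phys, size=n_total)
    col = np.repeat(np.arange(sp.n_x), n_per_col)
    amp = np.ones(n_total)
    return _Scatterers(z_um=z, col=col, amp=amp)


def _render_frame(
    scat: _Scatterers,
    sp: SpeckleParams,
    optics: OpticalParams,
    U_um: np.ndarray,
) -> np.ndarray:
    """Complex frame from displaced scatterers (no noise)."""
    z_now = scat.z_um + U_um
    z_air = sp.surface_um_air + optics.n * z_now
    dz = optics.dz_air_um
    sigma = sp.psf_fwhm(optics) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    K = int(np.ceil(3.0 * sigma / dz))
    phase = np.exp(1j * 4.0 * np.pi * optics.n * z_now / optics.lambda0_um)
    w0 = scat.amp * np.exp(-sp.attenuation_per_um * z_now) * phase
    m0 = np.round(z_air / dz).astype(np.int64)
    npix = sp.n_z * sp.n_x
    acc_r = np.zeros(npix)
    acc_i = np.zeros(npix)
    for o in range(-K, K + 1):
        m = m0 + o
        valid = (m >= 0) & (m < sp.n_z)
        if not valid.any():
            continue
        g = np.exp(-((m[valid] * dz - z_air[valid]) ** 2) / (2.0 * sigma**2))
        contrib = w0[valid] * g
        idx = m[valid] * sp.n_x + scat.col[valid]
        acc_r += np.bincount(idx, weights=contrib.real, minlength=npix)
        acc_i += np.bincount(idx, weights=contrib.imag, minlength=npix)
    return (acc_r + 1j * acc_i).reshape(sp.n_z, sp.n_x)


def _noise_sigma(frame: np.ndarray, sp: SpeckleParams, optics: OpticalParams) -> float:
    if sp.snr_db is None:
        return 0.0
    surf_px = int(round(sp.surface_um_air / optics.dz_air_um))
    power = float(np.mean(np.abs(frame[surf_px:, :]) ** 2))
    return float(np.sqrt(power * 10.0 ** (-sp.snr_db / 10.0) / 2.0))


def speckle_scan(
    sp: SpeckleParams,
    optics: OpticalParams,
    U_field=None,
    timestamp: float = 0.0,
) -> ComplexBScan:
    """One synthetic B-scan with an optional imposed displacement field.

    ``U_field`` is either None (no motion), a scalar rigid displacement in
    µm, a callable U(z_phys_um) → µm, or a pair (z_um, U_um) to interpolate.
    Scatterers and noise derive from ``sp.seed``.
    """
    ss = np.random.SeedSequence(sp.seed)
    rng_scat, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    scat = _make_scatterers(sp, optics, rng_scat)
    U = _eval_displacement(U_field, scat.z_um)
    frame = _render_frame(scat, sp, optics, U)
    sig = _noise_sigma(frame, sp, optics)
    if sig > 0:
        frame = frame + rng_noise.normal(scale=sig, size=frame.shape) + 1j * rng_noise.normal(
            scale=sig, size=frame.shape
        )
    return ComplexBScan(data=frame, optics=optics, timestamp=timestamp)


def _eval_displacement(U_field, z_um: np.ndarray) -> np.ndarray:
    if U_field is None:
        return np.zeros_like(z_um)
    if callable(U_field):
        return np.asarray(U_field(z_um), dtype=float)
    if np.isscalar(U_field):
        return np.full_like(z_um, float(U_field))
    z_grid, U_grid = U_field
    return np.interp(z_um, z_grid, U_grid)


def simulate_series(
    spec: StrainFieldSpec,
    sp: SpeckleParams,
    optics: OpticalParams,
    n_frames: int = 11,
    dt: float = 1.0,
    t0: float = 0.0,
) -> tuple[BScanSeries, GroundTruthBundle]:
    """Synthetic B-scan series under an evolving osmotic strain field.

    Frames are rendered at simulation times t0, t0+dt, …; the same
    scatterers persist across frames and move by the imposed cumulative
    displacement U(z, t) evaluated at their initial depth.  Frame
    timestamps are measured from the start of the series.  The returned
    bundle carries C, ε and U on the frame-time × pixel-depth grid plus the
    surface pixel index.
    """
    if n_frames < 2:
        raise ValueError("a series requires at least 2 frames")
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = t0 + dt * np.arange(n_frames)

    depth_phys = _tissue_depth_um(sp, optics)
    n_below = int(np.floor(depth_phys / optics.dz_phys_um)) + 1
    z_grid = np.arange(n_below) * optics.dz_phys_um

    bundle = displacement_field(strain_field(spec, z_grid, times))
    bundle.surface_px = int(round(sp.surface_um_air / optics.dz_air_um))
    bundle.spec = spec

    ss = np.random.SeedSequence(sp.seed)
    rng_scat, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    scat = _make_scatterers(sp, optics, rng_scat)

    frames = []
    sig = None
    for k, tk in enumerate(times):
        U = np.interp(scat.z_um, z_grid, bundle.U_um[k])
        frame = _render_frame(scat, sp, optics, U)
        if sig is None:
            sig = _noise_sigma(frame, sp, optics)
        if sig > 0:
            frame = frame + rng_noise.normal(scale=sig, size=frame.shape)
            frame = frame + 1j * rng_noise.normal(scale=sig, size=frame.shape)
        frames.append(ComplexBScan(data=frame, optics=optics, timestamp=float(tk - t0)))
    return BScanSeries(frames=frames, dt=dt), bundle
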