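"""Depth profiles, waterfall diagrams and extrema kinetics of cumulative strain.

Osmotic strain fields in plane-layered samples are summarized by laterally
averaged depth profiles (strain vs physical depth below the detected
surface), stacked over time into a waterfall diagram, from which the
kinetics of the dominant dilatation maximum, shrinkage minimum and the
neutral (zero-strain) line are tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import CumulativeStrainMap, OpticalParams, SurfaceMap
from .engine import window_px

__all__ = [
    "DepthProfile",
    "Waterfall",
    "ExtremaTrack",
    "depth_profile",
    "normalize_profile",
    "waterfall",
    "extrema_kinetics",
    "zero_crossings",
]

#: |strain| 95th-percentile below which the axial averaging window is widened
#: from 80 to 160 µm (low-strain regimes such as saline or agent elution).
WIDEN_THRESHOLD = 2e-4
WIDE_WINDOW_Z_UM = 160.0


@dataclass
class DepthProfile:
    """Laterally averaged cumulative strain versus physical depth.

    ``depth_um`` starts at 0 at the per-column surface and increases in
    physical (n-corrected) µm.
    """

    depth_um: np.ndarray
    strain: np.ndarray
    avg_window_z_um: float
    avg_window_x_um: float
    t: float

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.depth_um.shape != self.strain.shape:
            raise ValueError("depth and strain must share a shape")
        if self.depth_um.size > 1 and np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth axis must be strictly increasing")


@dataclass
class Waterfall:
    """Strain indexed by (time, depth)."""

    strain: np.ndarray
    time_s: np.ndarray
    depth_um: np.ndarray

    def __post_init__(self) -> None:
        if self.strain.shape != (len(self.time_s), len(self.depth_um)):
            raise ValueError("waterfall matrix shape must be (n_times, n_depths)")


@dataclass
class ExtremaTrack:
    """Per-timestamp depths/values of strain extrema and the neutral line.

    NaN entries mean "undefined at this time" (e.g. no negative strain, or
    the extremum suppressed by the prominence threshold).  ``*_edge`` flags
    mark extrema lying within one averaging window of the deepest analyzed
    depth, where their position cannot be determined reliably.
    """

    time_s: np.ndarray
    depth_min_um: np.ndarray
    value_min: np.ndarray
    depth_max_um: np.ndarray
    value_max: np.ndarray
    depth_neutral_um: np.ndarray
    min_edge: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_edge: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("depth_min_um", "value_min", "depth_max_um", "value_max",
                     "depth_neutral_um"):
            if len(getattr(self, name)) != n:
                raise ValueError("all track columns must share a length")
        if self.min_edge is None:
            self.min_edge = np.zeros(n, dtype=bool)
        if self.max_edge is None:
            self.max_edge = np.zeros(n, dtype=bool)


def depth_profile(
    cmap: CumulativeStrainMap,
    surface: SurfaceMap,
    optics: OpticalParams,
    avg_window_z_um: float = 80.0,
    avg_window_x_um: float = 800.0,
    depth_limit_um: float = 900.0,
    lateral_center_px: Optional[int] = None,
    auto_widen: bool = True,
) -> DepthProfile:
    """Laterally averaged strain depth profile below the detected surface.

    Each profile value is the mean of the valid map pixels inside an
    averaging window (default 80 µm axial x 800 µm lateral) centred on the
    depth bin; depth is counted per column from the surface and reported in
    physical µm (optical pixels x dz_air/n).  When the strain everywhere is
    small (95th percentile of |strain| below ``WIDEN_THRESHOLD``) the axial
    window is automatically widened to 160 µm to suppress noise, mirroring
    low-osmolarity measurement practice.
    """
    eps = cmap.eps_cum
    nz, nx = eps.shape
    dzp = optics.dz_phys_um
    wx = int(round(avg_window_x_um / optics.dx_um))
    if wx > nx:
        raise ValueError("lateral averaging window is wider than the scan")
    wx = max(wx, 1)

    center = nx // 2 if lateral_center_px is None else int(lateral_center_px)
    j0 = int(np.clip(center - wx // 2, 0, nx - wx))
    cols = slice(j0, j0 + wx)

    surf = surface.surf[cols]
    n_below = nz - int(surf.min())
    n_bins = min(n_below, int(np.floor(depth_limit_um / dzp)) + 1)
    wz = window_px(avg_window_z_um, dzp)
    if n_bins < wz:
        raise ValueError("analyzable depth is smaller than one averaging window")

    # surface-aligned view: aligned[d, j] = eps[surf[j] + d, j]
    aligned = np.full((n_bins + wz, wx), np.nan)
    sub_eps = eps[:, cols]
    sub_mask = cmap.mask[:, cols]
    for jj in range(wx):
        s = int(surf[jj])
        depth_avail = min(nz - s, n_bins + wz)
        col = sub_eps[s : s + depth_avail, jj].astype(float).copy()
        col[~sub_mask[s : s + depth_avail, jj]] = np.nan
        aligned[:depth_avail, jj] = col

    h = wz // 2
    strain = np.full(n_bins, np.nan)
    for d in range(n_bins):
        lo = max(d - h, 0)
        block = aligned[lo : d + h + 1, :]
        if np.any(np.isfinite(block)):
            strain[d] = np.nanmean(block)
    valid = np.isfinite(strain)
    depth = np.arange(n_bins) * dzp
    depth, strain = depth[valid], strain[valid]
    if strain.size == 0:
        raise ValueError("no valid pixels inside the averaging region")

    if (
        auto_widen
        and avg_window_z_um < WIDE_WINDOW_Z_UM
        and np.percentile(np.abs(strain), 95) < WIDEN_THRESHOLD
    ):
        return depth_profile(
            cmap,
            surface,
            optics,
            avg_window_z_um=WIDE_WINDOW_Z_UM,
            avg_window_x_um=avg_window_x_um,
            depth_limit_um=depth_limit_um,
            lateral_center_px=lateral_center_px,
            auto_widen=False,
        )
    return DepthProfile(
        depth_um=depth,
        strain=strain,
        avg_window_z_um=avg_window_z_um,
        avg_window_x_um=avg_window_x_um,
        t=cmap.t,
    )


def normalize_profile(p: DepthProfile) -> DepthProfile:
    """Divide a profile by its maximal positive strain (new profile peaks at 1).

    Undefined (raises) when the profile has no strictly positive value.
    """
    pos = p.strain[p.strain > 0]
    if pos.size == 0:
        raise ValueError("normalization undefined: profile has no positive strain")
    return DepthProfile(
        depth_um=p.depth_um.copy(),
        strain=p.strain / pos.max(),
        avg_window_z_um=p.avg_window_z_um,
        avg_window_x_um=p.avg_window_x_um,
        t=p.t,
    )


def waterfall(profiles: Sequence[DepthProfile]) -> Waterfall:
    """Stack depth profiles into a (time, depth) matrix, time ascending."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("waterfall requires at least one profile")
    depth = profiles[0].depth_um
    for p in profiles:
        if p.depth_um.shape != depth.shape or not np.allclose(p.depth_um, depth):
            raise ValueError("profiles must share the depth axis")
    times = np.array([p.t for p in profiles], dtype=float)
    order = np.argsort(times, kind="stable")
    return Waterfall(
        strain=np.vstack([profiles[i].strain for i in order]),
        time_s=times[order],
        depth_um=depth.copy(),
    )


def zero_crossings(depth_um: np.ndarray, strain: np.ndarray) -> np.ndarray:
    """Linearly interpolated depths of all sign changes of a profile."""
    s = np.asarray(strain, dtype=float)
    z = np.asarray(depth_um, dtype=float)
    out = []
    for k in range(len(s) - 1):
        a, b = s[k], s[k + 1]
        if a == 0.0:
            out.append(z[k])
        elif a * b < 0:
            out.append(z[k] + (z[k + 1] - z[k]) * a / (a - b))
    if len(s) and s[-1] == 0.0:
        out.append(z[-1])
    return np.array(out)


def extrema_kinetics(
    w: Waterfall,
    min_prominence: float = 0.0,
    edge_window_um: float = 80.0,
) -> ExtremaTrack:
    """Track the global strain extrema and the neutral line over time.

    Per time row: the global maximum and global minimum of the profile
    (ties broken toward the shallower depth); the neutral depth is the
    linearly interpolated zero crossing between the two extrema whenever
    they bracket zero (with several crossings, the one closest to the
    middle of the extrema).  Extrema with |value| below ``min_prominence``
    are reported as undefined, and extrema within ``edge_window_um`` of the
    deepest analyzed depth are flagged as unreliable.
    """
    nt = len(w.time_s)
    d_min = np.full(nt, np.nan)
    v_min = np.full(nt, np.nan)
    d_max = np.full(nt, np.nan)
    v_max = np.full(nt, np.nan)
    d_neu = np.full(nt, np.nan)
    min_edge = np.zeros(nt, dtype=bool)
    max_edge = np.zeros(nt, dtype=bool)
    z = w.depth_um
    z_deep = z[-1]

    for i in range(nt):
        s = w.strain[i]
        imax = int(np.argmax(s))
        imin = int(np.argmin(s))
        vmax, vmin = s[imax], s[imin]
        have_max = vmax >= min_prominence if min_prominence > 0 else True
        have_min = (-vmin) >= min_prominence if min_prominence > 0 else True
        if imax == imin:
            # flat profile: a single degenerate extremum; report it as the max
            have_min = False
        if have_max:
            d_max[i], v_max[i] = z[imax], vmax
            max_edge[i] = z_deep - z[imax] < edge_window_um
        if have_min:
            d_min[i], v_min[i] = z[imin], vmin
            min_edge[i] = z_deep - z[imin] < edge_window_um
        if have_max and have_min and vmin < 0.0 < vmax:
            lo, hi = sorted((imax, imin))
            seg = slice(lo, hi + 1)
            crossings = zero_crossings(z[seg], s[seg])
            inside = crossings[
                (crossings > min(z[imax], z[imin])) & (crossings < max(z[imax], z[imin]))
            ]
            if inside.size:
                mid = 0.5 * (z[imax] + z[imin])
                d_neu[i] = inside[np.argmin(np.abs(inside - mid))]
    return ExtremaTrack(
        time_s=w.time_s.copy(),
        depth_min_um=d_min,
        value_min=v_min,
        depth_max_um=d_max,
        value_max=v_max,
        depth_neutral_um=d_neu,
        min_edge=min_edge,
        max_edge=max_edge,
    )
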