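"""File I/O: HDF5 B-scan containers, ground-truth companions, TIFF/CSV exports.

The B-scan container is an HDF5 file with a single complex dataset
``/frames`` of shape (T, Z, X), a ``/timestamps`` dataset in seconds, and
root attributes ``lambda0_nm``, ``n``, ``dz_air_um``, ``dx_um``, ``dt_s``.
A JSON sidecar (same stem, ``.json``) duplicates the attributes for human
inspection.  Round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .containers import BScanSeries, ComplexBScan, CumulativeStrainMap, OpticalParams
from .kinetics import DepthProfile, ExtremaTrack, Waterfall
from .simulate import GroundTruthBundle

__all__ = [
    "write_series",
    "read_series",
    "write_ground_truth",
    "read_ground_truth",
    "export_strain_map",
    "export_profiles_csv",
    "read_profiles_csv",
    "export_waterfall_csv",
    "export_extrema_csv",
]

_REQUIRED_ATTRS = ("lambda0_nm", "n", "dz_air_um", "dx_um")


def write_series(path, series: BScanSeries, sidecar: bool = True) -> Path:
    """Write a B-scan series to an HDF5 container (+ JSON sidecar)."""
    path = Path(path)
    optics = series.optics
    data = np.stack([f.data for f in series.frames]).astype(np.complex128)
    attrs = {
        "lambda0_nm": float(optics.lambda0_nm),
        "n": float(optics.n),
        "dz_air_um": float(optics.dz_air_um),
        "dx_um": float(optics.dx_um),
        "dt_s": float(series.dt),
    }
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=data)
        h5.create_dataset("timestamps", data=series.timestamps)
        for k, v in attrs.items():
            h5.attrs[k] = v
    if sidecar:
        meta = dict(attrs, n_frames=len(series), shape=list(data.shape[1:]))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_series(path) -> BScanSeries:
    """Read a B-scan series; raises naming any missing metadata attribute."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for attr in _REQUIRED_ATTRS:
            if attr not in h5.attrs:
                raise KeyError(f"container is missing required attribute {attr!r}")
        optics = OpticalParams(
            lambda0_nm=float(h5.attrs["lambda0_nm"]),
            n=float(h5.attrs["n"]),
            dz_air_um=float(h5.attrs["dz_air_um"]),
            dx_um=float(h5.attrs["dx_um"]),
        )
        frames_data = h5["frames"][...]
        timestamps = h5["timestamps"][...]
        dt = float(h5.attrs.get("dt_s", np.median(np.diff(timestamps)) if len(timestamps) > 1 else 1.0))
    frames = [
        ComplexBScan(data=frames_data[k], optics=optics, timestamp=float(timestamps[k]))
        for k in range(frames_data.shape[0])
    ]
    return BScanSeries(frames=frames, dt=dt)


def write_ground_truth(path, bundle: GroundTruthBundle) -> Path:
    """Write a simulator ground-truth companion file."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("z_um", data=bundle.z_um)
        h5.create_dataset("t_s", data=bundle.t_s)
        h5.create_dataset("C", data=bundle.C)
        h5.create_dataset("eps", data=bundle.eps)
        if bundle.U_um is not None:
            h5.create_dataset("U_um", data=bundle.U_um)
        if bundle.surface_px is not None:
            h5.attrs["surface_px"] = int(bundle.surface_px)
        if bundle.spec is not None:
            s = bundle.spec
            h5.attrs["spec_json"] = json.dumps(
                {
                    "template": s.template,
                    "k_pos": s.k_pos,
                    "k_neg": s.k_neg,
                    "layer_depth_um": s.layer_depth_um,
                    "layer_strain": s.layer_strain,
                    "ramp_depth_um": s.ramp_depth_um,
                    "D_m2_s": s.diffusion.D_m2_s,
                    "C0": s.diffusion.C0,
                    "duration_s": s.diffusion.duration_s,
                }
            )
    return path


def read_ground_truth(path) -> GroundTruthBundle:
    from .simulate import DiffusionParams, StrainFieldSpec

    with h5py.File(path, "r") as h5:
        spec = None
        if "spec_json" in h5.attrs:
            d = json.loads(h5.attrs["spec_json"])
            spec = StrainFieldSpec(
                template=d["template"],
                k_pos=d["k_pos"],
                k_neg=d["k_neg"],
                layer_depth_um=d["layer_depth_um"],
                layer_strain=d["layer_strain"],
                ramp_depth_um=d["ramp_depth_um"],
                diffusion=DiffusionParams(
                    D_m2_s=d["D_m2_s"], C0=d["C0"], duration_s=d["duration_s"]
                ),
            )
        return GroundTruthBundle(
            z_um=h5["z_um"][...],
            t_s=h5["t_s"][...],
            C=h5["C"][...],
            eps=h5["eps"][...],
            U_um=h5["U_um"][...] if "U_um" in h5 else None,
            surface_px=int(h5.attrs["surface_px"]) if "surface_px" in h5.attrs else None,
            spec=spec,
        )


def export_strain_map(out_dir, cmap: CumulativeStrainMap, stem: str = "cumulative") -> dict:
    """Export a cumulative map: float32 TIFF, 8-bit mask TIFF, window-mean CSV.

    The CSV holds means over non-overlapping processing-window tiles (half-
    window step would oversample; tiles keep the file small and readable).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{stem}.tiff"
    mask_path = out_dir / f"{stem}_mask.tiff"
    csv_path = out_dir / f"{stem}_window_means.csv"
    tifffile.imwrite(tiff_path, cmap.eps_cum.astype(np.float32))
    tifffile.imwrite(mask_path, (cmap.mask.astype(np.uint8) * 255))

    optics = cmap.optics or OpticalParams()
    wz = max(int(round((cmap.window_z_um or 100.0) / optics.dz_air_um)), 1)
    wx = max(int(round((cmap.window_x_um or 100.0) / optics.dx_um)), 1)
    rows = []
    nz, nx = cmap.eps_cum.shape
    for zi in range(0, nz - wz + 1, wz):
        for xi in range(0, nx - wx + 1, wx):
            tile_mask = cmap.mask[zi : zi + wz, xi : xi + wx]
            if tile_mask.any():
                tile = cmap.eps_cum[zi : zi + wz, xi : xi + wx][tile_mask]
                rows.append(
                    {
                        "z_px": zi + wz // 2,
                        "x_px": xi + wx // 2,
                        "strain_mean": float(tile.mean()),
                        "n_valid": int(tile_mask.sum()),
                    }
                )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return {"tiff": tiff_path, "mask": mask_path, "csv": csv_path}


def export_profiles_csv(path, profiles: Sequence[DepthProfile]) -> Path:
    """Tidy CSV with time_s / depth_um / strain columns."""
    path = Path(path)
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": p.t,
                    "depth_um": p.depth_um,
                    "strain": p.strain,
                    "avg_window_z_um": p.avg_window_z_um,
                    "avg_window_x_um": p.avg_window_x_um,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_profiles_csv(path) -> list[DepthProfile]:
    df = pd.read_csv(path)
    profiles = []
    for t, g in df.groupby("time_s", sort=True):
        profiles.append(
            DepthProfile(
                depth_um=g["depth_um"].to_numpy(),
                strain=g["strain"].to_numpy(),
                avg_window_z_um=float(g["avg_window_z_um"].iloc[0]),
                avg_window_x_um=float(g["avg_window_x_um"].iloc[0]),
                t=float(t),
            )
        )
    return profiles


def export_waterfall_csv(path, w: Waterfall) -> Path:
    """Waterfall as a matrix CSV: rows = times, columns = depths (µm)."""
    path = Path(path)
    df = pd.DataFrame(w.strain, index=w.time_s, columns=np.round(w.depth_um, 3))
    df.index.name = "time_s"
    df.to_csv(path)
    return path


def export_extrema_csv(path, track: ExtremaTrack) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": track.time_s,
            "depth_min_um": track.depth_min_um,
            "value_min": track.value_min,
            "depth_max_um": track.depth_max_um,
            "value_max": track.value_max,
            "depth_neutral_um": track.depth_neutral_um,
            "min_edge_flag": track.min_edge,
            "max_edge_flag": track.max_edge,
        }
    ).to_csv(path, index=False)
    return path
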