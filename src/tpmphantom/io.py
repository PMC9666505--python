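"""File I/O: RI volumes (HDF5 / multi-page TIFF), projection sets (HDF5),
and YAML phantom configurations.

HDF5 volume layout: dataset ``"ri"`` with attributes ``voxel_pitch_um``,
``origin_um`` and optionally ``n_background``.  Projection-set layout:
datasets ``fields/real``, ``fields/imag`` (n_proj × H × W),
``azimuth_deg``, ``directions``; attributes ``wavelength_nm``,
``zenith_deg``, ``pixel_pitch_um``, ``n_immersion``, ``noise_sigma``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward import OpticalConfig, ProjectionSet
from .geometry import CellTargetSpec, PhantomSpec, RIVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_projection_set",
    "read_projection_set",
    "load_phantom_config",
    "dump_phantom_config",
]


def write_volume(path: str | Path, volume: RIVolume, n_background: float | None = None) -> None:
    """Write an RI volume; format chosen from the file extension.

    ``.h5``/``.hdf5`` store float64 losslessly; ``.tif``/``.tiff`` write
    32-bit float pages (one per z-slice) with the grid metadata in the
    image description.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("ri", data=volume.values)
            ds.attrs["voxel_pitch_um"] = volume.voxel_pitch
            ds.attrs["origin_um"] = volume.origin
            if n_background is not None:
                ds.attrs["n_background"] = n_background
    elif path.suffix in (".tif", ".tiff"):
        # pages along z: (nz, ny, nx) so each page is an xy slice
        pages = np.transpose(volume.values, (2, 1, 0)).astype(np.float32)
        meta = {
            "voxel_pitch_um": volume.voxel_pitch.tolist(),
            "origin_um": volume.origin.tolist(),
        }
        if n_background is not None:
            meta["n_background"] = n_background
        tifffile.imwrite(path, pages, description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")


def read_volume(path: str | Path) -> RIVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "ri" not in f:
                raise ValueError(f"{path}: missing dataset 'ri'")
            ds = f["ri"]
            for attr in ("voxel_pitch_um", "origin_um"):
                if attr not in ds.attrs:
                    raise ValueError(f"{path}: missing attribute {attr!r}")
            return RIVolume(ds[()], ds.attrs["voxel_pitch_um"], ds.attrs["origin_um"])
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else {}
        if "voxel_pitch_um" not in meta:
            raise ValueError(f"{path}: missing voxel_pitch_um metadata")
        values = np.transpose(pages, (2, 1, 0)).astype(np.float64)
        return RIVolume(values, meta["voxel_pitch_um"], meta.get("origin_um", (0, 0, 0)))
    raise ValueError(f"unsupported volume format {path.suffix!r}")


def write_projection_set(path: str | Path, pset: ProjectionSet) -> None:
    cfg = pset.config
    azimuth = np.degrees(np.arctan2(pset.directions[:, 1], pset.directions[:, 0]))
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("fields/real", data=pset.fields.real)
        f.create_dataset("fields/imag", data=pset.fields.imag)
        f.create_dataset("azimuth_deg", data=azimuth)
        f.create_dataset("directions", data=pset.directions)
        f.attrs["wavelength_nm"] = cfg.wavelength_nm
        f.attrs["zenith_deg"] = cfg.zenith_deg
        f.attrs["pixel_pitch_um"] = pset.pixel_pitch
        f.attrs["n_immersion"] = cfg.n_immersion
        f.attrs["na"] = cfg.na
        f.attrs["noise_sigma"] = pset.noise_sigma
        f.attrs["azimuth_step_deg"] = cfg.azimuth_step_deg
        f.attrs["pupil"] = cfg.pupil


def read_projection_set(path: str | Path) -> ProjectionSet:
    with h5py.File(Path(path), "r") as f:
        for ds in ("fields/real", "fields/imag", "azimuth_deg"):
            if ds not in f:
                raise ValueError(f"{path}: missing dataset {ds!r}")
        for attr in ("wavelength_nm", "zenith_deg", "pixel_pitch_um", "n_immersion"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing attribute {attr!r}")
        fields = f["fields/real"][()] + 1j * f["fields/imag"][()]
        azimuth = f["azimuth_deg"][()]
        cfg = OpticalConfig(
            wavelength_nm=float(f.attrs["wavelength_nm"]),
            na=float(f.attrs.get("na", 1.3)),
            n_immersion=float(f.attrs["n_immersion"]),
            zenith_deg=float(f.attrs["zenith_deg"]),
            n_projections=len(fields),
            azimuth_step_deg=float(
                f.attrs.get("azimuth_step_deg", 360.0 / max(len(fields), 1))
            ),
            pupil=bool(f.attrs.get("pupil", True)),
        )
        if "directions" in f:
            directions = f["directions"][()]
        else:
            th = np.radians(cfg.zenith_deg)
            phi = np.radians(azimuth)
            directions = np.stack(
                [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi),
                 np.full_like(phi, np.cos(th))], axis=1,
            )
        return ProjectionSet(
            fields,
            directions,
            np.asarray(f.attrs["pixel_pitch_um"]),
            cfg,
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
        )


def load_phantom_config(path: str | Path) -> tuple[PhantomSpec, CellTargetSpec | None]:
    """Read a YAML config with optional ``phantom:`` and ``cell:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pdata = raw.get("phantom", {})
    for key in ("cube_size", "rod_gap_range"):
        if key in pdata:
            pdata[key] = tuple(pdata[key])
    spec = PhantomSpec(**pdata)
    cell = None
    if "cell" in raw:
        cdata = raw["cell"] or {}
        for key in (
            "ellipsoid_size", "line_group_frequencies", "nucleus_center",
            "nucleus_semiaxes", "gradient_center", "gradient_size",
            "nucleoli_radii",
        ):
            if key in cdata:
                cdata[key] = tuple(cdata[key])
        if "nucleoli_centers" in cdata:
            cdata["nucleoli_centers"] = tuple(tuple(c) for c in cdata["nucleoli_centers"])
        cell = CellTargetSpec(**cdata)
    return spec, cell


def dump_phantom_config(
    path: str | Path, spec: PhantomSpec, cell: CellTargetSpec | None = None
) -> None:
    data: dict = {"phantom": spec.to_dict()}
    if cell is not None:
        data["cell"] = cell.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
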