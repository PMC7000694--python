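"""Container formats and result writing.

The FLIM stack lives in an open, documented HDF5 layout (vendor TCSPC
formats are proprietary and out of scope):

    /                attrs: schema_version, bin_width_ns, n_bins,
                     t_start_ns, pixel_size_um, tau_D_ns, tau_AD_ns,
                     metadata_json
    /frames/0000     (rows, cols, bins) uint photon counts,
                     attrs: time_s, z_index
    /ground_truth    optional JSON string (simulator sidecar)

Timestamps are signed seconds with t = 0 at the first uncaging pulse.
Intensity stacks go to OME-TIFF, lifetime maps to 32-bit float TIFF,
masks to labelled integer TIFF, tables to UTF-8 comma-separated CSV, and
every run emits a JSON manifest with a config hash, package version and
seeds (no timestamps, so reruns are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import CalibrationConstants
from .simulate import IntensityMovie, Scenario, ScenePhantom
from .stack import FLIMFrame, FLIMStack

__all__ = [
    "SchemaError",
    "SCHEMA_VERSION",
    "write_flim_container",
    "read_flim_container",
    "read_ground_truth",
    "write_intensity_stack",
    "read_intensity_stack",
    "write_label_mask",
    "read_label_mask",
    "write_dendrite_path",
    "read_dendrite_path",
    "write_lifetime_map",
    "write_results",
    "write_fixture",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario_file",
]

SCHEMA_VERSION = "1.0"
_REQUIRED_ATTRS = ("schema_version", "bin_width_ns", "n_bins", "t_start_ns", "pixel_size_um", "tau_D_ns", "tau_AD_ns")


class SchemaError(ValueError):
    """The container violates the documented schema; names the field."""


# ---------------------------------------------------------------------------
# FLIM container
# ---------------------------------------------------------------------------


def write_flim_container(stack: FLIMStack, path, ground_truth: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["bin_width_ns"] = float(stack.bin_edges[1] - stack.bin_edges[0])
        h5.attrs["n_bins"] = int(stack.n_bins)
        h5.attrs["t_start_ns"] = float(stack.bin_edges[0])
        h5.attrs["pixel_size_um"] = float(stack.pixel_size_um)
        h5.attrs["tau_D_ns"] = float(stack.calibration.tau_D)
        h5.attrs["tau_AD_ns"] = float(stack.calibration.tau_AD)
        h5.attrs["metadata_json"] = json.dumps(stack.metadata, sort_keys=True)
        grp = h5.create_group("frames")
        for i, frame in enumerate(stack.frames):
            ds = grp.create_dataset(f"{i:04d}", data=frame.counts, compression="gzip", compression_opts=1)
            ds.attrs["time_s"] = float(frame.time_s)
            ds.attrs["z_index"] = int(frame.z_index)
        if ground_truth is not None:
            h5.create_dataset("ground_truth", data=json.dumps(ground_truth))
    return path


def read_flim_container(path) -> FLIMStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:  # truncated / not HDF5: explicit failure, no partial load
        raise OSError(f"cannot read FLIM container {path}: {exc}") from exc
    with h5:
        for name in _REQUIRED_ATTRS:
            if name not in h5.attrs:
                raise SchemaError(f"container {path} missing required metadata field '{name}'")
        version = str(h5.attrs["schema_version"])
        if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise SchemaError(f"unsupported schema version '{version}' (reader supports {SCHEMA_VERSION})")
        n_bins = int(h5.attrs["n_bins"])
        width = float(h5.attrs["bin_width_ns"])
        start = float(h5.attrs["t_start_ns"])
        edges = start + width * np.arange(n_bins + 1)
        if "frames" not in h5:
            raise SchemaError(f"container {path} missing 'frames' group")
        frames = []
        for key in sorted(h5["frames"].keys()):
            ds = h5["frames"][key]
            if ds.ndim != 3 or ds.shape[2] != n_bins:
                raise SchemaError(f"frame '{key}' shape {ds.shape} inconsistent with n_bins={n_bins}")
            frames.append(FLIMFrame(ds[()], float(ds.attrs["time_s"]), int(ds.attrs["z_index"])))
        frames.sort(key=lambda f: (f.z_index, f.time_s))
        metadata = json.loads(h5.attrs.get("metadata_json", "{}"))
        return FLIMStack(
            frames=frames,
            bin_edges=edges,
            pixel_size_um=float(h5.attrs["pixel_size_um"]),
            calibration=CalibrationConstants(float(h5.attrs["tau_D_ns"]), float(h5.attrs["tau_AD_ns"])),
            metadata=metadata,
        )


def read_ground_truth(path) -> dict | None:
    with h5py.File(path, "r") as h5:
        if "ground_truth" not in h5:
            return None
        return json.loads(h5["ground_truth"][()].decode())


# ---------------------------------------------------------------------------
# TIFF / CSV helpers
# ---------------------------------------------------------------------------


def write_intensity_stack(movie: IntensityMovie, path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        movie.data.astype(np.float32),
        ome=False,  # shaped TIFF: JSON metadata round-trips the timestamps
        photometric="minisblack",
        metadata={
            "axes": "TZYX",
            "times_s": movie.times_s.tolist(),
            "pixel_size_um": movie.pixel_size_um,
            "z_spacing_um": movie.z_spacing_um,
        },
    )
    return path


def read_intensity_stack(path) -> IntensityMovie:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    times = np.asarray(meta.get("times_s", np.arange(data.shape[0])), dtype=float)
    return IntensityMovie(
        data=data,
        times_s=times,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        z_spacing_um=float(meta.get("z_spacing_um", 1.0)),
    )


def write_label_mask(labels: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))
    return path


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_lifetime_map(mean_tau: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mean_tau, dtype=np.float32))
    return path


def write_dendrite_path(path_um: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(path_um, dtype=float), columns=["x_um", "y_um"]).to_csv(path, index=False)
    return path


def read_dendrite_path(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_results(
    out_dir,
    tables: dict[str, pd.DataFrame] | None = None,
    maps: dict[str, np.ndarray] | None = None,
    config: dict | None = None,
    seeds=None,
) -> dict:
    """Write tidy CSV tables, float TIFF maps and a JSON run manifest.

    An empty analysis set still produces headers-only CSVs and a valid
    manifest.  The manifest records a hash of the configuration, the
    package version and the seeds, but no timestamps, so an unchanged
    (config, seed) rerun reproduces every file byte for byte.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p.name
    for name, arr in (maps or {}).items():
        p = out / f"{name}.tif"
        write_lifetime_map(arr, p)
        written[name] = p.name
    manifest = {
        "package": "flimspine",
        "version": __version__,
        "config_hash": _config_hash(config or {}),
        "seeds": list(np.atleast_1d(seeds).tolist()) if seeds is not None else [],
        "files": dict(sorted(written.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Scenario YAML
# ---------------------------------------------------------------------------


def scenario_to_dict(scenario: Scenario) -> dict:
    from .simulate import default_frame_times  # noqa: F401  (documented default)

    geo = dataclasses.asdict(scenario.geometry)
    geo["shape"] = list(scenario.geometry.shape)
    geo["spines"] = [dataclasses.asdict(s) for s in scenario.geometry.spines]
    acq = dataclasses.asdict(scenario.acquisition)
    acq["frame_shape"] = list(scenario.acquisition.frame_shape)
    acq["frame_times_s"] = np.asarray(scenario.acquisition.frame_times_s).tolist()
    acq["calibration"] = {
        "tau_D": scenario.acquisition.calibration.tau_D,
        "tau_AD": scenario.acquisition.calibration.tau_AD,
    }
    return {
        "name": scenario.name,
        "geometry": geo,
        "program": dataclasses.asdict(scenario.program),
        "acquisition": acq,
    }


def scenario_from_dict(d: dict) -> Scenario:
    from .simulate import AcquisitionConfig, GeometryConfig, PlasticityProgram, SpineSpec

    geo = dict(d.get("geometry", {}))
    if "shape" in geo:
        geo["shape"] = tuple(geo["shape"])
    if "spines" in geo:
        geo["spines"] = [SpineSpec(**s) for s in geo["spines"]]
    acq = dict(d.get("acquisition", {}))
    if "frame_shape" in acq:
        acq["frame_shape"] = tuple(acq["frame_shape"])
    times = acq.pop("frame_times_s", None)
    if isinstance(times, dict):
        from .simulate import default_frame_times

        times = default_frame_times(
            times["start"], times["stop"], times["step"],
            skip=tuple(times["skip"]) if "skip" in times else None,
        )
    if times is not None:
        acq["frame_times_s"] = np.asarray(times, dtype=float)
    cal = acq.pop("calibration", None)
    if cal is not None:
        acq["calibration"] = CalibrationConstants(float(cal["tau_D"]), float(cal["tau_AD"]))
    return Scenario(
        name=d.get("name", "unnamed"),
        geometry=GeometryConfig(**geo),
        program=PlasticityProgram(**d.get("program", {})),
        acquisition=AcquisitionConfig(**acq),
    )


def save_scenario(scenario: Scenario, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
    return path


def load_scenario_file(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def write_fixture(
    out_dir,
    scenario: Scenario,
    phantom: ScenePhantom,
    stack: FLIMStack,
    truth: dict,
    movie: IntensityMovie,
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "flim": write_flim_container(stack, out / "flim.h5", ground_truth=truth),
        "intensity": write_intensity_stack(movie, out / "intensity.tif"),
        "masks": write_label_mask(phantom.label_image, out / "masks.tif"),
        "dendrite_path": write_dendrite_path(phantom.dendrite_path, out / "dendrite_path.csv"),
        "scenario": save_scenario(scenario, out / "scenario.yaml"),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = out / "ground_truth.json"
    return {k: str(v) for k, v in paths.items()}
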