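"""File exchange: NIfTI volumes, event tables, truth/config sidecars.

EEG goes through :mod:`wmfusion.edf`, event schedules through
``TrialSchedule.to_tsv``/``from_tsv``; this module covers BOLD (NIfTI-1
with TR in the header), statistical and label maps, and YAML/NPZ sidecars
for configurations and simulation ground truth.
"""

from __future__ import annotations

import dataclasses
import json

import nibabel as nib
import numpy as np
import yaml

from .fusion_glm import StatMap
from .paradigm_sim import BoldSeries, ParadigmConfig, SimulationTruth
from .spectral import BandDefinition

__all__ = [
    "save_bold",
    "load_bold",
    "save_map",
    "load_map",
    "save_config",
    "load_config",
    "save_truth",
    "load_truth",
    "save_json",
    "save_stat_map",
    "save_segments",
    "load_segments",
]


def _affine(voxel_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def save_bold(bold: BoldSeries, path) -> None:
    img = nib.Nifti1Image(bold.data, _affine(bold.voxel_mm))
    img.header.set_zooms(tuple(bold.voxel_mm) + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path, tr_s: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = tr_s if tr_s is not None else float(zooms[3])
    if tr <= 0:
        raise ValueError("TR missing from NIfTI header; pass tr_s explicitly")
    return BoldSeries(
        data=np.asarray(img.dataobj, dtype=float),
        tr_s=tr,
        voxel_mm=tuple(float(z) for z in zooms[:3]),
    )


def save_map(arr: np.ndarray, voxel_mm, path) -> None:
    """Write a 3-D statistic or integer label map as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _affine(voxel_mm)), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_config(config: ParadigmConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=False)


def load_config(path) -> ParadigmConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    for key in ("isi_range_ms", "loads", "grid_shape", "voxel_mm"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return ParadigmConfig(**d)


def save_truth(truth: SimulationTruth, yaml_path, npz_path) -> None:
    """Scalars to YAML; topographies and voxel maps to a NPZ companion."""
    scalars = {
        "bands": [[b.name, b.lo_hz, b.hi_hz] for b in truth.bands],
        "mean_power": truth.mean_power,
        "load_effect": truth.load_effect,
        "trial_cv": truth.trial_cv,
        "channel_labels": list(truth.channel_labels),
        "ar1_rho": truth.ar1_rho,
        "noise_sd": truth.noise_sd,
        "eeg_noise_uv": truth.eeg_noise_uv,
        "baseline_bold": truth.baseline_bold,
        "seed": truth.seed,
    }
    with open(yaml_path, "w") as f:
        yaml.safe_dump(scalars, f, sort_keys=False)
    arrays = {}
    for b in truth.band_names:
        arrays[f"topography__{b}"] = truth.topography[b]
        arrays[f"coupling__{b}"] = truth.coupling_map[b]
        arrays[f"coupling_load_delta__{b}"] = truth.coupling_load_delta[b]
    for (phase, load), m in truth.task_beta_map.items():
        arrays[f"task__{phase}__{load}"] = m
    np.savez_compressed(npz_path, **arrays)


def load_truth(yaml_path, npz_path) -> SimulationTruth:
    with open(yaml_path) as f:
        s = yaml.safe_load(f)
    arrays = np.load(npz_path)
    bands = tuple(BandDefinition(n, float(lo), float(hi)) for n, lo, hi in s["bands"])
    names = [b.name for b in bands]
    task = {}
    for key in arrays.files:
        if key.startswith("task__"):
            _, phase, load = key.split("__")
            task[(phase, load)] = arrays[key]
    return SimulationTruth(
        bands=bands,
        mean_power={k: float(v) for k, v in s["mean_power"].items()},
        load_effect={k: float(v) for k, v in s["load_effect"].items()},
        trial_cv={k: float(v) for k, v in s["trial_cv"].items()},
        topography={b: arrays[f"topography__{b}"] for b in names},
        channel_labels=list(s["channel_labels"]),
        coupling_map={b: arrays[f"coupling__{b}"] for b in names},
        coupling_load_delta={b: arrays[f"coupling_load_delta__{b}"] for b in names},
        task_beta_map=task,
        ar1_rho=float(s["ar1_rho"]),
        noise_sd=float(s["noise_sd"]),
        eeg_noise_uv=float(s["eeg_noise_uv"]),
        baseline_bold=float(s["baseline_bold"]),
        seed=s["seed"],
    )


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=default)


def save_stat_map(stat_map: StatMap, path) -> None:
    voxel_mm = stat_map.voxel_mm or (1.0, 1.0, 1.0)
    save_map(stat_map.t, voxel_mm, path)


def save_segments(segs, path) -> None:
    """Write a SegmentSet with trial metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("segments", data=segs.segments, compression="gzip")
        f.create_dataset("trial_index", data=np.asarray(segs.trial_index, dtype=np.int64))
        f.create_dataset(
            "loads", data=np.asarray([str(x) for x in segs.loads], dtype="S8")
        )
        f.create_dataset("retained", data=np.asarray(segs.retained, dtype=bool))
        f.attrs["fs"] = segs.fs
        f.attrs["window_s"] = segs.window_s


def load_segments(path):
    import h5py

    from .eeg_clean import SegmentSet

    with h5py.File(path, "r") as f:
        return SegmentSet(
            segments=f["segments"][()],
            fs=float(f.attrs["fs"]),
            window_s=float(f.attrs["window_s"]),
            trial_index=f["trial_index"][()],
            loads=np.asarray([x.decode() for x in f["loads"][()]]),
            retained=f["retained"][()],
        )
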