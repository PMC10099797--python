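"""NIfTI/CSV/YAML handling, run configuration, and the end-to-end pipeline.

Volumes are stored as NIfTI (via nibabel) with voxel-to-world affines in mm
(standard s/q-form semantics, 0-based voxel indices).  A MEGE acquisition
is written as a single 5-D file (x, y, z, echo, TR) plus a YAML sidecar
describing the protocol; per-echo/per-TR single-volume files with explicit
labels are also readable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .core_model import MEGEDataset, MEGEProtocol
from .fitting import (fit_flip_angle_map, fit_relaxation_maps, rates_to_times,
                      smooth_flip_angle_map)
from .maps_roi import TissueMasks, roi_statistics

__all__ = [
    "read_nifti",
    "write_nifti",
    "protocol_to_dict",
    "protocol_from_dict",
    "write_mege_dataset",
    "read_mege_dataset",
    "RunConfig",
    "run_pipeline",
]


def write_nifti(path, array, affine=None):
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine),
             str(path))


def read_nifti(path):
    """Return (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def protocol_to_dict(protocol: MEGEProtocol) -> dict:
    return {
        "TR_list": list(protocol.TR_list),
        "averages_per_TR": list(protocol.averages_per_TR),
        "TE1": protocol.TE1,
        "deltaTE": protocol.deltaTE,
        "n_echoes": protocol.n_echoes,
        "nominal_flip": protocol.nominal_flip,
        "FOV": list(protocol.FOV),
        "voxel_size": list(protocol.voxel_size),
    }


def protocol_from_dict(d: dict) -> MEGEProtocol:
    return MEGEProtocol(
        TR_list=tuple(d["TR_list"]),
        averages_per_TR=tuple(d["averages_per_TR"]),
        TE1=float(d["TE1"]), deltaTE=float(d["deltaTE"]),
        n_echoes=int(d["n_echoes"]), nominal_flip=float(d["nominal_flip"]),
        FOV=tuple(d.get("FOV", (288.0, 288.0, 240.0))),
        voxel_size=tuple(d.get("voxel_size", (6.0, 6.0, 10.0))))


def write_mege_dataset(path, dataset: MEGEDataset):
    """Write a 5-D NIfTI plus a ``<stem>.protocol.yaml`` sidecar."""
    path = Path(path)
    write_nifti(path, dataset.data, dataset.affine)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    with open(str(sidecar) + ".protocol.yaml", "w") as fh:
        yaml.safe_dump(protocol_to_dict(dataset.protocol), fh)


def read_mege_dataset(source, protocol: MEGEProtocol = None) -> MEGEDataset:
    """Assemble a MEGE dataset from disk.

    ``source`` is either the path of a single 5-D NIfTI (the protocol is
    taken from its YAML sidecar unless passed explicitly) or a list of
    ``{"path": ..., "echo": j, "tr_index": i}`` entries of labelled 3-D
    volumes (0-based labels; order of the list does not matter).  All files
    must agree on grid shape and affine.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if protocol is None:
            sidecar = Path(str(path.with_suffix("").with_suffix(""))
                           + ".protocol.yaml")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"no protocol given and no sidecar at {sidecar}")
            with open(sidecar) as fh:
                protocol = protocol_from_dict(yaml.safe_load(fh))
        data, affine = read_nifti(path)
        if data.ndim != 5:
            raise ValueError(f"{path} is not a 5-D MEGE volume")
        return MEGEDataset(data=data, protocol=protocol, affine=affine)

    if protocol is None:
        raise ValueError("a protocol is required for labelled per-volume files")
    shape = None
    affine = None
    data = np.full(tuple(), np.nan)
    filled = np.zeros((protocol.n_echoes, protocol.n_TR), dtype=bool)
    for entry in source:
        vol, aff = read_nifti(entry["path"])
        j, i = int(entry["echo"]), int(entry["tr_index"])
        if not (0 <= j < protocol.n_echoes and 0 <= i < protocol.n_TR):
            raise ValueError(
                f"{entry['path']}: labels (echo={j}, tr_index={i}) do not "
                "match the protocol")
        if shape is None:
            shape, affine = vol.shape, aff
            data = np.full(shape + (protocol.n_echoes, protocol.n_TR), np.nan)
        elif vol.shape != shape:
            raise ValueError(
                f"{entry['path']}: grid {vol.shape} differs from {shape}")
        elif not np.allclose(aff, affine, atol=1e-6):
            raise ValueError(f"{entry['path']}: affine differs from the "
                             "first file's affine")
        data[..., j, i] = vol
        filled[j, i] = True
    if not filled.all():
        missing = np.argwhere(~filled)
        raise ValueError(f"missing volumes for (echo, tr_index) {missing.tolist()}")
    return MEGEDataset(data=data, protocol=protocol, affine=affine)


@dataclass
class RunConfig:
    """Configuration of one end-to-end relaxometry run.

    Either ``data_path`` (a 5-D MEGE NIfTI) or ``phantom`` (keyword
    arguments for :func:`hdomri.phantom.build_phantom`, plus optional
    ``target_snr``) must be given.  ``mask_paths`` maps ROI names to NIfTI
    masks on the data grid; with a phantom input the phantom's own masks
    are used when ``mask_paths`` is empty.
    """

    protocol: MEGEProtocol
    out_dir: str
    data_path: str = None
    phantom: dict = None
    mask_paths: dict = field(default_factory=dict)
    signal_threshold: float = 0.05
    rounding: str = "d2"
    seed: int = 0

    def __post_init__(self):
        if (self.data_path is None) == (self.phantom is None):
            raise ValueError("exactly one of data_path / phantom must be set")
        if self.rounding not in ("none", "d2", "h1"):
            raise ValueError(f"unknown rounding {self.rounding!r}")
        if not 0 <= self.signal_threshold < 1:
            raise ValueError("signal_threshold must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = protocol_to_dict(self.protocol)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["protocol"] = protocol_from_dict(d["protocol"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (inputs, options, seed);
        the output location does not participate."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run flip-angle fit -> 5x5x5 smoothing -> dual fit -> time maps -> ROI
    summary, writing all artifacts under ``config.out_dir``.

    Returns a dict with the output paths, the ROI summary DataFrame and the
    JSON-logged run metadata.  Deterministic for fixed inputs and seed.
    """
    from .phantom import build_phantom, sigma_for_snr, synthesize_mege

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "config_hash": config.config_hash(),
           "config": config.to_dict(), "seed": config.seed,
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.data_path is not None:
        dataset = _stage("read", read_mege_dataset, config.data_path,
                         config.protocol)
        masks = {name: read_nifti(p)[0] > 0.5
                 for name, p in config.mask_paths.items()}
        tissue_masks = TissueMasks(masks=masks, affine=dataset.affine)
    else:
        opts = dict(config.phantom)
        target_snr = opts.pop("target_snr", None)
        opts.setdefault("seed", config.seed)
        truth = _stage("phantom", build_phantom, **opts)
        if target_snr is not None:
            truth.noise_sigma = sigma_for_snr(truth, config.protocol,
                                              target_snr)
        dataset = _stage("synthesize", synthesize_mege, truth, config.protocol)
        tissue_masks = TissueMasks.from_phantom(truth, affine=dataset.affine)

    stage1 = _stage("fit-b1", fit_flip_angle_map, dataset,
                    signal_threshold=config.signal_threshold)
    alpha = _stage("smooth-b1", smooth_flip_angle_map,
                   stage1.flip_angle, stage1.qc_flags)
    maps = _stage("fit-relax", fit_relaxation_maps, dataset, alpha,
                  signal_threshold=config.signal_threshold,
                  r1_init=stage1.R1)
    times = _stage("rates-to-times", rates_to_times, maps)
    summary = _stage("roi-summary", roi_statistics, times["T1_ms"],
                     tissue_masks, maps.qc_flags, rounding=config.rounding)
    summary_t2s = _stage("roi-summary-t2star", roi_statistics,
                         times["T2star_ms"], tissue_masks, maps.qc_flags,
                         rounding=config.rounding)

    paths = {}
    for name, arr in [("flip_angle", alpha), ("R1", maps.R1),
                      ("R2star", maps.R2star), ("amplitude", maps.amplitude),
                      ("T1_ms", times["T1_ms"]),
                      ("T2star_ms", times["T2star_ms"]),
                      ("qc_flags", maps.qc_flags.astype(float))]:
        p = out / f"{name}.nii.gz"
        write_nifti(p, arr, dataset.affine)
        paths[name] = str(p)
    csv_path = out / "roi_summary.csv"
    joined = summary.table.join(summary_t2s.table, lsuffix="_T1",
                                rsuffix="_T2star")
    joined.insert(0, "config_hash", config.config_hash())
    joined.to_csv(csv_path)
    paths["roi_summary"] = str(csv_path)

    log["outputs"] = paths
    log["qc_flag_counts"] = maps.flag_counts()
    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2)
    paths["log"] = str(log_path)
    return {"paths": paths, "summary": joined, "log": log}
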