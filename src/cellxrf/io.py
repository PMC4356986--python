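"""File formats and provenance: HDF5 spectrum stacks, TIFF maps, YAML
configuration, CSV tables and JSON manifests.

Every writer has a matching reader that round-trips values exactly; the
manifest records the configuration hash and seed of each output so a run
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Dict, Optional, Union

import h5py
import numpy as np
import tifffile
import yaml

from .segmentation import CellMask, SAXSMap
from .spectral import ElementalMap, SpectrumStack

__all__ = [
    "write_stack_h5", "read_stack_h5",
    "write_map_tiff", "read_map_tiff",
    "write_saxs_tiff", "read_saxs_tiff",
    "write_mask", "read_mask",
    "write_series_tiff", "read_series_tiff",
    "write_hologram_png",
    "load_yaml", "dump_yaml",
    "config_hash", "write_manifest",
]

PathLike = Union[str, Path]


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# HDF5 spectrum stacks

def write_stack_h5(path: PathLike, stack: SpectrumStack) -> Path:
    """Layout: /counts (rows, cols, channels) uint32, /energy_keV,
    /dwell_s scalar, /meta JSON string; step sizes as /counts attrs."""
    path = Path(path)
    counts = stack.counts
    if not np.issubdtype(counts.dtype, np.integer):
        counts = np.rint(counts).astype(np.uint32)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=counts.astype(np.uint32),
                             compression="gzip", compression_opts=4)
        d.attrs["step_y_um"] = stack.step_y_um
        d.attrs["step_z_um"] = stack.step_z_um
        f.create_dataset("energy_keV", data=stack.energy_keV)
        f.create_dataset("dwell_s", data=float(stack.dwell_s))
        f.create_dataset("meta", data=json.dumps(_jsonable(stack.meta)))
    return path


def read_stack_h5(path: PathLike) -> SpectrumStack:
    with h5py.File(path, "r") as f:
        counts = f["counts"][()]
        return SpectrumStack(
            counts,
            f["energy_keV"][()],
            float(f["dwell_s"][()]),
            step_y_um=float(f["counts"].attrs.get("step_y_um", 1.0)),
            step_z_um=float(f["counts"].attrs.get("step_z_um", 1.0)),
            meta=json.loads(f["meta"][()]),
        )


# ---------------------------------------------------------------------------
# TIFF maps

def write_map_tiff(path: PathLike, emap: ElementalMap) -> Path:
    path = Path(path)
    tifffile.imwrite(path, emap.values.astype(np.float32),
                     metadata={"element": emap.element, "units": emap.units,
                               "step_y_um": emap.step_y_um,
                               "step_z_um": emap.step_z_um})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(_jsonable({
        "element": emap.element, "units": emap.units,
        "step_y_um": emap.step_y_um, "step_z_um": emap.step_z_um,
        "meta": emap.meta}), indent=2))
    return path


def read_map_tiff(path: PathLike) -> ElementalMap:
    path = Path(path)
    values = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    info: Dict[str, Any] = {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
    return ElementalMap(values, element=info.get("element", "?"),
                        step_y_um=info.get("step_y_um", 1.0),
                        step_z_um=info.get("step_z_um", 1.0),
                        units=info.get("units", "counts"),
                        meta=info.get("meta", {}))


def write_saxs_tiff(path: PathLike, saxs: SAXSMap) -> Path:
    path = Path(path)
    tifffile.imwrite(path, saxs.values.astype(np.float32))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_jsonable({
        "step_y_um": saxs.step_y_um, "step_z_um": saxs.step_z_um,
        "meta": saxs.meta}), indent=2))
    return path


def read_saxs_tiff(path: PathLike) -> SAXSMap:
    path = Path(path)
    values = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    info = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SAXSMap(values, step_y_um=info.get("step_y_um", 1.0),
                   step_z_um=info.get("step_z_um", 1.0),
                   meta=info.get("meta", {}))


def write_mask(path: PathLike, mask: CellMask) -> Path:
    """8-bit TIFF (0/255) plus JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_jsonable(mask.provenance), indent=2))
    return path


def read_mask(path: PathLike) -> CellMask:
    path = Path(path)
    arr = tifffile.imread(path) > 0
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CellMask(arr, provenance=prov)


def write_series_tiff(path: PathLike, frames: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32),
                     photometric="minisblack")
    return path


def read_series_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_hologram_png(path: PathLike, phase: np.ndarray) -> Path:
    """Phase [0, 2pi) quantised to 8-bit grey levels (SLM convention)."""
    from PIL import Image
    path = Path(path)
    levels = np.floor(np.asarray(phase) / (2 * np.pi) * 256).astype(np.uint8)
    Image.fromarray(levels, mode="L").save(path)
    return path


# ---------------------------------------------------------------------------
# config / manifest

def load_yaml(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: PathLike, obj: Any) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_jsonable(obj), fh, sort_keys=True)
    return path


def config_hash(obj: Any) -> str:
    """Stable SHA-256 of a configuration structure."""
    blob = json.dumps(_jsonable(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: PathLike, config: Any, seed: Optional[int],
                   outputs: Dict[str, str], extra: Optional[dict] = None
                   ) -> Path:
    path = Path(path)
    manifest = {
        "schema_version": 1,
        "config_hash": config_hash(config),
        "seed": seed,
        "outputs": outputs,
        "config": _jsonable(config),
    }
    if extra:
        manifest.update(_jsonable(extra))
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
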