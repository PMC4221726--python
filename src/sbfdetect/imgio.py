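"""Image, detection, scene and config I/O.

Images are read with tifffile (``.tif``/``.tiff``) or imageio (everything
else) and normalized to float64 in [0, 1] by dtype range; multi-channel
inputs require an explicit channel index.  Detections go to CSV with a
JSON sidecar that embeds the exact run parameters; synthetic scenes go to
16-bit TIFF plus a truth-manifest CSV and a spec JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
import yaml

from .detect import DetectionResult, NMSParams
from .filters import FilterParams, ResponseMap, normalize_image
from .synth import SceneSpec, SyntheticScene

__all__ = [
    "RunConfig",
    "load_image",
    "save_response",
    "save_detections",
    "load_detections",
    "save_scenes",
    "load_truth_manifest",
]


def load_image(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Read a grayscale image and normalize it to [0, 1] float64."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {arr.shape[-1] if arr.shape[-1] < 5 else arr.shape[0]} "
                "channels; pass a channel index")
        arr = arr[..., channel] if arr.shape[-1] < arr.shape[0] else arr[channel]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return normalize_image(arr)


def save_response(resp: ResponseMap, path: str | Path) -> None:
    """Write a response map as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), resp.values.astype(np.float32))


def save_detections(result: DetectionResult, path: str | Path,
                    image_name: str = "", params: dict | None = None) -> None:
    """Write detections as CSV plus a JSON sidecar with run parameters."""
    path = Path(path)
    df = pd.DataFrame({
        "image": [image_name] * result.count,
        "row": result.centers[:, 0] if result.count else [],
        "col": result.centers[:, 1] if result.count else [],
        "score": result.scores,
        "border_flag": result.border_flags.astype(int),
    })
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {"image": image_name, "n_detections": result.count,
               "parameters": params or {}}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"image", "row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: detections CSV missing columns {sorted(missing)}")
    return df


def save_scenes(scenes: list[SyntheticScene], out_dir: str | Path,
                prefix: str = "scene") -> Path:
    """Write scenes as 16-bit TIFFs plus a truth manifest CSV + spec JSON.

    Returns the manifest path.  Manifest columns: image, cell_id, row,
    col, radius.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scene in enumerate(scenes):
        name = f"{prefix}_{i:03d}.tif"
        tifffile.imwrite(out / name,
                         np.round(scene.image * 65535).astype(np.uint16))
        for j, ((r, c), rad) in enumerate(zip(scene.true_centers,
                                              scene.true_radii)):
            rows.append({"image": name, "cell_id": j, "row": r, "col": c,
                         "radius": rad})
        spec_path = out / f"{prefix}_{i:03d}.spec.json"
        spec_path.write_text(json.dumps(dataclasses.asdict(scene.spec),
                                        indent=2, sort_keys=True))
    manifest = out / "truth_manifest.csv"
    pd.DataFrame(rows, columns=["image", "cell_id", "row", "col",
                                "radius"]).to_csv(manifest, index=False)
    return manifest


def load_truth_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"image", "row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: truth manifest missing columns {sorted(missing)}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Serializable run configuration; CLI flags override file values."""

    inputs: tuple[str, ...] = ()
    out_dir: str = "."
    filter_params: FilterParams = field(default_factory=FilterParams)
    nms_params: NMSParams = field(default_factory=NMSParams)
    smoothing_sigma: float = 1.0
    log_level: str = "INFO"
    seed: int = 42

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "out_dir": self.out_dir,
            "filter_params": dataclasses.asdict(self.filter_params),
            "nms_params": dataclasses.asdict(self.nms_params),
            "smoothing_sigma": self.smoothing_sigma,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            inputs=tuple(d.get("inputs", ())),
            out_dir=d.get("out_dir", "."),
            filter_params=FilterParams(**d.get("filter_params", {})),
            nms_params=NMSParams(**d.get("nms_params", {})),
            smoothing_sigma=d.get("smoothing_sigma", 1.0),
            log_level=d.get("log_level", "INFO"),
            seed=d.get("seed", 42),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
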