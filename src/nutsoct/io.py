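"""File formats and run configuration.

Stacks travel as multi-page TIFF (one page per frame) or ``.npy`` arrays,
always time-major, with a JSON sidecar carrying the acquisition metadata the
pixel data cannot: frame interval ``ts``, sampling method, compression ratio
``r`` and nominal frame count ``N``.  Motility maps are written as 32-bit
float TIFF so values round-trip exactly.  Tables are CSV with a commented
provenance header (run configuration and seed) that pandas skips on read.
Region masks are 8-bit label images (TIFF or PNG; 0 = background).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageStack, MotilityImage
from .schedules import Method, SamplingSchedule, full_schedule, make_schedule

logger = logging.getLogger("nutsoct")

DEFAULT_TS = 1.0


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run: acquisition, schedule, seed."""

    ts: float = DEFAULT_TS
    n_frames: int | None = None
    method: str = "full"
    r: int = 1
    seed: int = 0
    extra: dict = dataclasses.field(default_factory=dict)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(d.pop("extra"))
        return d


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a flat mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Load a time-major stack (multi-page TIFF or .npy) plus its sidecar.

    Missing sidecar or missing schedule metadata defaults to full sampling
    over the stored frame count, with a logged warning; a page count that
    contradicts the declared schedule is rejected.
    """
    path = Path(path)
    if path.suffix == ".npy":
        frames = np.load(path)
    else:
        frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a T x axial x lateral stack, got shape {frames.shape}")

    meta_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        logger.warning("%s: no sidecar %s; assuming full sampling, ts=%s s", path, meta_path, DEFAULT_TS)
        meta = {}

    ts = float(meta.get("ts", DEFAULT_TS))
    method = Method(meta.get("method", "full"))
    if method is Method.FULL and "method" not in meta:
        schedule = full_schedule(frames.shape[0])
    else:
        n = int(meta.get("N", frames.shape[0]))
        schedule = make_schedule(method, n, int(meta.get("r", 1)))
    if schedule.n_samples != frames.shape[0]:
        raise ValueError(
            f"{path}: {frames.shape[0]} pages but schedule "
            f"({method.value}, r={schedule.r}, N={schedule.n_frames}) "
            f"retains {schedule.n_samples} frames"
        )
    return ImageStack(frames, ts=ts, schedule=schedule)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as 32-bit float multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "ts": stack.ts,
        "method": stack.schedule.method.value,
        "r": stack.schedule.r,
        "N": stack.schedule.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit label mask (0 = background, k = region k)."""
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        mask = tifffile.imread(path)
    else:
        mask = iio.imread(path)
    mask = np.asarray(mask)
    if mask.ndim == 3:  # collapse a grayscale-as-RGB mask
        mask = mask[..., 0]
    return mask.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask, dtype=np.uint8)
    if path.suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask)
    else:
        iio.imwrite(path, mask)
    return path


def write_motility_image(image: MotilityImage, base: str | Path) -> dict[str, Path]:
    """Write M, mean-signal and clamp maps as TIFFs next to a common stem."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "M": base.with_name(base.name + "_M.tif"),
        "mean": base.with_name(base.name + "_mean.tif"),
        "clamp": base.with_name(base.name + "_clamp.tif"),
    }
    tifffile.imwrite(paths["M"], image.m.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(paths["mean"], image.mean_image.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(paths["clamp"], image.clamp_mask.astype(np.uint8), photometric="minisblack")
    return paths


def read_motility_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float32)


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a CSV with a ``#``-commented provenance header.

    Read back with ``read_table`` (or ``pandas.read_csv(..., comment='#')``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for key, val in (provenance or {}).items():
        rendered = json.dumps(val) if isinstance(val, (dict, list)) else str(val)
        lines.append(f"# {key}: {rendered}".replace("\n", " "))
    body = df.to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
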