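"""Shared containers and file I/O for the imaging pipeline.

Images travel as :class:`ImageStack` (axis order ``(time, channel, y, x)``),
manual annotations as :class:`RoiSet` (a JSON dialect standing in for ImageJ
ROI files), and run parameters as :class:`RunConfig` (YAML).  Coordinates are
0-based pixel indices, x rightward, y downward; ROI points are pixel centers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "Roi",
    "RoiSet",
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "read_roi_set",
    "write_roi_set",
    "read_config",
    "write_config",
]

DEFAULT_POLYLINE_WIDTH_PX = 2  # segmented lines are drawn two pixels wide


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as the expected format."""


@dataclass
class ImageStack:
    """N-dimensional pixel data with named channels.

    ``pixels`` is indexed ``(time, channel, y, x)``; missing axes are inserted
    with length one so every consumer can rely on a 4-D array.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be (time, channel, y, x); got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        n_ch = self.pixels.shape[1]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def channel(self, name: str, t: int = 0) -> np.ndarray:
        """Return the 2-D frame for a named channel at time ``t``."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.pixels[t, idx]


@dataclass
class Roi:
    kind: str  # "polyline" | "polygon"
    points: np.ndarray  # (n, 2) float, (x, y) pixel coordinates
    width_px: int = DEFAULT_POLYLINE_WIDTH_PX
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("polyline", "polygon"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y) pairs")
        if len(self.points) < 2:
            raise ValueError("an ROI needs at least 2 points")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


@dataclass
class RoiSet:
    image_id: str
    rois: list[Roi] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class RunConfig:
    """Per-stage parameters with the workflow's published defaults.

    The segmentation defaults (512-px tiles, 50% overlap, 0.5 threshold,
    2200 iterations with validation every 100th) mirror the original
    tile-based training recipe; everything else is a documented choice.
    """

    seed: int = 0
    # colocalization
    max_shift: int = 10
    min_cells: int = 6
    # photobleaching FRET
    min_bleach_depth: float = 0.8
    # DAmFRET gating
    n_expression_bins: int = 16
    control_quantile: float = 0.99
    min_events_per_bin: int = 20
    min_acceptor: float = 10.0
    # FRAP
    solid_like_threshold: float = 0.2
    # segmentation
    tile_window: int = 512
    tile_overlap: float = 0.5
    seg_threshold: float = 0.5
    max_iterations: int = 2200
    validate_every: int = 100
    model_depth: int = 3
    base_channels: int = 8
    learning_rate: float = 3e-4
    lr_decay: float = 0.999
    batch_size: int = 4
    # screen triage
    fail_threshold: int = 1

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# TIFF images


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page TIFF as an ImageStack.

    Grayscale pages are treated as channels; an explicit axes tag on the
    file (written by :func:`write_image_stack`) is honored.  RGB-encoded
    files are rejected: their sample axis cannot be told apart from a
    channel axis.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            axes = tif.series[0].axes
            desc = tif.pages[0].description
    except Exception as exc:  # noqa: BLE001 - normalize into FormatError
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc

    meta: dict[str, Any] = {}
    channel_names: list[str] | None = None
    pixel_size = 1.0
    if desc:
        try:
            parsed = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            parsed = None
        if isinstance(parsed, dict):
            channel_names = parsed.get("channel_names")
            pixel_size = float(parsed.get("pixel_size_um", 1.0))
            meta = parsed.get("meta", {})

    if "S" in axes or arr.ndim > 4:
        raise FormatError(
            f"ambiguous axis layout in {path}: axes {axes!r}, shape {arr.shape}"
        )
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if channel_names is not None and arr.shape[0] % len(channel_names) == 0:
            # pages are (time x channel) in C-order, per our own writer
            arr = arr.reshape(-1, len(channel_names), *arr.shape[1:])
        elif axes.startswith("T"):
            arr = arr[:, None]
        else:  # pages as channels
            arr = arr[None, :]
    # 4-D arrays are taken as (T, C, Y, X) already
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(arr.shape[1])]
    return ImageStack(arr, channel_names, pixel_size, meta)


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    desc = json.dumps(
        {
            "channel_names": stack.channel_names,
            "pixel_size_um": stack.pixel_size_um,
            "meta": stack.meta,
        }
    )
    tifffile.imwrite(
        Path(path), stack.pixels, metadata=None, description=desc, photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# ROI JSON


def read_roi_set(path: str | Path) -> RoiSet:
    """Read a RoiSet from its JSON interchange form.

    Polylines missing a ``width_px`` default to the two-pixel segmented-line
    width used for intensity profiles.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "image_id" not in doc or "rois" not in doc:
        raise FormatError(f"{path}: expected object with 'image_id' and 'rois'")
    rois = []
    for i, r in enumerate(doc["rois"]):
        for key in ("kind", "points"):
            if key not in r:
                raise FormatError(f"{path}: roi {i} missing field {key!r}")
        try:
            rois.append(
                Roi(
                    kind=r["kind"],
                    points=np.asarray(r["points"], dtype=float),
                    width_px=int(r.get("width_px", DEFAULT_POLYLINE_WIDTH_PX)),
                    label=str(r.get("label", "")),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: roi {i}: {exc}") from exc
    return RoiSet(image_id=str(doc["image_id"]), rois=rois)


def write_roi_set(path: str | Path, roiset: RoiSet) -> None:
    doc = {
        "image_id": roiset.image_id,
        "rois": [
            {
                "kind": r.kind,
                "points": np.asarray(r.points, dtype=float).tolist(),
                "width_px": int(r.width_px),
                "label": r.label,
            }
            for r in roiset.rois
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# YAML config


def read_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(doc)


def write_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
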