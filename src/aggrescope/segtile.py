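"""Tile-based segmentation workflow.

Annotated frames become (image, mask, outline) triplets: the mask channel is
true inside any ROI polygon and the outline channel is true on the 1-px
rasterized ROI boundaries.  Frames are reflect-padded and cut into
overlapping square tiles (512 px with 50% overlap at full scale), augmented
by seeded random rotations and translations, normalized by
``(intensity - MEAN)/STDEV + 0.5`` where MEAN/STDEV come from the nonzero
pixel intensities of the training set, and fed to the encoder-decoder
network in :mod:`aggrescope.nnet`.  Inference stitches per-tile probability
maps back into a full frame with center-priority de-windowing, and objects
are recovered by thresholding the mask probability at 0.5, optionally after
subtracting the outline probability to separate touching objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon, polygon_perimeter

from .io_core import ImageStack, RoiSet
from .nnet import ModelConfig, TrainSchedule, UNet

__all__ = [
    "SegSample",
    "TileGrid",
    "NormalizationParams",
    "TrainedModel",
    "encode_rois",
    "make_tiles",
    "augment",
    "estimate_normalization",
    "normalize",
    "denormalize",
    "train",
    "infer_and_stitch",
    "postprocess",
    "segmentation_scores",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SegSample:
    """One image with its binary mask and outline target channels."""

    image: np.ndarray
    mask: np.ndarray
    outline: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.outline = np.asarray(self.outline, dtype=bool)
        if not (self.image.shape == self.mask.shape == self.outline.shape):
            raise ValueError("image, mask, outline must share shape")


@dataclass
class TileGrid:
    window: tuple[int, int]
    stride: int
    offsets: list[tuple[int, int]]  # (y, x) origins in the padded frame
    pad: tuple[int, int]  # bottom, right reflect-pad widths
    source_shape: tuple[int, int]


@dataclass
class NormalizationParams:
    """Nonzero-pixel mean/stdev stored at training time, reused at inference."""

    mean: float
    stdev: float  # population (n-denominator) standard deviation
    offset: float = 0.5

    def to_dict(self) -> dict:
        return {"mean": self.mean, "stdev": self.stdev, "offset": self.offset}


# ---------------------------------------------------------------------------
# Targets from ROIs


def encode_rois(image: ImageStack | np.ndarray, rois: RoiSet) -> SegSample:
    """Full-frame (image, mask, outline) triplet from polygon annotations.

    The mask is the union of filled polygons (no double counting of
    overlaps); the outline channel paints only the 1-px polygon boundaries.
    """
    frame = (
        image.pixels[0, 0] if isinstance(image, ImageStack) else np.asarray(image)
    ).astype(float)
    mask = np.zeros(frame.shape, dtype=bool)
    outline = np.zeros(frame.shape, dtype=bool)
    for roi in rois:
        if roi.kind != "polygon":
            continue
        rr, cc = _sk_polygon(roi.points[:, 1], roi.points[:, 0], shape=frame.shape)
        mask[rr, cc] = True
        rr, cc = polygon_perimeter(
            roi.points[:, 1], roi.points[:, 0], shape=frame.shape
        )
        # drop duplicate corner pixels so outline length matches the boundary
        uniq = np.unique(np.column_stack([rr, cc]), axis=0)
        outline[uniq[:, 0], uniq[:, 1]] = True
        mask[uniq[:, 0], uniq[:, 1]] = True  # fill semantics: boundary belongs to the object
    return SegSample(image=frame, mask=mask, outline=outline)


# ---------------------------------------------------------------------------
# Tiling


def _grid_1d(size: int, window: int, stride: int) -> tuple[int, list[int]]:
    """Padded size and tile origins along one axis."""
    if size <= window:
        return window, [0]
    n = int(np.ceil((size - window) / stride)) + 1
    padded = (n - 1) * stride + window
    return padded, [i * stride for i in range(n)]


def make_tiles(
    sample: SegSample, window: int = 512, stride: int | None = None
) -> tuple[TileGrid, list[SegSample]]:
    """Cut a frame into overlapping square tiles (50% overlap by default).

    The frame is reflect-padded on the bottom/right so offsets at stride
    multiples cover it exactly; image, mask, and outline are cut congruently.
    """
    if window < 32:
        raise ValueError("window must be >= 32")
    stride = stride or window // 2
    if stride > window:
        raise ValueError("stride must be <= window")
    h, w = sample.image.shape
    ph, oys = _grid_1d(h, window, stride)
    pw, oxs = _grid_1d(w, window, stride)
    pad = (ph - h, pw - w)

    def _pad(a: np.ndarray) -> np.ndarray:
        return np.pad(a, ((0, pad[0]), (0, pad[1])), mode="reflect")

    img, msk, out = _pad(sample.image), _pad(sample.mask), _pad(sample.outline)
    offsets = [(oy, ox) for oy in oys for ox in oxs]
    tiles = [
        SegSample(
            image=img[oy : oy + window, ox : ox + window],
            mask=msk[oy : oy + window, ox : ox + window],
            outline=out[oy : oy + window, ox : ox + window],
        )
        for oy, ox in offsets
    ]
    grid = TileGrid(
        window=(window, window),
        stride=stride,
        offsets=offsets,
        pad=pad,
        source_shape=(h, w),
    )
    return grid, tiles


def augment(
    tiles: list[SegSample], n_out: int, seed: int, max_shift: float | None = None
) -> list[SegSample]:
    """Seeded random rotations and translations of training tiles.

    Each output applies one uniform-angle rotation plus a translation of at
    most half a tile-stride to a randomly chosen source tile; the identical
    transform is applied to image, mask, and outline, with reflection fill.
    """
    if n_out == 0 or not tiles:
        return []
    rng = np.random.default_rng(seed)
    window = tiles[0].image.shape[0]
    if max_shift is None:
        max_shift = window / 4.0
    out = []
    for _ in range(n_out):
        src = tiles[rng.integers(len(tiles))]
        angle = float(rng.uniform(0.0, 360.0))
        shift = rng.uniform(-max_shift, max_shift, size=2)

        def _xform(a: np.ndarray, order: int) -> np.ndarray:
            b = ndimage.rotate(
                a.astype(float), angle, reshape=False, order=order, mode="reflect"
            )
            return ndimage.shift(b, shift, order=order, mode="reflect")

        out.append(
            SegSample(
                image=_xform(src.image, 1),
                mask=_xform(src.mask, 0) > 0.5,
                outline=_xform(src.outline, 0) > 0.5,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normalization


def estimate_normalization(pixels: np.ndarray | list[np.ndarray]) -> NormalizationParams:
    """MEAN and STDEV of the nonzero pixel intensities of a training set."""
    if isinstance(pixels, list):
        pixels = np.concatenate([np.asarray(p, dtype=float).ravel() for p in pixels])
    else:
        pixels = np.asarray(pixels, dtype=float).ravel()
    nz = pixels[pixels != 0]
    if nz.size == 0:
        raise ValueError("cannot estimate normalization from an all-zero image")
    stdev = float(nz.std())  # population sd
    if stdev == 0:
        raise ValueError("nonzero pixels have zero spread")
    return NormalizationParams(mean=float(nz.mean()), stdev=stdev)


def normalize(pixels: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """(intensity - MEAN)/STDEV + offset, applied to every pixel."""
    if params.stdev <= 0:
        raise ValueError("stdev must be > 0")
    return (np.asarray(pixels, dtype=float) - params.mean) / params.stdev + params.offset


def denormalize(pixels: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return (np.asarray(pixels, dtype=float) - params.offset) * params.stdev + params.mean


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedModel:
    net: UNet
    params: NormalizationParams
    model_cfg: ModelConfig
    log: pd.DataFrame = field(repr=False, default=None)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_arrays())
        sidecar = {
            "model_cfg": self.model_cfg.to_dict(),
            "normalization": self.params.to_dict(),
        }
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            doc = json.load(fh)
        cfg = ModelConfig(**doc["model_cfg"])
        net = UNet(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_arrays(dict(data))
        return cls(net=net, params=NormalizationParams(**doc["normalization"]),
                   model_cfg=cfg, log=None)


def _select_init(
    train_tiles: list[SegSample],
    schedule: TrainSchedule,
    model_cfg: ModelConfig,
    params: NormalizationParams,
    rng: np.random.Generator,
) -> UNet:
    """Probe candidate weight initializations and return a live one, fresh.

    The tanh output can saturate irrecoverably early in training (the net
    then predicts background everywhere and its gradients vanish), and
    whether that happens depends on the initial weights.  Each candidate is
    trained for a short probe; the first whose probe loss clearly beats the
    best constant predictor is re-instantiated untouched and returned.
    Deterministic given ``rng``.
    """
    probe_idx = np.arange(min(len(train_tiles), 8))
    px, py = _batch(train_tiles, probe_idx, params)
    py_soft = py * (1 - 2 * UNet.TARGET_EPS) + UNet.TARGET_EPS
    baseline = float(np.mean((py_soft - py_soft.mean()) ** 2))
    seeds = [int(rng.integers(2**31)) for _ in range(max(schedule.init_candidates, 1))]
    if schedule.probe_iterations <= 0 or baseline == 0.0:
        return UNet(model_cfg, seed=seeds[0])
    best_seed, best_loss = seeds[0], np.inf
    for seed in seeds:
        net = UNet(model_cfg, seed=seed)
        probe_rng = np.random.default_rng(seed ^ 0x5EED)
        for it in range(1, schedule.probe_iterations + 1):
            idx = probe_rng.integers(len(train_tiles), size=schedule.batch_size)
            x, y = _batch(train_tiles, idx, params)
            net.loss_and_backward(net.forward(x), y)
            net.adam_step(schedule.lr_at(it))
        loss = net.loss(net.forward(px), py_soft)
        if loss < best_loss:
            best_seed, best_loss = seed, loss
        if loss < 0.85 * baseline:
            break
    return UNet(model_cfg, seed=best_seed)


def _batch(tiles: list[SegSample], idx: np.ndarray, params: NormalizationParams):
    x = np.stack([normalize(tiles[i].image, params) for i in idx])[:, None]
    y = np.stack(
        [np.stack([tiles[i].mask, tiles[i].outline]).astype(float) for i in idx]
    )
    return x, y


def train(
    train_tiles: list[SegSample],
    val_tiles: list[SegSample],
    schedule: TrainSchedule | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    init_from: TrainedModel | None = None,
) -> TrainedModel:
    """Train the encoder-decoder on (mask, outline) targets.

    Runs exactly ``schedule.max_iterations`` Adam steps on seeded random
    mini-batches; validation loss over all validation tiles is logged at
    every iteration divisible by ``schedule.validate_every``.  Training
    aborts if the loss goes non-finite.  ``init_from`` warm-starts from an
    earlier checkpoint (retraining keeps the stored normalization).
    """
    if not train_tiles or not val_tiles:
        raise ValueError("need at least one training and one validation tile")
    schedule = schedule or TrainSchedule()
    model_cfg = model_cfg or ModelConfig()
    rng = np.random.default_rng(seed)

    if init_from is not None:
        params = init_from.params
        net = UNet(model_cfg, seed=int(rng.integers(2**31)))
        net.load_state_arrays(init_from.net.state_arrays())
    else:
        params = estimate_normalization([t.image for t in train_tiles])
        net = _select_init(train_tiles, schedule, model_cfg, params, rng)

    log_rows = []
    for it in range(1, schedule.max_iterations + 1):
        idx = rng.integers(len(train_tiles), size=schedule.batch_size)
        x, y = _batch(train_tiles, idx, params)
        prob = net.forward(x)
        loss = net.loss_and_backward(prob, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training loss non-finite at iteration {it}")
        net.adam_step(schedule.lr_at(it))
        if it % schedule.validate_every == 0:
            vx, vy = _batch(val_tiles, np.arange(len(val_tiles)), params)
            val_loss = net.loss(net.forward(vx), vy)
            log_rows.append(
                {"iteration": it, "train_loss": loss, "val_loss": val_loss}
            )
    log = pd.DataFrame(log_rows, columns=["iteration", "train_loss", "val_loss"])
    return TrainedModel(net=net, params=params, model_cfg=model_cfg, log=log)


# ---------------------------------------------------------------------------
# Inference


def infer_and_stitch(
    image: np.ndarray | ImageStack,
    model: TrainedModel,
    window: int = 512,
    stride: int | None = None,
    border: int = 0,
    average_overlaps: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile a frame, run the model, and de-window back to full size.

    By default each pixel takes its value from the tile in which it lies
    farthest from a tile border (center-priority de-windowing);
    ``average_overlaps`` averages contributing tiles instead.  The outer
    ``border`` pixels of the frame are blanked to 0.  Returns the (mask,
    outline) probability maps.
    """
    frame = (
        image.pixels[0, 0] if isinstance(image, ImageStack) else np.asarray(image)
    ).astype(float)
    sample = SegSample(
        image=frame,
        mask=np.zeros_like(frame, dtype=bool),
        outline=np.zeros_like(frame, dtype=bool),
    )
    grid, tiles = make_tiles(sample, window=window, stride=stride)
    ph = grid.source_shape[0] + grid.pad[0]
    pw = grid.source_shape[1] + grid.pad[1]

    yy, xx = np.mgrid[0:window, 0:window]
    center_score = np.minimum.reduce(
        [yy, xx, window - 1 - yy, window - 1 - xx]
    ).astype(float)

    out = np.zeros((2, ph, pw))
    if average_overlaps:
        weight = np.zeros((ph, pw))
    else:
        best = np.full((ph, pw), -1.0)

    for (oy, ox), tile in zip(grid.offsets, tiles):
        x = normalize(tile.image, model.params)[None, None]
        prob = model.net.forward(x)[0]  # (2, window, window)
        sl = (slice(oy, oy + window), slice(ox, ox + window))
        if average_overlaps:
            out[:, sl[0], sl[1]] += prob
            weight[sl] += 1.0
        else:
            take = center_score > best[sl]
            out[:, sl[0], sl[1]] = np.where(take, prob, out[:, sl[0], sl[1]])
            best[sl] = np.maximum(best[sl], center_score)
    if average_overlaps:
        out /= weight

    h, w = grid.source_shape
    mask_prob, outline_prob = out[0, :h, :w], out[1, :h, :w]
    if border > 0:
        for arr in (mask_prob, outline_prob):
            arr[:border] = 0
            arr[-border:] = 0
            arr[:, :border] = 0
            arr[:, -border:] = 0
    return mask_prob, outline_prob


def postprocess(
    mask_prob: np.ndarray,
    outline_prob: np.ndarray | None = None,
    threshold: float = 0.5,
    subtract_outline: bool = False,
) -> tuple[np.ndarray, int]:
    """Threshold probability maps into labeled objects.

    ``binary = (mask_prob - outline_prob if subtracting) > threshold``,
    then 8-connected components.  Outline subtraction separates touching
    objects at the cost of eroding their shared boundary.
    """
    score = np.asarray(mask_prob, dtype=float)
    if subtract_outline:
        if outline_prob is None:
            raise ValueError("outline probability required for subtraction")
        score = score - np.asarray(outline_prob, dtype=float)
    binary = score > threshold
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    return labels, int(n)


# ---------------------------------------------------------------------------
# Scores for synthetic benchmarks


def segmentation_scores(
    labels_pred: np.ndarray, labels_true: np.ndarray, match_iou: float = 0.5
) -> dict:
    """Pixel IoU of the foreground and object-level precision/recall/F1.

    Predicted and true objects match when their pairwise IoU exceeds
    ``match_iou``; each object may match at most once (greedy by IoU).
    """
    pred_fg = labels_pred > 0
    true_fg = labels_true > 0
    union = np.logical_or(pred_fg, true_fg).sum()
    iou = float(np.logical_and(pred_fg, true_fg).sum() / union) if union else 1.0

    n_pred = int(labels_pred.max())
    n_true = int(labels_true.max())
    pairs = []
    for i in range(1, n_pred + 1):
        pi = labels_pred == i
        overlapping = np.unique(labels_true[pi])
        for j in overlapping[overlapping > 0]:
            tj = labels_true == j
            pair_iou = np.logical_and(pi, tj).sum() / np.logical_or(pi, tj).sum()
            if pair_iou > match_iou:
                pairs.append((pair_iou, i, int(j)))
    pairs.sort(reverse=True)
    used_p, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "pixel_iou": iou,
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "n_pred": n_pred,
        "n_true": n_true,
    }
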