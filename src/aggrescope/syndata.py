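"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes — two-channel cells with controllable colocalization,
donor/acceptor pairs before and after acceptor photobleaching, half-bleach
recovery time series, Gaussian nuclei, serial-section organelle labels,
per-event DAmFRET tables, and deletion-screen growth tables with planted
hits — and records every planted parameter so downstream estimators can be
scored against ground truth.

All generators are deterministic given their seed.  The detector noise
model is Poisson shot noise (with a gain) plus additive Gaussian read
noise, applied after the noise-free signal is composed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .frap import FRAPTrace
from .io_core import ImageStack, Roi, RoiSet

__all__ = [
    "NoiseModel",
    "CellSpec",
    "GroundTruth",
    "simulate_coloc_cells",
    "simulate_bleach_pairs",
    "simulate_frap_series",
    "simulate_nuclei",
    "simulate_em_sections",
    "simulate_damfret_events",
    "simulate_screen_table",
    "simulate_blob_fields",
]

EM_CLASS_CODES = {"vesicle": 1, "lipid_droplet": 2, "mitochondrion": 3}


class GenerationError(RuntimeError):
    """A geometric constraint (e.g. puncta inside the cell) cannot be met."""


@dataclass
class NoiseModel:
    """Poisson-Gaussian detector model: gain * Poisson(S/gain) + N(0, sd).

    ``gain = 0`` disables shot noise; ``read_noise_sd = 0`` disables read
    noise (so ``NO_NOISE`` passes the signal through unchanged).
    """

    gain: float = 1.0
    read_noise_sd: float = 2.0

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = np.clip(np.asarray(signal, dtype=float), 0, None)
        out = self.gain * rng.poisson(s / self.gain) if self.gain > 0 else s.copy()
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=s.shape)
        return out


NO_NOISE = NoiseModel(gain=0.0, read_noise_sd=0.0)


def _apply_noise(signal, noise: NoiseModel | None, rng) -> np.ndarray:
    if noise is None:
        return np.asarray(signal, dtype=float)
    return noise.apply(signal, rng)


@dataclass
class CellSpec:
    """Geometry and optics of one synthetic two-channel cell."""

    image_size: int = 128
    axes_px: tuple[float, float] = (45.0, 35.0)  # ellipse semi-axes
    aggregate_mode: str = "dispersed"  # dispersed | single_inclusion | intravacuolar
    n_puncta: int = 12
    punctum_sigma_px: float = 2.5
    amplitudes: tuple[float, float] = (200.0, 200.0)
    coloc_fraction: float = 0.5  # rho: fraction of ch2 signal co-placed with ch1
    background: float = 20.0
    noise: NoiseModel | None = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if min(self.amplitudes) < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters, one record per generated artifact."""

    params: dict[str, Any] = field(default_factory=dict)
    records: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        doc = {
            "params": {k: _clean(v) for k, v in self.params.items()},
            "records": [
                {k: _clean(v) for k, v in rec.items()} for rec in self.records
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Colocalization cells


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _random_point_in_mask(mask: np.ndarray, rng, margin: float = 0.0,
                          max_tries: int = 2000) -> tuple[float, float]:
    size = mask.shape[0]
    for _ in range(max_tries):
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, size - margin)
        if mask[int(y), int(x)]:
            return x, y
    raise GenerationError("could not place a point inside the cell outline")


def _add_punctum(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def _random_walk_roi(mask: np.ndarray, rng, n_segments: int, step: float,
                     label: str) -> Roi:
    """Seeded self-avoiding walk inside the cell mask.

    Mimics a hand-drawn segmented line that randomly covers as much of the
    spore as possible: 5-10 segments, each step rejected if it leaves the
    mask or doubles back onto an earlier vertex.
    """
    start = _random_point_in_mask(mask, rng, margin=2)
    pts = [start]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n_segments):
        placed = False
        for _ in range(200):
            turn = rng.uniform(-np.pi / 2, np.pi / 2)
            cand_heading = heading + turn
            x = pts[-1][0] + step * np.cos(cand_heading)
            y = pts[-1][1] + step * np.sin(cand_heading)
            if not (0 <= int(y) < mask.shape[0] and 0 <= int(x) < mask.shape[1]):
                continue
            if not mask[int(y), int(x)]:
                continue
            if any(np.hypot(x - px, y - py) < step * 0.5 for px, py in pts[:-1]):
                continue  # self-avoidance
            pts.append((x, y))
            heading = cand_heading
            placed = True
            break
        if not placed:
            heading += np.pi  # dead end: turn around
    if len(pts) < 2:
        raise GenerationError("random-walk ROI collapsed to a point")
    return Roi(kind="polyline", points=np.array(pts), width_px=2, label=label)


def simulate_coloc_cells(
    n_cells: int, spec: CellSpec | None = None, seed: int = 0
) -> tuple[list[ImageStack], list[RoiSet], GroundTruth]:
    """Two-channel cells with a planted colocalization fraction.

    Channel-1 puncta are placed inside the cell; a fraction ``rho`` of
    channel-2 puncta are co-placed on channel-1 positions and the rest are
    placed away from them.  Each cell carries one segmented-line ROI from a
    seeded self-avoiding walk through the cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec = spec or CellSpec()
    rng = np.random.default_rng(seed)
    rho = spec.coloc_fraction
    size = spec.image_size
    images, roisets, records = [], [], []
    for ci in range(n_cells):
        cx = size / 2 + rng.uniform(-5, 5)
        cy = size / 2 + rng.uniform(-5, 5)
        mask = _ellipse_mask(size, cx, cy, *spec.axes_px)
        ch1 = np.zeros((size, size))
        ch2 = np.zeros((size, size))

        if spec.aggregate_mode == "dispersed":
            n_p = spec.n_puncta
            sigma = spec.punctum_sigma_px
        else:  # single perivacuolar/intravacuolar inclusion
            n_p = 1
            sigma = spec.punctum_sigma_px * 3.5

        ch1_pos = [_random_point_in_mask(mask, rng, margin=2) for _ in range(n_p)]
        for x, y in ch1_pos:
            _add_punctum(ch1, x, y, spec.amplitudes[0], sigma)

        n_coloc = int(round(rho * n_p))
        coloc_idx = rng.choice(n_p, size=n_coloc, replace=False)
        for i in coloc_idx:
            x, y = ch1_pos[i]
            _add_punctum(ch2, x, y, spec.amplitudes[1], sigma)
        min_sep = 4 * sigma
        for _ in range(n_p - n_coloc):
            for _ in range(500):
                x, y = _random_point_in_mask(mask, rng, margin=2)
                if all(np.hypot(x - px, y - py) >= min_sep for px, py in ch1_pos):
                    break
            else:
                raise GenerationError(
                    "could not place a non-colocalized punctum away from channel-1"
                )
            _add_punctum(ch2, x, y, spec.amplitudes[1], sigma)

        ch1 = np.where(mask, ch1 + spec.background, 0.0)
        ch2 = np.where(mask, ch2 + spec.background, 0.0)
        ch1 = _apply_noise(ch1, spec.noise, rng)
        ch2 = _apply_noise(ch2, spec.noise, rng)

        stack = ImageStack(
            np.stack([ch1, ch2])[None],
            channel_names=["ch1", "ch2"],
            meta={"cell": ci},
        )
        n_segments = int(rng.integers(5, 11))
        roi = _random_walk_roi(mask, rng, n_segments, step=14.0, label=f"cell{ci}")
        images.append(stack)
        roisets.append(RoiSet(image_id=f"cell{ci}", rois=[roi]))
        records.append({"cell": ci, "rho": rho, "n_puncta": n_p})
    gt = GroundTruth(params={"rho": rho, "seed": seed, "n_cells": n_cells},
                     records=records)
    return images, roisets, gt


# ---------------------------------------------------------------------------
# Acceptor-photobleaching FRET pairs


def simulate_bleach_pairs(
    n_cells: int,
    e_true: float,
    bleach_efficiency: float = 0.95,
    noise: NoiseModel | None = None,
    seed: int = 0,
    donor_total: float = 1000.0,
    acceptor_total: float = 800.0,
    background: float = 20.0,
    image_size: int = 64,
) -> tuple[list[tuple[ImageStack, ImageStack]], list[RoiSet], GroundTruth]:
    """Paired pre/post acceptor-photobleaching images with a set efficiency.

    Quenching model: the donor emits ``D0*(1 - E)`` before the bleach and
    ``D0*(1 - E*(1 - b))`` after a bleach of efficiency ``b``; the acceptor
    is reduced to ``(1 - b)`` of its pre level.  Noise is applied last.
    Returns (pre, post) stacks with donor/acceptor channels, one circular
    cell ROI per pair, and the planted ground truth.
    """
    if not 0.0 <= e_true < 1.0:
        raise ValueError("e_true must lie in [0, 1)")
    if not 0.0 < bleach_efficiency <= 1.0:
        raise ValueError("bleach_efficiency must lie in (0, 1]")
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    size = image_size
    radius = size * 0.3
    pairs, roisets, records = [], [], []
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    for ci in range(n_cells):
        cx = size / 2 + rng.uniform(-2, 2)
        cy = size / 2 + rng.uniform(-2, 2)
        mask = _ellipse_mask(size, cx, cy, radius, radius)
        d_pre = donor_total * (1.0 - e_true)
        d_post = donor_total * (1.0 - e_true * (1.0 - bleach_efficiency))
        a_pre = acceptor_total
        a_post = acceptor_total * (1.0 - bleach_efficiency)

        def _frame(level: float) -> np.ndarray:
            return np.where(mask, level + background, background)

        pre = np.stack([_frame(d_pre), _frame(a_pre)])
        post = np.stack([_frame(d_post), _frame(a_post)])
        pre = _apply_noise(pre, noise, rng)
        post = _apply_noise(post, noise, rng)
        names = ["donor", "acceptor"]
        pairs.append(
            (
                ImageStack(pre[None], channel_names=names, meta={"cell": ci}),
                ImageStack(post[None], channel_names=names, meta={"cell": ci}),
            )
        )
        r_roi = radius - 1.0
        pts = np.column_stack([cx + r_roi * np.cos(theta), cy + r_roi * np.sin(theta)])
        roisets.append(
            RoiSet(
                image_id=f"cell{ci}",
                rois=[Roi(kind="polygon", points=pts, label=f"cell{ci}")],
            )
        )
        records.append(
            {
                "cell": ci,
                "e_true": e_true,
                "bleach_efficiency": bleach_efficiency,
                "expected_apparent_e": (d_post - d_pre) / d_post,
            }
        )
    gt = GroundTruth(
        params={
            "e_true": e_true,
            "bleach_efficiency": bleach_efficiency,
            "seed": seed,
            "n_cells": n_cells,
        },
        records=records,
    )
    return pairs, roisets, gt


# ---------------------------------------------------------------------------
# FRAP traces


def simulate_frap_series(
    n: int,
    m_true: float,
    k: float = 0.05,
    frames: int = 180,
    dt: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    bleach_floor: float = 0.3,
    acq_bleach_rate: float = 0.0,
    pre_intensity: float = 1.0,
) -> tuple[list[FRAPTrace], GroundTruth]:
    """Half-bleach recovery traces with a planted mobile fraction.

    The bleached half follows ``I(t) = I_b + m (I_pre - I_b)(1 - e^{-kt})``;
    both halves additionally decay by the acquisition-bleaching factor
    ``exp(-acq_bleach_rate * t)`` (a free parameter of the generator) and
    carry additive Gaussian noise.  Defaults emulate one recovery frame per
    second for three minutes.
    """
    if not 0.0 <= m_true <= 1.0:
        raise ValueError("m_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(frames) * dt
    decay = np.exp(-acq_bleach_rate * t)
    i_bleach = bleach_floor * pre_intensity
    traces, records = [], []
    for i in range(n):
        ideal = i_bleach + m_true * (pre_intensity - i_bleach) * (1 - np.exp(-k * t))
        bleached = ideal * decay + rng.normal(0, noise_sd * pre_intensity, frames)
        reference = pre_intensity * decay + rng.normal(
            0, noise_sd * pre_intensity, frames
        )
        traces.append(
            FRAPTrace(
                t=t,
                bleached=np.clip(bleached, 0, None),
                reference=np.clip(reference, 1e-6, None),
                pre=pre_intensity,
                label=f"trace{i}",
            )
        )
        records.append({"trace": i, "m_true": m_true, "k_true": k})
    gt = GroundTruth(
        params={
            "m_true": m_true,
            "k_true": k,
            "frames": frames,
            "dt": dt,
            "acq_bleach_rate": acq_bleach_rate,
            "seed": seed,
        },
        records=records,
    )
    return traces, gt


# ---------------------------------------------------------------------------
# Nuclei


def simulate_nuclei(
    n_per_group: int,
    sigmas: list[float],
    seed: int = 0,
    amplitude: float = 300.0,
    offset: float = 30.0,
    window: int = 64,
    noise: NoiseModel | None = None,
) -> tuple[list[ImageStack], GroundTruth]:
    """Isotropic 2-D Gaussian nuclei, one group per planted width."""
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:window, 0:window]
    images, records = [], []
    for gi, sigma in enumerate(sigmas):
        for ni in range(n_per_group):
            x0 = window / 2 + rng.uniform(-2, 2)
            y0 = window / 2 + rng.uniform(-2, 2)
            frame = amplitude * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
            ) + offset
            frame = _apply_noise(frame, noise, rng)
            images.append(
                ImageStack(
                    frame[None, None],
                    channel_names=["rfp"],
                    meta={"group": gi, "nucleus": ni},
                )
            )
            records.append(
                {"group": gi, "nucleus": ni, "sigma_true": sigma,
                 "amplitude": amplitude, "center": (x0, y0)}
            )
    gt = GroundTruth(
        params={"sigmas": list(sigmas), "n_per_group": n_per_group, "seed": seed},
        records=records,
    )
    return images, gt


# ---------------------------------------------------------------------------
# Serial-section organelle labels


def rasterize_ball(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius_px: float,
    z_scale: float,
) -> np.ndarray:
    """Boolean mask of an anisotropic-voxel ball.

    A voxel (z, y, x) belongs to the ball when
    ``((z - cz) * z_scale)^2 + (y - cy)^2 + (x - cx)^2 <= radius_px^2``,
    with ``z_scale = dz / dxy`` expressing the section thickness in pixel
    units.
    """
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    cz, cy, cx = center
    return ((zz - cz) * z_scale) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def simulate_em_sections(
    n_cells: int,
    objects_per_cell: dict[str, float],
    section_count: int = 9,
    seed: int = 0,
    cell_size: int = 64,
    voxel_um: tuple[float, float, float] = (0.01, 0.01, 0.06),
    radii_px: dict[str, float] | None = None,
) -> tuple[ImageStack, RoiSet, GroundTruth]:
    """Serial-section label images of cells with countable organelles.

    Cells are ellipses on a grid in one frame; per cell, each organelle
    class gets a Poisson-distributed number of non-overlapping balls whose
    class code is painted into a single-channel label stack (sections on
    the time axis).  Planted counts and voxel volumes are recorded.
    """
    for cls_name in objects_per_cell:
        if cls_name not in EM_CLASS_CODES:
            raise ValueError(f"unknown object class {cls_name!r}")
    radii_px = radii_px or {"vesicle": 3.0, "lipid_droplet": 4.0, "mitochondrion": 5.0}
    rng = np.random.default_rng(seed)
    grid_n = int(np.ceil(np.sqrt(n_cells)))
    fh = fw = grid_n * cell_size
    labels = np.zeros((section_count, fh, fw), dtype=np.int16)
    dz_scale = voxel_um[2] / voxel_um[0]
    rois, records = [], []
    theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    occupied = np.zeros_like(labels, dtype=bool)
    for ci in range(n_cells):
        gy, gx = divmod(ci, grid_n)
        cx = gx * cell_size + cell_size / 2
        cy = gy * cell_size + cell_size / 2
        a = b = cell_size * 0.42
        pts = np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])
        rois.append(Roi(kind="polygon", points=pts, label=f"cell{ci}"))
        for cls_name, mean_count in objects_per_cell.items():
            code = EM_CLASS_CODES[cls_name]
            r = radii_px[cls_name]
            count = int(rng.poisson(mean_count))
            placed = 0
            for _ in range(count):
                for _ in range(300):
                    ox = rng.uniform(cx - a + r + 1, cx + a - r - 1)
                    oy = rng.uniform(cy - b + r + 1, cy + b - r - 1)
                    oz = rng.uniform(r / dz_scale, section_count - 1 - r / dz_scale)
                    ball = rasterize_ball(
                        labels.shape, (oz, oy, ox), r, dz_scale
                    )
                    if not (ball & occupied).any() and ball.any():
                        labels[ball] = code
                        occupied |= ball
                        placed += 1
                        records.append(
                            {
                                "cell": f"cell{ci}",
                                "class": cls_name,
                                "center_zyx": (oz, oy, ox),
                                "radius_px": r,
                                "voxels": int(ball.sum()),
                            }
                        )
                        break
                else:
                    raise GenerationError(
                        f"could not place a {cls_name} inside cell {ci}"
                    )
    stack = ImageStack(
        labels[:, None, :, :].astype(float),
        channel_names=["labels"],
        meta={"sections": section_count, "voxel_um": list(voxel_um)},
    )
    gt = GroundTruth(
        params={
            "n_cells": n_cells,
            "objects_per_cell": dict(objects_per_cell),
            "voxel_um": list(voxel_um),
            "seed": seed,
        },
        records=records,
    )
    return stack, RoiSet(image_id="em", rois=rois), gt


# ---------------------------------------------------------------------------
# DAmFRET event tables


def simulate_damfret_events(
    n_events: int,
    model: str = "always_assembled",
    seed: int = 0,
    cutpoint: float = 10**3.5,
    expression_range: tuple[float, float] = (1e2, 1e5),
    converted_fraction: float = 0.3,
    amfret_assembled: float = 0.30,
    amfret_assembled_sd: float = 0.05,
    amfret_monomer_sd: float = 0.02,
    n_control: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-event donor/acceptor/FRET tables over an expression range.

    Expression (donor + acceptor) is drawn log-uniformly; the acceptor is
    the photoconverted fraction of the total.  Events are monomeric
    (AmFRET scattered around zero like the fluorophore-only control) or
    assembled (AmFRET elevated) according to ``model``:

    - ``monomer_only``: every event monomeric;
    - ``always_assembled``: every event assembled, at every expression;
    - ``assembly_above_threshold``: assembled iff expression > ``cutpoint``.

    A fluorophore-only control table is always generated alongside.
    """
    if model not in ("monomer_only", "always_assembled", "assembly_above_threshold"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    n_control = n_control or n_events

    def _table(n: int, assembled_mask: np.ndarray) -> pd.DataFrame:
        lo, hi = np.log(expression_range[0]), np.log(expression_range[1])
        total = np.exp(rng.uniform(lo, hi, size=n))
        phi = np.clip(
            rng.normal(converted_fraction, 0.03, size=n), 0.05, 0.95
        )
        acceptor = total * phi
        donor = total * (1 - phi)
        amfret = rng.normal(0.0, amfret_monomer_sd, size=n)
        amfret[assembled_mask] = rng.normal(
            amfret_assembled, amfret_assembled_sd, size=int(assembled_mask.sum())
        )
        fret = acceptor * amfret
        return pd.DataFrame({"donor": donor, "acceptor": acceptor, "fret": fret})

    # sample
    lo, hi = np.log(expression_range[0]), np.log(expression_range[1])
    if model == "monomer_only":
        assembled = np.zeros(n_events, dtype=bool)
    elif model == "always_assembled":
        assembled = np.ones(n_events, dtype=bool)
    else:
        assembled = np.zeros(n_events, dtype=bool)  # filled below per event
    sample = _table(n_events, assembled)
    if model == "assembly_above_threshold":
        expr = sample["donor"] + sample["acceptor"]
        assembled = (expr > cutpoint).to_numpy()
        amfret = rng.normal(0.0, amfret_monomer_sd, size=n_events)
        amfret[assembled] = rng.normal(
            amfret_assembled, amfret_assembled_sd, size=int(assembled.sum())
        )
        sample["fret"] = sample["acceptor"] * amfret
    control = _table(n_control, np.zeros(n_control, dtype=bool))
    gt = GroundTruth(
        params={
            "model": model,
            "cutpoint": cutpoint if model == "assembly_above_threshold" else None,
            "n_events": n_events,
            "seed": seed,
        },
        records=[{"event": i, "assembled": bool(a)} for i, a in enumerate(assembled)],
    )
    return sample, control, gt


# ---------------------------------------------------------------------------
# Screen tables


def simulate_screen_table(
    n_strains: int,
    hit_fraction: float | None = None,
    galactose_sick_fraction: float = 0.03,
    seed: int = 0,
    n_hits: int | None = None,
    phenotype_fractions: dict[str, float] | None = None,
    score_noise: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Deletion-screen growth scores with planted hits.

    Growth is ordinal 0-4 over {toxin plasmids, empty vectors} x
    {inducing, non-inducing}.  Planted true hits fail only with the toxin
    plasmids on inducing media; planted galactose-sick strains fail on
    inducing media with empty vectors too (and are excluded at stage 2).
    Hits also receive imaging-feature columns whose planted phenotype
    categories follow ``phenotype_fractions``.  ``score_noise`` flips a
    healthy score to a random ordinal with that probability.
    """
    if (hit_fraction is None) == (n_hits is None):
        raise ValueError("give exactly one of hit_fraction or n_hits")
    n_hits = n_hits if n_hits is not None else int(round(hit_fraction * n_strains))
    phenotype_fractions = phenotype_fractions or {
        "dispersed_both": 81 / 106,
        "antidote_normal_poison_dispersed": 5 / 106,
        "low_signal": 20 / 106,
    }
    rng = np.random.default_rng(seed)
    n_sick = int(round(galactose_sick_fraction * n_strains))
    roles = np.array(["normal"] * n_strains, dtype=object)
    order = rng.permutation(n_strains)
    roles[order[:n_hits]] = "hit"
    roles[order[n_hits : n_hits + n_sick]] = "galactose_sick"

    def _healthy() -> int:
        return int(rng.integers(3, 5))

    def _failed() -> int:
        return int(rng.integers(0, 2))

    # assign planted phenotypes to hits
    phen_names = list(phenotype_fractions)
    probs = np.array([phenotype_fractions[p] for p in phen_names], dtype=float)
    probs = probs / probs.sum()
    hit_idx = np.nonzero(roles == "hit")[0]
    counts = np.floor(probs * len(hit_idx)).astype(int)
    while counts.sum() < len(hit_idx):
        counts[int(np.argmax(probs * len(hit_idx) - counts))] += 1
    planted_phen = np.concatenate(
        [[name] * c for name, c in zip(phen_names, counts)]
    ) if len(hit_idx) else np.array([], dtype=object)

    rows = []
    phen_by_strain = {}
    for pos, i in enumerate(hit_idx):
        phen_by_strain[i] = planted_phen[pos]
    for i in range(n_strains):
        role = roles[i]
        if role == "hit":
            g = [_failed(), _healthy(), _healthy(), _healthy()]
        elif role == "galactose_sick":
            g = [_failed(), _healthy(), _failed(), _healthy()]
        else:
            g = [_healthy()] * 4
        if score_noise > 0:
            for j in range(4):
                if rng.random() < score_noise:
                    g[j] = int(rng.integers(0, 5))
        phen = phen_by_strain.get(i)
        low = phen == "low_signal"
        row = {
            "strain": f"strain{i:05d}",
            "growth_wtf4_inducing": g[0],
            "growth_wtf4_noninducing": g[1],
            "growth_ev_inducing": g[2],
            "growth_ev_noninducing": g[3],
            "signal_level": rng.uniform(0.0, 0.15) if low else rng.uniform(0.5, 1.0),
            "antidote_dispersed": phen == "dispersed_both",
            "poison_dispersed": phen
            in ("dispersed_both", "antidote_normal_poison_dispersed"),
            "antidote_only_toxic": bool(phen is not None and rng.random() < 44 / 106),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    gt = GroundTruth(
        params={
            "n_strains": n_strains,
            "n_hits": int(n_hits),
            "n_galactose_sick": n_sick,
            "seed": seed,
        },
        records=[
            {
                "strain": f"strain{i:05d}",
                "role": roles[i],
                "phenotype": phen_by_strain.get(i, None),
            }
            for i in range(n_strains)
        ],
    )
    return table, gt


# ---------------------------------------------------------------------------
# Blob fields for the segmentation benchmark


def simulate_blob_fields(
    n_frames: int,
    seed: int = 0,
    frame_size: int = 96,
    n_blobs: tuple[int, int] = (3, 7),
    radius_px: tuple[float, float] = (6.0, 12.0),
    amplitude: float = 180.0,
    background: float = 15.0,
    noise: NoiseModel | None = None,
) -> tuple[list[np.ndarray], list[RoiSet], GroundTruth]:
    """Frames of bright, well-separated elliptical blobs with polygon ROIs.

    The standard fixture for training and scoring the tile segmentation:
    blob interiors are bright with soft edges, the annotation polygons
    delimit them, and planted centers/radii are recorded.
    """
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, 18, endpoint=False)
    frames, roisets, records = [], [], []
    for fi in range(n_frames):
        img = np.full((frame_size, frame_size), background, dtype=float)
        rois = []
        centers = []
        count = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
        for bi in range(count):
            for _ in range(300):
                r = rng.uniform(*radius_px)
                cx = rng.uniform(r + 3, frame_size - r - 3)
                cy = rng.uniform(r + 3, frame_size - r - 3)
                if all(
                    np.hypot(cx - px, cy - py) > r + pr + 4
                    for px, py, pr in centers
                ):
                    break
            else:
                break  # frame is full; accept fewer blobs
            centers.append((cx, cy, r))
            yy, xx = np.mgrid[0:frame_size, 0:frame_size]
            dist = np.hypot(xx - cx, yy - cy)
            img += amplitude / (1.0 + np.exp((dist - r) / 1.0))  # soft-edged disc
            pts = np.column_stack(
                [cx + r * np.cos(theta), cy + r * np.sin(theta)]
            )
            rois.append(Roi(kind="polygon", points=pts, label=f"blob{bi}"))
            records.append(
                {"frame": fi, "blob": bi, "center": (cx, cy), "radius_px": r}
            )
        frames.append(_apply_noise(img, noise, rng))
        roisets.append(RoiSet(image_id=f"frame{fi}", rois=rois))
    gt = GroundTruth(params={"n_frames": n_frames, "seed": seed}, records=records)
    return frames, roisets, gt
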