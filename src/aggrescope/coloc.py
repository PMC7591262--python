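"""Shift-resolved Pearson colocalization along segmented-line profiles.

A two-pixel-wide polyline is drawn through a spore or cell, resampled at
1-px arc-length spacing in both channels, and the Pearson correlation of the
two profiles is computed at integer sample shifts.  Per-cell shift curves are
averaged with their standard error; the zero-shift value is the headline
colocalization coefficient, and the decay away from zero shift reports the
spatial scale of the correlated structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import ImageStack, Roi

__all__ = [
    "IntensityProfile",
    "ShiftCorrCurve",
    "extract_profile",
    "pearson",
    "shift_correlation",
    "aggregate_curves",
]

MIN_PROFILE_SAMPLES = 8
MIN_OVERLAP = 3  # shortest overlap on which a correlation is still computed


class ZeroVarianceError(ValueError):
    """Correlation is undefined when either input has no variance."""


@dataclass
class IntensityProfile:
    ch1: np.ndarray
    ch2: np.ndarray
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("ch1/ch2 must be 1-D and equal length")
        if len(self.ch1) < MIN_PROFILE_SAMPLES:
            raise ValueError(
                f"profile needs >= {MIN_PROFILE_SAMPLES} samples, got {len(self.ch1)}"
            )
        if not (np.all(np.isfinite(self.ch1)) and np.all(np.isfinite(self.ch2))):
            raise ValueError("profile intensities must be finite")

    def __len__(self) -> int:
        return len(self.ch1)


@dataclass
class ShiftCorrCurve:
    shifts: np.ndarray  # integer sample offsets, symmetric about 0
    r: np.ndarray  # mean Pearson r per shift
    se: np.ndarray  # standard error of the mean per shift
    n: np.ndarray  # cells contributing per shift
    flagged_shifts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.shifts) == len(self.r) == len(self.se) == len(self.n)):
            raise ValueError("shifts, r, se, n must share length")
        if np.any(np.diff(self.shifts) <= 0):
            raise ValueError("shifts must be strictly increasing")


def _resample_polyline(points: np.ndarray, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at fixed arc-length spacing.

    Returns sample positions (n, 2) and unit tangents (n, 2), with
    ``round(arc_length) + 1`` samples at unit spacing.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    n_samples = int(round(total / spacing)) + 1
    s = np.linspace(0.0, total, n_samples)
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    samples = np.column_stack([x, y])
    # tangent per sample from the segment it falls in
    idx = np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(seg) - 1)
    tangents = seg[idx] / np.maximum(seg_len[idx], 1e-12)[:, None]
    return samples, tangents


def extract_profile(
    image: ImageStack, roi: Roi, ch1: str, ch2: str, t: int = 0
) -> IntensityProfile:
    """Sample two channels along a segmented-line ROI.

    The polyline is resampled at 1-px arc-length spacing; at each sample the
    intensity is averaged over ``width_px`` perpendicular offsets (for the
    default width of two: the two offsets at +/-0.5 px from the line) using
    bilinear interpolation.
    """
    if roi.kind != "polyline":
        raise ValueError("profiles require a polyline ROI")
    h, w = image.pixels.shape[-2:]
    pts = roi.points
    if (
        pts[:, 0].min() < -0.5
        or pts[:, 1].min() < -0.5
        or pts[:, 0].max() > w - 0.5
        or pts[:, 1].max() > h - 0.5
    ):
        raise ValueError(f"ROI {roi.label!r} lies outside the {h}x{w} image")

    samples, tangents = _resample_polyline(pts)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    # width w -> offsets centered on the line: w=2 gives (-0.5, +0.5)
    offsets = np.arange(roi.width_px, dtype=float) - (roi.width_px - 1) / 2.0

    means = []
    for name in (ch1, ch2):
        frame = image.channel(name, t=t).astype(float)
        acc = np.zeros(len(samples))
        for off in offsets:
            pos = samples + off * normals  # (n, 2) as (x, y)
            # map_coordinates wants (row, col) = (y, x)
            vals = ndimage.map_coordinates(
                frame, [pos[:, 1], pos[:, 0]], order=1, mode="nearest"
            )
            acc += vals
        means.append(acc / len(offsets))
    return IntensityProfile(ch1=means[0], ch2=means[1], roi_label=roi.label)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Values > 0 indicate positive correlation, 0 none, and < 0
    anti-correlation.  Zero-variance input raises rather than silently
    returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def shift_correlation(
    profile: IntensityProfile, max_shift: int = 10
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pearson r between ch1 and ch2 displaced by each integer shift.

    For shift ``s``, ch2 is displaced by ``s`` samples and correlated with
    ch1 over the overlapping region only (no wraparound or padding, which
    would bias r toward 0).  Returns ``(shifts, r, flagged)`` where flagged
    lists shifts omitted for having fewer than 3 overlapping samples or
    zero variance; their r is NaN.
    """
    L = len(profile)
    if max_shift >= L / 2:
        raise ValueError(f"max_shift {max_shift} too large for profile of {L} samples")
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.full(len(shifts), np.nan)
    flagged: list[int] = []
    for i, s in enumerate(shifts):
        a = profile.ch1[: L - abs(s)] if s >= 0 else profile.ch1[-s:]
        b = profile.ch2[s:] if s >= 0 else profile.ch2[: L + s]
        if len(a) < MIN_OVERLAP:
            flagged.append(int(s))
            continue
        try:
            r[i] = pearson(a, b)
        except ZeroVarianceError:
            flagged.append(int(s))
    return shifts, r, flagged


def aggregate_curves(
    per_cell: list[tuple[np.ndarray, np.ndarray]], min_cells: int = 6
) -> ShiftCorrCurve:
    """Average per-cell shift curves with the standard error of the mean.

    ``per_cell`` holds (shifts, r) pairs on a common shift grid; NaN entries
    (flagged shifts) reduce n at that shift and flag it in the result.
    """
    if len(per_cell) < min_cells:
        raise ValueError(
            f"need at least {min_cells} cells, got {len(per_cell)}"
        )
    grid = np.asarray(per_cell[0][0], dtype=int)
    for s, _ in per_cell[1:]:
        if not np.array_equal(np.asarray(s, dtype=int), grid):
            raise ValueError("per-cell curves must share a common shift grid")
    mat = np.vstack([r for _, r in per_cell]).astype(float)
    n = np.sum(np.isfinite(mat), axis=0)
    mean = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    ok = n > 0
    mean[ok] = np.nanmean(mat[:, ok], axis=0)
    multi = n > 1
    se[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1) / np.sqrt(n[multi])
    flagged = [int(s) for s, k in zip(grid, n) if k < len(per_cell)]
    return ShiftCorrCurve(shifts=grid, r=mean, se=se, n=n, flagged_shifts=flagged)
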