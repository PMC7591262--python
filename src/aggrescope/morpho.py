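"""Nuclear-condensation metrics and organelle counting/volumetry.

Nuclear size is measured as the full width at half maximum of the
fluorescence intensity, either from a 1-D profile through the nucleus or by
fitting an isotropic two-dimensional Gaussian; for a Gaussian of width sigma,
FWHM = 2*sqrt(2 ln 2)*sigma.  Condensed nuclei have a smaller FWHM than
controls; fragmented nuclei break into multiple bright components.

Organelles (vesicles, lipid droplets, mitochondria) are counted per cell on
label images via connected components (8-connectivity in 2-D); mitochondrial
volumes come from 3-D components across pre-aligned serial sections
(26-connectivity, default 60 nm section thickness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.draw import polygon as _sk_polygon
from skimage.measure import label as _sk_label

from .io_core import ImageStack, RoiSet

__all__ = [
    "NucleusFit",
    "FWHM_PER_SIGMA",
    "fwhm_profile",
    "fit_nucleus_2d",
    "compare_groups",
    "count_objects_per_cell",
    "volumes_3d",
    "call_nuclear_phenotype",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...


class BoundaryError(ValueError):
    """The half-maximum level is never crossed on one side of the peak."""


class FitError(RuntimeError):
    pass


@dataclass
class NucleusFit:
    center: tuple[float, float]  # (x, y) px
    sigma: float  # isotropic width, px
    amplitude: float
    offset: float
    rss: float
    method: str  # "profile-1d" | "gauss-2d"

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma


def fwhm_profile(profile, warn_multimodal: bool = True) -> float:
    """Full width at half maximum of a 1-D intensity profile.

    Background is the profile minimum; the width is measured between the
    two half-maximum crossings flanking the global peak, located to
    sub-sample precision by linear interpolation.  A profile whose half
    level is never crossed on one side raises :class:`BoundaryError`.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("profile must be 1-D with >= 5 samples")
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="same")
    background = float(y.min())
    peak_idx = int(np.argmax(smooth))
    half = background + (y[peak_idx] - background) / 2.0

    above = y > half
    if not above.any():
        raise BoundaryError("profile never exceeds the half-maximum level")

    # left crossing
    left = None
    for i in range(peak_idx, 0, -1):
        if y[i - 1] <= half < y[i]:
            left = (i - 1) + (half - y[i - 1]) / (y[i] - y[i - 1])
            break
    # right crossing
    right = None
    for i in range(peak_idx, len(y) - 1):
        if y[i] > half >= y[i + 1]:
            right = i + (y[i] - half) / (y[i] - y[i + 1])
            break
    if left is None or right is None:
        raise BoundaryError(
            "no half-maximum crossing on the "
            + ("left" if left is None else "right")
            + " side of the peak"
        )
    return float(right - left)


def fit_nucleus_2d(
    image: ImageStack | np.ndarray, channel: str | None = None, t: int = 0
) -> NucleusFit:
    """Fit one nucleus window to an isotropic 2-D Gaussian.

    Model: A * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2)) + b, initialized
    from image moments.  Raises :class:`FitError` on non-convergence or a
    degenerate (flat) window so callers can exclude the nucleus from group
    statistics.
    """
    if isinstance(image, ImageStack):
        frame = image.channel(channel, t=t).astype(float)
    else:
        frame = np.asarray(image, dtype=float)
    h, w = frame.shape
    b0 = float(frame.min())
    a0 = float(frame.max() - b0)
    if a0 <= 0 or not np.isfinite(frame).all():
        raise FitError("flat or non-finite window")
    yy, xx = np.mgrid[0:h, 0:w]
    weights = np.clip(frame - b0, 0, None)
    total = weights.sum()
    x0 = float((xx * weights).sum() / total)
    y0 = float((yy * weights).sum() / total)
    var = ((xx - x0) ** 2 + (yy - y0) ** 2) * weights
    s0 = float(np.sqrt(var.sum() / (2 * total))) or 1.0

    def residuals(p):
        a, x_c, y_c, s, b = p
        model = a * np.exp(-((xx - x_c) ** 2 + (yy - y_c) ** 2) / (2 * s**2)) + b
        return (model - frame).ravel()

    res = optimize.least_squares(
        residuals,
        x0=[a0, x0, y0, s0, b0],
        bounds=([0, -w, -h, 1e-3, -np.inf], [np.inf, 2 * w, 2 * h, max(h, w), np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not res.success:
        raise FitError("2-D Gaussian fit did not converge")
    a, x_c, y_c, s, b = res.x
    if a <= 0 or s >= max(h, w) * 0.99:
        raise FitError("degenerate 2-D Gaussian fit")
    return NucleusFit(
        center=(float(x_c), float(y_c)),
        sigma=float(s),
        amplitude=float(a),
        offset=float(b),
        rss=float(np.sum(res.fun**2)),
        method="gauss-2d",
    )


def compare_groups(values_a, values_b) -> dict:
    """Welch two-sample t-test (two-sided) with group summaries."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.array_equal(a, b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t_stat),
        "p": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def count_objects_per_cell(
    labels: ImageStack, cells: RoiSet, class_map: dict[int, str], t: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count class-coded 2-D objects per cell.

    ``labels`` holds integer class codes in a single channel; objects are
    8-connected components of each class, assigned to the cell polygon
    containing their centroid (unassigned objects get cell id "").
    Returns (object table, per-cell count table with one row per cell and
    one column per class).
    """
    frame = labels.pixels[t, 0]
    shape = frame.shape
    cell_masks = []
    for roi in cells:
        rr, cc = _sk_polygon(roi.points[:, 1], roi.points[:, 0], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        cell_masks.append((roi.label, m))

    rows = []
    for code, cls_name in class_map.items():
        comp, n = ndimage.label(frame == code, structure=_EIGHT_CONN)
        for obj_idx in range(1, n + 1):
            ys, xs = np.nonzero(comp == obj_idx)
            cy, cx = float(ys.mean()), float(xs.mean())
            cell_id = ""
            for label_name, m in cell_masks:
                if m[int(round(cy)), int(round(cx))]:
                    cell_id = label_name
                    break
            rows.append(
                {
                    "class": cls_name,
                    "cell_id": cell_id,
                    "area_px2": int(len(ys)),
                    "centroid_x": cx,
                    "centroid_y": cy,
                }
            )
    objects = pd.DataFrame(
        rows, columns=["class", "cell_id", "area_px2", "centroid_x", "centroid_y"]
    )
    cell_ids = [roi.label for roi in cells]
    counts = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"),
                          columns=list(class_map.values()))
    if len(objects):
        tab = objects[objects["cell_id"] != ""].groupby(["cell_id", "class"]).size()
        for (cid, cls_name), k in tab.items():
            if cid in counts.index:
                counts.loc[cid, cls_name] = int(k)
    return objects, counts


def volumes_3d(
    sections: ImageStack,
    voxel_um: tuple[float, float, float] = (0.01, 0.01, 0.06),
    class_map: dict[int, str] | None = None,
) -> pd.DataFrame:
    """3-D object volumes from pre-aligned serial-section label images.

    Sections ride on the time axis of ``sections``; components are
    26-connected in 3-D.  ``voxel_um`` is (dx, dy, dz); dz defaults to the
    60 nm section thickness.  Volume = voxel count * dx*dy*dz.
    """
    dx, dy, dz = voxel_um
    if dz <= 0 or dx <= 0 or dy <= 0:
        raise ValueError("voxel dimensions must be > 0")
    vol = sections.pixels[:, 0]  # (z, y, x)
    class_map = class_map or {
        int(c): f"class{int(c)}" for c in np.unique(vol) if c != 0
    }
    rows = []
    for code, cls_name in class_map.items():
        comp = _sk_label(vol == code, connectivity=3)
        for obj_idx in range(1, comp.max() + 1):
            sel = comp == obj_idx
            zs, ys, xs = np.nonzero(sel)
            rows.append(
                {
                    "class": cls_name,
                    "object": obj_idx,
                    "voxels": int(sel.sum()),
                    "volume_um3": float(sel.sum() * dx * dy * dz),
                    "section_min": int(zs.min()),
                    "section_max": int(zs.max()),
                    "centroid_z": float(zs.mean()),
                    "centroid_y": float(ys.mean()),
                    "centroid_x": float(xs.mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "class", "object", "voxels", "volume_um3",
            "section_min", "section_max",
            "centroid_z", "centroid_y", "centroid_x",
        ],
    )


def call_nuclear_phenotype(
    window: np.ndarray,
    control_fwhms,
    condensed_quantile: float = 0.1,
) -> str:
    """Threshold rule for 'condensed' vs 'fragmented' vs 'normal' nuclei.

    Fragmented: >= 2 above-half-max connected components in the window.
    Condensed: FWHM below the given quantile of the control group.
    """
    frame = np.asarray(window, dtype=float)
    half = frame.min() + (frame.max() - frame.min()) / 2.0
    _, n_comp = ndimage.label(frame > half, structure=_EIGHT_CONN)
    if n_comp >= 2:
        return "fragmented"
    fit = fit_nucleus_2d(frame)
    cutoff = float(np.quantile(np.asarray(control_fwhms, dtype=float), condensed_quantile))
    return "condensed" if fit.fwhm < cutoff else "normal"
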