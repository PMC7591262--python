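"""FRET analyses: acceptor-photobleaching efficiency and DAmFRET gating.

Acceptor photobleaching: bleaching the acceptor de-quenches the donor, so
the fractional donor increase estimates the FRET efficiency
``E = (D_post - D_pre) / D_post``.  A cell is accepted only if the acceptor
actually bleached (depth ``1 - A_post/A_pre`` above a configured minimum).

DAmFRET: per-event ratiometric FRET (AmFRET = FRET / acceptor) is examined
as a function of expression (donor + acceptor).  A gate is drawn at a high
quantile of a fluorophore-only control in each expression bin; the fraction
of sample events below that gate distinguishes continuous assembly (no
monomeric cells at any expression), a two-state nucleation regime, and a
purely monomeric population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import ImageStack, Roi
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "BleachMeasurement",
    "FretSummary",
    "NucleationCall",
    "fret_efficiency",
    "summarize_fret",
    "measure_bleach_pair",
    "compute_amfret",
    "detect_nucleation",
]

E_REPORT_MIN, E_REPORT_MAX = -0.5, 1.0


class InsufficientDataError(ValueError):
    pass


@dataclass
class BleachMeasurement:
    """Background-subtracted mean intensities over one cell ROI."""

    cell_id: str
    donor_pre: float
    donor_post: float
    acceptor_pre: float
    acceptor_post: float

    @property
    def bleach_depth(self) -> float:
        if self.acceptor_pre <= 0:
            return 0.0
        return 1.0 - self.acceptor_post / self.acceptor_pre


@dataclass
class FretSummary:
    mean_e: float  # mean efficiency over accepted cells, as a fraction
    se: float | None  # SEM; None for a single cell
    n: int
    table: pd.DataFrame  # per-cell: cell_id, e, flagged_negative
    exclusions: pd.DataFrame  # cell_id, reason

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_e


@dataclass
class NucleationCall:
    verdict: str  # "continuous-assembly" | "two-state" | "monomer-only"
    fraction_below_gate: float
    bin_edges: np.ndarray
    bin_fraction_below: np.ndarray
    gate: np.ndarray  # AmFRET gate level per bin
    changepoint: float | None = None  # expression where assembly switches on


def fret_efficiency(m: BleachMeasurement, min_bleach_depth: float = 0.8) -> float:
    """Acceptor-photobleaching FRET efficiency for one cell.

    Raises :class:`InsufficientDataError` when the acceptor did not bleach
    deeply enough or the post-bleach donor signal is unusable.  Negative
    apparent efficiencies are reported (not clipped to zero, which would
    bias group means upward); the report range is clamped to (-0.5, 1).
    """
    if m.donor_post <= 0:
        raise InsufficientDataError(f"{m.cell_id}: donor_post <= 0")
    if m.bleach_depth < min_bleach_depth:
        raise InsufficientDataError(
            f"{m.cell_id}: bleach depth {m.bleach_depth:.2f} < {min_bleach_depth}"
        )
    e = (m.donor_post - m.donor_pre) / m.donor_post
    return float(np.clip(e, E_REPORT_MIN, E_REPORT_MAX))


def summarize_fret(
    cells: Sequence[BleachMeasurement], min_bleach_depth: float = 0.8
) -> FretSummary:
    """Mean efficiency and SEM over accepted cells, with an exclusion log."""
    rows, excluded = [], []
    for m in cells:
        try:
            e = fret_efficiency(m, min_bleach_depth=min_bleach_depth)
        except InsufficientDataError as exc:
            excluded.append({"cell_id": m.cell_id, "reason": str(exc)})
            continue
        rows.append({"cell_id": m.cell_id, "e": e, "flagged_negative": e < 0})
    if not rows:
        raise InsufficientDataError("no accepted cells")
    table = pd.DataFrame(rows)
    e = table["e"].to_numpy()
    se = float(np.std(e, ddof=1) / np.sqrt(len(e))) if len(e) > 1 else None
    return FretSummary(
        mean_e=float(np.mean(e)),
        se=se,
        n=len(e),
        table=table,
        exclusions=pd.DataFrame(excluded, columns=["cell_id", "reason"]),
    )


def _polygon_mask(roi: Roi, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = _sk_polygon(roi.points[:, 1], roi.points[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def measure_bleach_pair(
    pre: ImageStack,
    post: ImageStack,
    roi: Roi,
    cell_id: str = "",
    donor: str = "donor",
    acceptor: str = "acceptor",
) -> BleachMeasurement:
    """Mean in-cell intensities (background-subtracted) before/after bleach.

    Background per channel/timepoint is the mean intensity outside the cell
    polygon.
    """
    shape = pre.pixels.shape[-2:]
    mask = _polygon_mask(roi, shape)
    if not mask.any() or mask.all():
        raise ValueError("cell ROI must cover part, not all, of the frame")

    def _mean(stack: ImageStack, name: str) -> float:
        frame = stack.channel(name).astype(float)
        return float(frame[mask].mean() - frame[~mask].mean())

    return BleachMeasurement(
        cell_id=cell_id or roi.label,
        donor_pre=_mean(pre, donor),
        donor_post=_mean(post, donor),
        acceptor_pre=_mean(pre, acceptor),
        acceptor_post=_mean(post, acceptor),
    )


def compute_amfret(events: pd.DataFrame, min_acceptor: float = 10.0) -> pd.DataFrame:
    """Add ``amfret`` (FRET/acceptor) and ``expression`` columns.

    Rows with acceptor below ``min_acceptor`` are dropped; the count of
    dropped rows is available as ``result.attrs['n_dropped']``.  Expression
    is the total fluorophore signal, donor + acceptor.
    """
    for col in ("donor", "acceptor", "fret"):
        if col not in events.columns:
            raise ValueError(f"events table lacks column {col!r}")
    keep = events["acceptor"] >= min_acceptor
    out = events.loc[keep].copy()
    out["amfret"] = out["fret"] / out["acceptor"]
    out["expression"] = out["donor"] + out["acceptor"]
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def _binned_gate(
    control: pd.DataFrame,
    edges: np.ndarray,
    quantile: float,
    min_events: int,
) -> np.ndarray:
    """Control AmFRET quantile per expression bin, widening sparse bins.

    A bin with fewer than ``min_events`` control events is widened
    symmetrically (in bin units) until populated; raises if the whole
    control table cannot populate a bin.
    """
    logx = np.log(control["expression"].to_numpy())
    amfret = control["amfret"].to_numpy()
    log_edges = np.log(edges)
    n_bins = len(edges) - 1
    gate = np.empty(n_bins)
    for i in range(n_bins):
        for widen in range(n_bins + 1):
            lo = log_edges[max(i - widen, 0)]
            hi = log_edges[min(i + 1 + widen, n_bins)]
            sel = (logx >= lo) & (logx <= hi)
            if sel.sum() >= min_events:
                gate[i] = np.quantile(amfret[sel], quantile)
                break
        else:
            raise InsufficientDataError(
                f"expression bin {i}: only {int(sel.sum())} control events after widening"
            )
    return gate


def detect_nucleation(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    quantile: float = 0.99,
    n_bins: int = 16,
    min_events_per_bin: int = 20,
    continuous_max_fraction: float = 0.01,
    monomer_min_fraction: float = 0.95,
) -> NucleationCall:
    """Classify a protein's self-assembly behavior over expression.

    Both tables must carry ``amfret`` and ``expression`` columns (from
    :func:`compute_amfret`).  The gate is the per-expression-bin
    ``quantile`` of the control AmFRET distribution.  Verdicts:

    - ``continuous-assembly``: essentially no events below the gate in any
      expression bin (assembly at every expression level, with no detectable
      monomeric population and hence no rate-limiting nucleation step);
    - ``monomer-only``: the overall fraction below the gate is what the gate
      construction predicts for a purely monomeric sample;
    - ``two-state``: otherwise; the changepoint is the expression at which
      the per-bin assembled fraction crosses one half.
    """
    if sample.empty or control.empty:
        raise InsufficientDataError("sample and control tables must be nonempty")
    x = sample["expression"].to_numpy()
    edges = np.exp(np.linspace(np.log(x.min()), np.log(x.max()) * (1 + 1e-12), n_bins + 1))
    gate = _binned_gate(control, edges, quantile, min_events_per_bin)

    amfret = sample["amfret"].to_numpy()
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    below = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        sel = idx == i
        counts[i] = sel.sum()
        if counts[i]:
            below[i] = np.mean(amfret[sel] <= gate[i])
    populated = counts > 0
    overall = float(np.mean(amfret <= gate[idx]))

    changepoint = None
    if np.all(below[populated] < continuous_max_fraction):
        verdict = "continuous-assembly"
    elif overall >= monomer_min_fraction:
        verdict = "monomer-only"
    else:
        verdict = "two-state"
        centers = np.sqrt(edges[:-1] * edges[1:])
        assembled = 1.0 - below
        cross = np.nonzero((assembled >= 0.5) & populated)[0]
        if len(cross):
            j = cross[0]
            if j > 0 and populated[j - 1] and assembled[j] > assembled[j - 1]:
                # interpolate in log-expression between the flanking bins
                f = (0.5 - assembled[j - 1]) / (assembled[j] - assembled[j - 1])
                changepoint = float(
                    np.exp(
                        np.log(centers[j - 1])
                        + f * (np.log(centers[j]) - np.log(centers[j - 1]))
                    )
                )
            else:
                changepoint = float(centers[j])
    return NucleationCall(
        verdict=verdict,
        fraction_below_gate=overall,
        bin_edges=edges,
        bin_fraction_below=below,
        gate=gate,
        changepoint=changepoint,
    )
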