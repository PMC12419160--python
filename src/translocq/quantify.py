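"""From stacks, masks and ROIs to the reported traces and summary numbers.

The confocal readout is a background-subtracted ratio: mean biosensor
intensity inside the membrane mask divided by the mean inside a cytosolic
(or whole-cell) ROI, per frame.  The TIRF readout normalizes footprint
intensity at each time to the mean over the pre-stimulus frames (F_t /
F_pre).  Both are summarized per cell as the area under the
baseline-subtracted curve (AUC, in ratio·min), the unit that then enters
replicate-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .stack import ImageStack
from .synth import TranslocationKinetics, membrane_fraction

__all__ = [
    "RoiSet",
    "TraceSet",
    "masked_mean",
    "ratio_trace",
    "footprint_roi",
    "ft_fpre_trace",
    "delta_trace",
    "max_normalize",
    "auc",
    "invert_ratio_to_fraction",
    "fit_first_order_response",
]


class EmptyRegionError(ValueError):
    """A measurement region contains no pixels."""


@dataclass(frozen=True)
class RoiSet:
    """The hand-drawn (or ground-truth) regions of one cell.

    ``cell`` outlines the whole cell, ``cytosol`` a membrane- and
    nucleus-free patch of cytoplasm inside it, and ``background`` a
    cell-free patch of the field used for offset subtraction.
    """

    cell: np.ndarray
    cytosol: np.ndarray
    background: np.ndarray
    nucleus: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("cell", "cytosol", "background"):
            region = getattr(self, name)
            if region.dtype != bool or not region.any():
                raise EmptyRegionError(f"ROI {name!r} must be a non-empty boolean mask")
        if (self.cell & self.background).any():
            raise ValueError("background ROI overlaps the cell ROI")
        if (self.cytosol & ~self.cell).any():
            raise ValueError("cytosol ROI must lie inside the cell ROI")


@dataclass
class TraceSet:
    """One cell's time series of a derived quantity.

    ``kind`` records what the values are (``pm_cyto_ratio``, ``ft_fpre``,
    ``delta``, ``max_normalized``); ``flagged`` marks frames whose raw
    measurement was invalid (empty mask, non-positive denominator) — their
    values are filled by linear interpolation so the time grid stays
    uniform, and the flags travel with the trace.
    """

    time_s: np.ndarray
    values: np.ndarray
    kind: str
    stimulus_frame: int
    cell_id: str = "cell0"
    replicate_id: str = "rep0"
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.values.shape, dtype=bool)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time and values must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def replace_values(self, values: np.ndarray, kind: str) -> "TraceSet":
        return TraceSet(
            time_s=self.time_s,
            values=values,
            kind=kind,
            stimulus_frame=self.stimulus_frame,
            cell_id=self.cell_id,
            replicate_id=self.replicate_id,
            flagged=self.flagged.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "replicate_id": self.replicate_id,
                "frame": np.arange(self.n_frames),
                "time_s": self.time_s,
                "value": self.values,
                "kind": self.kind,
                "flagged": self.flagged,
            }
        )


def masked_mean(frame: np.ndarray, region: np.ndarray) -> float:
    """Arithmetic mean of the pixels selected by a boolean region."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise EmptyRegionError("cannot average over an empty region")
    return float(np.asarray(frame, dtype=float)[region].mean())


def _fill_flagged(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Linear interpolation across flagged frames (edge values held)."""
    if not flagged.any():
        return values
    if flagged.all():
        raise ValueError("every frame is flagged; no valid measurements")
    idx = np.arange(len(values))
    out = values.copy()
    out[flagged] = np.interp(idx[flagged], idx[~flagged], values[~flagged])
    return out


def ratio_trace(
    stack: ImageStack,
    masks: np.ndarray,
    rois: RoiSet,
    denominator: str = "cytosol",
    biosensor_role: str = "biosensor",
    cell_id: str = "cell0",
    replicate_id: str = "rep0",
) -> TraceSet:
    """Background-subtracted membrane/denominator intensity ratio per frame.

    ``masks`` is (T, Y, X) or a single (Y, X) mask used for all frames; it
    is intersected with the cell ROI before measuring, so a marker that
    labels neighboring cells cannot leak into the numerator.  Per frame,

        r_t = (mean[mask_t & cell] - b_t) / (mean[denominator ROI] - b_t)

    with ``b_t`` the mean of the background ROI.  Frames with an empty
    numerator region or non-positive denominator are flagged and
    interpolated.
    """
    if denominator not in ("cytosol", "whole_cell"):
        raise ValueError("denominator must be 'cytosol' or 'whole_cell'")
    frames = stack.channel(biosensor_role)
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, frames.shape)
    denom_roi = rois.cytosol if denominator == "cytosol" else rois.cell
    values = np.zeros(stack.n_frames)
    flagged = np.zeros(stack.n_frames, dtype=bool)
    for t in range(stack.n_frames):
        b_t = masked_mean(frames[t], rois.background)
        num_region = masks[t] & rois.cell
        if not num_region.any():
            flagged[t] = True
            continue
        num = masked_mean(frames[t], num_region) - b_t
        den = masked_mean(frames[t], denom_roi) - b_t
        if den <= 0:
            flagged[t] = True
            continue
        values[t] = num / den
    values = _fill_flagged(values, flagged)
    return TraceSet(
        time_s=stack.times_s(),
        values=values,
        kind="pm_cyto_ratio",
        stimulus_frame=stack.stimulus_frame or 0,
        cell_id=cell_id,
        replicate_id=replicate_id,
        flagged=flagged,
    )


def footprint_roi(stack: ImageStack, role: str = "biosensor") -> np.ndarray:
    """Cell-footprint region from the minimum-intensity projection.

    The min projection over time keeps only pixels the cell covered in
    every frame (robust to transient bright frames and slight movement);
    Otsu's threshold separates footprint from background and the largest
    connected component is returned.
    """
    proj = stack.channel(role).min(axis=0)
    mask = proj > threshold_otsu(proj)
    if not mask.any():
        raise EmptyRegionError("Otsu threshold left no footprint pixels")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def ft_fpre_trace(
    stack: ImageStack,
    footprint: np.ndarray,
    background_roi: np.ndarray,
    stimulus_frame: int | None = None,
    n_pre: int | None = None,
    role: str = "biosensor",
    cell_id: str = "cell0",
    replicate_id: str = "rep0",
) -> TraceSet:
    """TIRF footprint intensity normalized to the pre-stimulus baseline.

    ``F_t`` is the background-subtracted mean footprint intensity of frame
    t; ``F_pre`` is the mean of F_t over the ``n_pre`` frames immediately
    before the stimulus (all pre-stimulus frames by default).  The returned
    trace is ``F_t / F_pre``, so the pre-window mean is exactly 1.
    """
    stim = stack.stimulus_frame if stimulus_frame is None else stimulus_frame
    if stim is None or stim < 1:
        raise ValueError("a stimulus frame >= 1 is required")
    if n_pre is None:
        n_pre = stim
    if not 1 <= n_pre <= stim:
        raise ValueError("need stimulus_frame >= n_pre >= 1")
    frames = stack.channel(role)
    f_t = np.array(
        [
            masked_mean(frames[t], footprint) - masked_mean(frames[t], background_roi)
            for t in range(stack.n_frames)
        ]
    )
    f_pre = f_t[stim - n_pre : stim].mean()
    if f_pre <= 0:
        raise ValueError(f"non-positive pre-stimulus baseline F_pre = {f_pre:.3g}")
    return TraceSet(
        time_s=stack.times_s(),
        values=f_t / f_pre,
        kind="ft_fpre",
        stimulus_frame=stim,
        cell_id=cell_id,
        replicate_id=replicate_id,
    )


def _check_window(window: tuple[int, int], n: int) -> tuple[int, int]:
    a, b = window
    if not 0 <= a < b <= n:
        raise ValueError(f"window {window} invalid for a {n}-frame trace")
    return a, b


def delta_trace(trace: TraceSet, baseline_window: tuple[int, int] | None = None) -> TraceSet:
    """Trace minus its mean over the baseline window (default: pre-stimulus)."""
    if baseline_window is None:
        baseline_window = (0, trace.stimulus_frame)
    a, b = _check_window(baseline_window, trace.n_frames)
    return trace.replace_values(trace.values - trace.values[a:b].mean(), "delta")


def max_normalize(trace: TraceSet) -> TraceSet:
    """Divide the trace by its maximum so the peak is 1."""
    peak = trace.values.max()
    if peak <= 0:
        raise ValueError("cannot max-normalize a trace with non-positive maximum")
    return trace.replace_values(trace.values / peak, "max_normalized")


def auc(
    trace: TraceSet,
    baseline_window: tuple[int, int] | None = None,
    response_window: tuple[int, int] | None = None,
) -> float:
    """Area under the baseline-subtracted trace, in value·minutes.

    Trapezoidal rule over the response window (default: stimulus to end) of
    the trace minus its baseline-window mean (default: all pre-stimulus
    frames).  Negative areas are meaningful (loss of signal).
    """
    if baseline_window is None:
        baseline_window = (0, trace.stimulus_frame)
    if response_window is None:
        response_window = (trace.stimulus_frame, trace.n_frames)
    a, b = _check_window(baseline_window, trace.n_frames)
    c, d = _check_window(response_window, trace.n_frames)
    if d - c < 2:
        raise ValueError("response window must span at least two frames")
    delta = trace.values - trace.values[a:b].mean()
    t_min = trace.time_s / 60.0
    return float(np.trapezoid(delta[c:d], t_min[c:d]))


def invert_ratio_to_fraction(ratio: np.ndarray, area_ratio: float) -> np.ndarray:
    """Membrane-bound fraction implied by a membrane/cytosol ratio.

    Inverts ``r = 1 + phi/(1-phi) * area_ratio`` (area_ratio = effective
    cytosolic area / compartment area), the relation that holds for a
    conserved probe pool partitioned between the two compartments.
    """
    u = (np.asarray(ratio, dtype=float) - 1.0) / area_ratio
    return u / (1.0 + u)


def fit_first_order_response(
    time_s: np.ndarray,
    fraction: np.ndarray,
    t_stim: float,
) -> TranslocationKinetics:
    """Least-squares fit of the single-exponential translocation model.

    Fits phi(t) = phi0 + delta_phi * (1 - exp(-(t - t_stim)/tau_on)) for
    t >= t_stim (phi0 before) to a recovered membrane-fraction trace, and
    returns the fitted kinetics.  The stimulus time is taken as known — it
    is an experimental fact, not a free parameter.
    """
    time_s = np.asarray(time_s, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    pre = time_s < t_stim
    if pre.sum() < 1 or (~pre).sum() < 3:
        raise ValueError("need at least 1 pre- and 3 post-stimulus samples")
    phi0_init = float(fraction[pre].mean())
    plateau_init = float(fraction[-max(3, len(fraction) // 10) :].mean())
    span = float(time_s[-1] - t_stim)

    def model(t, phi0, dphi, tau):
        k = TranslocationKinetics(
            phi0=np.clip(phi0, 0, 1),
            delta_phi=np.clip(dphi, -phi0, 1 - phi0),
            tau_on=max(tau, 1e-9),
            t_stim=t_stim,
        )
        return membrane_fraction(k, t)

    p0 = (phi0_init, plateau_init - phi0_init, max(span / 4.0, 1.0))
    popt, _ = optimize.curve_fit(
        model,
        time_s,
        fraction,
        p0=p0,
        bounds=([0.0, -1.0, 1e-6], [1.0, 1.0, 100.0 * max(span, 1.0)]),
        maxfev=20000,
    )
    return TranslocationKinetics(
        phi0=float(popt[0]), delta_phi=float(popt[1]), tau_on=float(popt[2]), t_stim=t_stim
    )
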