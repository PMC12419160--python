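"""Synthetic microscopy and benchmark data with analytic ground truth.

Real translocation experiments image a cell expressing a fluorescent
lipid-binding biosensor together with a membrane or organelle marker; after
a stimulus the biosensor redistributes from the cytosol onto the target
membrane.  This module renders idealized versions of those movies — a disc
cell with nucleus, cytosolic volume, and either a plasma-membrane ring or a
set of organelle-like blobs — from a phenomenological kinetic model of the
membrane-bound fraction, plus a camera noise model.  Because every scene is
generated from closed-form geometry and kinetics, the expected value of
every downstream quantity (membrane/cytosol ratio, TIRF F_t/F_pre trace,
area under the curve) is known analytically and can serve as an oracle.

The model
---------
A conserved probe pool of total signal :math:`N` partitions between the
target compartment (fraction :math:`\\varphi(t)`) and the cytosolic volume
(fraction :math:`1-\\varphi(t)`).  :math:`\\varphi` follows first-order
kinetics: constant at ``phi0`` before the stimulus, a single-exponential
rise of amplitude ``delta_phi`` with time constant ``tau_on`` after it, and
optionally a single-exponential relaxation back toward ``phi0`` after a
reversal event (antagonist, washout).  Per-pixel intensities follow by
dividing each pool by its compartment area; the nucleus carries the
cytosolic concentration times a free multiplier ``nuclear_ratio`` (1 for an
excluded-volume-free probe, >1 for probes with nuclear accumulation).

Camera noise is the standard sCMOS approximation: scaled Poisson shot noise
(``poisson_scale`` photons per intensity unit) plus additive Gaussian read
noise.  All randomness flows from the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .biochem import binding_model
from .stack import ImageStack

__all__ = [
    "TranslocationKinetics",
    "SceneSpec",
    "GroundTruth",
    "membrane_fraction",
    "expected_pm_cyto_ratio",
    "pm_cyto_ratio_formula",
    "render_confocal_timelapse",
    "render_tirf_timelapse",
    "synth_binding_data",
    "synth_replicate_dataset",
]


class DegenerateRatioError(ValueError):
    """The cytosolic pool is empty (membrane fraction = 1); the ratio diverges."""


class ConfigurationError(ValueError):
    """Scene geometry is inconsistent or exceeds the image bounds."""


@dataclass(frozen=True)
class TranslocationKinetics:
    """First-order on/off kinetics of the membrane-bound probe fraction.

    ``phi0`` is the basal membrane-bound fraction, ``delta_phi`` the response
    amplitude (``phi0 + delta_phi`` must stay in [0, 1]), ``tau_on`` the rise
    time constant in seconds, and ``t_stim`` the stimulus time.  An optional
    reversal at ``t_rev > t_stim`` relaxes the fraction back toward ``phi0``
    with time constant ``tau_off``.
    """

    phi0: float = 0.1
    delta_phi: float = 0.4
    tau_on: float = 60.0
    t_stim: float = 120.0
    t_rev: float | None = None
    tau_off: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError("phi0 must be in [0, 1]")
        if not 0.0 <= self.phi0 + self.delta_phi <= 1.0:
            raise ValueError("phi0 + delta_phi must be in [0, 1]")
        if self.tau_on <= 0:
            raise ValueError("tau_on must be positive")
        if (self.t_rev is None) != (self.tau_off is None):
            raise ValueError("t_rev and tau_off must be given together")
        if self.t_rev is not None:
            if self.tau_off <= 0:
                raise ValueError("tau_off must be positive")
            if self.t_rev <= self.t_stim:
                raise ValueError("t_rev must exceed t_stim")


def membrane_fraction(k: TranslocationKinetics, t: float | np.ndarray) -> float | np.ndarray:
    """Membrane-bound fraction phi(t) under first-order on/off kinetics.

    Piecewise: ``phi0`` before the stimulus; an exponential approach to
    ``phi0 + delta_phi`` after it; and, when a reversal is configured,
    an exponential relaxation from the fraction reached at ``t_rev`` back
    toward ``phi0``.  Continuous at both breakpoints.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    phi = np.full_like(t_arr, k.phi0, dtype=float)
    rising = t_arr >= k.t_stim
    if k.t_rev is not None:
        rising &= t_arr < k.t_rev
    phi[rising] = k.phi0 + k.delta_phi * (
        1.0 - np.exp(-(t_arr[rising] - k.t_stim) / k.tau_on)
    )
    if k.t_rev is not None:
        phi_rev = k.phi0 + k.delta_phi * (1.0 - np.exp(-(k.t_rev - k.t_stim) / k.tau_on))
        after = t_arr >= k.t_rev
        phi[after] = k.phi0 + (phi_rev - k.phi0) * np.exp(-(t_arr[after] - k.t_rev) / k.tau_off)
    return float(phi) if np.isscalar(t) else phi


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one synthetic cell, plus its seed.

    Defaults mirror a typical confocal translocation acquisition: a ~16 µm
    cell imaged at 160 nm/px every 15 s with a 2 min pre-stimulus baseline,
    shot noise around 1 photon per intensity unit (peak membrane signal on
    the order of 10^3 photons) and a few counts of read noise.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 160.0  # nm/px
    n_frames: int = 48
    frame_interval: float = 15.0  # s
    cell_center: tuple[float, float] | None = None  # (y, x) px; None = image center
    cell_radius: float = 50.0  # px
    nucleus_radius: float = 15.0  # px
    pm_thickness: float = 3.0  # px, ring width
    organelle: str = "pm"  # "pm" | "blobs"
    n_blobs: int = 6
    blob_radius: float = 4.0  # px
    kinetics: TranslocationKinetics = field(default_factory=TranslocationKinetics)
    total_probe: float = 1.2e6  # a.u., conserved pool
    marker_level: float = 600.0  # a.u. on the target compartment
    background_offset: float = 50.0  # a.u. camera offset
    nuclear_ratio: float = 1.0  # nucleus intensity / cytosol intensity
    poisson_scale: float = 1.0  # photons per a.u.; 0 disables shot noise
    read_sigma: float = 2.0  # a.u.; 0 disables read noise
    blur_sigma_px: float = 0.0  # optional partial-volume blur of noiseless frames
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx) cell drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ConfigurationError("nucleus_radius must be smaller than cell_radius")
        if self.pm_thickness < 1:
            raise ConfigurationError("pm_thickness must be >= 1 px")
        if self.organelle not in ("pm", "blobs"):
            raise ConfigurationError("organelle must be 'pm' or 'blobs'")
        cy, cx = self.center
        ny, nx = self.image_shape
        dy, dx = self.drift_px_per_frame
        total_dy, total_dx = dy * (self.n_frames - 1), dx * (self.n_frames - 1)
        for c, n, d in ((cy, ny, total_dy), (cx, nx, total_dx)):
            lo = min(c, c + d) - self.cell_radius
            hi = max(c, c + d) + self.cell_radius
            if lo < 0 or hi > n - 1:
                raise ConfigurationError("cell (including drift) exceeds image bounds")

    @property
    def center(self) -> tuple[float, float]:
        if self.cell_center is not None:
            return self.cell_center
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)


@dataclass
class GroundTruth:
    """Analytic truth accompanying a rendered scene."""

    compartment_mask: np.ndarray  # bool, ring or blob set (frame 0)
    cell_mask: np.ndarray
    cytosol_mask: np.ndarray
    nucleus_mask: np.ndarray
    background_mask: np.ndarray
    times_s: np.ndarray
    phi: np.ndarray
    expected_ratio: np.ndarray | None  # confocal only
    ft_fpre: np.ndarray | None  # TIRF only
    stimulus_frame: int
    area_ratio: float  # effective cytosolic area / compartment area
    compartment_masks_per_frame: np.ndarray | None = None  # (T, Y, X) when drifting

    def traces_frame(self) -> pd.DataFrame:
        """Ground-truth traces as a tidy table (frame, time_s, phi, ...)."""
        out = pd.DataFrame(
            {
                "frame": np.arange(len(self.times_s)),
                "time_s": self.times_s,
                "phi": self.phi,
            }
        )
        if self.expected_ratio is not None:
            out["expected_ratio"] = self.expected_ratio
        if self.ft_fpre is not None:
            out["ft_fpre"] = self.ft_fpre
        return out


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _scene_masks(
    s: SceneSpec, center: tuple[float, float] | None = None
) -> dict[str, np.ndarray]:
    center = s.center if center is None else center
    cell = _disc(s.image_shape, center, s.cell_radius)
    nucleus = _disc(s.image_shape, center, s.nucleus_radius)
    if s.organelle == "pm":
        inner = _disc(s.image_shape, center, s.cell_radius - s.pm_thickness)
        compartment = cell & ~inner
    else:
        rng = np.random.default_rng(s.seed + 104729)  # geometry stream, fixed offset
        compartment = np.zeros(s.image_shape, dtype=bool)
        placed = 0
        lo = s.nucleus_radius + s.blob_radius + 1
        hi = s.cell_radius - s.pm_thickness - s.blob_radius - 1
        while placed < s.n_blobs:
            r = rng.uniform(lo, hi)
            theta = rng.uniform(0, 2 * np.pi)
            c = (center[0] + r * np.sin(theta), center[1] + r * np.cos(theta))
            blob = _disc(s.image_shape, c, s.blob_radius)
            if not (blob & compartment).any():
                compartment |= blob
                placed += 1
    cytosol = cell & ~nucleus & ~compartment
    background = ~ndimage.binary_dilation(cell, iterations=3)
    if not cytosol.any() or not compartment.any():
        raise ConfigurationError("degenerate geometry: empty cytosol or compartment")
    return {
        "cell": cell,
        "nucleus": nucleus & ~compartment,
        "compartment": compartment,
        "cytosol": cytosol,
        "background": background,
    }


def _pool_areas(s: SceneSpec, masks: dict[str, np.ndarray]) -> tuple[float, float]:
    """(effective cytosolic area, compartment area) in pixels.

    The cytosolic pool spreads over cytosol, nucleus and compartment pixels
    (a membrane pixel also contains the cytosol above and below it in
    projection); nuclear pixels are weighted by ``nuclear_ratio``.  With
    this normalization total signal is conserved exactly, whatever the
    nuclear enrichment or the membrane-bound fraction.
    """
    a_eff = (
        masks["cytosol"].sum()
        + s.nuclear_ratio * masks["nucleus"].sum()
        + masks["compartment"].sum()
    )
    return float(a_eff), float(masks["compartment"].sum())


def pm_cyto_ratio_formula(
    total_probe: float, a_cyt: float, a_comp: float, phi: float
) -> float:
    """Noiseless membrane/cytosol per-pixel intensity ratio.

    With cytosolic per-pixel intensity ``c = total_probe * (1 - phi) / a_cyt``
    and membrane per-pixel intensity ``p = c + total_probe * phi / a_comp``,
    returns ``p / c``.  Strictly increasing in phi on [0, 1).
    """
    if phi >= 1.0:
        raise DegenerateRatioError("phi = 1 leaves the cytosol empty; ratio diverges")
    c = total_probe * (1.0 - phi) / a_cyt
    p = c + total_probe * phi / a_comp
    return p / c


def expected_pm_cyto_ratio(s: SceneSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Analytic membrane/cytosol ratio of the rendered scene at time(s) t.

    This is the oracle for the ratiometric quantifier: the value a perfect
    measurement (ground-truth masks, no noise, background subtracted) would
    return.
    """
    if s.organelle != "pm":
        raise ValueError("expected_pm_cyto_ratio is defined for the pm organelle")
    masks = _scene_masks(s)
    a_eff, a_comp = _pool_areas(s, masks)
    phi = membrane_fraction(s.kinetics, t)
    if np.isscalar(t):
        return pm_cyto_ratio_formula(s.total_probe, a_eff, a_comp, float(phi))
    return np.array(
        [pm_cyto_ratio_formula(s.total_probe, a_eff, a_comp, p) for p in np.atleast_1d(phi)]
    )


def _apply_noise(frames: np.ndarray, s: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = frames
    if s.poisson_scale and s.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0.0) * s.poisson_scale) / s.poisson_scale
    if s.read_sigma and s.read_sigma > 0:
        out = out + rng.normal(0.0, s.read_sigma, size=out.shape)
    return out


def _stimulus_frame(s: SceneSpec) -> int:
    return int(np.ceil(s.kinetics.t_stim / s.frame_interval))


def render_confocal_timelapse(s: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel (biosensor, marker) confocal time lapse.

    Per frame, cytosol pixels carry the cytosolic per-pixel concentration
    c(t), compartment pixels carry c(t) plus the membrane pool spread over
    the compartment, and nucleus pixels carry ``nuclear_ratio * c(t)``; the
    background offset is added everywhere, then seeded Poisson + Gaussian
    noise.  The marker channel labels the compartment at ``marker_level``.
    Total biosensor signal above background is conserved across frames by
    construction.
    """
    rng = np.random.default_rng(s.seed)
    times = np.arange(s.n_frames) * s.frame_interval
    phi = np.atleast_1d(membrane_fraction(s.kinetics, times))
    drifting = any(s.drift_px_per_frame)
    masks0 = _scene_masks(s)
    a_eff, a_comp = _pool_areas(s, masks0)

    frames = np.empty((s.n_frames, 2, *s.image_shape))
    per_frame_comp = np.empty((s.n_frames, *s.image_shape), dtype=bool) if drifting else None
    ratios = np.empty(s.n_frames)
    cy0, cx0 = s.center
    for i in range(s.n_frames):
        if drifting:
            center = (cy0 + s.drift_px_per_frame[0] * i, cx0 + s.drift_px_per_frame[1] * i)
            m = _scene_masks(s, center)
            per_frame_comp[i] = m["compartment"]
        else:
            m = masks0
        c = s.total_probe * (1.0 - phi[i]) / a_eff
        if c <= 0:
            raise DegenerateRatioError("phi reached 1; cytosolic concentration is zero")
        p = c + s.total_probe * phi[i] / a_comp
        ratios[i] = p / c
        bio = np.zeros(s.image_shape)
        bio[m["cytosol"]] = c
        bio[m["nucleus"]] = s.nuclear_ratio * c
        bio[m["compartment"]] = p
        marker = np.where(m["compartment"], s.marker_level, 0.0)
        if s.blur_sigma_px > 0:
            bio = ndimage.gaussian_filter(bio, s.blur_sigma_px, mode="reflect")
            marker = ndimage.gaussian_filter(marker, s.blur_sigma_px, mode="reflect")
        frames[i, 0] = bio + s.background_offset
        frames[i, 1] = marker + s.background_offset
    frames = _apply_noise(frames, s, rng)

    stack = ImageStack(
        data=frames,
        pixel_size_nm=s.pixel_size,
        frame_interval_s=s.frame_interval,
        channel_roles=("biosensor", "marker"),
        stimulus_frame=_stimulus_frame(s),
        extra={
            "seed": s.seed,
            "kinetics": {
                "phi0": s.kinetics.phi0,
                "delta_phi": s.kinetics.delta_phi,
                "tau_on": s.kinetics.tau_on,
                "t_stim": s.kinetics.t_stim,
            },
        },
    )
    truth = GroundTruth(
        compartment_mask=masks0["compartment"],
        cell_mask=masks0["cell"],
        cytosol_mask=masks0["cytosol"],
        nucleus_mask=masks0["nucleus"],
        background_mask=masks0["background"],
        times_s=times,
        phi=phi,
        expected_ratio=ratios,
        ft_fpre=None,
        stimulus_frame=_stimulus_frame(s),
        area_ratio=a_eff / a_comp,
        compartment_masks_per_frame=per_frame_comp,
    )
    return stack, truth


def render_tirf_timelapse(
    s: SceneSpec, a_f: float = 0.25, b_f: float = 1.0, footprint_level: float = 500.0
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-channel TIRF footprint time lapse.

    The evanescent field reports membrane-proximal probe, so mean footprint
    intensity is modeled as ``footprint_level * (a_f + b_f * phi(t))`` —
    an affine map from membrane-bound fraction to signal — plus background
    and noise.  Ground truth includes the F_t/F_pre trace normalized to the
    mean of the pre-stimulus frames.
    """
    if a_f < 0 or b_f <= 0:
        raise ConfigurationError("a_f must be >= 0 and b_f > 0")
    rng = np.random.default_rng(s.seed)
    times = np.arange(s.n_frames) * s.frame_interval
    phi = np.atleast_1d(membrane_fraction(s.kinetics, times))
    masks = _scene_masks(s)
    footprint = masks["cell"]
    signal = footprint_level * (a_f + b_f * phi)

    frames = np.empty((s.n_frames, 1, *s.image_shape))
    for i in range(s.n_frames):
        img = np.where(footprint, signal[i], 0.0)
        if s.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, s.blur_sigma_px, mode="reflect")
        frames[i, 0] = img + s.background_offset
    frames = _apply_noise(frames, s, rng)

    stim = _stimulus_frame(s)
    if stim < 1:
        raise ConfigurationError("stimulus must fall after at least one baseline frame")
    f_pre = signal[:stim].mean()
    stack = ImageStack(
        data=frames,
        pixel_size_nm=s.pixel_size,
        frame_interval_s=s.frame_interval,
        channel_roles=("biosensor",),
        stimulus_frame=stim,
        extra={"seed": s.seed, "tirf": {"a_f": a_f, "b_f": b_f}},
    )
    truth = GroundTruth(
        compartment_mask=footprint,
        cell_mask=footprint,
        cytosol_mask=masks["cytosol"],
        nucleus_mask=masks["nucleus"],
        background_mask=masks["background"],
        times_s=times,
        phi=phi,
        expected_ratio=None,
        ft_fpre=signal / f_pre,
        stimulus_frame=stim,
        area_ratio=float("nan"),
    )
    return stack, truth


def synth_binding_data(
    kd: float,
    bmax: float,
    bg: float,
    x: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent-bound measurements from the one-site-with-background model.

    ``y = BG + (Bmax - BG) * x / (Kd + x) + N(0, noise_sd)``, clipped to
    [0, 100] as befits a percentage read off a gel.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if bmax <= bg:
        raise ValueError("bmax must exceed bg")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    y = binding_model(x, kd, bmax, bg)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"x_uM": x, "y_pct": np.clip(y, 0.0, 100.0)})


def synth_replicate_dataset(
    n_reps: int,
    cells_per_rep: int,
    group_means: Sequence[float],
    rep_sd: float,
    cell_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced hierarchical (group / replicate / cell) dataset.

    Each replicate draws an offset ``N(0, rep_sd)`` shared by its cells; each
    cell adds ``N(0, cell_sd)``.  This is the two-level structure on which
    replicate-mean ("SuperPlot") statistics are exercised.
    """
    if n_reps < 1 or cells_per_rep < 1:
        raise ValueError("n_reps and cells_per_rep must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in enumerate(group_means):
        for r in range(n_reps):
            rep_off = rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0
            cells = mu + rep_off + (
                rng.normal(0.0, cell_sd, size=cells_per_rep) if cell_sd > 0 else np.zeros(cells_per_rep)
            )
            for c, v in enumerate(cells):
                rows.append((f"g{g}", r, c, float(v)))
    return pd.DataFrame(rows, columns=["group", "replicate", "cell", "value"])
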