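"""The in-memory image container and its on-disk TIFF + JSON sidecar form.

An :class:`ImageStack` is a T x C x Y x X array of fluorescence intensities
with the acquisition metadata needed downstream: pixel size, frame interval,
the frame at which the stimulus was added, and the biological role of each
channel (``biosensor``, ``marker``, ...).

On disk a stack is a multi-page 16-bit TIFF (pages in T-major, C-minor
order) accompanied by ``<name>.json`` holding the metadata.  16-bit storage
quantizes intensities; the sidecar records the scale factor so a round trip
through disk is exact for data already on an integer grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

_REQUIRED_META = ("pixel_size_nm", "frame_interval_s", "channel_roles")


@dataclass
class ImageStack:
    """T x C x Y x X fluorescence time lapse with acquisition metadata.

    Attributes
    ----------
    data : ndarray, shape (T, C, Y, X)
        Intensities in arbitrary camera units (float64 internally).
    pixel_size_nm : float
        Lateral pixel size.
    frame_interval_s : float
        Time between consecutive frames.
    channel_roles : tuple of str
        One role per channel, e.g. ``("biosensor", "marker")``.
    stimulus_frame : int or None
        Index of the first frame acquired after the stimulus was added.
    extra : dict
        Free-form metadata (seed, ground-truth parameters, ...), carried
        through serialization.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    channel_roles: tuple[str, ...]
    stimulus_frame: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be T x C x Y x X, got shape {self.data.shape}")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {self.data.shape[1]} channels"
            )
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """Return the T x Y x X sub-stack for the channel with this role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"no channel with role {role!r}; available: {self.channel_roles}"
            ) from None
        return self.data[:, idx]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, in seconds from the first frame."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar.

    Intensities are scaled by a stored factor so the brightest pixel maps
    near the top of the 16-bit range without clipping; a scale of 1 is kept
    whenever the data already fit.
    """
    path = Path(path)
    peak = float(stack.data.max()) if stack.data.size else 0.0
    scale = 1.0 if peak <= 65535.0 else 65535.0 / peak
    raw = np.clip(np.round(stack.data * scale), 0, 65535).astype(np.uint16)
    pages = raw.reshape(-1, *stack.shape_yx)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_roles": list(stack.channel_roles),
        "stimulus_frame": stack.stimulus_frame,
        "n_frames": stack.n_frames,
        "n_channels": stack.n_channels,
        "intensity_scale": scale,
        "extra": stack.extra,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack with its JSON sidecar back into an ImageStack.

    Raises
    ------
    FileNotFoundError
        If the sidecar is missing.
    ValueError
        Naming the absent metadata field, or on a page count that
        contradicts the sidecar.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_frames = int(meta.get("n_frames", pages.shape[0]))
    n_channels = int(meta.get("n_channels", len(meta["channel_roles"])))
    if pages.shape[0] != n_frames * n_channels:
        raise ValueError(
            f"{path} holds {pages.shape[0]} pages but sidecar declares "
            f"{n_frames} frames x {n_channels} channels"
        )
    data = pages.reshape(n_frames, n_channels, *pages.shape[1:]).astype(np.float64)
    data /= float(meta.get("intensity_scale", 1.0))
    return ImageStack(
        data=data,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channel_roles=tuple(meta["channel_roles"]),
        stimulus_frame=meta.get("stimulus_frame"),
        extra=meta.get("extra", {}),
    )
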