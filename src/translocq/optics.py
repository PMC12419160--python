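"""Optical parameters of the imaging system.

The segmentation recipe measures its Gaussian length scales in units of the
Airy disk radius of the marker fluorophore, so the optical configuration
(emission wavelength, numerical aperture, pixel size) is the bridge between
physical optics and pixel-space filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OpticalConfig", "airy_radius_px"]


@dataclass(frozen=True)
class OpticalConfig:
    """Emission optics of the marker channel.

    Parameters
    ----------
    wavelength : float
        Emission wavelength of the marker fluorophore, in nm.
    numerical_aperture : float
        Objective NA (dimensionless, <= 1.7 for practical immersion optics).
    pixel_size : float
        Image pixel size, in nm per pixel.
    """

    wavelength: float
    numerical_aperture: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive (nm)")
        if not 0 < self.numerical_aperture <= 1.7:
            raise ValueError("numerical_aperture must be in (0, 1.7]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm/px)")


def airy_radius_px(optics: OpticalConfig) -> float:
    """Airy disk (Rayleigh) radius in pixels.

    The diffraction-limited radius is ``1.22 * wavelength / (2 * NA)`` in nm,
    converted to pixels by the pixel size.  This is the unit length of the
    multi-scale Gaussian filters used for membrane-mask segmentation.
    """
    return 1.22 * optics.wavelength / (2.0 * optics.numerical_aperture) / optics.pixel_size
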