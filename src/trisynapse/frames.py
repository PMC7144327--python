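"""Biplane frame stacks and pixel-integrated Gaussian spot rendering.

A :class:`FrameStack` holds the two axially offset detection planes of a
biplane SMLM acquisition as photon-count pixel arrays.  Spots are rendered
with an error-function-integrated 2D Gaussian so that the photon count is
conserved exactly over the rendered window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf


@dataclass
class FrameStack:
    """Two co-registered detection planes (photons/pixel) per frame.

    ``plane_a``/``plane_b`` have shape (n_frames, ny, nx).  For bead
    calibration stacks each "frame" is one z plane and ``z_samples_nm``
    records the stage position of every plane.
    """

    plane_a: np.ndarray
    plane_b: np.ndarray
    pixel_size_nm: float = 100.0
    channel: str = ""
    z_samples_nm: np.ndarray | None = None
    n_skipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plane_a.shape != self.plane_b.shape:
            raise ValueError("plane A and plane B must have identical shapes")
        if np.any(self.plane_a < 0) or np.any(self.plane_b < 0):
            raise ValueError("pixel values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.plane_a.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane_a.shape[1:]


def pixel_integrated_gaussian(
    nx: int, ny: int, x_px: float, y_px: float, sigma_px: float
) -> np.ndarray:
    """Unit-mass 2D Gaussian integrated over the pixel grid.

    Pixel (r, c) spans [c, c+1) x [r, r+1) in pixel units, so a spot centred
    in the middle of pixel (0, 0) has x_px = y_px = 0.5.
    """
    xe = np.arange(nx + 1, dtype=float)
    ye = np.arange(ny + 1, dtype=float)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x_px) / s) - erf((xe[:-1] - x_px) / s))
    fy = 0.5 * (erf((ye[1:] - y_px) / s) - erf((ye[:-1] - y_px) / s))
    return np.outer(fy, fx)


def add_spot(img: np.ndarray, x_px: float, y_px: float, sigma_px: float, photons: float) -> None:
    """Accumulate a spot into ``img`` in place, touching only a +-4 sigma window."""
    ny, nx = img.shape
    half = max(3, int(np.ceil(4.0 * sigma_px)))
    c0 = max(0, int(np.floor(x_px)) - half)
    c1 = min(nx, int(np.floor(x_px)) + half + 1)
    r0 = max(0, int(np.floor(y_px)) - half)
    r1 = min(ny, int(np.floor(y_px)) + half + 1)
    if c0 >= c1 or r0 >= r1:
        return
    img[r0:r1, c0:c1] += photons * pixel_integrated_gaussian(
        c1 - c0, r1 - r0, x_px - c0, y_px - r0, sigma_px
    )


def defocus_width(z_nm, w0_nm: float, z_r_nm: float, focal_z_nm: float):
    """Gaussian-beam-style PSF width versus axial position.

    w(z) = w0 * sqrt(1 + ((z - zf)/zR)^2): minimal width w0 in the focal
    plane zf, broadening hyperbolically with defocus over the Rayleigh-type
    depth scale zR.
    """
    z = np.asarray(z_nm, dtype=float)
    return w0_nm * np.sqrt(1.0 + ((z - focal_z_nm) / z_r_nm) ** 2)
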