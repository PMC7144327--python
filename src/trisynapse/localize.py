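"""Minimal biplane SMLM localiser for simulated frame stacks.

The chain is the standard one: candidate spots are local maxima of a
smoothed frame above background, each candidate is fitted with a
pixel-integrated 2D Gaussian (least squares; amplitude parameterised as the
integrated photon count) independently in the two detection planes, the
lateral position is the photon-weighted mean of the two plane centres, and
the axial position is read off a bead-derived calibration of the PSF width
ratio between the planes.  The inversion works on the log width ratio,
which is strictly monotone in z over the calibration's valid range.

Localisation precision is reported with the CRLB-style scaling
sigma ~ PSF width / sqrt(N) (a documented approximation, adequate for
simulated data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import least_squares

from . import io
from .frames import FrameStack, pixel_integrated_gaussian

FIT_WINDOW = 11  # pixels, per plane
MAX_FIT_ITER = 100
MIN_SPOT_SEPARATION_PX = 5.0


class CalibrationError(RuntimeError):
    """The bead stack does not yield a usable (monotone) width-ratio curve."""


def diffraction_limit(wavelength_nm: float, na: float) -> float:
    """Abbe resolution limit d = 0.5 * wavelength / NA, in nm."""
    if wavelength_nm <= 0 or na <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.5 * wavelength_nm / na


@dataclass
class SpotFit:
    """Independent Gaussian fits of one candidate in both detection planes."""

    frame: int
    x_a_nm: float
    y_a_nm: float
    width_a_nm: float
    photons_a: float
    bg_a: float
    resid_a: float
    x_b_nm: float
    y_b_nm: float
    width_b_nm: float
    photons_b: float
    bg_b: float
    resid_b: float
    converged: bool


class PSFCalibration:
    """Per-channel biplane width-vs-z calibration.

    Stores the sampled width curves of both planes at the bead-stack z
    positions and interpolates them with monotone (PCHIP) splines.  The
    valid z range is the longest window over which the log width ratio is
    strictly monotone — the condition for a unique z inversion.
    """

    def __init__(
        self,
        channel: str,
        z_samples_nm: np.ndarray,
        width_a_samples_nm: np.ndarray,
        width_b_samples_nm: np.ndarray,
        valid_range_nm: tuple[float, float] | None = None,
    ) -> None:
        self.channel = channel
        self.z_samples_nm = np.asarray(z_samples_nm, dtype=float)
        self.width_a_samples_nm = np.asarray(width_a_samples_nm, dtype=float)
        self.width_b_samples_nm = np.asarray(width_b_samples_nm, dtype=float)
        if np.any(self.width_a_samples_nm <= 0) or np.any(self.width_b_samples_nm <= 0):
            raise CalibrationError("PSF widths must be positive")
        log_ratio = np.log(self.width_a_samples_nm / self.width_b_samples_nm)
        if valid_range_nm is None:
            # the usable branch is the monotone run around the equal-width
            # (focus) point; the ratio reverses again at strong defocus
            i0, i1 = _monotone_run_around(log_ratio, int(np.argmin(np.abs(log_ratio))))
            valid_range_nm = (float(self.z_samples_nm[i0]), float(self.z_samples_nm[i1]))
        self.valid_range_nm = (float(valid_range_nm[0]), float(valid_range_nm[1]))
        sel = (self.z_samples_nm >= self.valid_range_nm[0]) & (
            self.z_samples_nm <= self.valid_range_nm[1]
        )
        z_v = self.z_samples_nm[sel]
        lr_v = log_ratio[sel]
        if len(z_v) < 3:
            raise CalibrationError("valid monotone range covers fewer than 3 samples")
        d = np.diff(lr_v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CalibrationError("log width ratio is not strictly monotone in the valid range")
        self._width_a = PchipInterpolator(self.z_samples_nm, self.width_a_samples_nm)
        self._width_b = PchipInterpolator(self.z_samples_nm, self.width_b_samples_nm)
        if d[0] > 0:
            self._z_of_lr = PchipInterpolator(lr_v, z_v)
            self._lr_lo, self._lr_hi = lr_v[0], lr_v[-1]
        else:
            self._z_of_lr = PchipInterpolator(lr_v[::-1], z_v[::-1])
            self._lr_lo, self._lr_hi = lr_v[-1], lr_v[0]

    def width_a(self, z_nm):
        return self._width_a(np.clip(z_nm, self.z_samples_nm[0], self.z_samples_nm[-1]))

    def width_b(self, z_nm):
        return self._width_b(np.clip(z_nm, self.z_samples_nm[0], self.z_samples_nm[-1]))

    def z_from_widths(self, width_a_nm: float, width_b_nm: float) -> float:
        """Invert the monotone log width ratio; values beyond the calibrated
        range clamp to the range ends (i.e. toward smaller |z| excursions)."""
        lr = float(np.clip(np.log(width_a_nm / width_b_nm), self._lr_lo, self._lr_hi))
        return float(self._z_of_lr(lr))

    def z_slope_nm_per_logratio(self, z_nm: float) -> float:
        """|dz / d log-ratio| used for the axial precision estimate."""
        eps = 1e-6
        lr = np.clip(
            np.log(self.width_a(z_nm) / self.width_b(z_nm)), self._lr_lo + eps, self._lr_hi - eps
        )
        dz = self._z_of_lr(lr + eps) - self._z_of_lr(lr - eps)
        return abs(float(dz)) / (2 * eps)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "channel": self.channel,
                    "z_samples_nm": self.z_samples_nm.tolist(),
                    "width_a_samples_nm": self.width_a_samples_nm.tolist(),
                    "width_b_samples_nm": self.width_b_samples_nm.tolist(),
                    "valid_range_nm": list(self.valid_range_nm),
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PSFCalibration":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            d["channel"],
            np.array(d["z_samples_nm"]),
            np.array(d["width_a_samples_nm"]),
            np.array(d["width_b_samples_nm"]),
            tuple(d["valid_range_nm"]),
        )


def _monotone_run_around(values: np.ndarray, centre: int) -> tuple[int, int]:
    """Largest strictly monotone index range [i0, i1] containing ``centre``."""
    signs = np.sign(np.diff(values))
    if len(signs) == 0:
        raise CalibrationError("width ratio has no monotone segment")
    # direction at the centre: prefer the side with a defined slope
    s = signs[min(centre, len(signs) - 1)]
    if s == 0 and centre > 0:
        s = signs[centre - 1]
    if s == 0:
        raise CalibrationError("width ratio is flat around the focus")
    i0 = centre
    while i0 > 0 and signs[i0 - 1] == s:
        i0 -= 1
    i1 = centre
    while i1 < len(signs) and signs[i1] == s:
        i1 += 1
    if i1 - i0 < 2:
        raise CalibrationError("width ratio has no monotone segment around the focus")
    return i0, i1


def detect_spots(stack: FrameStack, threshold_photons: float) -> list[np.ndarray]:
    """Candidate spot pixels per frame.

    Local maxima of the Gaussian-smoothed summed planes exceeding the frame
    median (background proxy) by ``threshold_photons``; maxima closer than
    5 px are suppressed, the brighter one winning (ties: lower (row, col)).
    """
    if stack.n_frames == 0:
        return []
    out = []
    for f in range(stack.n_frames):
        img = stack.plane_a[f] + stack.plane_b[f]
        sm = gaussian_filter(img, sigma=1.0)
        bg = float(np.median(sm))
        is_max = (sm == maximum_filter(sm, size=5)) & (sm > bg + threshold_photons)
        rows, cols = np.nonzero(is_max)
        cand = sorted(zip(rows, cols), key=lambda rc: (-sm[rc[0], rc[1]], rc[0], rc[1]))
        kept: list[tuple[int, int]] = []
        for r, c in cand:
            if all((r - r2) ** 2 + (c - c2) ** 2 >= MIN_SPOT_SEPARATION_PX**2 for r2, c2 in kept):
                kept.append((int(r), int(c)))
        out.append(np.array(kept, dtype=int).reshape(-1, 2))
    return out


def _fit_window(win: np.ndarray) -> tuple[float, float, float, float, float, float, bool]:
    """Least-squares pixel-integrated Gaussian on one window.

    Returns (x_px, y_px, sigma_px, photons, bg, resid, converged); positions
    are relative to the window origin.
    """
    ny, nx = win.shape
    if np.ptp(win) <= 0:
        return (nx / 2, ny / 2, 1.0, 0.0, float(win.mean()), 0.0, False)
    bg0 = float(np.percentile(win, 20))
    n0 = max(float(win.sum() - bg0 * win.size), 1.0)
    ys, xs = np.mgrid[0:ny, 0:nx]
    w = np.clip(win - bg0, 0, None)
    x0 = float((xs * w).sum() / w.sum()) + 0.5
    y0 = float((ys * w).sum() / w.sum()) + 0.5

    def resid(p):
        x, y, s, n, b = p
        model = b + n * pixel_integrated_gaussian(nx, ny, x, y, s)
        return (model - win).ravel()

    try:
        res = least_squares(
            resid,
            x0=[x0, y0, 1.5, n0, bg0],
            bounds=([0, 0, 0.3, 0.0, 0.0], [nx, ny, nx, np.inf, np.inf]),
            max_nfev=MAX_FIT_ITER,
        )
    except Exception:
        return (x0, y0, 1.5, n0, bg0, np.inf, False)
    x, y, s, n, b = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    converged = bool(res.status > 0 and n > 0 and s > 0.3)
    return (float(x), float(y), float(s), float(n), float(b), rms, converged)


def fit_spot(
    stack: FrameStack, frame: int, seed_pos: tuple[int, int], window: int = FIT_WINDOW
) -> SpotFit:
    """Fit a ``window`` x ``window`` (default 11x11) region around ``seed_pos``
    (row, col) in both planes.

    ``converged`` is False when the window clips the frame border, the fit
    degenerates (flat window) or the iteration cap is hit.
    """
    r, c = int(seed_pos[0]), int(seed_pos[1])
    half = window // 2
    ny, nx = stack.shape
    px = stack.pixel_size_nm
    clipped = r - half < 0 or c - half < 0 or r + half + 1 > ny or c + half + 1 > nx
    r0, c0 = max(0, r - half), max(0, c - half)
    r1, c1 = min(ny, r + half + 1), min(nx, c + half + 1)
    results = []
    ok = not clipped
    for plane in (stack.plane_a, stack.plane_b):
        win = plane[frame, r0:r1, c0:c1]
        x, y, s, n, b, rms, conv = _fit_window(win)
        ok = ok and conv
        results.append(((c0 + x) * px, (r0 + y) * px, s * px, n, b, rms))
    (xa, ya, wa, na, ba, ra), (xb, yb, wb, nb, bb, rb) = results
    return SpotFit(frame, xa, ya, wa, na, ba, ra, xb, yb, wb, nb, bb, rb, ok)


CALIBRATION_FIT_WINDOW = 41  # px; defocused bead PSFs are far wider than spots


def calibrate_psf(
    bead_stack: FrameStack, threshold_photons: float = 50.0, smooth: bool = True
) -> PSFCalibration:
    """Fit per-plane bead widths at every z plane and build the calibration.

    Beads are detected on the z-averaged image; widths are averaged across
    beads plane by plane, with a wide fit window so strongly defocused PSFs
    are not truncated, then (by default) smoothed with a quadratic fit to
    the squared widths.
    """
    if bead_stack.z_samples_nm is None:
        raise CalibrationError("bead stack has no z positions")
    n_planes = bead_stack.n_frames
    mean_img = (bead_stack.plane_a + bead_stack.plane_b).mean(axis=0)
    mean_stack = FrameStack(
        mean_img[None, :, :],
        mean_img[None, :, :],
        pixel_size_nm=bead_stack.pixel_size_nm,
        channel=bead_stack.channel,
    )
    cands = detect_spots(mean_stack, threshold_photons)[0]
    if len(cands) == 0:
        raise CalibrationError("no beads detected")
    width_a = np.full(n_planes, np.nan)
    width_b = np.full(n_planes, np.nan)
    for k in range(n_planes):
        was, wbs = [], []
        for rc in cands:
            fit = fit_spot(bead_stack, k, rc, window=CALIBRATION_FIT_WINDOW)
            if fit.converged:
                was.append(fit.width_a_nm)
                wbs.append(fit.width_b_nm)
        if was:
            width_a[k] = np.mean(was)
            width_b[k] = np.mean(wbs)
    good = ~np.isnan(width_a)
    if good.sum() < 5:
        raise CalibrationError("too few planes with converged bead fits")
    z = bead_stack.z_samples_nm[good]
    if smooth:
        # a defocusing Gaussian PSF has w^2 exactly quadratic in z, so a
        # quadratic fit to w^2 removes bead shot noise without model bias;
        # weight by 1/w^2 so the near-focus minimum is not swamped by the
        # numerically huge defocused values
        wa2, wb2 = width_a[good] ** 2, width_b[good] ** 2
        width_a_s = np.sqrt(np.polyval(np.polyfit(z, wa2, 2, w=1.0 / wa2), z))
        width_b_s = np.sqrt(np.polyval(np.polyfit(z, wb2, 2, w=1.0 / wb2), z))
    else:
        width_a_s, width_b_s = width_a[good], width_b[good]
    return PSFCalibration(bead_stack.channel, z, width_a_s, width_b_s)


LOCALIZE_FIT_WINDOW = 15  # px; wide enough for defocused spots over the z range


def fit_spot_biplane(
    stack: FrameStack,
    frame: int,
    seed_pos: tuple[int, int],
    cal: PSFCalibration,
    window: int = LOCALIZE_FIT_WINDOW,
) -> tuple[float, float, float, float, float, bool]:
    """Joint least-squares fit of both planes with z as an explicit parameter.

    The two windows share (x, y, z, N); per-plane widths are tied to the
    calibration curves width_a(z)/width_b(z), which is what makes the axial
    estimate far more precise than inverting independently fitted widths.
    Initialised from the per-plane fits and the width-ratio inversion.
    Returns (x_nm, y_nm, z_nm, photons, bg, converged).
    """
    r, c = int(seed_pos[0]), int(seed_pos[1])
    half = window // 2
    ny, nx = stack.shape
    px = stack.pixel_size_nm
    if r - half < 0 or c - half < 0 or r + half + 1 > ny or c + half + 1 > nx:
        return (c * px, r * px, 0.0, 0.0, 0.0, False)
    init = fit_spot(stack, frame, seed_pos, window=window)
    if not init.converged or init.photons_a + init.photons_b <= 0:
        return (c * px, r * px, 0.0, 0.0, 0.0, False)
    z0 = cal.z_from_widths(init.width_a_nm, init.width_b_nm)
    win_a = stack.plane_a[frame, r - half : r + half + 1, c - half : c + half + 1]
    win_b = stack.plane_b[frame, r - half : r + half + 1, c - half : c + half + 1]
    wn = 2 * half + 1
    z_lo, z_hi = cal.valid_range_nm

    def resid(p):
        x, y, z, n, ba, bb = p
        w_a = float(cal.width_a(z)) / px
        w_b = float(cal.width_b(z)) / px
        m_a = ba + 0.5 * n * pixel_integrated_gaussian(wn, wn, x, y, w_a)
        m_b = bb + 0.5 * n * pixel_integrated_gaussian(wn, wn, x, y, w_b)
        return np.concatenate([(m_a - win_a).ravel(), (m_b - win_b).ravel()])

    x0 = (init.x_a_nm * init.photons_a + init.x_b_nm * init.photons_b) / (
        init.photons_a + init.photons_b
    ) / px - (c - half)
    y0 = (init.y_a_nm * init.photons_a + init.y_b_nm * init.photons_b) / (
        init.photons_a + init.photons_b
    ) / px - (r - half)
    try:
        res = least_squares(
            resid,
            x0=[x0, y0, z0, init.photons_a + init.photons_b, init.bg_a, init.bg_b],
            bounds=([0, 0, z_lo, 0, 0, 0], [wn, wn, z_hi, np.inf, np.inf, np.inf]),
            max_nfev=2 * MAX_FIT_ITER,
        )
    except Exception:
        return (c * px, r * px, z0, 0.0, 0.0, False)
    x, y, z, n, ba, bb = res.x
    return (
        (c - half + x) * px,
        (r - half + y) * px,
        float(z),
        float(n),
        0.5 * (ba + bb),
        bool(res.status > 0 and n > 0),
    )


def localize_stack(
    stack: FrameStack, cal: PSFCalibration, threshold_photons: float = 100.0
) -> io.LocalizationTable:
    """detect -> joint biplane fit for a whole stack; unconverged fits dropped.

    Precision estimates use the CRLB-style PSF-width / sqrt(photons) scaling
    laterally and the calibrated ratio-slope scaling axially.
    """
    if len(cal.z_samples_nm) == 0:
        raise CalibrationError("empty calibration")
    candidates = detect_spots(stack, threshold_photons)
    rows: list[tuple] = []
    dropped = 0
    for f, cands in enumerate(candidates):
        for rc in cands:
            x, y, z, n_tot, bgm, ok = fit_spot_biplane(stack, f, rc, cal)
            if not ok:
                dropped += 1
                continue
            width_mean = 0.5 * (float(cal.width_a(z)) + float(cal.width_b(z)))
            sigma_xy = width_mean / np.sqrt(n_tot)
            sigma_z = cal.z_slope_nm_per_logratio(z) * np.sqrt(2.0 / n_tot)
            rows.append((f, x, y, z, n_tot, bgm, sigma_xy, sigma_z))
    n = len(rows)
    arr = np.array(rows, dtype=float).reshape(n, 8)
    table = io.make_table(
        channel=np.full(n, stack.channel or "unknown", dtype=object),
        frame=arr[:, 0].astype(int),
        xyz=arr[:, 1:4],
        photons=arr[:, 4],
        bg=arr[:, 5],
        sigma_xy=arr[:, 6],
        sigma_z=arr[:, 7],
        meta={
            "channels": [stack.channel or "unknown"],
            "pixel_size_nm": stack.pixel_size_nm,
            "source": "trisynapse.localize",
            "n_dropped_fits": dropped,
        },
    )
    return table
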