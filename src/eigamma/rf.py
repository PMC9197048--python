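"""Receptive-field estimation from flashed-grating evoked responses.

Small gratings flashed on a 9x9 grid of visual-field locations evoke a
negative LFP deflection 40-100 ms after onset at sites whose RF covers the
location.  The baseline-corrected deflection magnitude over the grid is fit
with an axis-aligned 2D Gaussian; its center is the RF estimate, and sites
whose centers fall within a small radius of the stimulus center are the
"center sites" entering all condition-wise analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StimGrid",
    "RFEstimate",
    "evoked_response",
    "fit_rf",
    "select_center_sites",
]


@dataclass
class StimGrid:
    """Evoked-response magnitudes on a rectangular grid of stimulus positions.

    azimuths : (n_az,) degrees, strictly increasing
    elevations : (n_el,) degrees, strictly increasing
    responses : (n_el, n_az) scalar response per position
    """

    azimuths: np.ndarray
    elevations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.azimuths = np.asarray(self.azimuths, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(np.diff(self.azimuths) <= 0) or np.any(np.diff(self.elevations) <= 0):
            raise ValueError("grid axes must be strictly increasing (unique positions)")
        if self.responses.shape != (len(self.elevations), len(self.azimuths)):
            raise ValueError("responses must have shape (n_el, n_az)")


@dataclass
class RFEstimate:
    center: tuple[float, float]  # (azimuth, elevation) degrees
    sigmas: tuple[float, float]  # (sigma_az, sigma_el) degrees
    amplitude: float
    baseline: float
    size: float  # degrees; geometric mean of the two sigmas
    converged: bool = True
    extrapolated: bool = False  # center outside the grid's convex hull


def evoked_response(lfp: np.ndarray, fs: float, t0_index: int) -> float:
    """Baseline-corrected evoked deflection of a trial-averaged LFP.

    Minimum over [40, 100] ms after onset minus the minimum over
    [-100, -40] ms before it; signed, more negative = stronger response.
    """
    lfp = np.asarray(lfp, dtype=float)
    a_post = t0_index + int(round(0.040 * fs))
    b_post = t0_index + int(round(0.100 * fs)) + 1
    a_pre = t0_index + int(round(-0.100 * fs))
    b_pre = t0_index + int(round(-0.040 * fs)) + 1
    if a_pre < 0 or b_post > len(lfp):
        raise ValueError("series must cover [-100, 100] ms around onset")
    return float(lfp[a_post:b_post].min() - lfp[a_pre:b_pre].min())


def _gauss2d(xy, amp, x0, y0, sx, sy, base):
    x, y = xy
    return amp * np.exp(-((x - x0) ** 2) / (2 * sx**2) - ((y - y0) ** 2) / (2 * sy**2)) + base


def fit_rf(grid: StimGrid) -> RFEstimate:
    """Axis-aligned 2D Gaussian fit to |evoked response| over the grid.

    Nonlinear least squares (amplitude, center, two SDs, baseline); initial
    center and widths from the first and second moments of the
    baseline-subtracted magnitude map.  Non-convergence returns a flagged
    estimate rather than raising.  ``size`` is the geometric mean of the two
    fitted SDs.
    """
    z = np.abs(grid.responses)
    if z.size < 9 or not np.all(np.isfinite(z)):
        raise ValueError("need >= 9 finite grid responses")
    X, Y = np.meshgrid(grid.azimuths, grid.elevations)
    x, y, zf = X.ravel(), Y.ravel(), z.ravel()
    base0 = float(zf.min())
    w = np.maximum(zf - base0, 0)
    if w.sum() == 0:
        w = np.ones_like(zf)
    x0 = float(np.sum(w * x) / w.sum())
    y0 = float(np.sum(w * y) / w.sum())
    span_x = grid.azimuths[-1] - grid.azimuths[0]
    span_y = grid.elevations[-1] - grid.elevations[0]
    sx0 = max(float(np.sqrt(np.sum(w * (x - x0) ** 2) / w.sum())), span_x / 50)
    sy0 = max(float(np.sqrt(np.sum(w * (y - y0) ** 2) / w.sum())), span_y / 50)
    p0 = [float(zf.max() - base0) or 1.0, x0, y0, sx0, sy0, base0]
    bounds = (
        [0, grid.azimuths[0] - span_x, grid.elevations[0] - span_y, 1e-6, 1e-6, -np.inf],
        [np.inf, grid.azimuths[-1] + span_x, grid.elevations[-1] + span_y,
         5 * span_x, 5 * span_y, np.inf],
    )
    try:
        popt, _ = curve_fit(_gauss2d, (x, y), zf, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    amp, cx, cy, sx, sy, base = (float(v) for v in popt)
    extrapolated = not (
        grid.azimuths[0] <= cx <= grid.azimuths[-1]
        and grid.elevations[0] <= cy <= grid.elevations[-1]
    )
    return RFEstimate(
        center=(cx, cy), sigmas=(sx, sy), amplitude=amp, baseline=base,
        size=float(np.sqrt(sx * sy)), converged=converged, extrapolated=extrapolated,
    )


def select_center_sites(
    rf_centers: dict,
    stimulus_center: tuple[float, float],
    radius: float,
) -> list:
    """Sites whose RF center lies within ``radius`` degrees of the stimulus
    center (Euclidean, boundary inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = stimulus_center
    return [
        site
        for site, (x, y) in rf_centers.items()
        if np.hypot(x - cx, y - cy) <= radius
    ]
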