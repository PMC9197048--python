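"""Single-taper spectral pipeline for stimulus-locked LFP trials.

The estimator throughout is a single Slepian (DPSS) taper with
time-bandwidth product 1 applied to a 0.25 s window, giving 4 Hz spectral
resolution at the 2 kHz sampling rate of the recordings the pipeline
emulates.  Power is averaged across trials *before* the logarithm; change
from baseline is expressed in decibels as 10*(log10 stim - log10 baseline).

Gamma-band bookkeeping follows the conventions of the recordings: fast
gamma is [35, 65] Hz or [45, 75] Hz depending on the animal, shifted down
by 5 Hz when both the center and surround gratings are below full contrast
(gamma frequency drops with contrast); band power is the plain sum of PSD
values over in-band bins; per-site normalized gamma power divides each
condition's band power by the maximum across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import periodogram
from scipy.signal.windows import dpss

__all__ = [
    "TrialSet",
    "BandSpec",
    "TFSpectrum",
    "PSDChange",
    "tf_difference_spectrum",
    "change_in_power",
    "select_gamma_band",
    "band_power",
    "normalized_band_power",
    "condition_band_powers",
]

_LOG_FLOOR = 1e-300  # guards log10 of empty bins (detrended DC)


@dataclass
class TrialSet:
    """Stimulus-aligned LFP trials (trials x samples) from one site.

    ``t0_index`` is the sample of stimulus onset; trials must provide at
    least 0.5 s before and 0.8 s after onset (the baseline and stimulus
    analysis spans).
    """

    lfp: np.ndarray
    fs: float = 2000.0
    t0_index: int = 0
    condition: object = None

    def __post_init__(self) -> None:
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=float))
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be a trials x samples array")
        n = self.lfp.shape[1]
        if self.t0_index / self.fs < 0.5 - 1e-9:
            raise ValueError("need >= 0.5 s of pre-onset baseline")
        if (n - self.t0_index) / self.fs < 0.8 - 1e-9:
            raise ValueError("need >= 0.8 s of post-onset data")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(self.lfp.shape[1]) - self.t0_index) / self.fs


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [lo, hi] in Hz, edges inclusive."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"require 0 < lo < hi, got ({self.lo}, {self.hi})")


@dataclass
class TFSpectrum:
    """Time-frequency change from baseline, in dB.

    ``values`` has shape (len(freqs), len(time_centers)); time centers are
    seconds relative to stimulus onset.
    """

    time_centers: np.ndarray
    freqs: np.ndarray
    values: np.ndarray


@dataclass
class PSDChange:
    """Stimulus-vs-baseline PSD comparison for one trial set."""

    freqs: np.ndarray
    delta_db: np.ndarray
    stim_psd: np.ndarray  # trial-mean raw power, stimulus epoch
    base_psd: np.ndarray  # trial-mean raw power, baseline epoch
    stim_window: tuple[float, float] = (0.25, 0.75)
    base_window: tuple[float, float] = (-0.5, 0.0)


def _single_taper(n: int) -> np.ndarray:
    """First Slepian sequence, time-bandwidth product NW = 1."""
    return dpss(n, NW=1, Kmax=1)[0]


def _taper_psd(segments: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-taper PSD of each row; per-segment mean removed first."""
    taper = _single_taper(segments.shape[-1])
    return periodogram(segments, fs=fs, window=taper, detrend="constant", axis=-1)


def tf_difference_spectrum(
    trials: TrialSet, window_s: float = 0.25, step_s: float = 0.025
) -> TFSpectrum:
    """Sliding-window difference spectrogram in dB relative to baseline.

    Per window: single-taper power per trial, mean across trials, log10;
    then the mean log-spectrum over all windows lying fully inside the
    [-0.5, 0] s spontaneous period is subtracted per frequency and the
    result multiplied by 10.  Windows extending past the trial edges are
    dropped.
    """
    if trials.n_trials < 2:
        raise ValueError("need at least 2 trials")
    fs, t0 = trials.fs, trials.t0_index
    n_w = int(round(window_s * fs))
    n_step = max(1, int(round(step_s * fs)))
    n = trials.lfp.shape[1]
    starts = np.arange(0, n - n_w + 1, n_step)
    if len(starts) == 0:
        raise ValueError("trials shorter than one analysis window")
    segs = np.stack([trials.lfp[:, s : s + n_w] for s in starts], axis=0)
    freqs, p = _taper_psd(segs, fs)  # (n_windows, n_trials, n_freqs)
    logp = np.log10(np.maximum(p.mean(axis=1), _LOG_FLOOR))  # (n_windows, n_freqs)
    centers = (starts + n_w / 2.0 - t0) / fs
    base = (starts >= t0 - int(round(0.5 * fs))) & (starts + n_w <= t0)
    if not np.any(base):
        raise ValueError("no analysis window fits inside the [-0.5, 0] s baseline")
    values = 10.0 * (logp - logp[base].mean(axis=0))
    return TFSpectrum(time_centers=centers, freqs=freqs, values=values.T)


def _epoch(trials: TrialSet, window: tuple[float, float]) -> np.ndarray:
    a = trials.t0_index + int(round(window[0] * trials.fs))
    b = trials.t0_index + int(round(window[1] * trials.fs))
    if a < 0 or b > trials.lfp.shape[1] or b <= a:
        raise ValueError(f"window {window} s outside the trial span")
    return trials.lfp[:, a:b]


def change_in_power(
    trials: TrialSet,
    stim_window: tuple[float, float] = (0.25, 0.75),
    base_window: tuple[float, float] = (-0.5, 0.0),
) -> PSDChange:
    """Stimulus-period PSD vs the spontaneous period, in dB.

    Both epochs are estimated with one single-taper window spanning the full
    epoch (0.5 s -> 2 Hz bins); trial-mean power is taken before the log.
    """
    if trials.n_trials < 2:
        raise ValueError("need at least 2 trials")
    freqs, p_stim = _taper_psd(_epoch(trials, stim_window), trials.fs)
    _, p_base = _taper_psd(_epoch(trials, base_window), trials.fs)
    stim = p_stim.mean(axis=0)
    base = p_base.mean(axis=0)
    delta = 10.0 * (np.log10(np.maximum(stim, _LOG_FLOOR)) - np.log10(np.maximum(base, _LOG_FLOOR)))
    return PSDChange(
        freqs=freqs, delta_db=delta, stim_psd=stim, base_psd=base,
        stim_window=stim_window, base_window=base_window,
    )


def select_gamma_band(
    config_band: BandSpec, inner_contrast: float, outer_contrast: float, shift_hz: float = 5.0
) -> BandSpec:
    """Contrast-dependent gamma band selection.

    The configured band applies whenever at least one of the center (inner)
    or surround (outer) gratings is at 100% contrast; when both are below
    100% the band is shifted down by ``shift_hz`` (gamma slows at low
    contrast).
    """
    for name, c in (("inner", inner_contrast), ("outer", outer_contrast)):
        if not (0.0 <= c <= 100.0):
            raise ValueError(f"{name} contrast must lie in [0, 100], got {c}")
    if inner_contrast == 100.0 or outer_contrast == 100.0:
        return config_band
    return BandSpec(lo=config_band.lo - shift_hz, hi=config_band.hi - shift_hz)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandSpec) -> float:
    """Sum of PSD values over bins with lo <= f <= hi (edges inclusive)."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not np.any(mask):
        raise ValueError(f"no frequency bins inside [{band.lo}, {band.hi}] Hz")
    return float(psd[mask].sum())


def normalized_band_power(per_condition: Mapping[object, float]) -> dict:
    """Divide per-condition band powers by their maximum (per site).

    The maximum maps to exactly 1; all-zero input is an error.
    """
    if not per_condition:
        raise ValueError("empty condition map")
    mx = max(per_condition.values())
    if mx <= 0:
        raise ValueError("all condition powers are zero or negative")
    return {k: v / mx for k, v in per_condition.items()}


def condition_band_powers(
    trialsets: Mapping[object, TrialSet],
    band: BandSpec,
    stim_window: tuple[float, float] = (0.25, 0.75),
) -> dict:
    """Raw stimulus-epoch gamma band power per condition (one site)."""
    out = {}
    for cond, ts in trialsets.items():
        ch = change_in_power(ts, stim_window=stim_window)
        out[cond] = band_power(ch.freqs, ch.stim_psd, band)
    return out
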