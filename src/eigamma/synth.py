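"""Seeded generators of synthetic recording sessions.

A session emulates the structure the analysis pipeline assumes: per
discontinuity condition, LFP trials of 1/f-type background noise carrying a
stimulus-locked narrowband gamma component whose amplitude decays
exponentially with discontinuity magnitude (A(d) = A0*exp(-d/lambda)) and
whose frequency rises linearly (f(d) = f0 + k*d); per-unit spike trains are
inhomogeneous Poisson with a modest linear rate increase with discontinuity
(surround suppression weakens) scaled by per-unit lognormal heterogeneity.
The gamma component has a fresh uniform phase on every trial (induced, not
evoked, rhythm) and 50 ms cosine on/off ramps.

A model-driven mode replaces the sinusoid with post-transient E-population
activity of the E-I network simulated at discontinuity-dependent effective
weights, so the full pipeline can be exercised against the dynamical model.
All generators are deterministic given (config, seed); ground truth is
returned alongside every session for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .model import ExternalInput, ModelSpec, apply_discontinuity, simulate
from .rf import StimGrid
from .spectral import TrialSet
from .spikes import SpikeSet

__all__ = [
    "SessionConfig",
    "SessionGroundTruth",
    "Session",
    "generate_session",
    "generate_model_driven_session",
    "generate_rf_grid",
    "pink_noise",
]

#: Default gamma amplitude; gives ~10 dB in-band SNR over the default
#: unit-variance 1/f background in the [35, 65] Hz analysis band
#: (sinusoid band power A0^2/4 per 2 Hz bin-sum vs ~0.038 for the noise).
DEFAULT_GAMMA_AMPLITUDE = 1.25


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions of a synthetic session (one recording site)."""

    discontinuity_levels: tuple = (0.0, 0.025, 0.05, 0.1, 0.2)  # degrees
    n_trials: int = 20
    fs: float = 2000.0
    t_start: float = -1.0  # s relative to onset
    t_stop: float = 1.0
    stim_span: tuple = (0.0, 0.8)
    # narrowband gamma component
    gamma_amplitude: float = DEFAULT_GAMMA_AMPLITUDE  # A0, arbitrary LFP units
    gamma_freq: float = 50.0  # f0, Hz
    attenuation_deg: float = 0.1  # lambda, degrees
    freq_slope_hz_per_deg: float = 10.0  # k
    ramp_s: float = 0.05
    # 1/f background
    noise_exponent: float = 1.0  # beta
    noise_scale: float = 1.0  # trial standard deviation
    # spiking
    n_units: int = 3
    base_rate: float = 5.0  # spikes/s outside the stimulus epoch
    stim_rate: float = 20.0  # r0 at zero discontinuity
    rate_slope_per_deg: float = 1.0  # s in r0*(1 + s*d)
    rate_heterogeneity: float = 0.3  # lognormal sigma of per-unit factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_deg <= 0:
            raise ValueError("attenuation constant must be positive")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials per condition")
        if not (self.t_start <= -0.5 and self.t_stop >= self.stim_span[1]):
            raise ValueError("trial span must cover the baseline and stimulus epochs")
        if self.noise_scale <= 0 or self.gamma_amplitude < 0:
            raise ValueError("invalid amplitude/scale")


@dataclass
class SessionGroundTruth:
    """Programmed per-condition parameters, kept with every session."""

    gamma_amplitude: dict  # condition -> LFP units
    gamma_frequency: dict  # condition -> Hz
    unit_stim_rates: dict  # unit -> {condition -> spikes/s}
    attenuation_deg: float | None = None
    rf: dict | None = None


@dataclass
class Session:
    lfp: dict  # condition -> TrialSet
    spikes: SpikeSet
    truth: SessionGroundTruth
    config: SessionConfig


def pink_noise(n_samples: int, fs: float, exponent: float, rng: np.random.Generator,
               size: int = 1) -> np.ndarray:
    """1/f^beta noise by spectral shaping of white noise; unit variance rows."""
    white = rng.standard_normal((size, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.empty_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _stim_envelope(t: np.ndarray, span: tuple[float, float], ramp: float) -> np.ndarray:
    """Unit envelope over the stimulus epoch with raised-cosine ramps."""
    on, off = span
    env = np.zeros_like(t)
    inside = (t >= on) & (t < off)
    env[inside] = 1.0
    if ramp > 0:
        rise = inside & (t < on + ramp)
        fall = inside & (t >= off - ramp)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
        env[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp))
    return env


def _poisson_train(rng: np.random.Generator, segments: list[tuple[float, float, float]]) -> np.ndarray:
    """Piecewise-constant-rate Poisson spike train (rate in spikes/s)."""
    times = []
    for lo, hi, rate in segments:
        if rate <= 0 or hi <= lo:
            continue
        n = rng.poisson(rate * (hi - lo))
        times.append(rng.uniform(lo, hi, n))
    return np.sort(np.concatenate(times)) if times else np.array([])


def _generate_spikes(cfg: SessionConfig, rng: np.random.Generator) -> tuple[SpikeSet, dict]:
    factors = np.exp(rng.normal(-cfg.rate_heterogeneity**2 / 2.0, cfg.rate_heterogeneity,
                                cfg.n_units))
    trains: dict = {}
    unit_rates: dict = {}
    on, off = cfg.stim_span
    for u in range(cfg.n_units):
        trains[u] = {}
        unit_rates[u] = {}
        for d in cfg.discontinuity_levels:
            r_stim = cfg.stim_rate * (1.0 + cfg.rate_slope_per_deg * abs(d)) * factors[u]
            unit_rates[u][d] = float(r_stim)
            trains[u][d] = [
                _poisson_train(
                    rng,
                    [
                        (cfg.t_start, on, cfg.base_rate * factors[u]),
                        (on, off, r_stim),
                        (off, cfg.t_stop, cfg.base_rate * factors[u]),
                    ],
                )
                for _ in range(cfg.n_trials)
            ]
    return SpikeSet(trains=trains, trial_span=(cfg.t_start, cfg.t_stop)), unit_rates


def _assemble(cfg: SessionConfig, rng: np.random.Generator,
              component_fn: Callable[[object, np.ndarray, np.random.Generator], np.ndarray],
              amp_truth: dict, freq_truth: dict) -> Session:
    n = int(round((cfg.t_stop - cfg.t_start) * cfg.fs))
    t = cfg.t_start + np.arange(n) / cfg.fs
    t0_index = int(round(-cfg.t_start * cfg.fs))
    env = _stim_envelope(t, cfg.stim_span, cfg.ramp_s)
    lfp_sets = {}
    for d in cfg.discontinuity_levels:
        noise = pink_noise(n, cfg.fs, cfg.noise_exponent, rng, size=cfg.n_trials) * cfg.noise_scale
        comp = np.stack([component_fn(d, t, rng) for _ in range(cfg.n_trials)])
        lfp_sets[d] = TrialSet(lfp=noise + comp * env, fs=cfg.fs, t0_index=t0_index, condition=d)
    spikes, unit_rates = _generate_spikes(cfg, rng)
    truth = SessionGroundTruth(
        gamma_amplitude=amp_truth, gamma_frequency=freq_truth,
        unit_stim_rates=unit_rates, attenuation_deg=cfg.attenuation_deg,
    )
    return Session(lfp=lfp_sets, spikes=spikes, truth=truth, config=cfg)


def generate_session(cfg: SessionConfig, seed: int | None = None) -> Session:
    """Noise-driven session: sinusoidal gamma over 1/f background.

    Identical (config, seed) reproduces the session exactly.  The seed
    argument overrides ``cfg.seed`` when given.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # |d| so that signed discontinuities (orientation/phase, both sides of
    # zero) attenuate symmetrically
    amp = {d: cfg.gamma_amplitude * np.exp(-abs(d) / cfg.attenuation_deg)
           for d in cfg.discontinuity_levels}
    freq = {d: cfg.gamma_freq + cfg.freq_slope_hz_per_deg * abs(d)
            for d in cfg.discontinuity_levels}

    def component(d, t, rng_):
        phase = rng_.uniform(0, 2 * np.pi)
        return amp[d] * np.sin(2 * np.pi * freq[d] * t + phase)

    return _assemble(cfg, rng, component, amp, freq)


def generate_model_driven_session(
    spec: ModelSpec,
    mapping: Mapping[float, float],
    cfg: SessionConfig,
    seed: int | None = None,
    weight_name: str = "wee",
    inp: ExternalInput = ExternalInput(iE=3.0, iI=7.5),
    transient_ms: float = 1000.0,
    segment_ms: float = 3000.0,
) -> Session:
    """Session whose gamma component is simulated E-population activity.

    ``mapping`` sends each discontinuity magnitude to an effective-weight
    scale (monotone non-increasing in d); per condition the E-I network is
    simulated at the scaled weight and its post-transient, mean-subtracted
    E(t) — resampled to the session rate — becomes the stimulus-epoch
    component.  Trials differ by noise realization and by a random circular
    offset into the model segment.  A common gain maps model activity to
    LFP units so that the least-attenuated condition matches
    ``cfg.gamma_amplitude``; relative attenuation across conditions comes
    from the model alone.
    """
    ds = list(cfg.discontinuity_levels)
    scales = [float(mapping[d]) for d in ds]
    if any(b > a + 1e-12 for a, b in zip(scales, scales[1:])):
        raise ValueError("weight-scale mapping must be non-increasing in discontinuity")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dt = 0.05  # ms; resampling to cfg.fs requires 1000/dt to be a multiple of fs
    decim = int(round(1000.0 / dt / cfg.fs))
    segments: dict = {}
    amp_truth: dict = {}
    freq_truth: dict = {}
    from .dynamics import oscillation_metrics  # local import avoids a cycle

    for d, s in zip(ds, scales):
        pspec = apply_discontinuity(spec, weight_name, s)
        traj = simulate(pspec, inp, transient_ms + segment_ms, dt)
        keep = traj.times >= transient_ms
        seg = traj.E[keep][::decim]
        seg = seg - seg.mean()
        segments[d] = seg
        m = oscillation_metrics(traj, transient_ms=transient_ms)
        amp_truth[d] = float(np.sqrt(2.0) * seg.std())  # sinusoid-equivalent amplitude
        freq_truth[d] = m.peak_frequency
    ref = max(amp_truth.values())
    gain = cfg.gamma_amplitude / ref if ref > 0 else 0.0
    amp_truth = {d: gain * v for d, v in amp_truth.items()}

    def component(d, t, rng_):
        seg = segments[d]
        off = rng_.integers(0, len(seg))
        rolled = np.roll(seg, -off)
        reps = int(np.ceil(len(t) / len(rolled)))
        return gain * np.tile(rolled, reps)[: len(t)]

    return _assemble(cfg, rng, component, amp_truth, freq_truth)


def generate_rf_grid(
    center: tuple[float, float],
    sigmas: tuple[float, float],
    amplitude: float,
    grid_extent: float = 1.0,
    n_grid: int = 9,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
) -> tuple[StimGrid, dict]:
    """9x9 (by default) evoked-response grid from a known 2D Gaussian RF.

    The grid spans ``center +- grid_extent`` degrees on both axes; responses
    are the Gaussian plus i.i.d. normal noise.  Returns (grid, truth dict).
    """
    rng = np.random.default_rng(seed)
    az = center[0] + np.linspace(-grid_extent, grid_extent, n_grid)
    el = center[1] + np.linspace(-grid_extent, grid_extent, n_grid)
    X, Y = np.meshgrid(az, el)
    z = amplitude * np.exp(
        -((X - center[0]) ** 2) / (2 * sigmas[0] ** 2)
        - ((Y - center[1]) ** 2) / (2 * sigmas[1] ** 2)
    ) + baseline
    if noise_sd > 0:
        z = z + rng.normal(0, noise_sd, z.shape)
    truth = {"center": tuple(center), "sigmas": tuple(sigmas),
             "amplitude": amplitude, "baseline": baseline, "noise_sd": noise_sd}
    return StimGrid(azimuths=az, elevations=el, responses=z), truth
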