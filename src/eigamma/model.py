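"""Lumped excitatory-inhibitory (E-I) rate model of a V1 orientation column.

Two coupled populations, E and I, evolve as

    tau_x dX/dt = -X + f_x(I_x),        x in {E, I}

where ``f_x`` is a shifted logistic (zero at zero drive) and the total
synaptic drives fold the recurrent and lateral-recurrent (LR) connections
of the hypercolumn into four effective weights:

    I_e = wee*E - wei*I + iE,   I_i = wie*E - wii*I + iI
    wee = Wee + WeELR,  wei = Wei + WeILR,  wie = Wie + WiELR,  wii = Wii + WiILR

A stimulus discontinuity (an annular gap, an orientation or phase mismatch
between the receptive-field center and surround) removes part of the lateral
recurrent drive, i.e. scales an effective weight down.  With the default
parameter set the network sits in an inhibition-stabilized regime where a
supercritical Hopf bifurcation produces gamma-band (~30-80 Hz) limit cycles
whose amplitude is exquisitely sensitive to such weight reductions.

Time is measured in milliseconds throughout (tau_e = 20 ms, tau_i = 10 ms put
the limit cycle in the gamma range); activities are bounded by the sigmoid's
range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "PopulationParams",
    "ConnectionGains",
    "EffectiveWeights",
    "TimeConstants",
    "ExternalInput",
    "ModelSpec",
    "Trajectory",
    "sigmoid_response",
    "sigmoid_slope",
    "sigmoid_curvature",
    "inverse_sigmoid",
    "effective_weights",
    "apply_discontinuity",
    "simulate",
]


@dataclass(frozen=True)
class PopulationParams:
    """Sigmoid transfer parameters of one population.

    gain : logistic slope m (unitless, > 0)
    threshold : half-activation drive theta (input units, >= 0)
    """

    gain: float
    threshold: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gain) and self.gain > 0):
            raise ValueError(f"sigmoid gain must be positive, got {self.gain}")
        if not (np.isfinite(self.threshold) and self.threshold >= 0):
            raise ValueError(f"sigmoid threshold must be >= 0, got {self.threshold}")

    @property
    def lower_offset(self) -> float:
        """The sigmoid's value at -inf: -1/(1 + exp(m*theta))."""
        return -1.0 / (1.0 + np.exp(self.gain * self.threshold))


def _check_gain(name: str, value: float) -> None:
    if not (np.isfinite(value) and value >= 0):
        raise ValueError(f"synaptic gain {name} must be finite and >= 0, got {value}")


@dataclass(frozen=True)
class ConnectionGains:
    """Base synaptic gains W_xy and lateral recurrent gains W_xELR / W_xILR."""

    Wee: float
    Wei: float
    Wie: float
    Wii: float
    WeELR: float = 0.0
    WeILR: float = 0.0
    WiELR: float = 0.0
    WiILR: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Wee", "Wei", "Wie", "Wii", "WeELR", "WeILR", "WiELR", "WiILR"):
            _check_gain(name, getattr(self, name))


@dataclass(frozen=True)
class EffectiveWeights:
    """Effective network gains: base plus lateral recurrent contribution."""

    wee: float
    wei: float
    wie: float
    wii: float

    def __post_init__(self) -> None:
        for name in ("wee", "wei", "wie", "wii"):
            _check_gain(name, getattr(self, name))


@dataclass(frozen=True)
class TimeConstants:
    """Population time constants in milliseconds."""

    tau_e: float = 20.0
    tau_i: float = 10.0

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_i > 0):
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class ExternalInput:
    """External drives iE, iI to the two populations (input units)."""

    iE: float
    iI: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.iE) and np.isfinite(self.iI)):
            raise ValueError("external inputs must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of the E-I network."""

    e_params: PopulationParams
    i_params: PopulationParams
    gains: ConnectionGains
    taus: TimeConstants

    @classmethod
    def default(cls) -> "ModelSpec":
        """The published default set: wee=16, wei=26, wie=20, wii=1,
        mE=mI=1, thetaE=5, thetaI=20, tauE=20 ms, tauI=10 ms (all lateral
        gains folded into the base values)."""
        return cls(
            e_params=PopulationParams(gain=1.0, threshold=5.0),
            i_params=PopulationParams(gain=1.0, threshold=20.0),
            gains=ConnectionGains(Wee=16.0, Wei=26.0, Wie=20.0, Wii=1.0),
            taus=TimeConstants(tau_e=20.0, tau_i=10.0),
        )

    @property
    def weights(self) -> EffectiveWeights:
        return effective_weights(self.gains)


@dataclass
class Trajectory:
    """Simulated activity time series with uniform step ``dt`` (ms)."""

    times: np.ndarray  # ms
    E: np.ndarray
    I: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.E) == len(self.I)):
            raise ValueError("times, E and I must have equal length")


def sigmoid_response(drive, pop: PopulationParams):
    """Population transfer function: a logistic shifted to pass through 0.

        f(x) = 1/(1 + exp(-m (x - theta))) - 1/(1 + exp(m theta))

    Strictly increasing in the drive; f(0) = 0 so the origin is a fixed
    point of the zero-input network.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive must be finite")
    m, th = pop.gain, pop.threshold
    out = expit(m * (drive - th)) - expit(-m * th)
    return out if out.ndim else float(out)


def sigmoid_slope(drive, pop: PopulationParams):
    """First derivative f'(x) = m s (1 - s) with s the plain logistic."""
    drive = np.asarray(drive, dtype=float)
    m, th = pop.gain, pop.threshold
    s = expit(m * (drive - th))
    out = m * s * (1.0 - s)
    return out if out.ndim else float(out)


def sigmoid_curvature(drive, pop: PopulationParams):
    """Second derivative f''(x) = m^2 s (1-s)(1-2s); negative above threshold
    (sublinear/saturating), positive below (superlinear/expansive)."""
    drive = np.asarray(drive, dtype=float)
    m, th = pop.gain, pop.threshold
    s = expit(m * (drive - th))
    out = m * m * s * (1.0 - s) * (1.0 - 2.0 * s)
    return out if out.ndim else float(out)


def inverse_sigmoid(activity, pop: PopulationParams):
    """Drive producing a given activity; defined on the open sigmoid range
    (lower_offset, 1 + lower_offset)."""
    activity = np.asarray(activity, dtype=float)
    m, th = pop.gain, pop.threshold
    p = activity + expit(-m * th)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("activity outside the open sigmoid range")
    out = th + np.log(p / (1.0 - p)) / m
    return out if out.ndim else float(out)


def effective_weights(gains: ConnectionGains) -> EffectiveWeights:
    """Fold lateral recurrent gains into the four effective weights."""
    return EffectiveWeights(
        wee=gains.Wee + gains.WeELR,
        wei=gains.Wei + gains.WeILR,
        wie=gains.Wie + gains.WiELR,
        wii=gains.Wii + gains.WiILR,
    )


_WEIGHT_TO_GAINS = {
    "wee": ("Wee", "WeELR"),
    "wei": ("Wei", "WeILR"),
    "wie": ("Wie", "WiELR"),
    "wii": ("Wii", "WiILR"),
}


def apply_discontinuity(spec: ModelSpec, weight_name: str, scale: float) -> ModelSpec:
    """Model a stimulus discontinuity as a loss of lateral recurrent drive.

    The named *effective* weight is multiplied by ``scale`` in [0, 1].  The
    reduction is taken from the lateral recurrent gain first (discontinuities
    remove lateral input), clamped at zero, with any remainder taken from the
    base gain.  Returns a new spec; the input is untouched.
    """
    if weight_name not in _WEIGHT_TO_GAINS:
        raise ValueError(f"unknown effective weight {weight_name!r}; "
                         f"expected one of {sorted(_WEIGHT_TO_GAINS)}")
    if not (0.0 <= scale <= 1.0):
        raise ValueError(f"scale must lie in [0, 1], got {scale}")
    base_name, lat_name = _WEIGHT_TO_GAINS[weight_name]
    base = getattr(spec.gains, base_name)
    lat = getattr(spec.gains, lat_name)
    reduction = (base + lat) * (1.0 - scale)
    lat_new = max(0.0, lat - reduction)
    base_new = base - max(0.0, reduction - lat)
    gains = replace(spec.gains, **{base_name: base_new, lat_name: lat_new})
    return replace(spec, gains=gains)


def _derivs(E, I, w: EffectiveWeights, spec: ModelSpec, iE, iI):
    dE = (-E + sigmoid_response(w.wee * E - w.wei * I + iE, spec.e_params)) / spec.taus.tau_e
    dI = (-I + sigmoid_response(w.wie * E - w.wii * I + iI, spec.i_params)) / spec.taus.tau_i
    return dE, dI


def integrate_grid(
    spec: ModelSpec,
    iE,
    iI,
    duration: float,
    dt: float = 0.05,
    initial_state=(0.0, 0.0),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Fixed-step RK4 integration, vectorized over arrays of (iE, iI).

    Returns (times, E, I) where E and I have shape (n_samples, *input_shape).
    The optional additive state noise (Euler-Maruyama increment after each
    RK4 step) is off by default; the reference simulations are deterministic.
    """
    iE = np.asarray(iE, dtype=float)
    iI = np.asarray(iI, dtype=float)
    if iE.shape != iI.shape:
        raise ValueError("iE and iI must have the same shape")
    if dt > spec.taus.tau_i / 50.0:
        raise ValueError(f"dt={dt} too coarse; require dt <= tau_i/50 = {spec.taus.tau_i / 50.0}")
    if duration < 10.0 * spec.taus.tau_e:
        raise ValueError(f"duration={duration} too short; require >= 10*tau_e")
    w = spec.weights
    n = int(round(duration / dt))
    E = np.full(iE.shape, float(initial_state[0]))
    I = np.full(iI.shape, float(initial_state[1]))
    lo_e, lo_i = spec.e_params.lower_offset, spec.i_params.lower_offset
    if not (lo_e <= E.min() and E.max() <= 1 + lo_e and lo_i <= I.min() and I.max() <= 1 + lo_i):
        raise ValueError("initial state outside the sigmoid range")
    out_E = np.empty((n + 1,) + iE.shape)
    out_I = np.empty((n + 1,) + iI.shape)
    out_E[0], out_I[0] = E, I
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng()
    half = 0.5 * dt
    for k in range(n):
        dE1, dI1 = _derivs(E, I, w, spec, iE, iI)
        dE2, dI2 = _derivs(E + half * dE1, I + half * dI1, w, spec, iE, iI)
        dE3, dI3 = _derivs(E + half * dE2, I + half * dI2, w, spec, iE, iI)
        dE4, dI4 = _derivs(E + dt * dE3, I + dt * dI3, w, spec, iE, iI)
        E = E + dt / 6.0 * (dE1 + 2 * dE2 + 2 * dE3 + dE4)
        I = I + dt / 6.0 * (dI1 + 2 * dI2 + 2 * dI3 + dI4)
        if noise_sd > 0:
            E = E + noise_sd * np.sqrt(dt) * rng.standard_normal(E.shape)
            I = I + noise_sd * np.sqrt(dt) * rng.standard_normal(I.shape)
            E = np.clip(E, lo_e, 1 + lo_e)
            I = np.clip(I, lo_i, 1 + lo_i)
        if k % 1000 == 0 and not (np.all(np.isfinite(E)) and np.all(np.isfinite(I))):
            raise FloatingPointError("E-I integration diverged (non-finite state)")
        out_E[k + 1], out_I[k + 1] = E, I
    if not (np.all(np.isfinite(out_E)) and np.all(np.isfinite(out_I))):
        raise FloatingPointError("E-I integration diverged (non-finite state)")
    times = np.arange(n + 1) * dt
    return times, out_E, out_I


def simulate(
    spec: ModelSpec,
    inp: ExternalInput,
    duration: float,
    dt: float = 0.05,
    initial_state=(0.0, 0.0),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate the network at a single operating point.

    Classical fixed-step RK4 with default dt = 0.05 ms; ``duration`` in ms.
    Deterministic unless ``noise_sd`` > 0.  Raises ``FloatingPointError`` on
    numerical blow-up (cannot occur for valid bounded-sigmoid specs).
    """
    times, E, I = integrate_grid(
        spec, np.asarray(inp.iE), np.asarray(inp.iI), duration, dt,
        initial_state=initial_state, noise_sd=noise_sd, rng=rng,
    )
    return Trajectory(times=times, E=E.reshape(len(times)), I=I.reshape(len(times)), dt=dt)
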