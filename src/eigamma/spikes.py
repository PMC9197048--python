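"""Spiking-unit processing and discontinuity-sensitivity statistics.

Firing rates are normalized per unit by the maximum across time and
conditions; per-condition scalar tuning values (for both normalized gamma
power and normalized firing rate) are regressed on discontinuity magnitude
to yield a sensitivity slope per site, and gamma-vs-rate slope magnitudes
are compared across sites with a Wilcoxon signed-rank (exact for small n)
or paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "SpikeSet",
    "NormalizedTuning",
    "RegressionResult",
    "TwoSidedRegressionResult",
    "PairedTestResult",
    "select_spiking_units",
    "normalized_rates",
    "rate_time_courses",
    "discontinuity_regression",
    "two_sided_regression",
    "signed_rank_test",
    "paired_comparison",
]

STIM_WINDOW = (0.25, 0.75)  # s after onset, the stimulus analysis epoch


@dataclass
class SpikeSet:
    """Per-unit, per-condition, per-trial spike times (s, onset-relative).

    ``trains[unit][condition]`` is a list of 1-D arrays, one per trial.
    """

    trains: Mapping[object, Mapping[object, Sequence[np.ndarray]]]
    trial_span: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValueError("empty spike set")
        lo, hi = self.trial_span
        for unit, conds in self.trains.items():
            for cond, trials in conds.items():
                for k, t in enumerate(trials):
                    t = np.asarray(t, dtype=float)
                    if t.size and (np.any(np.diff(t) < 0)):
                        raise ValueError(f"unit {unit} cond {cond} trial {k}: spike times not sorted")
                    if t.size and (t.min() < lo - 1e-9 or t.max() > hi + 1e-9):
                        raise ValueError(f"unit {unit} cond {cond} trial {k}: spikes outside trial span")

    @property
    def units(self) -> list:
        return list(self.trains)

    @property
    def conditions(self) -> list:
        first = next(iter(self.trains.values()))
        return list(first)


@dataclass
class NormalizedTuning:
    """Per-condition normalized scalar response of one site (max = 1)."""

    values: dict  # condition -> [0, 1]
    site: object = None
    quantity: str = "firing_rate"  # or "gamma_power"


@dataclass
class RegressionResult:
    slope: float  # change in normalized value per degree
    intercept: float
    n: int


@dataclass
class TwoSidedRegressionResult:
    slope_pos: float
    slope_neg: float
    mean_abs_slope: float
    n_pos: int
    n_neg: int


@dataclass
class PairedTestResult:
    statistic: float  # z-value (signed_rank) or t-value
    p_value: float
    n: int
    test_name: str
    degenerate: bool = False  # all paired differences were zero


def _window_rate(trials: Sequence[np.ndarray], window: tuple[float, float]) -> float:
    """Mean firing rate (spikes/s) inside a window, across trials."""
    lo, hi = window
    count = sum(int(np.count_nonzero((np.asarray(t) >= lo) & (np.asarray(t) <= hi))) for t in trials)
    return count / (len(trials) * (hi - lo))


def select_spiking_units(
    spikes: SpikeSet,
    stim_window: tuple[float, float] = STIM_WINDOW,
    min_rate: float = 1.0,
) -> list:
    """Units whose stimulus-window rate reaches ``min_rate`` spikes/s in at
    least one condition (boundary inclusive)."""
    keep = []
    for unit, conds in spikes.trains.items():
        if any(_window_rate(trials, stim_window) >= min_rate for trials in conds.values()):
            keep.append(unit)
    return keep


def rate_time_courses(
    spikes: SpikeSet,
    units: Sequence,
    bin_ms: float = 10.0,
    smooth_ms: float = 50.0,
) -> tuple[np.ndarray, dict]:
    """Trial-averaged smoothed firing-rate time courses per unit/condition.

    Returns (bin_centers_s, {unit: {condition: rate array in spikes/s}}).
    Rates are boxcar-smoothed over ``smooth_ms``.
    """
    lo, hi = spikes.trial_span
    edges = np.arange(lo, hi + 1e-12, bin_ms / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_smooth = max(1, int(round(smooth_ms / bin_ms)))
    kern = np.ones(n_smooth) / n_smooth
    out: dict = {}
    for unit in units:
        out[unit] = {}
        for cond, trials in spikes.trains[unit].items():
            counts = np.zeros(len(centers))
            for t in trials:
                counts += np.histogram(np.asarray(t), bins=edges)[0]
            rate = counts / (len(trials) * bin_ms / 1000.0)
            out[unit][cond] = np.convolve(rate, kern, mode="same")
    return centers, out


def normalized_rates(
    spikes: SpikeSet,
    units: Sequence,
    bin_ms: float = 10.0,
    smooth_ms: float = 50.0,
    stim_window: tuple[float, float] = STIM_WINDOW,
    scalar_norm: str = "condition_mean",
) -> tuple[dict, dict]:
    """Normalized rate time courses and per-condition scalar tuning.

    Time courses are divided per unit by the global maximum over time and
    conditions.  The scalar tuning value per condition is the unbinned mean
    rate over the stimulus window, normalized per unit by either the maximum
    of those condition means (``condition_mean``, default) or by the same
    global time-course maximum (``time_course_max``).

    Returns ({unit: {condition: normalized rate array}},
             {unit: NormalizedTuning}).
    """
    if scalar_norm not in ("condition_mean", "time_course_max"):
        raise ValueError("scalar_norm must be 'condition_mean' or 'time_course_max'")
    centers, courses = rate_time_courses(spikes, units, bin_ms, smooth_ms)
    norm_courses: dict = {}
    tuning: dict = {}
    for unit in units:
        gmax = max(float(r.max()) for r in courses[unit].values())
        if gmax <= 0:
            raise ValueError(f"unit {unit} has zero global maximum rate")
        norm_courses[unit] = {c: r / gmax for c, r in courses[unit].items()}
        means = {
            c: _window_rate(trials, stim_window)
            for c, trials in spikes.trains[unit].items()
        }
        denom = max(means.values()) if scalar_norm == "condition_mean" else gmax
        if denom <= 0:
            raise ValueError(f"unit {unit}: zero normalization denominator")
        tuning[unit] = NormalizedTuning(
            values={c: v / denom for c, v in means.items()}, site=unit, quantity="firing_rate"
        )
    return norm_courses, tuning


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate regressor (zero variance)")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def discontinuity_regression(
    values: Sequence[float] | Mapping[float, float],
    magnitudes: Sequence[float] | None = None,
) -> RegressionResult:
    """OLS slope of normalized response on discontinuity magnitude (degrees).

    Accepts either parallel sequences or a {magnitude: value} mapping;
    magnitudes must be strictly increasing and number at least 3.
    """
    if isinstance(values, Mapping):
        mags = np.array(sorted(values), dtype=float)
        vals = np.array([values[m] for m in mags])
    else:
        if magnitudes is None:
            raise ValueError("magnitudes required when values is a sequence")
        mags = np.asarray(magnitudes, dtype=float)
        vals = np.asarray(values, dtype=float)
    if len(mags) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.any(np.diff(mags) <= 0):
        raise ValueError("magnitudes must be strictly increasing")
    slope, intercept = _ols(mags, vals)
    return RegressionResult(slope=slope, intercept=intercept, n=len(mags))


def two_sided_regression(
    values: Mapping[float, float],
    subrange: float,
) -> TwoSidedRegressionResult:
    """Per-side slopes for symmetric discontinuities (orientation, phase).

    ``values`` maps signed magnitudes to normalized responses; each side is
    regressed on |magnitude| over 0..``subrange`` (inclusive, zero shared by
    both sides) and the magnitudes of the two slopes are averaged.
    """
    mags = np.array(sorted(values), dtype=float)
    vals = np.array([values[m] for m in mags])
    pos = (mags >= 0) & (mags <= subrange)
    neg = (mags <= 0) & (mags >= -subrange)
    if np.count_nonzero(pos) < 2 or np.count_nonzero(neg) < 2:
        raise ValueError("need at least 2 points on each side of zero")
    slope_p, _ = _ols(np.abs(mags[pos]), vals[pos])
    slope_n, _ = _ols(np.abs(mags[neg]), vals[neg])
    return TwoSidedRegressionResult(
        slope_pos=slope_p,
        slope_neg=slope_n,
        mean_abs_slope=0.5 * (abs(slope_p) + abs(slope_n)),
        n_pos=int(np.count_nonzero(pos)),
        n_neg=int(np.count_nonzero(neg)),
    )


def _exact_signed_rank_sf(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments, on doubled ranks.

    ``ranks2`` are tie-averaged ranks times 2 (integers).  Returns the pmf
    of the doubled statistic as counts (length sum(ranks2)+1).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def signed_rank_test(diffs: np.ndarray, exact_max_n: int = 25) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Ties get averaged ranks.  The p-value is
    exact (full distribution over sign assignments) for n <= ``exact_max_n``
    and a normal approximation with continuity and tie correction above.
    The reported statistic is the z-value in both cases.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, n=0,
                                test_name="signed_rank", degenerate=True)
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction for the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, n=n,
                                test_name="signed_rank", degenerate=True)
    z = (w_plus - mean) / np.sqrt(var)
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _exact_signed_rank_sf(ranks2)
        total = pmf.sum()
        w2 = int(round(2 * w_plus))
        p_lo = pmf[: w2 + 1].sum() / total
        p_hi = pmf[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        zc = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(2.0 * sstats.norm.sf(abs(zc)))
    return PairedTestResult(statistic=float(z), p_value=float(p), n=n, test_name="signed_rank")


def paired_comparison(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "signed_rank",
) -> PairedTestResult:
    """Paired comparison of two per-site value sets.

    ``signed_rank`` (default, used e.g. for |slope_gamma| vs |slope_rate|
    across sites) or ``t_two_sided``.  Requires n >= 5 pairs for the rank
    test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if test == "signed_rank":
        if len(a) < 5:
            raise ValueError("signed-rank comparison requires at least 5 pairs")
        return signed_rank_test(a - b)
    if test == "t_two_sided":
        if np.allclose(a, b):
            return PairedTestResult(statistic=0.0, p_value=1.0, n=len(a),
                                    test_name="t_two_sided", degenerate=True)
        t, p = sstats.ttest_rel(a, b)
        return PairedTestResult(statistic=float(t), p_value=float(p), n=len(a),
                                test_name="t_two_sided")
    raise ValueError(f"unknown test {test!r}")
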