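"""Ensemble change-point detection.

Two detector families — a Gaussian mean-shift cost and a nonparametric
empirical-distribution cost — are each solved either exactly (PELT
pruned dynamic programming) or greedily (binary segmentation) across a
grid of penalties, normalization options and sampling resolutions. Onsets
that recur across configurations form a time-binned occurrence
frequency; local maxima above a consensus threshold are retained and
near-coincident onsets are merged to their frequency-weighted mean time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from melophys.core import ConfigError, DataError, UniformSeries

#: Ensemble defaults (the source study defers exact values to
#: supplementary material; these are configurable stand-ins).
DEFAULT_CONSENSUS = 0.5      # minimum occurrence frequency tau
DEFAULT_TOLERANCE_S = 1.0    # half-width of the occurrence bin (+/- 1 s)
DEFAULT_MIN_SPACING_S = 5.0  # merge onsets closer than delta
DEFAULT_PENALTY_FACTORS = (0.5, 1.0, 2.0, 3.0)  # x log n


@dataclass(frozen=True)
class DetectorConfig:
    family: str = "mean"          # "mean" | "nonparametric"
    method: str = "pelt"          # "pelt" | "binseg"
    penalty_factor: float = 3.0   # penalty = factor * log(n); conservative
                                  # default so pure noise stays empty
    normalize: bool = True
    resolution_hz: float = 5.0

    def __post_init__(self):
        if self.family not in ("mean", "nonparametric"):
            raise ConfigError(f"unknown detector family {self.family!r}")
        if self.method not in ("pelt", "binseg"):
            raise ConfigError(f"unknown segmentation method {self.method!r}")
        if self.penalty_factor <= 0:
            raise ConfigError("penalty must be positive")
        if self.resolution_hz <= 0:
            raise ConfigError("resolution must be positive")


@dataclass(frozen=True)
class ChangePointSet:
    channel: str
    onsets: np.ndarray         # seconds, strictly increasing
    probabilities: np.ndarray  # occurrence frequency in [0, 1]
    categories: list           # e.g. "tempo_up" / annotation category
    flags: dict = field(default_factory=dict, compare=False)

    def __len__(self):
        return len(self.onsets)


def default_grid(resolutions=(5.0, 1.0), penalty_factors=DEFAULT_PENALTY_FACTORS):
    """The 2x2x4x2x|resolutions| default detector grid (64 configurations)."""
    return [
        DetectorConfig(family=f, method=m, penalty_factor=p, normalize=z, resolution_hz=r)
        for f, m, p, z, r in itertools.product(
            ("mean", "nonparametric"), ("pelt", "binseg"),
            penalty_factors, (True, False), resolutions)
    ]


# ---------------------------------------------------------------------------
# segment costs


class MeanCost:
    """Gaussian mean-shift cost: residual sum of squares around segment
    means, scaled by a robust noise-variance estimate so penalties are
    dimensionless."""

    min_size = 2

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DataError("series contains non-finite values")
        self.n = len(x)
        self.s1 = np.concatenate([[0.0], np.cumsum(x)])
        self.s2 = np.concatenate([[0.0], np.cumsum(x * x)])
        mad = np.median(np.abs(np.diff(x) - np.median(np.diff(x)))) if self.n > 1 else 0.0
        sigma2 = (mad / 0.6745) ** 2 / 2.0
        self.scale = max(sigma2, 1e-12)

    def seg(self, s, e):
        s = np.asarray(s)
        e = np.asarray(e)
        n = e - s
        rss = (self.s2[e] - self.s2[s]) - (self.s1[e] - self.s1[s]) ** 2 / n
        return np.maximum(rss, 0.0) / self.scale


class EmpiricalCost:
    """Nonparametric empirical-distribution cost over quantile bins.

    Segment cost is a Bernoulli log-likelihood of the segment's empirical
    CDF evaluated at ceil(log n) quantiles of the full series — a purely
    rank-based quantity, invariant under monotone value transforms.
    """

    min_size = 3

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DataError("series contains non-finite values")
        self.n = n = len(x)
        self.k = max(int(np.ceil(np.log(max(n, 2)))), 2)
        qs = (np.arange(self.k) + 0.5) / self.k
        tks = np.quantile(x, qs, method="inverted_cdf")
        # cum[k, i] = count of x_j <= t_k among the first i samples
        ind = (x[None, :] <= tks[:, None]).astype(float)
        self.cum = np.concatenate([np.zeros((self.k, 1)), np.cumsum(ind, axis=1)], axis=1)

    def seg(self, s, e):
        s, e = np.broadcast_arrays(np.asarray(s), np.asarray(e))
        n = (e - s).astype(float)
        p = (self.cum[:, e] - self.cum[:, s]) / n
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = p * np.log(p) + (1 - p) * np.log1p(-p)
        return -(2.0 / self.k) * n * ll.sum(axis=0)


def _make_cost(x, family: str):
    return MeanCost(x) if family == "mean" else EmpiricalCost(x)


# ---------------------------------------------------------------------------
# solvers


def pelt_segment(cost, penalty: float):
    """Exact penalized segmentation via PELT pruning.

    Returns sorted change indices (each the start of a new segment).
    """
    n = cost.n
    m = cost.min_size
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    # candidates appended as t - m + 1 are admissible from iteration t + 1,
    # so no per-iteration admissibility filter is needed
    cands = np.array([0], dtype=int)
    for t in range(m, n + 1):
        vals = f[cands] + cost.seg(cands, t)
        j = int(np.argmin(vals))
        f[t] = vals[j] + penalty
        prev[t] = cands[j]
        cands = np.append(cands[vals <= f[t]], t - m + 1)
    # backtrack
    cps = []
    t = n
    while t > 0:
        r = int(prev[t])
        if r > 0:
            cps.append(r)
        t = r
    return sorted(cps)


def binseg_segment(cost, penalty: float):
    """Greedy binary segmentation with the same cost/penalty objective."""
    n = cost.n
    m = cost.min_size
    cps = []
    stack = [(0, n)]
    while stack:
        s, e = stack.pop()
        if e - s < 2 * m:
            continue
        ts = np.arange(s + m, e - m + 1)
        gains = cost.seg(s, e) - cost.seg(np.full_like(ts, s), ts) - cost.seg(ts, np.full_like(ts, e))
        j = int(np.argmax(gains))
        if gains[j] > penalty:
            t = int(ts[j])
            cps.append(t)
            stack.append((s, t))
            stack.append((t, e))
    return sorted(cps)


def _decimate(x: np.ndarray, rate: float, target: float):
    """Block-mean downsampling to the detector's working resolution."""
    factor = int(round(rate / target))
    if factor <= 1:
        return x, rate
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1), rate / factor


def _detect(series: UniformSeries, config: DetectorConfig, family: str):
    x = series.values
    if not np.all(np.isfinite(x)):
        raise DataError("series contains non-finite values")
    x, work_rate = _decimate(x, series.rate, config.resolution_hz)
    if len(x) < 10:
        raise DataError("series too short at the chosen resolution")
    if config.normalize:
        sd = np.std(x)
        x = (x - np.mean(x)) / sd if sd > 0 else x - np.mean(x)
    cost = _make_cost(x, family)
    penalty = config.penalty_factor * np.log(len(x))
    solver = pelt_segment if config.method == "pelt" else binseg_segment
    idx = solver(cost, penalty)
    return series.start + np.asarray(idx, dtype=float) / work_rate


def detect_mean(series: UniformSeries, config: DetectorConfig) -> np.ndarray:
    """Mean-shift change-point onsets (seconds) for one configuration."""
    return _detect(series, config, "mean")


def detect_np(series: UniformSeries, config: DetectorConfig) -> np.ndarray:
    """Nonparametric (distribution-change) onsets for one configuration."""
    return _detect(series, config, "nonparametric")


# ---------------------------------------------------------------------------
# ensemble


def ensemble_detect(
    series: UniformSeries,
    grid=None,
    consensus: float = DEFAULT_CONSENSUS,
    min_spacing_s: float = DEFAULT_MIN_SPACING_S,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> ChangePointSet:
    """Consensus change points across a detector-configuration grid.

    Each configuration's onsets vote into an occurrence-frequency series
    with a +/- ``tolerance_s`` box kernel; local maxima with frequency
    >= ``consensus`` are retained, and retained onsets closer than
    ``min_spacing_s`` are merged at their frequency-weighted mean time.
    """
    if grid is None:
        grid = default_grid()
    if len(grid) == 0:
        raise ConfigError("detector grid is empty")
    if not (0 < consensus <= 1):
        raise ConfigError("consensus threshold must be in (0, 1]")
    if min_spacing_s <= 0:
        raise ConfigError("min spacing must be positive")

    grid_rate = series.rate
    n = len(series)
    votes = np.zeros(n)
    half = int(round(tolerance_s * grid_rate))
    for config in grid:
        onsets = _detect(series, config, config.family)
        mask = np.zeros(n, dtype=bool)  # one vote per config per bin
        for t in onsets:
            i = int(round((t - series.start) * grid_rate))
            mask[max(i - half, 0): min(i + half + 1, n)] = True
        votes += mask
    freq = votes / len(grid)

    peaks, props = sps.find_peaks(freq, height=consensus, plateau_size=1)
    # plateau midpoints (box kernels create flat tops)
    mids = (props["left_edges"] + props["right_edges"]) / 2.0
    times = series.start + mids / grid_rate
    probs = props["peak_heights"]

    times, probs = _merge_close(times, probs, min_spacing_s)
    return ChangePointSet(series.channel, times, probs, [series.channel] * len(times))


def _merge_close(times: np.ndarray, probs: np.ndarray, delta: float):
    """Merge onsets closer than delta to their probability-weighted mean."""
    times = np.asarray(times, dtype=float)
    probs = np.asarray(probs, dtype=float)
    while len(times) > 1:
        gaps = np.diff(times)
        if np.all(gaps >= delta):
            break
        j = int(np.argmin(gaps))
        w = probs[j] + probs[j + 1]
        merged_t = (times[j] * probs[j] + times[j + 1] * probs[j + 1]) / w
        merged_p = max(probs[j], probs[j + 1])
        times = np.concatenate([times[:j], [merged_t], times[j + 2:]])
        probs = np.concatenate([probs[:j], [merged_p], probs[j + 2:]])
    return times, probs


def directionize(series: UniformSeries, cps: ChangePointSet, window_s: float = 10.0) -> ChangePointSet:
    """Label each onset with the sign of (10 s post mean - 10 s pre mean).

    Ties (exact zero difference) are labelled "up" and flagged; onsets
    whose windows spill past the series support use truncated windows
    and are flagged as such.
    """
    t = series.times
    labels = []
    flagged = []
    for onset in cps.onsets:
        pre = series.values[(t >= onset - window_s) & (t < onset)]
        post = series.values[(t > onset) & (t <= onset + window_s)]
        if len(pre) == 0 or len(post) == 0:
            raise DataError(f"onset {onset} outside series support")
        truncated = onset - window_s < series.start or onset + window_s > series.end
        diff = float(np.mean(post) - np.mean(pre))
        if diff > 0:
            d = "up"
        elif diff < 0:
            d = "down"
        else:
            d = "up"
            truncated = True  # degenerate tie, flagged
        labels.append(f"{cps.channel}_{d}")
        flagged.append(truncated)
    return ChangePointSet(
        cps.channel, cps.onsets, cps.probabilities, labels,
        flags={"truncated_or_tied": flagged},
    )
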