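"""Gaussian-kernel event-density series and CCA input matrices.

Every change point contributes a unit-peak Gaussian bump; their sum per
channel forms a continuous event-density series. Physiological series
are averaged across listeners of a performance, and both sets are
sampled at the musical change-point onsets to build the CCA input
matrices X (musical, p = 12) and Y (physiological, q = 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from melophys.core import (
    ACOUSTIC_CHANNELS,
    ANNOTATION_CATEGORIES,
    PHYSIO_CHANNELS,
    ConfigError,
    DataError,
    UniformSeries,
)
from melophys.changepoints import _merge_close

#: Default Gaussian kernel width (s); the source analysis defers this to
#: supplementary material, so it is configurable throughout.
DEFAULT_SIGMA_S = 2.0

#: Column order of the musical matrix X: 5 acoustic channels then the 7
#: retained annotation categories (p = 12).
MUSIC_COLUMNS = tuple(ACOUSTIC_CHANNELS) + tuple(ANNOTATION_CATEGORIES)

#: Column order of the physiological matrix Y (q = 9).
PHYSIO_COLUMNS = tuple(PHYSIO_CHANNELS)


@dataclass(frozen=True)
class GKFSeries:
    label: str
    series: UniformSeries
    sigma_s: float
    peak: float = 1.0


@dataclass(frozen=True)
class CCAInputs:
    x: pd.DataFrame       # n x p, columns MUSIC_COLUMNS
    y: pd.DataFrame       # n x q, columns PHYSIO_COLUMNS
    index: pd.DataFrame   # per-row (piece, version, onset_s)

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise DataError("X and Y row counts differ")


def gkf(onsets, sigma_s: float, grid: np.ndarray, label: str = "", peak: float = 1.0) -> GKFSeries:
    """Sum of unit-peak Gaussian kernels centred at the onsets.

    value(t) = peak * sum_k exp(-(t - t_k)^2 / (2 sigma^2)); an empty
    onset list yields an all-zero series.
    """
    if sigma_s <= 0:
        raise ConfigError("kernel sigma must be positive")
    grid = np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for t_k in np.atleast_1d(np.asarray(onsets, dtype=float)):
        values += peak * np.exp(-((grid - t_k) ** 2) / (2 * sigma_s**2))
    rate = 1.0 / (grid[1] - grid[0])
    return GKFSeries(label, UniformSeries(label or "gkf", values, rate=rate, start=grid[0]), sigma_s, peak)


def average_listeners(series_by_listener: list) -> UniformSeries:
    """Pointwise mean of per-listener series sharing one grid."""
    if len(series_by_listener) == 0:
        raise DataError("no listeners to average")
    first = series_by_listener[0]
    for s in series_by_listener[1:]:
        if len(s) != len(first) or s.rate != first.rate or s.start != first.start:
            raise DataError("listener series grids do not match")
    mean = np.mean([s.values for s in series_by_listener], axis=0)
    out = first.with_values(mean)
    out.flags["n_listeners"] = len(series_by_listener)
    return out


def musical_onsets(acoustic_cps: dict, annotation_events: list, min_spacing_s: float = 5.0):
    """The row universe for one performance: union of consensus acoustic
    onsets and annotation onsets, deduplicated with the ensemble's merge
    rule (equal weights)."""
    times = []
    for cps in acoustic_cps.values():
        times.extend(cps.onsets)
    times.extend(t for t, _ in annotation_events)
    if not times:
        return np.empty(0)
    times = np.sort(np.asarray(times, dtype=float))
    merged, _ = _merge_close(times, np.ones_like(times), min_spacing_s)
    return merged


def assemble(x_sources: dict, y_sources: dict, rows: list) -> CCAInputs:
    """Sample GKF channels at musical change-point onsets.

    ``x_sources`` / ``y_sources`` map (performance_id, column) ->
    :class:`GKFSeries`; ``rows`` is a list of (piece, version, onset_s).
    Rows are ordered by (piece, version, onset).
    """
    rows = sorted(rows)
    x_data = np.zeros((len(rows), len(MUSIC_COLUMNS)))
    y_data = np.zeros((len(rows), len(PHYSIO_COLUMNS)))
    for i, (piece, version, onset) in enumerate(rows):
        perf = f"{piece}__{version}"
        for j, col in enumerate(MUSIC_COLUMNS):
            x_data[i, j] = _sample(x_sources, perf, col, onset, i)
        for j, col in enumerate(PHYSIO_COLUMNS):
            y_data[i, j] = _sample(y_sources, perf, col, onset, i)
    index = pd.DataFrame(rows, columns=["piece", "version", "onset_s"])
    return CCAInputs(
        x=pd.DataFrame(x_data, columns=list(MUSIC_COLUMNS)),
        y=pd.DataFrame(y_data, columns=list(PHYSIO_COLUMNS)),
        index=index,
    )


def _sample(sources, perf, col, onset, row):
    g = sources.get((perf, col))
    if g is None:
        raise DataError(f"row {row}: no source for {(perf, col)}")
    s = g.series
    if not (s.start <= onset <= s.end):
        raise DataError(f"row {row}: onset {onset:.2f} s outside support of {(perf, col)}")
    return float(s.value_at(onset))


def write_inputs(inputs: CCAInputs, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs.x.to_csv(out / "X.csv", index=False)
    inputs.y.to_csv(out / "Y.csv", index=False)
    inputs.index.to_json(out / "rows.json", orient="records", indent=1)
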