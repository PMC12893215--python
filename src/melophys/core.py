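"""Shared domain types and channel vocabularies."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

class ConfigError(ValueError):
    """Invalid configuration."""


class DataError(ValueError):
    """Input data violates a precondition."""


#: Default analysis grid rate (Hz). All derived channels live on this grid.
GRID_RATE_HZ = 5.0

#: Acoustic feature channels analysed for automatic change points.
ACOUSTIC_CHANNELS = ("tempo", "loudness", "spectral_centroid", "mfcc", "diameter")

#: Expert-annotation categories retained for analysis (>= 15 annotations
#: in the source study; the under-represented ones are never generated).
ANNOTATION_CATEGORIES = (
    "Novel Melody",
    "Return",
    "Resolve/Release",
    "Melodic Interaction",
    "Significant Melody",
    "Standout Articulation",
    "Runs/Fast Sequence",
)

#: The nine physiological analysis channels.
PHYSIO_CHANNELS = ("rr", "resp", "sys", "dia", "pp", "plf", "phf", "flf", "fhf")

#: Units per physiological channel.
PHYSIO_UNITS = {
    "rr": "s",
    "resp": "s",
    "sys": "mmHg",
    "dia": "mmHg",
    "pp": "mmHg",
    "plf": "ms^2",
    "phf": "ms^2",
    "flf": "Hz",
    "fhf": "Hz",
}


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled time series — the common currency of the pipeline.

    Parameters
    ----------
    channel : str
        Channel label (e.g. ``"rr"``, ``"tempo"``).
    values : np.ndarray
        Sample values; must be 1-D with at least two finite entries.
    rate : float
        Sample rate in Hz (default 5).
    start : float
        Time of the first sample in seconds.
    units : str
        Physical units of the values.
    """

    channel: str
    values: np.ndarray
    rate: float = GRID_RATE_HZ
    start: float = 0.0
    units: str = ""
    flags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("UniformSeries values must be 1-D")
        if len(values) < 2:
            raise ValueError("UniformSeries needs at least 2 samples")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.rate

    @property
    def end(self) -> float:
        return self.start + self.duration

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times (endpoints held)."""
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray, **kwargs) -> "UniformSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kwargs)


def common_grid(duration: float, rate: float = GRID_RATE_HZ, start: float = 0.0) -> np.ndarray:
    """Time grid [start, start + duration] sampled at ``rate``."""
    n = int(round(duration * rate)) + 1
    return start + np.arange(n) / rate
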