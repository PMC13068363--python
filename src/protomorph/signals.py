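"""Lightweight time-series container shared by the generators and analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A sampled scalar signal.

    Parameters
    ----------
    time_s : array of sample times in seconds (strictly increasing).
    values : array of samples, same length as ``time_s``.
    units : unit tag for ``values`` (e.g. ``"mV"``, ``"V"``, ``"ohm"``).
        Unit tags are mandatory on ingestion paths: a potential log in mV
        squared as if it were volts is off by 10^6 in energy.
    name : optional channel label.
    """

    time_s: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.ndim != 1 or self.values.ndim != 1:
            raise ValueError("time_s and values must be 1-D")
        if self.time_s.size != self.values.size:
            raise ValueError("time_s and values must have equal length")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True when sample spacing is constant to relative tolerance."""
        if len(self) < 3:
            return True
        dt = np.diff(self.time_s)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * abs(dt[0])))

    def sample_rate_hz(self) -> float:
        if len(self) < 2:
            raise ValueError("need at least two samples to infer a rate")
        if not self.is_uniform():
            raise ValueError("sampling is not uniform; resample first")
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def to_volts(self) -> "TimeSeries":
        """Return a copy expressed in volts; requires a recognised unit tag."""
        scale = {"V": 1.0, "v": 1.0, "mV": 1e-3, "mv": 1e-3, "uV": 1e-6}
        if self.units not in scale:
            raise ValueError(
                f"cannot convert units {self.units!r} to volts; tag the channel"
            )
        return TimeSeries(self.time_s, self.values * scale[self.units], "V", self.name)
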