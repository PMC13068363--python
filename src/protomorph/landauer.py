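"""Landauer-limit energy accounting for oscillatory events.

The Landauer bound E_L = k_B T ln 2 is the minimum energy that erasing one
bit of information must dissipate.  Measured dissipation is obtained by
integrating the instantaneous power V(t)^2 / R_eff over the record
(trapezoid rule), dividing by the number of detected events, and comparing
the per-event energy with E_L across effective-resistance regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import TimeSeries

__all__ = [
    "K_BOLTZMANN",
    "LandauerRegime",
    "LandauerReport",
    "landauer_limit",
    "energy_dissipation",
    "regime_report",
]

#: Boltzmann constant, CODATA exact value (J/K)
K_BOLTZMANN = 1.380649e-23


@dataclass
class LandauerRegime:
    label: str
    r_eff_ohm: float
    e_total_j: float
    e_event_j: float
    ratio_to_limit: float


@dataclass
class LandauerReport:
    temperature_k: float
    k_b: float
    e_limit_j_per_bit: float
    n_events: int
    regimes: list[LandauerRegime]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "regime": r.label,
                    "R (Ohm)": r.r_eff_ohm,
                    "E_total (J)": r.e_total_j,
                    "E_event (J)": r.e_event_j,
                    "E_event/E_L": r.ratio_to_limit,
                }
                for r in self.regimes
            ]
        )


def landauer_limit(temperature_k: float | np.ndarray) -> float | np.ndarray:
    """E_L = k_B T ln 2 in joules per bit; linear in T with slope k_B ln 2."""
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t < 0):
        raise ValueError("absolute temperature cannot be negative")
    out = K_BOLTZMANN * t * math.log(2.0)
    return float(out) if np.isscalar(temperature_k) else out


def energy_dissipation(potential_series_v: TimeSeries, r_eff_ohm: float) -> float:
    """Total dissipated energy: trapezoidal integral of V(t)^2 / R_eff.

    The series must carry a voltage unit tag; mV channels are converted to
    volts before squaring (a silent mV/V mixup is a 10^6 energy error).
    """
    if r_eff_ohm <= 0:
        raise ValueError("R_eff must be positive")
    series = potential_series_v.to_volts()
    power = series.values**2 / r_eff_ohm
    return float(np.trapezoid(power, series.time_s))


def regime_report(
    e_total_inputs: list[tuple],
    n_events: int,
    temperature_k: float = 298.15,
) -> LandauerReport:
    """Per-regime energy accounting against the Landauer limit.

    Each input is either ``(label, r_eff_ohm, e_total_j)`` — a precomputed
    total — or ``(label, r_eff_ohm, series)`` with a voltage
    :class:`~protomorph.signals.TimeSeries`, in which case the total is
    integrated here.  A single shared ``integral_v2_s`` (the value of
    ``∫V² dt`` in V²·s) may be passed instead of per-regime totals via
    ``(label, r_eff_ohm, None)`` entries plus the keyword-style tuple
    ``("__integral__", integral_v2_s)`` as the first element; then
    E_total = integral / R for every regime (inverse-R scaling).
    E_event = E_total / n_events and ratio = E_event / E_L(T).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    e_l = landauer_limit(temperature_k)

    shared_integral = None
    inputs = list(e_total_inputs)
    if inputs and inputs[0][0] == "__integral__":
        shared_integral = float(inputs[0][1])
        inputs = inputs[1:]

    regimes = []
    for entry in inputs:
        label, r_eff, third = entry
        if r_eff <= 0:
            raise ValueError("R_eff must be positive")
        if third is None:
            if shared_integral is None:
                raise ValueError(f"regime {label!r}: no energy input")
            e_total = shared_integral / r_eff
        elif isinstance(third, TimeSeries):
            e_total = energy_dissipation(third, r_eff)
        else:
            e_total = float(third)
        e_event = e_total / n_events
        regimes.append(
            LandauerRegime(
                label=label,
                r_eff_ohm=float(r_eff),
                e_total_j=e_total,
                e_event_j=e_event,
                ratio_to_limit=e_event / e_l,
            )
        )
    return LandauerReport(
        temperature_k=float(temperature_k),
        k_b=K_BOLTZMANN,
        e_limit_j_per_bit=float(e_l),
        n_events=int(n_events),
        regimes=regimes,
    )
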