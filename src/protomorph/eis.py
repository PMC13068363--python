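"""Electrochemical impedance records and derived quantities.

The central object is :class:`ImpedanceRecord`, one timestamped impedance
measurement.  Impedance follows the capacitive-system convention

    Z(omega) = Z' - j Z'' = |Z| e^{-j phi},

with the record storing a *positive* Z'' for capacitive behaviour and the
displayed phase being the negative of ``atan2(Z'', Z')``.  This is the
convention under which a tabulated positive Z'' of 0.384 ohm coexists with a
reported mean phase of -1.166 degrees.

Series capacitance is C_s = 1/(2 pi f Z''); a negative Z'' therefore yields a
negative C_s, which is reported as-is (negative capacitance excursions are
physically meaningful diagnostics of transient responses, not data errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signals import TimeSeries

__all__ = [
    "ImpedanceRecord",
    "CircuitParams",
    "RollingSummary",
    "complete_record",
    "equivalent_circuit_z",
    "rolling_summary",
    "summary_stats",
    "records_to_frame",
    "read_impedance_csv",
]

#: canonical column order for summary tables (units in headers)
SUMMARY_COLUMNS = [
    "freq (Hz)",
    "neg. phase (deg)",
    "Idc (uA)",
    "|Z| (Ohm)",
    "Z' (Ohm)",
    "Z'' (Ohm)",
    "Cs (F)",
    "phase (deg)",
    "mod |Z| (Ohm)",
]


@dataclass
class ImpedanceRecord:
    """One impedance measurement; unfilled fields are ``None``.

    All resistances are in ohms internally; readers accepting kOhm columns
    scale at ingestion.
    """

    time_s: float = 0.0
    freq_hz: float | None = None
    z_mag_ohm: float | None = None
    phase_deg: float | None = None  # signed phase of Z'' relative to Z' (atan2)
    z_real_ohm: float | None = None
    z_imag_ohm: float | None = None
    c_series_f: float | None = None
    i_dc_ua: float | None = None

    @property
    def neg_phase_deg(self) -> float | None:
        """Displayed phase under the Z = Z' - jZ'' convention."""
        if self.phase_deg is None:
            return None
        return -self.phase_deg


@dataclass(frozen=True)
class CircuitParams:
    """Randles-type equivalent circuit: R_s in series with (R_ct || C_dl)."""

    r_s_ohm: float
    r_ct_ohm: float
    c_dl_f: float

    def __post_init__(self) -> None:
        if self.r_s_ohm <= 0 or self.r_ct_ohm <= 0 or self.c_dl_f <= 0:
            raise ValueError("circuit parameters must be positive")


@dataclass
class RollingSummary:
    window: int
    center_times: np.ndarray
    means: np.ndarray
    stds: np.ndarray


def complete_record(partial: ImpedanceRecord) -> ImpedanceRecord:
    """Fill the derivable fields of a partially specified record.

    Requires either the Cartesian pair (Z', Z'') or the polar pair (|Z|, phi).
    |Z| = sqrt(Z'^2 + Z''^2), phi = atan2(Z'', Z') in degrees, and
    C_s = 1/(2 pi f Z'') when the frequency is known and Z'' is nonzero.
    """
    rec = replace(partial)
    have_cart = rec.z_real_ohm is not None and rec.z_imag_ohm is not None
    have_polar = rec.z_mag_ohm is not None and rec.phase_deg is not None
    if not (have_cart or have_polar):
        raise ValueError(
            "incomplete record: need (Z', Z'') or (|Z|, phase) to complete"
        )
    if have_cart:
        zr, zi = float(rec.z_real_ohm), float(rec.z_imag_ohm)
        rec.z_mag_ohm = math.hypot(zr, zi)
        rec.phase_deg = math.degrees(math.atan2(zi, zr))
    else:
        mag, phi = float(rec.z_mag_ohm), math.radians(float(rec.phase_deg))
        rec.z_real_ohm = mag * math.cos(phi)
        rec.z_imag_ohm = mag * math.sin(phi)
    if rec.freq_hz is not None and rec.z_imag_ohm != 0.0:
        rec.c_series_f = 1.0 / (2.0 * math.pi * rec.freq_hz * rec.z_imag_ohm)
    # Z'' == 0 leaves C_s undefined (None); a pure resistor is not an error.
    return rec


def equivalent_circuit_z(
    p: CircuitParams, freq_hz: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward-evaluate Z_total = R_s + R_ct / (1 + j omega R_ct C_dl).

    Returns ``(Z', Z'', |Z|, phase_deg)`` under the Z = Z' - jZ'' convention,
    i.e. Z'' is positive for this capacitive circuit at any finite nonzero
    frequency.  Accepts scalar or array frequency (Hz, >= 0).
    """
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    omega = 2.0 * math.pi * f
    z = p.r_s_ohm + p.r_ct_ohm / (1.0 + 1j * omega * p.r_ct_ohm * p.c_dl_f)
    z_real = np.real(z)
    z_imag = -np.imag(z)  # store positive Z'' for the capacitive branch
    z_mag = np.abs(z)
    phase = np.degrees(np.arctan2(z_imag, z_real))
    return z_real, z_imag, z_mag, phase


def rolling_summary(series: TimeSeries, window: int) -> RollingSummary:
    """Centered rolling mean and standard deviation.

    ``window`` must be odd and no longer than the series.  Edge positions use
    shrinking windows (``min_periods=1``), so the output has the same length
    as the input; single-sample windows report a std of 0.
    """
    n = len(series)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError("window longer than series")
    s = pd.Series(series.values)
    roll = s.rolling(window, center=True, min_periods=1)
    means = roll.mean().to_numpy()
    stds = roll.std(ddof=1).fillna(0.0).to_numpy()
    return RollingSummary(window, series.time_s.copy(), means, stds)


def records_to_frame(records: Sequence[ImpedanceRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical summary column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "time (s)": r.time_s,
                "freq (Hz)": r.freq_hz,
                "neg. phase (deg)": r.neg_phase_deg,
                "Idc (uA)": r.i_dc_ua,
                "|Z| (Ohm)": r.z_mag_ohm,
                "Z' (Ohm)": r.z_real_ohm,
                "Z'' (Ohm)": r.z_imag_ohm,
                "Cs (F)": r.c_series_f,
                "phase (deg)": -r.neg_phase_deg if r.neg_phase_deg is not None else None,
                "mod |Z| (Ohm)": r.z_mag_ohm,
            }
        )
    return pd.DataFrame(rows)


def summary_stats(records: Sequence[ImpedanceRecord] | pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics table for a set of impedance records.

    Rows: count, mean, std, min, 25%, 50%, 75%, max.  Columns follow the
    canonical order (frequency, negative phase, DC current, |Z|, Z', Z'',
    C_s, phase, and |Z| modulus repeated — the modulus column is a duplicate
    of |Z| kept for layout compatibility).  Quantiles use linear interpolation
    between order statistics; the std is the n-1 sample standard deviation and
    is reported as 0 for a single record.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if len(records) == 0:
            raise ValueError("no records")
        frame = records_to_frame(records)
    if len(frame) == 0:
        raise ValueError("no records")
    cols = [c for c in SUMMARY_COLUMNS if c in frame.columns]
    out = {}
    for c in cols:
        col = frame[c].astype(float)
        std = col.std(ddof=1)
        out[c] = {
            "count": float(col.count()),
            "mean": col.mean(),
            "std": 0.0 if math.isnan(std) else std,
            "min": col.min(),
            "25%": col.quantile(0.25, interpolation="linear"),
            "50%": col.quantile(0.50, interpolation="linear"),
            "75%": col.quantile(0.75, interpolation="linear"),
            "max": col.max(),
        }
    return pd.DataFrame(out)[cols]


#: recognised CSV header aliases -> record field
_COLUMN_ALIASES = {
    "time": "time_s",
    "time_s": "time_s",
    "t": "time_s",
    "freq": "freq_hz",
    "frequency": "freq_hz",
    "zmag": "z_mag_ohm",
    "|z|": "z_mag_ohm",
    "phase": "phase_deg",
    "zre": "z_real_ohm",
    "z'": "z_real_ohm",
    "zim": "z_imag_ohm",
    "z''": "z_imag_ohm",
    "cs": "c_series_f",
    "idc": "i_dc_ua",
}


def read_impedance_csv(
    path,
    column_map: dict[str, str] | None = None,
    resistance_unit: str = "ohm",
    decimal: str = ".",
) -> list[ImpedanceRecord]:
    """Read impedance records from a CSV export.

    Header names are matched case-insensitively against common aliases
    (time, freq, Zmag, phase, Zre, Zim, Cs, Idc); ``column_map`` overrides the
    mapping per file.  ``resistance_unit`` may be ``"ohm"`` or ``"kohm"``;
    kOhm columns are scaled to ohms on ingestion.
    """
    df = pd.read_csv(path, decimal=decimal)
    scale = {"ohm": 1.0, "kohm": 1e3}[resistance_unit]
    mapping = {}
    for col in df.columns:
        key = col.strip().lower()
        if column_map and col in column_map:
            mapping[col] = column_map[col]
        elif key in _COLUMN_ALIASES:
            mapping[col] = _COLUMN_ALIASES[key]
    if not mapping:
        raise ValueError(f"no recognised impedance columns in {list(df.columns)}")
    records = []
    ohm_fields = {"z_mag_ohm", "z_real_ohm", "z_imag_ohm"}
    for _, row in df.iterrows():
        kwargs = {}
        for col, field_name in mapping.items():
            val = float(row[col])
            if field_name in ohm_fields:
                val *= scale
            kwargs[field_name] = val
        records.append(ImpedanceRecord(**kwargs))
    return records
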