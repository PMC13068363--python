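"""Impedance-threshold Boolean logic transduction.

A continuous |Z| trace is binarised against a resistance threshold
(bit = 1 iff |Z| >= threshold), then consecutive bits form the two gate
inputs: A is the current sample, B the previous one.  Six gate channels
(AND, OR, XOR, NAND, NOR, NOT A) are evaluated elementwise; XOR spikes mark
the rising and falling edges of the thresholded signal, and maximal constant
runs are reported as plateaus ("memory" segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinarySequence",
    "GateTrace",
    "TransitionReport",
    "ThresholdSuggestion",
    "binarize",
    "eval_gate",
    "logic_trace",
    "detect_transitions",
    "suggest_threshold",
]

GATES = ("AND", "OR", "XOR", "NAND", "NOR", "NOT")


@dataclass
class BinarySequence:
    times_s: np.ndarray
    bits: np.ndarray  # values in {0, 1}
    threshold_ohm: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bits = np.asarray(self.bits, dtype=int)
        if self.times_s.size != self.bits.size:
            raise ValueError("times and bits must have equal length")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0 or 1")

    def __len__(self) -> int:
        return self.bits.size


@dataclass
class GateTrace:
    times_s: np.ndarray  # aligned to input A (current sample)
    input_a: np.ndarray
    input_b: np.ndarray
    and_out: np.ndarray
    or_out: np.ndarray
    xor_out: np.ndarray
    nand_out: np.ndarray
    nor_out: np.ndarray
    not_a_out: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times_s,
                "A": self.input_a,
                "B": self.input_b,
                "AND": self.and_out,
                "OR": self.or_out,
                "XOR": self.xor_out,
                "NAND": self.nand_out,
                "NOR": self.nor_out,
                "NOT_A": self.not_a_out,
            }
        )


@dataclass
class TransitionReport:
    rising: list[float]
    falling: list[float]
    plateaus: list[tuple[float, float, int]]  # (start_s, end_s, level)


@dataclass
class ThresholdSuggestion:
    threshold_ohm: float
    median_ohm: float
    fraction_above: float
    degenerate: bool
    gap_score: float


def binarize(values_ohm: np.ndarray, threshold_ohm: float,
             times_s: np.ndarray | None = None) -> BinarySequence:
    """Threshold a resistance trace to bits; the comparison is inclusive
    (a value exactly at the threshold maps to 1)."""
    values = np.asarray(values_ohm, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if threshold_ohm <= 0:
        raise ValueError("threshold must be positive")
    if times_s is None:
        times_s = np.arange(values.size, dtype=float)
    bits = (values >= threshold_ohm).astype(int)
    return BinarySequence(np.asarray(times_s, dtype=float), bits, threshold_ohm)


def eval_gate(gate: str, a: int, b: int | None = None) -> int:
    """Evaluate one Boolean gate on bit inputs.

    NOT takes a single input; the five binary gates require both.
    """
    gate = gate.upper()
    if gate == "NOT":
        if b is not None:
            raise ValueError("NOT takes exactly one input")
        return 1 - int(a)
    if b is None:
        raise ValueError(f"{gate} requires two inputs")
    a, b = int(a), int(b)
    if gate == "AND":
        return a & b
    if gate == "OR":
        return a | b
    if gate == "XOR":
        return a ^ b
    if gate == "NAND":
        return 1 - (a & b)
    if gate == "NOR":
        return 1 - (a | b)
    raise ValueError(f"unknown gate {gate!r}")


def logic_trace(bits: BinarySequence) -> GateTrace:
    """Evaluate all gate channels on temporally paired inputs.

    A = bits[1:], B = bits[:-1]; the first sample is dropped (its previous
    state is undefined, and padding B=0 would fabricate an initial XOR
    spike).  Outputs align to A's timestamps.
    """
    if len(bits) < 2:
        raise ValueError("need at least 2 samples")
    a = bits.bits[1:]
    b = bits.bits[:-1]
    return GateTrace(
        times_s=bits.times_s[1:],
        input_a=a,
        input_b=b,
        and_out=a & b,
        or_out=a | b,
        xor_out=a ^ b,
        nand_out=1 - (a & b),
        nor_out=1 - (a | b),
        not_a_out=1 - a,
    )


def detect_transitions(bits: BinarySequence) -> TransitionReport:
    """Edges and plateaus of a binary sequence.

    A rising edge is timestamped at the first 1 of each 0->1 flip, a falling
    edge at the first 0 of each 1->0 flip; plateaus are the maximal constant
    runs with their start/end times and level.
    """
    if len(bits) < 2:
        raise ValueError("need at least 2 samples")
    b = bits.bits
    t = bits.times_s
    d = np.diff(b)
    rising = t[1:][d == 1].tolist()
    falling = t[1:][d == -1].tolist()
    plateaus = []
    start = 0
    for i in range(1, len(b) + 1):
        if i == len(b) or b[i] != b[start]:
            plateaus.append((float(t[start]), float(t[i - 1]), int(b[start])))
            start = i
    return TransitionReport(rising, falling, plateaus)


def suggest_threshold(values_ohm: np.ndarray, n_bins: int = 20,
                      gap_floor: float = 0.05) -> ThresholdSuggestion:
    """Suggest a binarisation threshold from a bimodal value histogram.

    The candidate is the midpoint of the widest run of empty histogram bins
    between the two dominant clusters; the median and the fraction of
    samples above the candidate accompany it so the analyst can apply a
    "just below the median" rule.  When the histogram shows no usable gap
    (gap score below ``gap_floor`` as a fraction of the value range) the
    data are flagged degenerate and the median is returned.
    """
    values = np.asarray(values_ohm, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    med = float(np.median(values))
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return ThresholdSuggestion(med, med, 0.0, True, 0.0)
    counts, edges = np.histogram(values, bins=n_bins)
    # widest interior run of empty bins
    best_len, best_mid = 0, med
    run_start = None
    for i, c in enumerate(counts):
        if c == 0 and 0 < i < n_bins:
            if run_start is None:
                run_start = i
            if i - run_start + 1 > best_len and i < n_bins - 1:
                best_len = i - run_start + 1
                best_mid = 0.5 * (edges[run_start] + edges[i + 1])
        else:
            run_start = None
    gap_score = best_len * (edges[1] - edges[0]) / (hi - lo)
    if gap_score < gap_floor:
        return ThresholdSuggestion(med, med, float(np.mean(values >= med)),
                                   True, gap_score)
    frac_above = float(np.mean(values >= best_mid))
    return ThresholdSuggestion(float(best_mid), med, frac_above, False, gap_score)
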