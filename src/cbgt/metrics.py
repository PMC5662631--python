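"""Thalamic relay fidelity metrics: error index, rates, phase diagrams.

The error index (EI) quantifies degradation of thalamic throughput.
Response events in a thalamic voltage trace are classified against a
reference maximum (the cell's response amplitude in a healthy
calibration run): events reaching at least 90% of the reference are
*normal* peaks, events between 10% and 90% are *incomplete*, and
expected-response windows containing no event above 10% are *lost*
(the rest state).  EI is the number of incomplete peaks divided by the
number of normal peaks.

Expected-response windows tile the trace with the healthy rhythm's
inter-event period, because counting "lost" responses requires an
expectation of when responses should occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EIResult",
    "UndefinedEIError",
    "classify_peaks",
    "error_index",
    "calibrate_reference",
    "mean_firing_rate",
    "spikes_per_burst",
    "PhaseDiagram",
    "phase_diagram",
]


class UndefinedEIError(ZeroDivisionError):
    """EI is undefined when the trace contains no normal peaks."""


@dataclass(frozen=True)
class EIResult:
    """Peak counts and the error index of one trace."""

    n_lost: int
    n_incomplete: int
    n_normal: int
    peak_max: float

    @property
    def ei(self) -> float:
        if self.n_normal == 0:
            raise UndefinedEIError(
                "no normal peaks: the error index is undefined")
        return self.n_incomplete / self.n_normal


def _detect_events(trace: np.ndarray, dt: float, baseline: float,
                   floor: float, min_separation: float = 20.0):
    """(times, heights) of local maxima at least ``floor`` above baseline."""
    distance = max(int(round(min_separation / dt)), 1)
    idx, props = find_peaks(trace, height=baseline + floor,
                            distance=distance)
    heights = trace[idx] - baseline
    return idx * dt, heights


def classify_peaks(trace: np.ndarray, dt: float, baseline: float,
                   ref_max: float | None = None,
                   window: float | None = None,
                   t0: float = 0.0) -> EIResult:
    """Count lost / incomplete / normal response peaks in a trace.

    ``ref_max``: reference maximum response amplitude above baseline
    (from a healthy calibration run; defaults to the trace's own
    maximum).  ``window``: expected-response period (ms); windows
    ``[t0 + k*window, t0 + (k+1)*window)`` each contribute exactly one
    count.  With ``window=None`` every detected event is classified and
    nothing is counted lost.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must hold at least 2 samples")
    if ref_max is None:
        ref_max = float(trace.max() - baseline)
    if ref_max <= 0:
        raise ValueError("degenerate trace: reference maximum must be > 0")
    times, heights = _detect_events(trace, dt, baseline, 0.10 * ref_max)
    if window is None:
        n_normal = int(np.sum(heights >= 0.90 * ref_max))
        n_incomplete = int(len(heights) - n_normal)
        return EIResult(0, n_incomplete, n_normal, ref_max)
    t_end = len(trace) * dt
    n_lost = n_incomplete = n_normal = 0
    edges = np.arange(t0, t_end + 1e-9, window)
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (times >= a) & (times < b)
        if not sel.any():
            n_lost += 1
        elif heights[sel].max() >= 0.90 * ref_max:
            n_normal += 1
        else:
            n_incomplete += 1
    return EIResult(n_lost, n_incomplete, n_normal, ref_max)


def error_index(counts: EIResult) -> float:
    """EI = incomplete / normal (raises if no normal peaks)."""
    return counts.ei


def calibrate_reference(trace: np.ndarray, dt: float,
                        baseline: float) -> tuple[float, float]:
    """(ref_max, window) from a healthy-state trace.

    ref_max is the largest response amplitude above baseline; window is
    the median inter-event interval of responses exceeding half of it,
    i.e. the healthy rhythm's period.
    """
    trace = np.asarray(trace, dtype=float)
    ref_max = float(trace.max() - baseline)
    if ref_max <= 0:
        raise ValueError("degenerate calibration trace")
    times, heights = _detect_events(trace, dt, baseline, 0.5 * ref_max)
    if len(times) < 3:
        raise ValueError("calibration trace has too few response events")
    window = float(np.median(np.diff(times)))
    return ref_max, window


def mean_firing_rate(spike_times, window: float) -> float:
    """Spike count divided by the window (ms); returns Hz."""
    if window <= 0:
        raise ValueError("window must be positive")
    return len(np.asarray(spike_times)) / (window / 1000.0)


def spikes_per_burst(spike_times, isi_gap: float = 50.0) -> float:
    """Mean spikes per burst, bursts delimited by ISIs > isi_gap (ms)."""
    if isi_gap <= 0:
        raise ValueError("isi_gap must be positive")
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return 0.0
    groups = np.split(st, np.where(np.diff(st) > isi_gap)[0] + 1)
    return float(np.mean([len(g) for g in groups]))


@dataclass
class PhaseDiagram:
    """Time-aligned (v_gpi, v_th) pairs with conditional dispersion."""

    pairs: np.ndarray  # (n, 2)
    bin_centers: np.ndarray
    dispersion: np.ndarray  # std of v_th per v_gpi bin

    def mean_dispersion(self, v_gpi_min: float | None = None) -> float:
        """Average v_th spread, optionally only over bins above a
        v_gpi cutoff (e.g. -70 mV for the suprathreshold region)."""
        sel = np.isfinite(self.dispersion)
        if v_gpi_min is not None:
            sel &= self.bin_centers > v_gpi_min
        if not sel.any():
            return float("nan")
        return float(np.nanmean(self.dispersion[sel]))


def phase_diagram(gpi_trace: np.ndarray, th_trace: np.ndarray,
                  bin_width: float = 2.0) -> PhaseDiagram:
    """Pair the two voltage traces sample-by-sample.

    The dispersion summary is the standard deviation of v_th within
    each v_gpi bin: near zero everywhere when the thalamus responds
    deterministically to pallidal output, broad when the relay has
    broken down.
    """
    g = np.asarray(gpi_trace, dtype=float)
    t = np.asarray(th_trace, dtype=float)
    if g.shape != t.shape:
        raise ValueError("traces must have equal length")
    lo = np.floor(g.min() / bin_width) * bin_width
    hi = np.ceil(g.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 1e-9, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    disp = np.full(len(centers), np.nan)
    which = np.digitize(g, edges) - 1
    for b in range(len(centers)):
        sel = which == b
        if sel.sum() >= 5:
            disp[b] = t[sel].std()
    return PhaseDiagram(pairs=np.column_stack([g, t]),
                        bin_centers=centers, dispersion=disp)
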