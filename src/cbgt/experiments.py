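"""Scenario driver: lesion sweeps, depletion scans, cortical stimulation.

Each condition is simulated for ``trials`` independently seeded runs;
the thalamic error index (EI) and population firing rates are computed
per trial and summarized as mean +/- sd (or the five-number box summary
for stimulation grids).

The *normal band* of a metric is its mean +/- 2 sd over the trials of
the healthy (zero-depletion) condition; sweep results are judged
against that pre-registered band.  The EI reference (healthy response
amplitude and rhythm period) is calibrated once per seed from the
healthy run and reused for every lesioned condition of that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .engine import Recording, SimulationSpec, integrate
from .network import LesionSpec, NetworkConfig, build

__all__ = [
    "Scenario",
    "EIReference",
    "run_condition",
    "thalamic_ei",
    "calibrate_seed",
    "run_depletion_scan",
    "run_spine_sweep",
    "run_dendrite_sweep",
    "run_cortical_stim_grid",
    "DISCARD_MS",
]

#: initial transient discarded before computing metrics (ms)
DISCARD_MS = 500.0


@dataclass(frozen=True)
class Scenario:
    """A named sweep: base config, axis, grid, trials and seeds."""

    name: str
    base: NetworkConfig
    axis: str  # 'ns' | 'nd' | 'depletion' | 'stim'
    grid: tuple
    trials: int = 10
    seeds: tuple = ()
    duration: float = 2000.0

    def __post_init__(self):
        if not self.grid:
            raise ValueError("sweep grid must be non-empty")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclass
class EIReference:
    """Healthy-state calibration for the error index (one seed)."""

    ref_max: float
    window: float
    baseline: float


def _th_record(cfg: NetworkConfig):
    return tuple(("th", i) for i in range(cfg.n_th))


def run_condition(cfg: NetworkConfig, duration: float = 2000.0,
                  stimuli: tuple = (), extra_record: tuple = ()) -> Recording:
    """Build the network for ``cfg`` and integrate one trial."""
    nw = build(cfg)
    spec = SimulationSpec(duration=duration, stimuli=stimuli,
                          record=_th_record(cfg) + tuple(extra_record))
    return integrate(nw, spec)


def _baseline_of(trace: np.ndarray) -> float:
    return float(np.percentile(trace, 20.0))


def calibrate_seed(cfg: NetworkConfig, duration: float = 2000.0) -> EIReference:
    """Calibrate the EI reference from the healthy state of one seed."""
    ref, _ = _calibrate_with_recording(cfg, duration)
    return ref


def _calibrate_with_recording(cfg: NetworkConfig, duration: float):
    """(EIReference, healthy Recording) — the recording is reusable as
    the zero-depletion condition of the same seed."""
    healthy = replace(cfg, dopamine_depletion=0.0, lesion=LesionSpec())
    rec = run_condition(healthy, duration)
    n_skip = int(round(DISCARD_MS / rec.dt))
    refs, wins, bases = [], [], []
    for i in range(cfg.n_th):
        tr = rec.trace("th", i)[n_skip:]
        base = _baseline_of(tr)
        try:
            ref_max, window = metrics.calibrate_reference(tr, rec.dt, base)
        except ValueError:
            continue
        refs.append(ref_max)
        wins.append(window)
        bases.append(base)
    if not refs:
        raise RuntimeError("no thalamic cell produced a healthy rhythm "
                           "to calibrate the error index against")
    ref = EIReference(ref_max=float(np.median(refs)),
                      window=float(np.median(wins)),
                      baseline=float(np.median(bases)))
    return ref, rec


def thalamic_ei(rec: Recording, ref: EIReference,
                n_th: int) -> float:
    """Mean error index over thalamic cells for one trial.

    Cells with no normal peak contribute the incomplete/1 ratio
    computed with a single pseudo-normal count only if *no* cell has a
    normal peak; otherwise undefined cells are skipped.  Returns NaN if
    the EI is undefined for every cell.
    """
    n_skip = int(round(DISCARD_MS / rec.dt))
    eis = []
    for i in range(n_th):
        tr = rec.trace("th", i)[n_skip:]
        res = metrics.classify_peaks(tr, rec.dt, ref.baseline,
                                     ref_max=ref.ref_max,
                                     window=ref.window)
        if res.n_normal > 0:
            eis.append(res.ei)
    return float(np.mean(eis)) if eis else float("nan")


def _th_mfr(rec: Recording, n_th: int, duration: float) -> float:
    window = duration - DISCARD_MS
    rates = []
    for i in range(n_th):
        st = rec.spike_times("th", i)
        rates.append(metrics.mean_firing_rate(
            st[st >= DISCARD_MS], window))
    return float(np.mean(rates))


def _trial_seeds(seeds: Sequence[int] | None, trials: int,
                 base: int = 0) -> list[int]:
    if seeds is not None:
        seeds = list(seeds)
        if len(seeds) < trials:
            raise ValueError("need at least one seed per trial")
        return seeds[:trials]
    return [base + 1000 + 17 * k for k in range(trials)]


def run_depletion_scan(fractions: Sequence[float], trials: int = 10,
                       seeds: Sequence[int] | None = None,
                       duration: float = 2000.0,
                       base: NetworkConfig | None = None) -> pd.DataFrame:
    """TH firing rate and EI as dopamine depletion grows.

    Returns one row per depletion fraction with th_mfr/ei mean and sd
    over trials.  The fraction-0 rows define the normal bands
    (mean +/- 2 sd).
    """
    base = base or NetworkConfig()
    seeds = _trial_seeds(seeds, trials, base.seed)
    refs, healthy_recs = {}, {}
    for s in seeds:
        refs[s], healthy_recs[s] = _calibrate_with_recording(
            replace(base, seed=s), duration)
    rows = []
    for frac in fractions:
        mfrs, eis = [], []
        for s in seeds:
            cfg = replace(base, seed=s, dopamine_depletion=float(frac))
            if frac == 0.0 and not (base.lesion.ns or base.lesion.nd):
                rec = healthy_recs[s]  # identical condition: reuse
            else:
                rec = run_condition(cfg, duration)
            mfrs.append(_th_mfr(rec, cfg.n_th, duration))
            eis.append(thalamic_ei(rec, refs[s], cfg.n_th))
        rows.append(dict(fraction=float(frac),
                         th_mfr=np.mean(mfrs), th_mfr_sd=np.std(mfrs),
                         ei=np.nanmean(eis), ei_sd=np.nanstd(eis),
                         n_trials=len(seeds)))
    return pd.DataFrame(rows)


def _lesion_sweep(axis: str, depletion: float, grid: Sequence[int],
                  trials: int, seeds: Sequence[int] | None,
                  duration: float, base: NetworkConfig | None,
                  spine_order: str = "type1_first") -> pd.DataFrame:
    base = base or NetworkConfig()
    seeds = _trial_seeds(seeds, trials, base.seed)
    refs = {s: calibrate_seed(replace(base, seed=s), duration)
            for s in seeds}
    rows = []
    for val in grid:
        eis, mfrs = [], []
        for s in seeds:
            lesion = (LesionSpec(ns=int(val), spine_order=spine_order)
                      if axis == "ns" else LesionSpec(nd=int(val)))
            cfg = replace(base, seed=s, dopamine_depletion=depletion,
                          lesion=lesion)
            rec = run_condition(cfg, duration)
            eis.append(thalamic_ei(rec, refs[s], cfg.n_th))
            mfrs.append(_th_mfr(rec, cfg.n_th, duration))
        rows.append({axis: int(val), f"{axis}_fraction": val / 32.0,
                     "ei": np.nanmean(eis), "ei_sd": np.nanstd(eis),
                     "th_mfr": np.mean(mfrs), "n_trials": len(seeds)})
    return pd.DataFrame(rows)


def run_spine_sweep(depletion_fraction: float, ns_grid: Sequence[int],
                    trials: int = 10, seeds: Sequence[int] | None = None,
                    duration: float = 2000.0,
                    base: NetworkConfig | None = None) -> pd.DataFrame:
    """EI versus spine loss (type-1-first ordering) at fixed depletion."""
    if any(not 0 <= v <= 32 for v in ns_grid):
        raise ValueError("ns grid values must lie in 0..32")
    return _lesion_sweep("ns", depletion_fraction, ns_grid, trials, seeds,
                         duration, base)


def run_dendrite_sweep(depletion_fraction: float, nd_grid: Sequence[int],
                       trials: int = 10,
                       seeds: Sequence[int] | None = None,
                       duration: float = 2000.0,
                       base: NetworkConfig | None = None) -> pd.DataFrame:
    """EI versus dendrite-tree degeneration at fixed depletion."""
    if any(not 0 <= v <= 32 for v in nd_grid):
        raise ValueError("nd grid values must lie in 0..32")
    return _lesion_sweep("nd", depletion_fraction, nd_grid, trials, seeds,
                         duration, base)


def run_cortical_stim_grid(depletion: float, amp_grid: Sequence[float],
                           freq_grid: Sequence[float], trials: int = 10,
                           seeds: Sequence[int] | None = None,
                           duration: float = 2000.0,
                           base: NetworkConfig | None = None) -> pd.DataFrame:
    """EI five-number summaries under sinusoidal cortical stimulation.

    ``I_stim = A sin(omega t)`` is injected into every pyramidal cell;
    the grid crosses amplitudes (uA/cm^2) with frequencies (Hz).  Each
    cell of the grid reports min, q1, median, q3, max of the trial EIs,
    plus the unstimulated rows (amplitude 0) for reference.
    """
    base = base or NetworkConfig()
    seeds = _trial_seeds(seeds, trials, base.seed)
    refs = {s: calibrate_seed(replace(base, seed=s), duration)
            for s in seeds}
    rows = []
    for amp in amp_grid:
        for freq in freq_grid:
            eis = []
            for s in seeds:
                cfg = replace(base, seed=s, dopamine_depletion=depletion)
                stim = (("py", {"kind": "sine", "amplitude": float(amp),
                                "freq_hz": float(freq)}),)
                rec = run_condition(cfg, duration, stimuli=stim)
                eis.append(thalamic_ei(rec, refs[s], cfg.n_th))
            eis = np.asarray(eis, dtype=float)
            good = eis[np.isfinite(eis)]
            q = (np.percentile(good, [0, 25, 50, 75, 100])
                 if good.size else [np.nan] * 5)
            rows.append(dict(amplitude=float(amp), freq_hz=float(freq),
                             ei_min=q[0], ei_q1=q[1], ei_median=q[2],
                             ei_q3=q[3], ei_max=q[4],
                             n_defined=int(good.size)))
    return pd.DataFrame(rows)
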