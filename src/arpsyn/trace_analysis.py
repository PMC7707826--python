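"""Analysis of pyrene-actin polymerization time courses.

Pyrene fluorescence is proportional to filamentous actin, so a plate-reader
trace (RFU vs time) can be converted to polymer concentration given two
anchors: filament concentration is zero at the minimum fluorescence, and the
critical concentration (0.1 uM by default) remains unpolymerized at the
maximum fluorescence.  The maximum polymerization rate of a trace is the
largest local slope, converted from RFU/s to nM/s.  Titrating Dip1 and
plotting maximum rates yields a hyperbolic saturation curve

    rate([Dip1]) = rate_max * [Dip1] / (K_half + [Dip1]) + y_intercept

whose plateau (y_intercept + rate_max) is the saturating-Dip1 rate; the ratio
of plateaus between +Wsp1-VCA and -Wsp1-VCA arms measures NPF synergy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

#: Sliding OLS window (samples) used for slope estimation; at the typical
#: plate-reader sampling of ~10 s this spans ~100 s.
SLOPE_WINDOW = 11


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """Two-point RFU <-> actin conversion shared by one trace set."""

    f_min: float
    f_max: float
    total_actin_uM: float
    unpolymerized_uM: float = 0.1

    def __post_init__(self) -> None:
        if self.f_max <= self.f_min:
            raise ValueError("calibration requires f_max > f_min")
        if not (self.total_actin_uM > self.unpolymerized_uM >= 0):
            raise ValueError("need total actin > unpolymerized-at-plateau >= 0")

    @property
    def nm_per_rfu(self) -> float:
        span = self.total_actin_uM - self.unpolymerized_uM
        return span * 1000.0 / (self.f_max - self.f_min)

    def to_filament_uM(self, signal: np.ndarray) -> np.ndarray:
        return (np.asarray(signal) - self.f_min) * self.nm_per_rfu / 1000.0

    def to_rfu(self, filament_uM: np.ndarray) -> np.ndarray:
        return self.f_min + np.asarray(filament_uM) * 1000.0 / self.nm_per_rfu


@dataclass
class Condition:
    """Biochemical composition of one polymerization reaction."""

    actin_uM: float = 3.0
    pyrene_fraction: float = 0.15
    arp23_nM: float = 0.0
    dip1_uM: float = 0.0
    wsp1: str = "none"        # none | VCA | GST-VCA | CA
    wsp1_uM: float = 0.0


@dataclass
class PolymerizationTrace:
    """One fluorescence time course with its condition and calibration."""

    time: np.ndarray
    signal: np.ndarray
    condition: Condition
    calibration: Calibration
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def filament_uM(self) -> np.ndarray:
        return self.calibration.to_filament_uM(self.signal)


@dataclass
class TraceSet:
    """A family of traces sharing one calibration."""

    traces: list[PolymerizationTrace]
    calibration: Calibration

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def by_id(self, trace_id: str) -> PolymerizationTrace:
        for tr in self.traces:
            if tr.trace_id == trace_id:
                return tr
        raise KeyError(trace_id)

    def actin_alone(self) -> PolymerizationTrace | None:
        """The set's actin-alone control (no Arp2/3, no NPFs), if present."""
        for tr in self.traces:
            c = tr.condition
            if c.arp23_nM == 0 and c.dip1_uM == 0 and c.wsp1_uM == 0:
                return tr
        return None


@dataclass
class SaturationFit:
    """Hyperbolic fit of maximum polymerization rate vs [Dip1]."""

    max_rate_max: float   # nM/s
    k_half: float         # uM Dip1
    y_intercept: float    # nM/s
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    identifiable: bool = True

    @property
    def plateau(self) -> float:
        """Fitted rate in the saturating-Dip1 limit."""
        return self.y_intercept + self.max_rate_max

    def predict(self, dip1_uM: np.ndarray) -> np.ndarray:
        x = np.asarray(dip1_uM, dtype=float)
        return self.max_rate_max * x / (self.k_half + x) + self.y_intercept


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sliding_slopes(time: np.ndarray, signal: np.ndarray,
                   window: int = SLOPE_WINDOW) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint slope by OLS over a sliding window.

    Returns (window-center times, slopes).  Windows are fully interior, so
    the first and last ``window//2`` points carry no slope estimate.
    """
    if len(time) < window:
        raise ValueError(f"trace shorter than the {window}-point slope window")
    tw = sliding_window_view(np.asarray(time, float), window)
    sw = sliding_window_view(np.asarray(signal, float), window)
    tm = tw.mean(axis=1, keepdims=True)
    sm = sw.mean(axis=1, keepdims=True)
    dt = tw - tm
    slopes = (dt * (sw - sm)).sum(axis=1) / (dt * dt).sum(axis=1)
    centers = tw[:, window // 2]
    return centers, slopes


def max_poly_rate(trace: PolymerizationTrace, window: int = SLOPE_WINDOW) -> float:
    """Maximum polymerization rate of one trace, in nM actin / s.

    The slope is estimated at every interior time point by local linear
    regression and the maximum is converted from RFU/s using the set's
    two-point calibration.
    """
    _, slopes = sliding_slopes(trace.time, trace.signal, window)
    return float(slopes.max() * trace.calibration.nm_per_rfu)


def max_rates_table(traces: TraceSet, window: int = SLOPE_WINDOW) -> pd.DataFrame:
    """Maximum polymerization rate for every trace, with its condition."""
    rows = []
    for tr in traces:
        c = tr.condition
        rows.append({
            "trace_id": tr.trace_id, "actin_uM": c.actin_uM,
            "arp23_nM": c.arp23_nM, "dip1_uM": c.dip1_uM,
            "wsp1": c.wsp1, "wsp1_uM": c.wsp1_uM,
            "max_rate_nM_s": max_poly_rate(tr, window),
        })
    return pd.DataFrame(rows)


def _hyperbola(x, rate_max, k_half, y0):
    return rate_max * x / (k_half + x) + y0


def fit_saturation(points: list[tuple[float, float]] | np.ndarray) -> SaturationFit:
    """Nonlinear least-squares fit of the Dip1 saturation hyperbola.

    ``points`` are ([Dip1] in uM, max rate in nM/s) pairs covering at least
    four distinct Dip1 concentrations including zero.  A design in which the
    rates do not respond to Dip1 is flagged non-identifiable instead of
    silently fitted.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 4 or 0.0 not in x:
        raise ValueError("need >= 4 distinct Dip1 concentrations including 0")

    span = float(y.max() - y.min())
    scale = max(float(np.abs(y).max()), 1e-12)
    if span <= 1e-9 * scale:
        return SaturationFit(0.0, np.inf, float(y.mean()),
                             residuals=y - y.mean(), identifiable=False)

    y0_guess = float(y[x == 0].mean())
    k_guess = max(float(np.median(x[x > 0])), 1e-3)
    p0 = (max(span, 1e-9), k_guess, y0_guess)
    popt, _ = curve_fit(
        _hyperbola, x, y, p0=p0, maxfev=20000,
        bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
    )
    rate_max, k_half, y0 = (float(v) for v in popt)
    fit = SaturationFit(rate_max, k_half, y0, residuals=y - _hyperbola(x, *popt))
    # Flat-line degeneracies: vanishing amplitude or K far beyond the design.
    if rate_max <= 1e-6 * scale or k_half > 1e3 * x.max():
        fit.identifiable = False
    return fit


def plateau_ratio(fit_plus: SaturationFit, fit_minus: SaturationFit) -> float:
    """Fold-change of the saturating-Dip1 rate, +Wsp1 over -Wsp1."""
    if fit_minus.plateau <= 0:
        raise ValueError("reference plateau must be positive")
    return fit_plus.plateau / fit_minus.plateau


# ---------------------------------------------------------------------------
# TSV I/O (long-format traces + condition table keyed by trace_id)
# ---------------------------------------------------------------------------

_COND_COLS = ["trace_id", "actin_uM", "pyrene_fraction", "arp23_nM",
              "dip1_uM", "wsp1", "wsp1_uM",
              "f_min", "f_max", "total_actin_uM", "unpolymerized_uM"]


def write_trace_set(ts: TraceSet, traces_path, conditions_path) -> None:
    long = pd.concat(
        [pd.DataFrame({"time_s": tr.time, "rfu": tr.signal, "trace_id": tr.trace_id})
         for tr in ts],
        ignore_index=True,
    )
    long.to_csv(traces_path, sep="\t", index=False, float_format="%.6f")
    cal = ts.calibration
    rows = []
    for tr in ts:
        c = tr.condition
        rows.append([tr.trace_id, c.actin_uM, c.pyrene_fraction, c.arp23_nM,
                     c.dip1_uM, c.wsp1, c.wsp1_uM,
                     cal.f_min, cal.f_max, cal.total_actin_uM, cal.unpolymerized_uM])
    pd.DataFrame(rows, columns=_COND_COLS).to_csv(
        conditions_path, sep="\t", index=False, float_format="%.6f")


def read_trace_set(traces_path, conditions_path) -> TraceSet:
    long = pd.read_csv(traces_path, sep="\t")
    cond = pd.read_csv(conditions_path, sep="\t").set_index("trace_id")
    first = cond.iloc[0]
    cal = Calibration(float(first.f_min), float(first.f_max),
                      float(first.total_actin_uM), float(first.unpolymerized_uM))
    traces = []
    for tid, grp in long.groupby("trace_id", sort=False):
        row = cond.loc[tid]
        condition = Condition(float(row.actin_uM), float(row.pyrene_fraction),
                              float(row.arp23_nM), float(row.dip1_uM),
                              str(row.wsp1), float(row.wsp1_uM))
        traces.append(PolymerizationTrace(
            grp.time_s.to_numpy(), grp.rfu.to_numpy(), condition, cal, str(tid)))
    return TraceSet(traces, cal)
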