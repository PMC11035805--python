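"""Growth and metabolite kinetics for expansion cultures.

Per-interval quantities derived from a sampled culture time course:

* population doublings  PD_n = log2(C_n / C_{n-1}) and their running sum cPD
* cell-fold increase    fold = 2**cPD
* specific growth rate  mu_n = ln(C_n / C_{n-1}) / dt   [1/day]
* specific consumption  q_met,n (glucose, glutamine)    [per cell per day]
* specific production   p_met,n (lactate, ammonia)      [per cell per day]
* lactate-from-glucose yield dLac/dGluc                 [mol/mol]

The consumption/production rates correct for exponential growth over the
interval and for perfusion dilution (fraction ``d`` of the culture volume
exchanged per day against fresh medium at concentration ``m_x``):

    q = (mu / C_prev) * ((c_prev*(1-d) + m_x*d) - c_now) / (exp(mu*dt) - 1)
    p = (mu / C_prev) * (c_now - c_prev*(1-d))           / (exp(mu*dt) - 1)

When ``|mu|*dt`` is tiny the ``exp(mu*dt)-1`` denominator underflows; the
analytic mu->0 limit (difference over ``C_prev*dt``) is used instead.

Sign convention: a decreasing consumed analyte gives q > 0; an increasing
produced analyte gives p > 0. Negative values are reported as-is (net
production of a nominally consumed analyte and vice versa), never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ANALYTES = ("glucose", "lactate", "glutamine", "ammonia")
CONSUMED_ANALYTES = ("glucose", "glutamine")
PRODUCED_ANALYTES = ("lactate", "ammonia")

#: below this |mu|*dt the analytic small-growth limit replaces the full formula
MU_DT_SWITCH = 1e-8

#: default averaging window (days) spanning the exponential expansion phase
DEFAULT_WINDOW = (2.0, 7.0)

LN2 = math.log(2.0)


class KineticsError(ValueError):
    """Domain error in a kinetic computation (non-positive counts, bad window)."""


class UndefinedYieldError(KineticsError):
    """dLac/dGluc denominator (change in specific glucose consumption) is zero."""


@dataclass(frozen=True)
class CultureTimeSeries:
    """One run's sampled growth curve.

    ``perfusion_rate[i]`` is the daily fraction of volume exchanged during the
    interval ending at ``times[i]`` (entry 0 is unused and must be 0).
    """

    run_id: str
    donor_id: str
    times: np.ndarray           # days, strictly increasing
    viable_density: np.ndarray  # cells/mL, > 0
    viability: np.ndarray       # percent, [0, 100]
    volume_ml: np.ndarray       # mL, > 0
    perfusion_rate: np.ndarray  # per-day fraction in [0, 1)

    def __post_init__(self) -> None:
        for name in ("times", "viable_density", "viability", "volume_ml", "perfusion_rate"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if n < 2:
            raise KineticsError(f"run {self.run_id}: need at least 2 timepoints, got {n}")
        for name in ("viable_density", "viability", "volume_ml", "perfusion_rate"):
            if getattr(self, name).size != n:
                raise KineticsError(f"run {self.run_id}: field {name} length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise KineticsError(f"run {self.run_id}: sampling times must be strictly increasing")
        if np.any(self.viable_density <= 0):
            raise KineticsError(f"run {self.run_id}: viable densities must be positive")
        if np.any((self.viability < 0) | (self.viability > 100)):
            raise KineticsError(f"run {self.run_id}: viability outside [0, 100]")
        if np.any(self.volume_ml <= 0):
            raise KineticsError(f"run {self.run_id}: volumes must be positive")
        if np.any((self.perfusion_rate < 0) | (self.perfusion_rate >= 1)):
            raise KineticsError(f"run {self.run_id}: perfusion rate must lie in [0, 1)")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def cell_number(self) -> np.ndarray:
        """Total viable cells per timepoint (density x volume)."""
        return self.viable_density * self.volume_ml


@dataclass(frozen=True)
class MetabolitePanel:
    """Concentration trace for one analyte of one run, aligned to the culture's
    sampling times, plus the fresh-feed concentration used under perfusion."""

    run_id: str
    analyte: str
    concentrations: np.ndarray      # mmol/L per timepoint
    feed_concentration: float = 0.0  # mmol/L

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise KineticsError(
                f"unknown analyte {self.analyte!r}; accepted: {', '.join(ANALYTES)}"
            )
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if np.any(self.concentrations < 0):
            raise KineticsError(f"run {self.run_id}: negative {self.analyte} concentration")
        if self.feed_concentration < 0:
            raise KineticsError(f"run {self.run_id}: negative feed concentration")


# ---------------------------------------------------------------------------
# elementary growth quantities
# ---------------------------------------------------------------------------

def population_doublings(c_prev: float, c_now: float) -> float:
    """Doublings over one interval, log2(c_now / c_prev); negative if shrinking."""
    if c_prev <= 0 or c_now <= 0:
        raise KineticsError(f"cell counts must be positive (got {c_prev}, {c_now})")
    return math.log2(c_now / c_prev)


def cumulative_pd(pd_series) -> np.ndarray:
    """Running sum of per-interval doublings."""
    arr = np.asarray(pd_series, dtype=float)
    return np.cumsum(arr) if arr.size else arr


def cell_fold(cpd_final: float) -> float:
    """Fold increase implied by cumulative doublings, 2**cPD."""
    return float(2.0 ** cpd_final)


def specific_growth_rate(c_prev: float, c_now: float, dt: float) -> float:
    """Exponential growth rate ln(c_now / c_prev) / dt, in 1/day."""
    if dt <= 0:
        raise KineticsError(f"dt must be positive (got {dt})")
    return population_doublings(c_prev, c_now) * LN2 / dt


# ---------------------------------------------------------------------------
# specific consumption / production (growth- and perfusion-corrected)
# ---------------------------------------------------------------------------

def _rate(mu: float, c_x_prev: float, numerator: float, dt: float) -> float:
    if c_x_prev <= 0:
        raise KineticsError(f"previous cell count must be positive (got {c_x_prev})")
    if dt <= 0:
        raise KineticsError(f"dt must be positive (got {dt})")
    if abs(mu * dt) < MU_DT_SWITCH:
        # analytic mu -> 0 limit: mu / (exp(mu dt) - 1) -> 1 / dt
        return numerator / (c_x_prev * dt)
    return (mu / c_x_prev) * numerator / math.expm1(mu * dt)


def specific_consumption(
    mu: float,
    c_x_prev: float,
    conc_prev: float,
    conc_now: float,
    feed_conc: float = 0.0,
    d: float = 0.0,
    dt: float = 1.0,
) -> float:
    """Per-cell consumption rate of an analyte over one interval.

    Positive when the analyte is depleted faster than perfusion replaces it.
    Units follow the inputs: concentration units per cell per day.
    """
    if not 0.0 <= d < 1.0:
        raise KineticsError(f"perfusion fraction must lie in [0, 1) (got {d})")
    mixed_prev = conc_prev * (1.0 - d) + feed_conc * d
    return _rate(mu, c_x_prev, mixed_prev - conc_now, dt)


def specific_production(
    mu: float,
    c_x_prev: float,
    conc_prev: float,
    conc_now: float,
    d: float = 0.0,
    dt: float = 1.0,
) -> float:
    """Per-cell production rate of an analyte over one interval.

    Positive when the analyte accumulates beyond what perfusion washes out.
    """
    if not 0.0 <= d < 1.0:
        raise KineticsError(f"perfusion fraction must lie in [0, 1) (got {d})")
    return _rate(mu, c_x_prev, conc_now - conc_prev * (1.0 - d), dt)


def lactate_glucose_yield(
    p_lac_final: float, p_lac_initial: float,
    q_gluc_final: float, q_gluc_initial: float,
) -> float:
    """Moles of lactate produced per mole of glucose consumed.

    Ratio of the change in specific lactate production to the change in
    specific glucose consumption between the initial and final timepoints of
    the evaluation window. 2.0 is the pure-glycolysis ceiling (2 mol lactate
    per mol glucose); lower values indicate oxidative glucose use.
    """
    dq = q_gluc_final - q_gluc_initial
    if dq == 0.0:
        raise UndefinedYieldError(
            "glucose consumption rate did not change between the window endpoints "
            f"(q_final = q_initial = {q_gluc_final!r}); dLac/dGluc is undefined"
        )
    return (p_lac_final - p_lac_initial) / dq


# ---------------------------------------------------------------------------
# whole-series summary
# ---------------------------------------------------------------------------

@dataclass
class KineticSummary:
    """All per-interval and window-averaged kinetic quantities for one run.

    Rates are in pmol per cell per day; interval ``i`` spans
    ``times[i] -> times[i+1]``.
    """

    run_id: str
    times: np.ndarray
    pd: np.ndarray
    cpd: np.ndarray
    fold: float
    mu: np.ndarray
    q: dict[str, np.ndarray] = field(default_factory=dict)
    p: dict[str, np.ndarray] = field(default_factory=dict)
    q_avg: dict[str, float] = field(default_factory=dict)
    p_avg: dict[str, float] = field(default_factory=dict)
    dlac_dgluc: float | None = None
    window: tuple[float, float] = DEFAULT_WINDOW

    def to_frame(self):
        """Flat one-row-per-interval-per-analyte table (plus growth rows)."""
        import pandas as pd_mod

        rows = []
        for i in range(self.pd.size):
            t0, t1 = self.times[i], self.times[i + 1]
            rows.append({
                "run_id": self.run_id, "analyte": "cells",
                "t_start": t0, "t_end": t1, "quantity": "pd", "value": self.pd[i],
            })
            rows.append({
                "run_id": self.run_id, "analyte": "cells",
                "t_start": t0, "t_end": t1, "quantity": "mu", "value": self.mu[i],
            })
            for analyte, series in self.q.items():
                rows.append({
                    "run_id": self.run_id, "analyte": analyte,
                    "t_start": t0, "t_end": t1, "quantity": "q", "value": series[i],
                })
            for analyte, series in self.p.items():
                rows.append({
                    "run_id": self.run_id, "analyte": analyte,
                    "t_start": t0, "t_end": t1, "quantity": "p", "value": series[i],
                })
        return pd_mod.DataFrame(rows)


def window_intervals(times: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Indices of sampling intervals wholly inside [start, end].

    Interval ``i`` (spanning ``times[i] -> times[i+1]``) is selected when both
    endpoints lie inside the window; on a daily-sampled day 0-7 series with
    window (2, 7) this picks the five intervals 2->3 ... 6->7.
    """
    start, end = window
    if end <= start:
        raise KineticsError(f"window must be ascending (got {window})")
    times = np.asarray(times, dtype=float)
    idx = np.nonzero((times[:-1] >= start - 1e-9) & (times[1:] <= end + 1e-9))[0]
    if idx.size == 0:
        raise KineticsError(
            f"no sampling interval falls inside window [{start}, {end}] "
            f"for times {times.tolist()}"
        )
    return idx


def window_average(values: np.ndarray, times: np.ndarray,
                   window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """Arithmetic mean of per-interval values over the window's intervals."""
    idx = window_intervals(times, window)
    return float(np.mean(np.asarray(values, dtype=float)[idx]))


def kinetic_summary(
    series: CultureTimeSeries,
    panels: dict[str, MetabolitePanel] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> KineticSummary:
    """Derive all kinetic responses for one run.

    Cell number is density x volume; concentrations are mmol/L, so the raw
    rate (mmol/L per cell per day) is scaled by the interval's starting
    volume in litres and reported in pmol per cell per day.
    """
    panels = panels or {}
    cells = series.cell_number
    n_int = series.n_points - 1
    dt = np.diff(series.times)

    pd_arr = np.array([
        population_doublings(cells[i], cells[i + 1]) for i in range(n_int)
    ])
    cpd = cumulative_pd(pd_arr)
    mu = pd_arr * LN2 / dt
    fold = cell_fold(cpd[-1])

    q: dict[str, np.ndarray] = {}
    p: dict[str, np.ndarray] = {}
    for analyte, panel in panels.items():
        if panel.concentrations.size != series.n_points:
            raise KineticsError(
                f"run {series.run_id}: {analyte} panel has {panel.concentrations.size} "
                f"points, expected {series.n_points}"
            )
        if np.any(series.perfusion_rate[1:] > 0) and panel.feed_concentration is None:
            raise KineticsError(
                f"run {series.run_id}: feed concentration required under perfusion"
            )
        conc = panel.concentrations
        vol_l = series.volume_ml[:-1] / 1000.0
        rates = np.empty(n_int)
        for i in range(n_int):
            d = series.perfusion_rate[i + 1]
            args = (mu[i], cells[i], conc[i], conc[i + 1])
            if analyte in CONSUMED_ANALYTES:
                raw = specific_consumption(*args, feed_conc=panel.feed_concentration,
                                           d=d, dt=dt[i])
            else:
                raw = specific_production(*args, d=d, dt=dt[i])
            rates[i] = raw * vol_l[i] * 1e9  # mmol/cell/day -> pmol/cell/day
        if analyte in CONSUMED_ANALYTES:
            q[analyte] = rates
        else:
            p[analyte] = rates

    summary = KineticSummary(
        run_id=series.run_id, times=series.times, pd=pd_arr, cpd=cpd,
        fold=fold, mu=mu, q=q, p=p, window=window,
    )
    for analyte, rates in q.items():
        summary.q_avg[analyte] = window_average(rates, series.times, window)
    for analyte, rates in p.items():
        summary.p_avg[analyte] = window_average(rates, series.times, window)

    if "glucose" in q and "lactate" in p:
        idx = window_intervals(series.times, window)
        first, last = idx[0], idx[-1]
        summary.dlac_dgluc = lactate_glucose_yield(
            p["lactate"][last], p["lactate"][first],
            q["glucose"][last], q["glucose"][first],
        )
    return summary
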