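"""Reactor time-series metrics: yields, rates, purity, stability.

Turns measured (or simulated) fermentation time series into the headline
quantities of a mixed-culture acetate/methane process:

* steady-state CSTR yields in mol per mol glucose, with the methane yield
  from the volumetric gas production rate (rate * P_CH4 * HRT / V_m, with
  V_m the gas molar volume at the configured reference temperature);
* acetate purity (acetate over total liquid metabolites, mass basis by
  default, COD basis on request);
* fed-batch production rates (ordinary least squares on the stated window)
  and cumulative yields against the feed schedule;
* batch-stability verdicts (does the effluent keep fermenting or not).

Series travel as tidy CSV (time_d, variable, value, unit) or as a wide
frame with one row per observation.
"""

from __future__ import annotations

import csv
import io
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._io import read_text_or_path
from .cod import BIOMASS_FORMULA, METABOLITE_FORMULAS, YieldTable, cod_of_metabolite
from .formulas import molar_mass

__all__ = [
    "LIQUID_METABOLITES",
    "MOLAR_VOLUME_25C",
    "ReactorSeries",
    "FeedSchedule",
    "FeedEvent",
    "SteadyStateWindow",
    "DriftReport",
    "UnsteadyWindowError",
    "cstr_yields",
    "purity",
    "fedbatch_yields",
    "FedBatchResult",
    "batch_stability",
    "StabilityReport",
]

#: Liquid fermentation metabolites tracked in a series (glucose is the
#: substrate and is excluded from purity).
LIQUID_METABOLITES = (
    "acetate",
    "ethanol",
    "propionate",
    "butyrate",
    "lactate",
    "formate",
    "butanol",
)

GAS_COLUMNS = ("p_h2", "p_ch4", "p_co2")

#: Ideal-gas molar volume at 25 degC, 1 atm (L/mol) — default gas-meter
#: reference.
MOLAR_VOLUME_25C = 24.45

#: Effluent glucose below this is treated as zero (detection limit, g/L).
GLUCOSE_DETECTION_LIMIT = 0.1

_M_GLUCOSE = molar_mass(METABOLITE_FORMULAS["glucose"])
_M_BIOMASS_CMOL = molar_mass(BIOMASS_FORMULA)  # 24.62 g per C-mol


@dataclass
class ReactorSeries:
    """Timestamped liquid/gas/biomass measurements for one vessel.

    ``data`` is a wide frame with a ``time_d`` column (days, strictly
    increasing) and any of: liquid metabolites + ``glucose`` (g/L), gas
    partial pressures ``p_h2``/``p_ch4``/``p_co2`` (atm, <= 1.05), total
    ``gas_rate`` (L gas per L liquid per day), ``biomass`` (g/L), ``ph``,
    and ``hrt`` (days, CSTR only).
    """

    data: pd.DataFrame
    temperature_c: float = 70.0

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        if "time_d" not in df.columns:
            raise ValueError("series needs a 'time_d' column")
        t = df["time_d"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time_d must be strictly increasing")
        for col in (*LIQUID_METABOLITES, "glucose", "biomass", "gas_rate"):
            if col in df.columns and (df[col].to_numpy(float) < 0).any():
                raise ValueError(f"negative values in column {col!r}")
        for col in GAS_COLUMNS:
            if col in df.columns:
                v = df[col].to_numpy(float)
                if (v < 0).any() or (v > 1.05).any():
                    raise ValueError(f"{col} must lie in [0, 1.05] atm")
        if "hrt" in df.columns:
            hrt = df["hrt"].to_numpy(float)
            if (hrt[~np.isnan(hrt)] <= 0).any():
                raise ValueError("hrt must be positive where present")
        self.data = df

    @property
    def time(self) -> np.ndarray:
        return self.data["time_d"].to_numpy(float)

    def window(self, start: float, end: float) -> pd.DataFrame:
        mask = (self.data["time_d"] >= start) & (self.data["time_d"] <= end)
        return self.data.loc[mask]

    def liquid_at(self, time_d: float) -> dict[str, float]:
        """Liquid metabolite concentrations at the observation nearest a time."""
        idx = int(np.argmin(np.abs(self.time - time_d)))
        row = self.data.iloc[idx]
        return {
            m: float(row[m])
            for m in LIQUID_METABOLITES
            if m in self.data.columns and not math.isnan(row[m])
        }

    # -- tidy CSV round trip ----------------------------------------------
    _UNITS = {
        **{m: "g/L" for m in (*LIQUID_METABOLITES, "glucose", "biomass")},
        **{g: "atm" for g in GAS_COLUMNS},
        "gas_rate": "L/(L*day)",
        "ph": "-",
        "hrt": "d",
    }

    def to_tidy_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["time_d", "variable", "value", "unit"])
        for _, row in self.data.iterrows():
            for col in self.data.columns:
                if col == "time_d" or pd.isna(row[col]):
                    continue
                writer.writerow(
                    [repr(float(row["time_d"])), col, repr(float(row[col])),
                     self._UNITS.get(col, "-")]
                )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tidy_csv(
        cls, source: str | Path, temperature_c: float = 70.0
    ) -> "ReactorSeries":
        text = read_text_or_path(source)
        tidy = pd.read_csv(io.StringIO(text))
        wide = tidy.pivot_table(index="time_d", columns="variable", values="value")
        wide = wide.reset_index().rename_axis(None, axis=1)
        return cls(wide, temperature_c=temperature_c)


@dataclass(frozen=True)
class FeedEvent:
    time_d: float
    glucose_g_l: float
    yeast_extract_g_l: float = 0.0


@dataclass
class FeedSchedule:
    """Pulse-feed schedule: substrate added per event, in g per L of broth."""

    events: list[FeedEvent]

    def __post_init__(self) -> None:
        times = [e.time_d for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("feed times must be non-decreasing")
        for e in self.events:
            if e.glucose_g_l <= 0 and e.yeast_extract_g_l <= 0:
                raise ValueError(f"feed at day {e.time_d} adds nothing")
            if e.glucose_g_l < 0 or e.yeast_extract_g_l < 0:
                raise ValueError("feed additions must be positive")

    def glucose_added_between(self, start: float, end: float) -> float:
        """Total glucose added in (start, end], g/L."""
        return sum(
            e.glucose_g_l for e in self.events if start < e.time_d <= end
        )

    @property
    def first_feed_time(self) -> float:
        if not self.events:
            raise ValueError("empty feed schedule")
        return self.events[0].time_d

    @classmethod
    def from_csv(cls, source: str | Path) -> "FeedSchedule":
        text = read_text_or_path(source)
        rows = list(csv.DictReader(io.StringIO(text)))
        return cls(
            [
                FeedEvent(
                    float(r["time_d"]),
                    float(r["glucose_g_l"]),
                    float(r.get("yeast_extract_g_l", 0) or 0),
                )
                for r in rows
            ]
        )

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["time_d", "glucose_g_l", "yeast_extract_g_l"])
        for e in self.events:
            writer.writerow([e.time_d, e.glucose_g_l, e.yeast_extract_g_l])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class DriftReport:
    """Per-metabolite relative drift over a candidate steady-state window."""

    drifts: Mapping[str, float]
    hrt_constant: bool
    steady: bool


class UnsteadyWindowError(RuntimeError):
    def __init__(self, report: DriftReport):
        self.report = report
        bad = {m: round(d, 3) for m, d in report.drifts.items() if d > 0}
        super().__init__(
            f"window fails the steady-state criterion (drift={bad}, "
            f"hrt_constant={report.hrt_constant})"
        )


@dataclass(frozen=True)
class SteadyStateWindow:
    """A candidate steady-state interval with its acceptance criterion.

    Steady means: each major metabolite (mean above ``floor_g_l``) shows a
    systematic trend of less than ``rel_drift_tol`` of its mean across the
    window (|OLS slope| times window length over mean — robust to
    uncorrelated measurement noise, sensitive to transients) and HRT is
    constant across the window.
    """

    start: float
    end: float
    rel_drift_tol: float = 0.10
    floor_g_l: float = 0.2
    min_obs: int = 3

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    def check(self, series: ReactorSeries) -> DriftReport:
        frame = series.window(self.start, self.end)
        if len(frame) < self.min_obs:
            raise ValueError(
                f"window [{self.start}, {self.end}] holds {len(frame)} "
                f"observations; need >= {self.min_obs}"
            )
        t_all = frame["time_d"].to_numpy(float)
        span = float(t_all[-1] - t_all[0])
        drifts: dict[str, float] = {}
        steady = True
        for m in (*LIQUID_METABOLITES, "biomass"):
            if m not in frame.columns:
                continue
            v = frame[m].to_numpy(float)
            keep = ~np.isnan(v)
            v = v[keep]
            if v.size < 2 or v.mean() < self.floor_g_l:
                continue
            slope = float(np.polyfit(t_all[keep], v, 1)[0])
            drift = abs(slope) * span / float(v.mean())
            drifts[m] = drift
            if drift > self.rel_drift_tol:
                steady = False
        hrt_constant = True
        if "hrt" in frame.columns:
            hrt = frame["hrt"].to_numpy(float)
            hrt = hrt[~np.isnan(hrt)]
            if hrt.size and np.ptp(hrt) > 1e-9 * max(1.0, abs(hrt).max()):
                hrt_constant = False
        return DriftReport(drifts, hrt_constant, steady and hrt_constant)


def cstr_yields(
    series: ReactorSeries,
    window: SteadyStateWindow,
    influent_glucose: float,
    molar_volume_l: float = MOLAR_VOLUME_25C,
) -> YieldTable:
    """Steady-state CSTR yields, mol per mol glucose consumed.

    Liquid yields come from mean effluent concentrations over the window;
    the methane yield from the mean volumetric gas rate times P_CH4 times
    HRT, converted with the gas molar volume; biomass in C-mol using the
    per-carbon pseudo-formula.  Refuses windows that fail the steady-state
    criterion.
    """
    report = window.check(series)
    if not report.steady:
        raise UnsteadyWindowError(report)
    frame = series.window(window.start, window.end)
    if "hrt" not in frame.columns or frame["hrt"].isna().all():
        raise ValueError("cstr_yields needs an 'hrt' column (CSTR series only)")
    hrt = float(frame["hrt"].mean())

    s_out = float(frame["glucose"].mean()) if "glucose" in frame.columns else 0.0
    if s_out < GLUCOSE_DETECTION_LIMIT:
        s_out = 0.0
    if s_out >= influent_glucose:
        raise ValueError("effluent glucose must be below the influent concentration")
    glc_mol = (influent_glucose - s_out) / _M_GLUCOSE  # mol/L consumed

    yields: dict[str, float] = {}
    for m in LIQUID_METABOLITES:
        if m not in frame.columns:
            continue
        conc = float(frame[m].mean())
        if math.isnan(conc):
            continue
        yields[m] = (conc / molar_mass(METABOLITE_FORMULAS[m])) / glc_mol

    if {"gas_rate", "p_ch4"} <= set(frame.columns):
        ch4_rate = float((frame["gas_rate"] * frame["p_ch4"]).mean())  # L/(L d)
        yields["methane"] = (ch4_rate * hrt / molar_volume_l) / glc_mol
    if "biomass" in frame.columns:
        x = float(frame["biomass"].mean())
        yields["biomass"] = (x / _M_BIOMASS_CMOL) / glc_mol
    return YieldTable(
        {m: y for m, y in yields.items() if y > 0},
        label=f"day {window.start:g}-{window.end:g}",
    )


def purity(concentrations: Mapping[str, float], basis: str = "mass") -> float:
    """Acetate fraction of total liquid metabolites (glucose excluded).

    ``basis="mass"`` works on g/L as reported; ``basis="cod"`` weights each
    concentration by its COD per gram.
    """
    if basis not in ("mass", "cod"):
        raise ValueError("basis must be 'mass' or 'cod'")
    totals = {
        m: c
        for m, c in concentrations.items()
        if m in LIQUID_METABOLITES and c > 0
    }
    if not totals:
        raise ValueError("all liquid metabolite concentrations are zero")
    if basis == "cod":
        totals = {
            m: c * cod_of_metabolite(m) / molar_mass(METABOLITE_FORMULAS[m])
            for m, c in totals.items()
        }
    return totals.get("acetate", 0.0) / sum(totals.values())


@dataclass(frozen=True)
class FedBatchResult:
    """Fed-batch window summary: rates plus cumulative yields."""

    acetate_rate_g_l_d: float  # OLS slope of acetate(t) on the window
    methane_rate_l_l_d: float | None  # mean gas_rate * P_CH4
    yields: YieldTable  # cumulative mol per mol glucose added


def fedbatch_yields(
    series: ReactorSeries,
    schedule: FeedSchedule,
    window: tuple[float, float],
    molar_volume_l: float = MOLAR_VOLUME_25C,
) -> FedBatchResult:
    """Rates and cumulative yields over a fed-batch window.

    The acetate rate is the least-squares slope of acetate(t); yields are
    net mol formed per mol glucose added on the window, corrected for
    residual (unconsumed) glucose when a glucose column is present.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    if schedule.first_feed_time >= end:
        raise ValueError(
            f"window ends at day {end}, before the first feed at "
            f"day {schedule.first_feed_time}"
        )
    frame = series.window(start, end)
    if len(frame) < 2:
        raise ValueError("need at least two observations in the window")
    t = frame["time_d"].to_numpy(float)

    acetate = frame["acetate"].to_numpy(float)
    slope = float(np.polyfit(t, acetate, 1)[0])

    glucose_added = schedule.glucose_added_between(start, end)
    if "glucose" in frame.columns:
        residual = float(frame["glucose"].iloc[-1] - frame["glucose"].iloc[0])
        glucose_added -= max(residual, 0.0)

    # with no glucose consumed in the window the rates are still defined,
    # but per-substrate yields are not
    yields: dict[str, float] = {}
    glc_mol = glucose_added / _M_GLUCOSE if glucose_added > 0 else 0.0
    if glc_mol > 0:
        for m in LIQUID_METABOLITES:
            if m not in frame.columns:
                continue
            delta = float(frame[m].iloc[-1] - frame[m].iloc[0])
            y = (delta / molar_mass(METABOLITE_FORMULAS[m])) / glc_mol
            if y > 0:
                yields[m] = y

    methane_rate = None
    if {"gas_rate", "p_ch4"} <= set(frame.columns):
        ch4 = (frame["gas_rate"] * frame["p_ch4"]).to_numpy(float)
        methane_rate = float(np.mean(ch4))
        # cumulative CH4 over the window via trapezoidal integration
        ch4_mol = float(np.trapezoid(ch4, t)) / molar_volume_l
        if ch4_mol > 0 and glc_mol > 0:
            yields["methane"] = ch4_mol / glc_mol
    return FedBatchResult(
        acetate_rate_g_l_d=slope,
        methane_rate_l_l_d=methane_rate,
        yields=YieldTable(yields, label=f"fed-batch day {start:g}-{end:g}"),
    )


@dataclass(frozen=True)
class StabilityReport:
    """Per-metabolite max deviations from the initial state of a batch hold."""

    deltas: Mapping[str, float]  # max |C(t) - C(0)|, g/L
    stable_metabolites: Mapping[str, bool]
    p_ch4_increase: float | None
    stable: bool


def batch_stability(
    series: ReactorSeries,
    tolerance_g_l: float = 0.5,
    p_ch4_rise_bound: float = 0.05,
) -> StabilityReport:
    """Verdict on whether a batch hold converts anything further.

    Stable means every liquid metabolite stays within ``tolerance_g_l`` of
    its initial concentration and P_CH4 rises by no more than
    ``p_ch4_rise_bound`` atm — the signature of an effluent whose acetate
    is not being consumed (no active aceticlastic pathway).
    """
    frame = series.data
    if len(frame) < 2:
        raise ValueError("need at least two time points")
    deltas: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for m in LIQUID_METABOLITES:
        if m not in frame.columns:
            continue
        v = frame[m].to_numpy(float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            continue
        delta = float(np.max(np.abs(v - v[0])))
        deltas[m] = delta
        flags[m] = delta <= tolerance_g_l
    p_rise = None
    p_ok = True
    if "p_ch4" in frame.columns:
        p = frame["p_ch4"].to_numpy(float)
        p = p[~np.isnan(p)]
        if p.size:
            p_rise = float(np.max(p) - p[0])
            p_ok = p_rise <= p_ch4_rise_bound
    return StabilityReport(
        deltas=deltas,
        stable_metabolites=flags,
        p_ch4_increase=p_rise,
        stable=all(flags.values()) and p_ok,
    )
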