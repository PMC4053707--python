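"""Mechanistic synthetic reactor data with known ground truth.

The generator produces CSTR, fed-batch and batch time series with the
structure the analysis modules assume, so every estimator can be tested
against a latent noise-free truth without any external data.  It is a
regime-switching flux-partition model, not a kinetic digester model:

* glucose uptake is first-order (fast relative to dilution), slowed by a
  smooth acetate-inhibition factor above a configurable threshold;
* consumed glucose COD is split exactly among products.  Fixed shares go
  to biomass, propionate and butyrate per the configured true yield
  table; the remaining acetate + H2 pool is diverted towards ethanol by a
  fraction that grows with the hydrogen partial pressure (the classic
  product shift of fermenting bacteria under H2 inhibition);
* hydrogenotrophic methanogens draw headspace H2 down to a thermodynamic
  threshold pressure, capacity-limited by a methanogen biomass state that
  grows on consumed H2 (capped by a maximum growth rate) and washes out
  with the dilution rate — which is what makes low HRT a transient-H2,
  ethanol-producing regime and high HRT a clean acetate regime;
* the headspace is a well-mixed 1 atm gas pool; produced gas displaces
  outflow, which is what a gas meter integrates;
* observations are multiplicative lognormal (CV-specified) on top of the
  latent state; partial pressures are renormalized to at most 1.05 atm.

COD is conserved exactly at every step of the latent state; each step's
closure residual is recomputed from the realized increments and logged,
so conservation is testable rather than assumed.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cod import YieldTable, cod_of_metabolite
from .community import CloneLibrary, CloneRecord
from .formulas import molar_mass
from .metrics import FeedEvent, FeedSchedule, ReactorSeries
from .thermo import ATM_TO_PA

__all__ = [
    "GeneratorConfig",
    "TrueState",
    "simulate_cstr",
    "simulate_fedbatch",
    "simulate_batch",
    "sample_clone_library",
    "nominal_cstr_config",
    "nominal_fedbatch_config",
    "nominal_batch_config",
    "default_fedbatch_feeds",
]

_M_GLC = molar_mass("C6H12O6")
_M_AC = molar_mass("C2H4O2")
_M_ETH = molar_mass("C2H6O")
_M_PROP = molar_mass("C3H6O2")
_M_BUT = molar_mass("C4H8O2")
_M_BIO = molar_mass("CH1.8O0.5N0.2")  # g per C-mol

_COD_GLC = cod_of_metabolite("glucose")  # 192
_COD_AC = cod_of_metabolite("acetate")  # 64
_COD_ETH = cod_of_metabolite("ethanol")  # 96
_COD_PROP = cod_of_metabolite("propionate")  # 112
_COD_BUT = cod_of_metabolite("butyrate")  # 160
_COD_CH4 = cod_of_metabolite("methane")  # 64
_COD_H2 = cod_of_metabolite("hydrogen")  # 16
_COD_BIO = cod_of_metabolite("biomass")  # 33.6 per C-mol

_CARBONS = {"acetate": 2.0, "ethanol": 2.0, "propionate": 3.0, "butyrate": 4.0}


def default_fedbatch_feeds() -> FeedSchedule:
    """The pulse-feed regime used for the maximum-acetate experiment.

    1 g-glucose/L at days 0 and 2.0, then 6 g-glucose/L pulses roughly
    twice daily through day 12.2, with 1 g/L yeast extract at five of the
    feeds.
    """
    six_g_days = (2.5, 2.9, 3.2, 3.7, 4.2, 4.8, 5.2, 5.8, 6.2, 6.8,
                  7.2, 7.7, 8.2, 8.7, 9.2, 9.8, 10.2, 11.2, 12.2)
    ye_days = {0.0, 4.2, 7.2, 8.7, 11.2}
    events = [FeedEvent(0.0, 1.0, 1.0), FeedEvent(2.0, 1.0, 0.0)]
    events += [
        FeedEvent(d, 6.0, 1.0 if d in ye_days else 0.0) for d in six_g_days
    ]
    return FeedSchedule(sorted(events, key=lambda e: e.time_d))


def _default_true_yields() -> YieldTable:
    # Liquid + biomass true yields; methane follows from the COD closure
    # (H2 pool routed through methanogenesis).
    return YieldTable(
        {"acetate": 1.5, "propionate": 0.08, "butyrate": 0.01, "biomass": 0.4},
        label="true",
    )


@dataclass
class GeneratorConfig:
    """Study conditions and kinetic fixtures for one simulated run.

    Defaults describe the extreme-thermophilic (70 degC) acetate+methane
    process: 9 g/L influent glucose, true yields 1.5 acetate / 0.08
    propionate / 0.01 butyrate / 0.4 C-mol biomass per mol glucose, a
    ~60 Pa methanogen H2 threshold, acetate inhibition near 34 g/L, and
    5 % CV measurement noise.  Kinetic rate constants are generator
    fixtures (the process data constrain steady states and regime shifts,
    not rate constants).
    """

    mode: str = "cstr"  # cstr | fed-batch | batch
    seed: int = 0
    true_yields: YieldTable = field(default_factory=_default_true_yields)
    influent_glucose: float = 9.0  # g/L (CSTR feed)
    hrt_schedule: Sequence[tuple[float, float]] = (
        (0.0, 2.2), (10.0, 8.9), (52.0, 5.0), (91.0, 6.5),
    )
    ph_schedule: Sequence[tuple[float, float]] = ((0.0, 7.5), (30.0, 6.5), (38.0, 7.0))
    feed_schedule: FeedSchedule | None = None
    h2_threshold_pa: float = 60.0  # methanogen H2 threshold
    acetate_inhibition_g_l: float = 34.0
    inhibition_width_g_l: float = 0.5
    noise_cv: float | Mapping[str, float] = 0.05
    temperature_c: float = 70.0
    horizon_d: float | None = None  # mode default when None
    dt: float = 0.05  # explicit Euler step, days
    obs_interval_d: float = 0.5
    # --- kinetic fixtures -------------------------------------------------
    glucose_uptake_per_d: float = 20.0  # first-order uptake rate constant
    methanogen_qmax: float = 1.0  # mol H2 per g methanogen per day
    methanogen_mu_max: float = 1.0  # 1/day cap on methanogen growth
    methanogen_yield_g_per_mol_h2: float = 0.5
    shift_onset_atm: float = 0.005  # P_H2 where the ethanol shift engages
    shift_scale_atm: float = 0.005
    shift_max: float = 0.9
    co2_gas_fraction: float = 0.25  # rest stays as bicarbonate at pH ~7
    headspace_ratio: float = 0.6  # L headspace per L liquid
    molar_volume_l: float = 24.45
    aceticlastic_rate_g_l_d: float = 0.0  # acetate consumer, off by default
    initial: str | Mapping[str, float] = "inoculum"  # or "steady" / overrides

    def __post_init__(self) -> None:
        if self.mode not in ("cstr", "fed-batch", "batch"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.h2_threshold_pa <= 0 or self.acetate_inhibition_g_l <= 0:
            raise ValueError("thresholds must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        cvs = (
            self.noise_cv.values()
            if isinstance(self.noise_cv, Mapping)
            else [self.noise_cv]
        )
        if any(cv < 0 for cv in cvs):
            raise ValueError("noise CV must be >= 0")
        if self.mode == "cstr":
            min_hrt = min(h for _, h in self.hrt_schedule)
            if min_hrt <= 0:
                raise ValueError("HRT must be positive")
            # explicit-Euler stability guard
            assert self.dt <= min_hrt / 10.0, (
                f"dt={self.dt} too large for min HRT {min_hrt}"
            )
        if self.mode == "fed-batch" and self.feed_schedule is None:
            object.__setattr__(self, "feed_schedule", default_fedbatch_feeds())
        # COD shares of the true yield table must leave a non-negative H2 pool
        y = self.true_yields
        fixed = (
            y["biomass"] * _COD_BIO
            + y["propionate"] * _COD_PROP
            + y["butyrate"] * _COD_BUT
        )
        pool = _COD_GLC - fixed
        if y["acetate"] * _COD_AC > pool + 1e-9:
            raise ValueError(
                "true yield table over-commits COD: acetate share exceeds the "
                "glucose COD left after biomass/propionate/butyrate"
            )

    @property
    def horizon(self) -> float:
        if self.horizon_d is not None:
            return self.horizon_d
        return {"cstr": 100.0, "fed-batch": 15.0, "batch": 14.0}[self.mode]

    def noise_cv_for(self, variable: str) -> float:
        if isinstance(self.noise_cv, Mapping):
            return float(self.noise_cv.get(variable, self.noise_cv.get("default", 0.0)))
        return float(self.noise_cv)


def _schedule_value(schedule: Sequence[tuple[float, float]], t: float) -> float:
    value = schedule[0][1]
    for start, v in schedule:
        if t >= start:
            value = v
    return value


@dataclass
class TrueState:
    """Latent noise-free trajectories plus per-step closure residuals.

    ``frame`` has one row per Euler step with concentrations, pressures,
    cumulative molar production (``cum_*``) and the per-step COD closure
    residual in g COD/L (``cod_residual``, recomputed from the realized
    increments).  ``realized_yields`` integrates the production fluxes to
    the generator's actual yields over a window — the estimand that the
    reactor-metrics estimators should recover.
    """

    frame: pd.DataFrame
    config: GeneratorConfig

    def realized_yields(self, start: float, end: float) -> dict[str, float]:
        t = self.frame["time_d"].to_numpy()
        i0 = int(np.argmin(np.abs(t - start)))
        i1 = int(np.argmin(np.abs(t - end)))
        row0, row1 = self.frame.iloc[i0], self.frame.iloc[i1]
        glc = row1["cum_glucose_mol"] - row0["cum_glucose_mol"]
        if glc <= 0:
            raise ValueError("no glucose consumed in the window")
        out = {}
        for name in ("acetate", "ethanol", "propionate", "butyrate", "methane"):
            out[name] = (row1[f"cum_{name}_mol"] - row0[f"cum_{name}_mol"]) / glc
        out["biomass"] = (row1["cum_biomass_cmol"] - row0["cum_biomass_cmol"]) / glc
        return out

    @property
    def max_cod_residual(self) -> float:
        return float(self.frame["cod_residual"].abs().max())


def _initial_state(config: GeneratorConfig) -> dict[str, float]:
    """Latent initial state per mode, overridable via ``config.initial``."""
    y = config.true_yields
    n_cap = config.headspace_ratio / config.molar_volume_l
    if config.mode == "cstr":
        state = {
            "glucose": 0.05,
            "acetate": 4.9, "ethanol": 0.0, "propionate": 0.1, "butyrate": 0.15,
            "x_ferm": 0.4, "x_meth": 0.02,
            "n_h2": 0.0, "n_ch4": 0.0, "n_co2": 0.0, "n_n2": n_cap,
        }
        if config.initial == "steady":
            hrt0 = _schedule_value(config.hrt_schedule, 0.0)
            s0 = config.influent_glucose / (1.0 + config.glucose_uptake_per_d * hrt0)
            g_mol = (config.influent_glucose - s0) / _M_GLC  # mol/L per HRT
            state.update(
                glucose=s0,
                acetate=y["acetate"] * _M_AC * g_mol,
                propionate=y["propionate"] * _M_PROP * g_mol,
                butyrate=y["butyrate"] * _M_BUT * g_mol,
                ethanol=0.0,
                x_ferm=y["biomass"] * _M_BIO * g_mol,
            )
            fixed = (y["biomass"] * _COD_BIO + y["propionate"] * _COD_PROP
                     + y["butyrate"] * _COD_BUT)
            pool = _COD_GLC - fixed
            h2_rate = g_mol / hrt0 * (pool - y["acetate"] * _COD_AC) / _COD_H2
            growth_rate = config.methanogen_yield_g_per_mol_h2 * h2_rate
            state["x_meth"] = growth_rate * hrt0
            ch4_rate = (h2_rate * _COD_H2 - growth_rate * _COD_BIO / _M_BIO) / _COD_CH4
            co2_rate = config.co2_gas_fraction * g_mol / hrt0 * (
                6.0 - 2.0 * y["acetate"] - 3.0 * y["propionate"]
                - 4.0 * y["butyrate"] - y["biomass"]
            )
            total = ch4_rate + co2_rate
            state.update(
                n_n2=0.0,
                n_ch4=n_cap * ch4_rate / total,
                n_co2=n_cap * co2_rate / total,
                n_h2=n_cap * config.h2_threshold_pa / ATM_TO_PA,
            )
    elif config.mode == "fed-batch":
        state = {
            "glucose": 0.0,
            "acetate": 0.0, "ethanol": 0.0, "propionate": 0.0, "butyrate": 0.0,
            "x_ferm": 1.95, "x_meth": 0.05,
            "n_h2": 0.0, "n_ch4": 0.0, "n_co2": 0.0, "n_n2": n_cap,
        }
    else:  # batch hold of CSTR effluent
        state = {
            "glucose": 0.05,
            "acetate": 4.4, "ethanol": 0.15, "propionate": 0.25, "butyrate": 0.05,
            "x_ferm": 0.35, "x_meth": 0.1,
            "n_h2": 0.0, "n_ch4": 0.008 * n_cap, "n_co2": 0.01 * n_cap,
            "n_n2": 0.982 * n_cap,
        }
    if isinstance(config.initial, Mapping):
        state.update({k: float(v) for k, v in config.initial.items()})
    return state


def _simulate(config: GeneratorConfig) -> tuple[TrueState, ReactorSeries]:
    rng = np.random.default_rng(config.seed)
    y = config.true_yields
    dt = config.dt
    n_cap = config.headspace_ratio / config.molar_volume_l
    p_star = config.h2_threshold_pa / ATM_TO_PA
    fixed_cod = (y["biomass"] * _COD_BIO + y["propionate"] * _COD_PROP
                 + y["butyrate"] * _COD_BUT)
    pool_cod = _COD_GLC - fixed_cod  # acetate + H2 COD per mol glucose
    sigma_ac = y["acetate"] * _COD_AC / pool_cod
    bio_cod_per_g = _COD_BIO / _M_BIO

    st = _initial_state(config)
    cum = {k: 0.0 for k in ("glucose", "acetate", "ethanol", "propionate",
                            "butyrate", "methane")}
    cum_bio = 0.0

    n_steps = int(round(config.horizon / dt))
    truth_rows: list[dict[str, float]] = []
    obs_rows: list[dict[str, float]] = []
    outflow_since_obs = 0.0
    next_obs = 0.0

    def pressures() -> tuple[float, float, float]:
        return st["n_h2"] / n_cap, st["n_ch4"] / n_cap, st["n_co2"] / n_cap

    def record_obs(t: float, gas_rate: float, hrt: float | None, ph: float) -> None:
        def noisy(name: str, value: float) -> float:
            cv = config.noise_cv_for(name)
            if cv <= 0 or value <= 0:
                return value
            sig = math.sqrt(math.log1p(cv * cv))
            return value * math.exp(sig * rng.standard_normal() - 0.5 * sig * sig)

        p_h2, p_ch4, p_co2 = pressures()
        row = {
            "time_d": t,
            "acetate": noisy("acetate", st["acetate"]),
            "ethanol": noisy("ethanol", st["ethanol"]),
            "propionate": noisy("propionate", st["propionate"]),
            "butyrate": noisy("butyrate", st["butyrate"]),
            "glucose": noisy("glucose", st["glucose"]),
            "biomass": noisy("biomass", st["x_ferm"] + st["x_meth"]),
            "p_h2": noisy("p_h2", p_h2),
            "p_ch4": noisy("p_ch4", p_ch4),
            "p_co2": noisy("p_co2", p_co2),
            "gas_rate": noisy("gas_rate", gas_rate),
            "ph": ph,
        }
        total_p = row["p_h2"] + row["p_ch4"] + row["p_co2"]
        if total_p > 1.05:
            scale = 1.05 / total_p
            for g in ("p_h2", "p_ch4", "p_co2"):
                row[g] *= scale
        if hrt is not None:
            row["hrt"] = hrt
        obs_rows.append(row)

    for k in range(n_steps + 1):
        t = k * dt
        hrt = _schedule_value(config.hrt_schedule, t) if config.mode == "cstr" else None
        ph = (_schedule_value(config.ph_schedule, t) if config.mode == "cstr"
              else (7.0 if config.mode == "fed-batch" else 7.5))

        # ---- observation uses the post-consumption state from the previous
        # step, which is what a sampled reactor shows
        if t >= next_obs - 1e-9:
            gas_rate = (
                outflow_since_obs * config.molar_volume_l / config.obs_interval_d
                if k else 0.0
            )
            record_obs(t, gas_rate, hrt, ph)
            outflow_since_obs = 0.0
            next_obs += config.obs_interval_d

        if k == n_steps:
            p_h2, p_ch4, p_co2 = pressures()
            truth_rows.append({
                "time_d": t, "glucose": st["glucose"], "acetate": st["acetate"],
                "ethanol": st["ethanol"], "propionate": st["propionate"],
                "butyrate": st["butyrate"], "biomass": st["x_ferm"] + st["x_meth"],
                "x_ferm": st["x_ferm"], "x_meth": st["x_meth"],
                "p_h2": p_h2, "p_ch4": p_ch4, "p_co2": p_co2,
                "cum_glucose_mol": cum["glucose"], "cum_acetate_mol": cum["acetate"],
                "cum_ethanol_mol": cum["ethanol"],
                "cum_propionate_mol": cum["propionate"],
                "cum_butyrate_mol": cum["butyrate"],
                "cum_methane_mol": cum["methane"], "cum_biomass_cmol": cum_bio,
                "cod_residual": 0.0,
            })
            break

        # ---- feed pulses in [t, t+dt)
        if config.feed_schedule is not None:
            for e in config.feed_schedule.events:
                if t <= e.time_d < t + dt:
                    st["glucose"] += e.glucose_g_l

        # ---- regime factors from the current (post-consumption) state
        p_h2, _, _ = pressures()
        inh = 1.0 / (1.0 + math.exp(
            (st["acetate"] - config.acetate_inhibition_g_l)
            / config.inhibition_width_g_l
        ))
        excess_p = max(p_h2 - config.shift_onset_atm, 0.0)
        shift = config.shift_max * excess_p / (excess_p + config.shift_scale_atm)

        # ---- glucose uptake and product partition (COD-exact)
        ds = min(config.glucose_uptake_per_d * st["glucose"] * inh * dt,
                 st["glucose"])
        st["glucose"] -= ds
        g_mol = ds / _M_GLC
        bio_cmol = y["biomass"] * g_mol
        prop_mol = y["propionate"] * g_mol
        but_mol = y["butyrate"] * g_mol
        pool = pool_cod * g_mol
        eth_mol = shift * pool / _COD_ETH
        ac_mol = (1.0 - shift) * pool * sigma_ac / _COD_AC
        h2_mol = (1.0 - shift) * pool * (1.0 - sigma_ac) / _COD_H2
        co2_mol = 6.0 * g_mol - (
            _CARBONS["acetate"] * ac_mol + _CARBONS["ethanol"] * eth_mol
            + _CARBONS["propionate"] * prop_mol + _CARBONS["butyrate"] * but_mol
            + bio_cmol
        )

        st["acetate"] += ac_mol * _M_AC
        st["ethanol"] += eth_mol * _M_ETH
        st["propionate"] += prop_mol * _M_PROP
        st["butyrate"] += but_mol * _M_BUT
        st["x_ferm"] += bio_cmol * _M_BIO
        st["n_h2"] += h2_mol
        st["n_co2"] += config.co2_gas_fraction * max(co2_mol, 0.0)

        # closure residual of the fermentation partition, recomputed from the
        # realized increments (g COD per L this step)
        residual = ds * (_COD_GLC / _M_GLC) - (
            ac_mol * _COD_AC + eth_mol * _COD_ETH + prop_mol * _COD_PROP
            + but_mol * _COD_BUT + bio_cmol * _COD_BIO + h2_mol * _COD_H2
        )

        cum["glucose"] += g_mol
        cum["acetate"] += ac_mol
        cum["ethanol"] += eth_mol
        cum["propionate"] += prop_mol
        cum["butyrate"] += but_mol
        cum_bio += bio_cmol

        # ---- hydrogenotrophic methanogenesis down to the threshold pressure
        excess_h2 = max(st["n_h2"] - p_star * n_cap, 0.0)
        capacity = config.methanogen_qmax * st["x_meth"] * inh * dt
        cons = min(excess_h2, capacity)
        growth = min(config.methanogen_yield_g_per_mol_h2 * cons,
                     config.methanogen_mu_max * st["x_meth"] * dt)
        ch4_mol = (cons * _COD_H2 - growth * bio_cod_per_g) / _COD_CH4
        st["n_h2"] -= cons
        st["n_ch4"] += ch4_mol
        st["x_meth"] += growth
        residual += cons * _COD_H2 - ch4_mol * _COD_CH4 - growth * bio_cod_per_g
        cum["methane"] += ch4_mol
        cum_bio += growth / _M_BIO

        # ---- optional aceticlastic consumer (counter-case fixture)
        if config.aceticlastic_rate_g_l_d > 0:
            d_ac = min(config.aceticlastic_rate_g_l_d * dt, st["acetate"])
            acl_mol = d_ac / _M_AC
            st["acetate"] -= d_ac
            st["n_ch4"] += acl_mol
            st["n_co2"] += config.co2_gas_fraction * acl_mol
            residual += d_ac * (_COD_AC / _M_AC) - acl_mol * _COD_CH4
            cum["methane"] += acl_mol
            cum["acetate"] -= acl_mol

        # ---- dilution (CSTR only)
        if hrt is not None:
            d = dt / hrt
            st["glucose"] += (config.influent_glucose - st["glucose"]) * d
            for m in ("acetate", "ethanol", "propionate", "butyrate"):
                st[m] -= st[m] * d
            st["x_ferm"] -= st["x_ferm"] * d
            st["x_meth"] -= st["x_meth"] * d

        # ---- headspace displacement (gas meter)
        n_tot = st["n_h2"] + st["n_ch4"] + st["n_co2"] + st["n_n2"]
        step_out = 0.0
        if n_tot > n_cap:
            scale = n_cap / n_tot
            step_out = n_tot - n_cap
            for g in ("n_h2", "n_ch4", "n_co2", "n_n2"):
                st[g] *= scale
        outflow_since_obs += step_out

        p_h2, p_ch4, p_co2 = pressures()
        truth_rows.append({
            "time_d": t, "glucose": st["glucose"], "acetate": st["acetate"],
            "ethanol": st["ethanol"], "propionate": st["propionate"],
            "butyrate": st["butyrate"], "biomass": st["x_ferm"] + st["x_meth"],
            "x_ferm": st["x_ferm"], "x_meth": st["x_meth"],
            "p_h2": p_h2, "p_ch4": p_ch4, "p_co2": p_co2,
            "cum_glucose_mol": cum["glucose"], "cum_acetate_mol": cum["acetate"],
            "cum_ethanol_mol": cum["ethanol"],
            "cum_propionate_mol": cum["propionate"],
            "cum_butyrate_mol": cum["butyrate"],
            "cum_methane_mol": cum["methane"], "cum_biomass_cmol": cum_bio,
            "cod_residual": residual,
        })

    truth = TrueState(pd.DataFrame(truth_rows), config)
    series = ReactorSeries(pd.DataFrame(obs_rows),
                           temperature_c=config.temperature_c)
    return truth, series


def simulate_cstr(config: GeneratorConfig) -> tuple[TrueState, ReactorSeries]:
    """Simulate a continuous run; see the module docstring for the model."""
    if config.mode != "cstr":
        raise ValueError("config.mode must be 'cstr'")
    return _simulate(config)


def simulate_fedbatch(config: GeneratorConfig) -> tuple[TrueState, ReactorSeries]:
    """Simulate a pulse-fed batch; acetate inhibition caps the product."""
    if config.mode != "fed-batch":
        raise ValueError("config.mode must be 'fed-batch'")
    if config.feed_schedule is None or not config.feed_schedule.events:
        raise ValueError("fed-batch mode needs a non-empty feed schedule")
    return _simulate(config)


def simulate_batch(config: GeneratorConfig) -> tuple[TrueState, ReactorSeries]:
    """Simulate a batch hold (effluent stability experiment)."""
    if config.mode != "batch":
        raise ValueError("config.mode must be 'batch'")
    return _simulate(config)


def nominal_cstr_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The 100-day three-period CSTR run (HRT 2.2 -> 8.9 -> 5.0 -> 6.5 d)."""
    return replace(GeneratorConfig(mode="cstr", seed=seed), **overrides)


def nominal_fedbatch_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The pulse-fed maximum-acetate run with inhibition near 34 g/L."""
    return replace(GeneratorConfig(mode="fed-batch", seed=seed), **overrides)


def nominal_batch_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The 14-day effluent stability hold."""
    return replace(GeneratorConfig(mode="batch", seed=seed), **overrides)


def sample_clone_library(
    proportions: Mapping[str, float],
    n: int,
    seed: int,
    domain: str = "Archaea",
    relatives: Mapping[str, str] | None = None,
) -> CloneLibrary:
    """Multinomial clone sampling from true phylotype proportions.

    ``proportions`` maps clone names to probabilities summing to 1;
    categories drawn zero times are dropped from the library (a clone table
    only lists observed clones).  Deterministic under a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    names = list(proportions)
    p = np.asarray([proportions[name] for name in names], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p)
    records = [
        CloneRecord(
            clone=name,
            closest_relative=(relatives or {}).get(name, name),
            similarity=99.0,
            count=int(c),
        )
        for name, c in zip(names, counts)
        if c > 0
    ]
    return CloneLibrary(records, domain=domain)
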