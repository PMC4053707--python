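"""Bioenergetics of competing hydrogen sinks in anaerobic fermentation.

The module computes standard-transformed Gibbs energies (the biochemical
dG0', defined at pH 7, 1 M aqueous / 1 atm gaseous standard states, water
activity 1) for element- and charge-balanced reactions, extrapolates them
across temperature with the linear Gibbs-Helmholtz relation

    dG0'(T) = dG0'(T0) * (T/T0) + dH0' * (1 - T/T0),      T0 = 298.15 K,

with the reaction enthalpy taken as temperature-independent over the
25-70 degC range of interest, and evaluates actual reaction energies

    dG = dG0'(T) + R*T*ln(Q)

for arbitrary metabolite activities and hydrogen partial pressures.  Because
dG is monotone in ln(P_H2), the hydrogen partial pressure at which a
H2-producing or H2-consuming reaction becomes reversible (dG = 0) has the
closed form used by :func:`h2_threshold`; such thresholds are the standard
currency for reasoning about interspecies hydrogen transfer (methanogenesis
keeps P_H2 near ~0.1-1 Pa, homoacetogenesis needs more, and NADH-driven H2
evolution is only feasible below ~60 Pa).

Inorganic carbon is represented as aqueous bicarbonate plus a proton by
default (the convention under which the packaged formation table reproduces
the tabulated methanogenesis/homoacetogenesis energies); gaseous-CO2
variants ship alongside under ``*_gas_co2`` names.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

from .formulas import parse_formula

__all__ = [
    "R_KJ",
    "T_REF",
    "ATM_TO_PA",
    "Species",
    "Reaction",
    "ThermoConditions",
    "ReactionBalanceError",
    "FormationDataError",
    "DeltaG",
    "load_species",
    "load_reactions",
    "delta_g_standard_prime",
    "delta_g_actual",
    "h2_threshold",
    "rank_h2_sinks",
    "RankedSink",
]

R_KJ = 8.314462618e-3  # gas constant, kJ/(mol K)
T_REF = 298.15  # reference temperature, K
ATM_TO_PA = 101325.0
PH_REF = 7.0  # pH of the transformed (primed) standard state
_BALANCE_TOL = 1e-9

PROTON = "H+"
HYDROGEN = "H2"


class ReactionBalanceError(ValueError):
    """A reaction does not balance in some element or in charge."""


class FormationDataError(LookupError):
    """A species lacks the formation data needed for an energy sum."""


@dataclass(frozen=True, eq=False)
class Species:
    """A chemical entity with formation properties.

    Parameters
    ----------
    name : str
        Registry identifier (e.g. ``"acetate"``, ``"H2"``).
    formula : mapping or str
        Element -> count map.  Counts must be non-negative; fractional
        counts are only meaningful for per-carbon biomass pseudo-formulas.
    charge : int
        Net charge of the species as written.
    phase : {"aqueous", "gas", "water"}
        ``water`` marks the solvent: its activity is fixed at 1 in every
        mass-action quotient.
    dgf0, dhf0 : float or None
        Standard formation Gibbs energy / enthalpy at 298.15 K, kJ/mol.
        ``None`` means "not available" and triggers an explicit error if an
        energy computation needs it.
    """

    name: str
    formula: Mapping[str, float]
    charge: int = 0
    phase: str = "aqueous"
    dgf0: float | None = None
    dhf0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", dict(parse_formula(self.formula)))
        if self.phase not in ("aqueous", "gas", "water"):
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")
        fractional_ok = "biomass" in self.name.lower()
        for el, n in self.formula.items():
            if n < 0:
                raise ValueError(f"negative count of {el} in {self.name}")
            if not float(n).is_integer() and not fractional_ok:
                raise ValueError(
                    f"fractional element count {el}={n} only allowed for "
                    f"biomass pseudo-species, not {self.name!r}"
                )

    def __hash__(self) -> int:
        return hash(self.name)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and other.name == self.name

    def __repr__(self) -> str:  # keep reprs short in reaction dumps
        return f"Species({self.name!r})"


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric map over :class:`Species` (reactants negative)."""

    name: str
    stoichiometry: Mapping[Species, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "stoichiometry",
            {sp: float(c) for sp, c in self.stoichiometry.items() if c != 0},
        )

    # -- balance -----------------------------------------------------------
    def element_imbalance(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for sp, coef in self.stoichiometry.items():
            for el, n in sp.formula.items():
                totals[el] = totals.get(el, 0.0) + coef * n
        return {el: v for el, v in totals.items() if abs(v) > _BALANCE_TOL}

    def charge_imbalance(self) -> float:
        return sum(coef * sp.charge for sp, coef in self.stoichiometry.items())

    def validate(self) -> None:
        bad = self.element_imbalance()
        if bad:
            raise ReactionBalanceError(f"{self.name}: element imbalance {bad}")
        q = self.charge_imbalance()
        if abs(q) > _BALANCE_TOL:
            raise ReactionBalanceError(f"{self.name}: charge imbalance {q:+g}")

    # -- algebra -----------------------------------------------------------
    def reversed(self) -> "Reaction":
        return Reaction(
            f"{self.name}_reversed",
            {sp: -c for sp, c in self.stoichiometry.items()},
        )

    def __add__(self, other: "Reaction") -> "Reaction":
        combined: dict[Species, float] = dict(self.stoichiometry)
        for sp, c in other.stoichiometry.items():
            combined[sp] = combined.get(sp, 0.0) + c
        return Reaction(f"{self.name}+{other.name}", combined)

    def coefficient(self, species_name: str) -> float:
        for sp, c in self.stoichiometry.items():
            if sp.name == species_name:
                return c
        return 0.0

    def __repr__(self) -> str:
        lhs = " + ".join(
            f"{-c:g} {sp.name}" for sp, c in self.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            f"{c:g} {sp.name}" for sp, c in self.stoichiometry.items() if c > 0
        )
        return f"Reaction({self.name}: {lhs} -> {rhs})"


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature, pH and species activities for an energy evaluation.

    Activities are relative to the standard states (mol/L over 1 M for
    aqueous species, partial pressure in atm over 1 atm for gases).  The
    proton activity is always derived from ``ph`` and may not be set in
    ``activities``.
    """

    temperature: float = T_REF  # K
    ph: float = PH_REF
    activities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if PROTON in self.activities:
            raise ValueError("H+ activity is derived from pH; do not set it")
        for name, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {name} must be positive, got {a}")
        object.__setattr__(self, "activities", dict(self.activities))

    def with_activity(self, name: str, value: float) -> "ThermoConditions":
        acts = dict(self.activities)
        acts[name] = value
        return ThermoConditions(self.temperature, self.ph, acts)


class DeltaG(float):
    """A Gibbs energy (kJ/mol) carrying evaluation metadata.

    ``defaulted`` lists species whose activity was not supplied and was
    taken as 1 (standard state).
    """

    defaulted: tuple[str, ...] = ()

    def __new__(cls, value: float, defaulted: Iterable[str] = ()) -> "DeltaG":
        obj = super().__new__(cls, value)
        obj.defaulted = tuple(defaulted)
        return obj


# ---------------------------------------------------------------------------
# registry loading
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("mcferm.data").joinpath(filename)


def load_species(path: str | Path | None = None) -> dict[str, Species]:
    """Load the species table (packaged TSV by default, user-overridable)."""
    source = Path(path).read_text() if path is not None else _data_path(
        "species.tsv"
    ).read_text()
    species: dict[str, Species] = {}
    header: list[str] | None = None
    for line in source.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        dgf = row.get("dGf0_kJ_mol", "")
        dhf = row.get("dHf0_kJ_mol", "")
        species[row["name"]] = Species(
            name=row["name"],
            formula=row["formula"],
            charge=int(row["charge"]),
            phase=row["phase"],
            dgf0=float(dgf) if dgf not in ("", None) else None,
            dhf0=float(dhf) if dhf not in ("", None) else None,
        )
    return species


def load_reactions(
    species: Mapping[str, Species] | None = None,
    path: str | Path | None = None,
) -> dict[str, Reaction]:
    """Load and validate the reaction registry."""
    if species is None:
        species = load_species()
    source = Path(path).read_text() if path is not None else _data_path(
        "reactions.txt"
    ).read_text()
    reactions: dict[str, Reaction] = {}
    for line in source.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, body = line.partition(":")
        name = name.strip()
        lhs, arrow, rhs = body.partition("->")
        if not arrow:
            raise ValueError(f"reaction line without '->': {line!r}")
        stoich: dict[Species, float] = {}
        # terms are separated by " + " (species names may themselves end in +)
        for side, sign in ((lhs, -1.0), (rhs, +1.0)):
            for term in side.split(" + "):
                term = term.strip()
                if not term:
                    continue
                coef_str, _, sp_name = term.partition(" ")
                sp_name = sp_name.strip()
                if sp_name not in species:
                    raise FormationDataError(
                        f"reaction {name!r} references unknown species {sp_name!r}"
                    )
                sp = species[sp_name]
                stoich[sp] = stoich.get(sp, 0.0) + sign * float(coef_str)
        rxn = Reaction(name, stoich)
        rxn.validate()
        reactions[name] = rxn
    return reactions


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _formation_sums(reaction: Reaction) -> tuple[float, float]:
    """(dG0, dH0) stoichiometric sums at 298.15 K, unprimed (pH 0)."""
    dg = 0.0
    dh = 0.0
    for sp, coef in reaction.stoichiometry.items():
        if sp.dgf0 is None or sp.dhf0 is None:
            raise FormationDataError(
                f"species {sp.name!r} has no formation data; cannot compute "
                f"energies for reaction {reaction.name!r}"
            )
        dg += coef * sp.dgf0
        dh += coef * sp.dhf0
    return dg, dh


def delta_g_standard_prime(reaction: Reaction, T: float = T_REF) -> float:
    """Standard-transformed Gibbs energy dG0'(T) in kJ/mol.

    The primed standard state fixes the proton activity at 10**-7 (pH 7);
    temperature extrapolation is linear Gibbs-Helmholtz with the reaction
    enthalpy held constant.  Valid for 273 K <= T <= 400 K.
    """
    reaction.validate()
    if not (273.0 <= T <= 400.0):
        raise ValueError(f"temperature {T} K outside supported range 273-400 K")
    dg0, dh0 = _formation_sums(reaction)
    nu_h = reaction.coefficient(PROTON)
    dg0p_ref = dg0 + nu_h * R_KJ * T_REF * math.log(10.0 ** (-PH_REF))
    # The pH term is an activity (RT ln) contribution: it scales with T under
    # the Gibbs-Helmholtz extrapolation exactly as written here.
    return dg0p_ref * (T / T_REF) + dh0 * (1.0 - T / T_REF)


def delta_g_actual(reaction: Reaction, cond: ThermoConditions) -> DeltaG:
    """Actual Gibbs energy dG = dG0'(T) + RT ln Q in kJ/mol.

    Water activity is 1; the proton enters through ``cond.ph`` relative to
    the pH-7 reference of the primed standard state.  Species without an
    activity in ``cond`` default to 1 and are listed in the result's
    ``defaulted`` attribute.
    """
    T = cond.temperature
    dg0p = delta_g_standard_prime(reaction, T)
    ln_q = 0.0
    defaulted: list[str] = []
    for sp, coef in reaction.stoichiometry.items():
        if sp.phase == "water":
            continue
        if sp.name == PROTON:
            ln_q += coef * math.log(10.0 ** (PH_REF - cond.ph))
            continue
        if sp.name in cond.activities:
            a = cond.activities[sp.name]
        else:
            a = 1.0
            defaulted.append(sp.name)
        if a <= 0:
            raise ValueError(f"activity of {sp.name} must be positive, got {a}")
        ln_q += coef * math.log(a)
    return DeltaG(dg0p + R_KJ * T * ln_q, defaulted)


def h2_threshold(reaction: Reaction, cond: ThermoConditions | None = None) -> float:
    """Hydrogen partial pressure (Pa) at which the reaction is reversible.

    Holds every activity other than H2 fixed at its value in ``cond`` and
    solves dG = 0.  Since dG = dG_rest + n_H2 * R * T * ln(P_H2), the
    solution is the closed form P_H2 = exp(-dG_rest / (n_H2 R T)) atm.
    """
    if cond is None:
        cond = ThermoConditions()
    nu_h2 = reaction.coefficient(HYDROGEN)
    if nu_h2 == 0:
        raise ValueError(f"reaction {reaction.name!r} does not involve H2")
    dg_rest = float(delta_g_actual(reaction, cond.with_activity(HYDROGEN, 1.0)))
    T = cond.temperature
    p_atm = math.exp(-dg_rest / (nu_h2 * R_KJ * T))
    return p_atm * ATM_TO_PA


class RankedSink(NamedTuple):
    """One entry of a hydrogen-sink favourability ranking."""

    reaction: Reaction
    delta_g: float  # kJ/mol reaction
    delta_g_per_mol_h2: float | None  # kJ per mol H2 consumed, None if no H2


_SINK_NAMES = (
    "hydrogenotrophic_methanogenesis",
    "homoacetogenesis",
    "aceticlastic_methanogenesis",
)


def rank_h2_sinks(
    T: float = T_REF,
    cond: ThermoConditions | None = None,
    reactions: Sequence[Reaction] | None = None,
) -> list[RankedSink]:
    """Rank competing sink reactions by ascending dG (most favourable first).

    By default ranks the three packaged pathways that compete for reducing
    equivalents in an anaerobic digester: hydrogenotrophic methanogenesis,
    homoacetogenesis and aceticlastic methanogenesis.  ``cond`` overrides
    the standard-state evaluation; its temperature, if given, must agree
    with ``T``.
    """
    if reactions is None:
        registry = load_reactions()
        reactions = [registry[name] for name in _SINK_NAMES]
    if cond is None:
        cond = ThermoConditions(temperature=T)
    elif abs(cond.temperature - T) > 1e-9:
        raise ValueError("cond.temperature disagrees with T")
    ranked = []
    for rxn in reactions:
        dg = float(delta_g_actual(rxn, cond))
        nu = rxn.coefficient(HYDROGEN)
        per_h2 = dg / abs(nu) if nu else None
        ranked.append(RankedSink(rxn, dg, per_h2))
    ranked.sort(key=lambda r: r.delta_g)
    return ranked
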