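"""Reaction energetics: formation sums, temperature correction, thresholds."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcferm import thermo
from mcferm.thermo import (
    ATM_TO_PA,
    R_KJ,
    FormationDataError,
    Reaction,
    ReactionBalanceError,
    Species,
    ThermoConditions,
    delta_g_actual,
    delta_g_standard_prime,
    h2_threshold,
    rank_h2_sinks,
)

T70 = 343.15
T25 = 298.15


# ------------------------------------------------------------- registry --
def test_packaged_reactions_balance_exactly(reactions):
    for rxn in reactions.values():
        assert rxn.element_imbalance() == {}
        assert abs(rxn.charge_imbalance()) < 1e-9


def test_species_table_covers_core_metabolites(species):
    core = {"H2", "CH4", "CO2", "HCO3-", "H2O", "H+", "acetate", "glucose",
            "ethanol", "propionate", "butyrate"}
    assert core <= set(species)
    assert species["H2O"].phase == "water"
    assert species["H2"].phase == "gas"


def test_fractional_formula_rejected_except_biomass():
    Species("biomass", "CH1.8O0.5N0.2")  # allowed
    with pytest.raises(ValueError, match="fractional"):
        Species("oddball", "CH1.5O")


# ---------------------------------------------- standard-transformed dG --
@pytest.mark.parametrize(
    ("name", "t_k", "expected"),
    [
        ("hydrogenotrophic_methanogenesis", T25, -135.5),
        ("hydrogenotrophic_methanogenesis", T70, -119.6),
        ("homoacetogenesis", T25, -104.5),
        ("homoacetogenesis", T70, -83.2),
        ("aceticlastic_methanogenesis", T25, -31.0),
        ("aceticlastic_methanogenesis", T70, -36.4),
    ],
)
def test_sink_reaction_energies_at_both_temperatures(reactions, name, t_k, expected):
    """The packaged formation table reproduces the tabulated dG0' values."""
    assert delta_g_standard_prime(reactions[name], t_k) == pytest.approx(
        expected, abs=1.5
    )


def test_empty_reaction_has_zero_energy():
    assert delta_g_standard_prime(Reaction("empty", {}), 310.0) == 0.0


def test_gibbs_helmholtz_fixed_point(reactions, species):
    """At 298.15 K the temperature correction vanishes: pure formation sum."""
    rxn = reactions["aceticlastic_methanogenesis"]  # no H+, so unprimed == primed
    expected = sum(c * sp.dgf0 for sp, c in rxn.stoichiometry.items())
    assert delta_g_standard_prime(rxn, 298.15) == pytest.approx(expected, abs=1e-9)


def test_unbalanced_reaction_rejected(species):
    rxn = Reaction("broken", {species["H2"]: -1, species["CH4"]: 1})
    with pytest.raises(ReactionBalanceError):
        delta_g_standard_prime(rxn, 298.15)


def test_missing_formation_data_names_species():
    # balanced isomerization between a data-less species and a known one
    a = Species("mystery", "C2H4O2", 0, "aqueous", None, None)
    b = Species("acetic_known", "C2H4O2", 0, "aqueous", -396.0, -485.0)
    rxn = Reaction("iso", {a: -1.0, b: 1.0})
    with pytest.raises(FormationDataError, match="mystery"):
        delta_g_standard_prime(rxn, 298.15)


# --------------------------------------------------------- actual dG, Q --
def test_all_unit_activities_reduce_to_standard(reactions):
    rxn = reactions["hydrogenotrophic_methanogenesis"]
    cond = ThermoConditions(temperature=T70, ph=7.0)
    dg = delta_g_actual(rxn, cond)
    assert float(dg) == pytest.approx(delta_g_standard_prime(rxn, T70), abs=1e-9)
    assert set(dg.defaulted) == {"H2", "HCO3-", "CH4"}


def test_low_hydrogen_pressure_pulls_methanogenesis_toward_zero(reactions):
    """At P_H2 = 1e-5 atm the driving force shrinks to about -21 kJ/mol."""
    rxn = reactions["hydrogenotrophic_methanogenesis"]
    cond = ThermoConditions(temperature=T25, activities={"H2": 1e-5})
    dg = float(delta_g_actual(rxn, cond))
    closed_form = delta_g_standard_prime(rxn, T25) - 4 * R_KJ * T25 * math.log(1e-5)
    assert dg == pytest.approx(closed_form, abs=1e-9)
    assert dg == pytest.approx(-21.4, abs=0.5)


def test_reversal_antisymmetry_and_additivity(reactions):
    cond = ThermoConditions(
        temperature=T70, ph=6.8, activities={"H2": 1e-4, "CH4": 0.7, "acetate": 0.05}
    )
    hydro = reactions["hydrogenotrophic_methanogenesis"]
    acl = reactions["aceticlastic_methanogenesis"]
    assert float(delta_g_actual(hydro.reversed(), cond)) == pytest.approx(
        -float(delta_g_actual(hydro, cond)), abs=1e-9
    )
    combined = hydro + acl
    assert float(delta_g_actual(combined, cond)) == pytest.approx(
        float(delta_g_actual(hydro, cond)) + float(delta_g_actual(acl, cond)),
        abs=1e-9,
    )


def test_nonpositive_activity_rejected():
    with pytest.raises(ValueError):
        ThermoConditions(activities={"H2": 0.0})
    with pytest.raises(ValueError, match="pH"):
        ThermoConditions(activities={"H+": 1e-7})


# ------------------------------------------------------------ threshold --
def test_methanogenesis_threshold_is_sub_pascal(reactions):
    """Hydrogenotrophic methanogens can pull H2 to ~0.1 Pa at 25 C."""
    thr = h2_threshold(reactions["hydrogenotrophic_methanogenesis"],
                       ThermoConditions(temperature=T25))
    assert 0.05 < thr < 1.0
    closed = math.exp(
        delta_g_standard_prime(
            reactions["hydrogenotrophic_methanogenesis"], T25
        ) / (4 * R_KJ * T25)
    ) * ATM_TO_PA
    assert thr == pytest.approx(closed, rel=1e-12)


def test_nadh_couple_threshold_matches_fermentative_feasibility_bound(reactions):
    """NADH-driven H2 evolution shuts off near the classic ~60 Pa ceiling."""
    thr = h2_threshold(reactions["nadh_h2_evolution"], ThermoConditions(temperature=T25))
    assert 60.0 / 1.5 <= thr <= 60.0 * 1.5


def test_delta_g_vanishes_at_returned_threshold(reactions):
    for name in ("hydrogenotrophic_methanogenesis", "homoacetogenesis",
                 "nadh_h2_evolution"):
        rxn = reactions[name]
        cond = ThermoConditions(temperature=T25)
        p_atm = h2_threshold(rxn, cond) / ATM_TO_PA
        dg = float(delta_g_actual(rxn, cond.with_activity("H2", p_atm)))
        assert abs(dg) < 1e-6


def test_threshold_direction_under_warming_follows_reaction_enthalpy(reactions):
    """Exothermic H2 consumption gets less favourable when heated, raising
    the threshold; the sign of the shift must match the enthalpy sign."""
    rxn = reactions["hydrogenotrophic_methanogenesis"]
    dh = sum(c * sp.dhf0 for sp, c in rxn.stoichiometry.items())
    thr_25 = h2_threshold(rxn, ThermoConditions(temperature=T25))
    thr_70 = h2_threshold(rxn, ThermoConditions(temperature=T70))
    assert dh < 0  # methanogenesis is exothermic
    assert thr_70 > thr_25


def test_threshold_requires_hydrogen(reactions):
    with pytest.raises(ValueError, match="H2"):
        h2_threshold(reactions["aceticlastic_methanogenesis"])


# -------------------------------------------------------------- ranking --
def test_hydrogenotrophic_methanogenesis_outranks_competitors(reactions):
    for t_k in (T25, T70):
        ranked = rank_h2_sinks(t_k)
        names = [s.reaction.name for s in ranked]
        assert names[0] == "hydrogenotrophic_methanogenesis"
        assert names.index("hydrogenotrophic_methanogenesis") < names.index(
            "homoacetogenesis"
        )
        per_h2 = [s.delta_g_per_mol_h2 for s in ranked]
        assert per_h2[0] is not None and per_h2[0] < 0


def test_single_reaction_registry_ranks_alone(reactions):
    ranked = rank_h2_sinks(T25, reactions=[reactions["homoacetogenesis"]])
    assert len(ranked) == 1
    assert ranked[0].reaction.name == "homoacetogenesis"


# ------------------------------------------------------ property checks --
@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    t_k=st.floats(min_value=273.0, max_value=400.0),
    scale=st.floats(min_value=0.25, max_value=4.0),
)
def test_energy_scales_linearly_with_stoichiometry(t_k, scale):
    reactions = thermo.load_reactions()
    rxn = reactions["hydrogenotrophic_methanogenesis"]
    scaled = Reaction("scaled", {sp: c * scale for sp, c in rxn.stoichiometry.items()})
    assert delta_g_standard_prime(scaled, t_k) == pytest.approx(
        scale * delta_g_standard_prime(rxn, t_k), rel=1e-12
    )
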