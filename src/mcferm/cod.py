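"""Electron (COD) accounting for fermentation products.

Chemical oxygen demand is the electron-conserving currency used to close
mass balances over a fermentation: each compound's theoretical oxygen
demand is 8 times its degree of reduction,

    ThOD = 8 * (4*C + H - 2*O - 3*N - z)   g O2 per mol,

with nitrogen released as ammonia and z the net charge (so an anion and its
conjugate acid carry the same COD).  Glucose is 192 g/mol; a balanced,
redox-neutral conversion conserves COD exactly, which makes the per-row
"COD balance" of a yield table a sharp completeness check on measured
product spectra.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from ._io import read_text_or_path
from .formulas import parse_formula

__all__ = [
    "OverOxidizedWarning",
    "BIOMASS_FORMULA",
    "METABOLITE_FORMULAS",
    "cod_of",
    "cod_of_metabolite",
    "YieldTable",
    "cod_balance",
    "theoretical_yields",
    "aggregate_yield_tables",
]


class OverOxidizedWarning(UserWarning):
    """A formula is oxidized beyond O2-neutrality (negative ThOD, clamped to 0)."""


#: Per-carbon biomass pseudo-formula used throughout anaerobic bioprocess
#: accounting; 24.62 g/C-mol, 33.6 g COD/C-mol.
BIOMASS_FORMULA = "CH1.8O0.5N0.2"

#: Neutral (protonated) formulas used for COD of the usual fermentation
#: metabolites.  Yields are expressed per mol glucose.
METABOLITE_FORMULAS: dict[str, str] = {
    "glucose": "C6H12O6",
    "acetate": "C2H4O2",
    "propionate": "C3H6O2",
    "butyrate": "C4H8O2",
    "lactate": "C3H6O3",
    "formate": "CH2O2",
    "ethanol": "C2H6O",
    "butanol": "C4H10O",
    "methane": "CH4",
    "hydrogen": "H2",
    "co2": "CO2",
    "biomass": BIOMASS_FORMULA,
}

_ELECTRON_WEIGHTS = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0}


def cod_of(formula: str | Mapping[str, float], charge: float = 0.0) -> float:
    """Theoretical oxygen demand in g O2 per mol of the given formula.

    Nitrogen is assumed released as ammonia (no nitrification demand).
    Over-oxidized inputs (e.g. CO2) clamp to 0 with an
    :class:`OverOxidizedWarning` rather than returning a negative demand.
    """
    counts = parse_formula(formula)
    # Elements outside C/H/O/N carry no electron weight in the
    # ammonia-release convention.
    degree = sum(_ELECTRON_WEIGHTS.get(el, 0.0) * n for el, n in counts.items())
    degree -= charge
    thod = 8.0 * degree
    if thod < 0:
        warnings.warn(
            f"formula {formula!r} is over-oxidized (ThOD {thod:.1f} g/mol); "
            "clamping to 0",
            OverOxidizedWarning,
            stacklevel=2,
        )
        return 0.0
    return thod


def cod_of_metabolite(name: str) -> float:
    """COD (g O2/mol, per C-mol for biomass) of a named metabolite."""
    try:
        formula = METABOLITE_FORMULAS[name]
    except KeyError:
        known = ", ".join(sorted(METABOLITE_FORMULAS))
        raise KeyError(f"unknown metabolite {name!r}; known: {known}") from None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverOxidizedWarning)
        return cod_of(formula)


#: Homoacetogenic ceiling: at most 3 mol acetate can come from 1 mol glucose
#: even when every reducing equivalent is routed back into acetate.
ACETATE_YIELD_CEILING = 3.0


@dataclass
class YieldTable:
    """Per-metabolite yields in mol per mol glucose.

    Biomass yields are in C-mol per mol glucose (per-carbon pseudo-formula).
    """

    yields: dict[str, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        for name, y in self.yields.items():
            if name not in METABOLITE_FORMULAS:
                known = ", ".join(sorted(METABOLITE_FORMULAS))
                raise KeyError(f"unknown metabolite {name!r}; known: {known}")
            if not math.isfinite(y) or y < 0:
                raise ValueError(f"yield of {name} must be finite and >= 0, got {y}")
        if self.yields.get("acetate", 0.0) > ACETATE_YIELD_CEILING + 1e-12:
            raise ValueError(
                f"acetate yield {self.yields['acetate']} exceeds the "
                f"homoacetogenic ceiling of {ACETATE_YIELD_CEILING} mol/mol-glucose"
            )

    def __getitem__(self, name: str) -> float:
        return self.yields.get(name, 0.0)

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["metabolite", "yield_mol_per_mol_glucose"])
        for name, y in self.yields.items():
            writer.writerow([name, repr(y)])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path, label: str | None = None) -> "YieldTable":
        text = read_text_or_path(source)
        rows = list(csv.DictReader(io.StringIO(text)))
        yields = {
            r["metabolite"]: float(r["yield_mol_per_mol_glucose"]) for r in rows
        }
        return cls(yields, label=label)


def cod_balance(yields: YieldTable | Mapping[str, float]) -> float:
    """COD closure of a yield table, percent of the glucose COD.

    100 % means the measured products account for every electron in the
    consumed glucose; shortfalls flag undetected products, excesses flag
    measurement bias.
    """
    table = yields.yields if isinstance(yields, YieldTable) else dict(yields)
    YieldTable(dict(table))  # validate names/values
    glucose_cod = cod_of_metabolite("glucose")
    total = sum(
        y * cod_of_metabolite(name)
        for name, y in table.items()
        if name != "glucose"
    )
    return 100.0 * total / glucose_cod


def theoretical_yields(biomass_fraction: float = 0.0) -> YieldTable:
    """Theoretical product spectrum of the overall acetate+methane conversion.

    The acetate-type fermentation (glucose -> 2 acetate + 2 CO2 + 4 H2)
    coupled to hydrogenotrophic methanogenesis (4 H2 + CO2 -> CH4 + 2 H2O)
    eliminates H2 and gives glucose -> 2 acetate + CH4 + CO2.  A requested
    electron fraction is diverted to biomass, scaling acetate and methane
    down proportionally (COD-proportional divert), so the returned table
    closes its COD balance at exactly 100 %.
    """
    f = float(biomass_fraction)
    if not 0.0 <= f < 1.0:
        raise ValueError(f"biomass_fraction must be in [0, 1), got {f}")
    glucose_cod = cod_of_metabolite("glucose")
    biomass_cmol = f * glucose_cod / cod_of_metabolite("biomass")
    acetate = 2.0 * (1.0 - f)
    methane = 1.0 * (1.0 - f)
    # CO2 closes the carbon balance (6 C per glucose).
    co2 = 6.0 - 2.0 * acetate - methane - biomass_cmol
    table = {"acetate": acetate, "methane": methane, "co2": co2}
    if f > 0:
        table["biomass"] = biomass_cmol
    return YieldTable(table, label=f"theoretical(f_biomass={f:g})")


def aggregate_yield_tables(
    tables: Sequence[YieldTable] | Iterable[YieldTable],
) -> tuple[YieldTable, YieldTable]:
    """Mean and sample standard deviation (ddof=1) across yield tables.

    Metabolites missing from a table count as zero, matching how sampling-day
    tables omit undetected products.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one yield table")
    names = sorted({n for t in tables for n in t.yields})
    k = len(tables)
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for name in names:
        vals = [t[name] for t in tables]
        mu = sum(vals) / k
        means[name] = mu
        if k > 1:
            stds[name] = math.sqrt(sum((v - mu) ** 2 for v in vals) / (k - 1))
        else:
            stds[name] = 0.0
    return YieldTable(means, label="mean"), YieldTable(stds, label="std")
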