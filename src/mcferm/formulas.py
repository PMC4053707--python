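"""Elemental formula parsing and molar-mass arithmetic.

Formulas are plain condensed strings ("C6H12O6", "CH1.8O0.5N0.2"); counts may
be fractional, which is how per-carbon biomass pseudo-formulas are written.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

__all__ = ["parse_formula", "format_formula", "molar_mass", "ATOMIC_MASSES"]

# Standard atomic weights for the handful of elements that occur in
# fermentation metabolites and mineral media.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?)?")


def parse_formula(formula: str | Mapping[str, float]) -> dict[str, float]:
    """Parse a condensed formula into an element -> count map.

    A mapping passes through (copied), so call sites can accept either form.
    """
    if isinstance(formula, Mapping):
        return {el: float(n) for el, n in formula.items() if n != 0}
    counts: dict[str, float] = {}
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        element = m.group(1)
        n = float(m.group(2)) if m.group(2) else 1.0
        counts[element] = counts.get(element, 0.0) + n
        pos = m.end()
    if not counts:
        raise ValueError(f"empty formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, float]) -> str:
    """Condensed-string form, Hill-ish ordering (C, H, then alphabetical)."""
    order = sorted(counts, key=lambda el: (el != "C", el != "H", el))
    parts = []
    for el in order:
        n = counts[el]
        if n == 0:
            continue
        if n == 1:
            parts.append(el)
        elif float(n).is_integer():
            parts.append(f"{el}{int(n)}")
        else:
            parts.append(f"{el}{n:g}")
    return "".join(parts)


def molar_mass(formula: str | Mapping[str, float]) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_MASSES[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - config error
        raise KeyError(f"no atomic mass for element {exc.args[0]!r}") from exc
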