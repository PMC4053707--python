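"""Loaders for the small tables shipped with the package.

These are the printed study tables the analysis consumes: sampling-day
yield tables from the 100-day extreme-thermophilic CSTR run, the archaeal
and bacterial clone libraries from the same reactor, and the default
guild map for those libraries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cod import YieldTable
from .community import CloneLibrary, GuildMap

__all__ = [
    "load_cstr_yield_frame",
    "load_cstr_yield_tables",
    "load_archaea_clones",
    "load_bacteria_clones",
    "load_guild_map",
]

_METABOLITE_COLUMNS = ["acetate", "butyrate", "propionate", "ethanol", "methane", "biomass"]


def _data(name: str):
    return resources.files("mcferm.data").joinpath(name)


def load_cstr_yield_frame() -> pd.DataFrame:
    """Sampling-day CSTR yields as a DataFrame.

    Columns: day, cod_balance_percent (the value reported alongside the
    measurements), and per-metabolite yields in mol/mol-glucose (biomass in
    C-mol/mol-glucose).
    """
    with _data("cstr_yields.csv").open() as fh:
        return pd.read_csv(fh)


def load_cstr_yield_tables() -> list[YieldTable]:
    """The same sampling-day yields as a list of :class:`YieldTable`."""
    frame = load_cstr_yield_frame()
    tables = []
    for _, row in frame.iterrows():
        yields = {m: float(row[m]) for m in _METABOLITE_COLUMNS if row[m] > 0}
        tables.append(YieldTable(yields, label=f"day {int(row['day'])}"))
    return tables


def load_archaea_clones() -> CloneLibrary:
    """Archaeal 16S clone library from the steady-state CSTR (48 clones)."""
    return CloneLibrary.from_tsv(_data("archaea_clones.tsv").read_text(), domain="Archaea")


def load_bacteria_clones() -> CloneLibrary:
    """Bacterial 16S clone library from the steady-state CSTR (53 clones)."""
    return CloneLibrary.from_tsv(_data("bacteria_clones.tsv").read_text(), domain="Bacteria")


def load_guild_map() -> GuildMap:
    """Default genus-level guild assignment for the packaged libraries."""
    return GuildMap.from_yaml(_data("guilds.yaml").read_text())
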