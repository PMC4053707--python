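"""Clone-library summaries: phylotype abundances and metabolic guilds.

A 16S rRNA clone library is a count table of phylotypes; relative
abundances are always recomputed from the counts (printed percent columns
in literature tables are not trusted), reported to one decimal with
half-up rounding.  Guild fractions collapse phylotypes into functional
groups (hydrogenotrophic vs aceticlastic methanogens, homoacetogens,
fermenters) so that the observed community can be confronted with the
thermodynamic ranking of the competing hydrogen sinks.
"""

from __future__ import annotations

import csv
import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from ._io import read_text_or_path
from .thermo import RankedSink

__all__ = [
    "GUILDS",
    "CloneRecord",
    "CloneLibrary",
    "GuildMap",
    "UncoveredCloneError",
    "relative_abundance",
    "guild_fractions",
    "consistency_check",
    "ConsistencyReport",
]

GUILDS = (
    "hydrogenotrophic_methanogen",
    "aceticlastic_methanogen",
    "homoacetogen",
    "fermenter",
    "other",
)

#: Guilds that act as sinks for acetate or hydrogen; used when matching
#: community dominance against the bioenergetic ranking.
_REACTION_GUILDS = {
    "hydrogenotrophic_methanogenesis": "hydrogenotrophic_methanogen",
    "homoacetogenesis": "homoacetogen",
    "aceticlastic_methanogenesis": "aceticlastic_methanogen",
}


class UncoveredCloneError(KeyError):
    """A clone's closest relative has no guild assignment."""


def _round1(value: float) -> float:
    """One-decimal half-up rounding, as percent columns are printed."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class CloneRecord:
    """One phylotype row: clone name, closest relative, similarity, count."""

    clone: str
    closest_relative: str
    similarity: float  # percent identity to the closest relative
    count: int

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity <= 100.0):
            raise ValueError(f"similarity must be in (0, 100], got {self.similarity}")
        if not isinstance(self.count, int) or self.count <= 0:
            raise ValueError(f"count must be a positive integer, got {self.count!r}")


@dataclass
class CloneLibrary:
    """A clone-count table for one domain (Archaea or Bacteria)."""

    records: list[CloneRecord]
    domain: str = "Archaea"

    def __post_init__(self) -> None:
        names = [r.clone for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clone names in library")

    @property
    def total(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def counts(self) -> dict[str, int]:
        return {r.clone: r.count for r in self.records}

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_tsv(cls, source: str | Path, domain: str = "Archaea") -> "CloneLibrary":
        text = read_text_or_path(source)
        rows = csv.DictReader(io.StringIO(text), delimiter="\t")
        records = [
            CloneRecord(
                clone=r["clone"],
                closest_relative=r["closest_relative"],
                similarity=float(r["similarity_percent"]),
                count=int(r["count"]),
            )
            for r in rows
        ]
        return cls(records, domain=domain)

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t")
        writer.writerow(["clone", "closest_relative", "similarity_percent", "count"])
        for r in self.records:
            writer.writerow([r.clone, r.closest_relative, r.similarity, r.count])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class GuildMap:
    """Closest-relative name -> guild assignment.

    Keys may be full relative names or genus-level prefixes (the first
    whitespace-separated token); full-name matches take precedence.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, guild in self.entries.items():
            if guild not in GUILDS:
                raise ValueError(
                    f"unknown guild {guild!r} for {key!r}; choose from {GUILDS}"
                )

    def guild_of(self, record: CloneRecord) -> str:
        relative = record.closest_relative
        if relative in self.entries:
            return self.entries[relative]
        genus = relative.split()[0]
        if genus in self.entries:
            return self.entries[genus]
        raise UncoveredCloneError(
            f"no guild assignment for clone {record.clone!r} "
            f"(closest relative {relative!r})"
        )

    @classmethod
    def from_yaml(cls, source: str | Path) -> "GuildMap":
        text = read_text_or_path(source)
        data = yaml.safe_load(text)
        if isinstance(data, dict) and "guilds" in data:
            data = data["guilds"]
        return cls(dict(data))


def relative_abundance(lib: CloneLibrary, group: Iterable[str]) -> float:
    """Percent of library counts in ``group`` (clone names), one decimal."""
    group = set(group)
    known = set(lib.counts)
    unknown = group - known
    if unknown:
        raise KeyError(f"unknown clone names: {sorted(unknown)}")
    if lib.total <= 0:
        raise ValueError("library has no counts")
    frac = 100.0 * sum(lib.counts[name] for name in group) / lib.total
    return _round1(frac)


def guild_fractions(lib: CloneLibrary, guilds: GuildMap) -> dict[str, float]:
    """Percent of library counts per guild, recomputed from counts.

    Every clone must map to exactly one guild; an uncovered clone raises
    :class:`UncoveredCloneError` naming it.  Fractions are reported to one
    decimal and sum to 100 within rounding.
    """
    totals: dict[str, int] = {}
    for record in lib:
        guild = guilds.guild_of(record)  # raises with the clone named
        totals[guild] = totals.get(guild, 0) + record.count
    n = lib.total
    return {guild: _round1(100.0 * c / n) for guild, c in totals.items()}


@dataclass(frozen=True)
class ConsistencyReport:
    """Observed-community vs thermodynamic-ranking comparison."""

    consistent: bool | None  # None when there is no community data
    dominant_guild: str | None
    top_ranked_guild: str | None
    narrative: str

    def __bool__(self) -> bool:
        return bool(self.consistent)


def consistency_check(
    fractions: Mapping[str, float],
    ranking: Sequence[RankedSink],
) -> ConsistencyReport:
    """Does the dominant methanogenic/acetogenic guild match the bioenergetics?

    Compares the most abundant sink guild in ``fractions`` with the guild of
    the top-ranked (most exergonic) reaction in ``ranking``; both inputs
    must refer to the same temperature.
    """
    sink_fracs = {
        g: f for g, f in fractions.items() if g in _REACTION_GUILDS.values()
    }
    if not sink_fracs:
        return ConsistencyReport(None, None, None, "no data: no sink-guild counts")
    dominant = max(sink_fracs, key=sink_fracs.get)
    top_sink = None
    top_guild = None
    for sink in ranking:
        guild = _REACTION_GUILDS.get(sink.reaction.name)
        if guild is not None:
            top_sink, top_guild = sink, guild
            break
    if top_guild is None:
        return ConsistencyReport(None, dominant, None, "no data: empty ranking")
    consistent = dominant == top_guild
    verdict = "CONSISTENT" if consistent else "INCONSISTENT"
    narrative = (
        f"{verdict}: dominant observed sink guild is {dominant} "
        f"({sink_fracs[dominant]:.1f}% of clones); the most favourable sink "
        f"reaction is {top_sink.reaction.name} "
        f"(dG = {top_sink.delta_g:.1f} kJ/mol), i.e. guild {top_guild}."
    )
    return ConsistencyReport(consistent, dominant, top_guild, narrative)
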