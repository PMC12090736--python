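"""Taxonomic lineages, rank-wise comparison, and cross-namespace name mapping.

Host lineages arrive as semicolon-delimited strings, either GTDB-style with
rank prefixes (``d__Bacteria;p__Bacteroidota;...``) or as bare names in rank
order. Prefixes are stripped at parse time and every downstream comparison
operates on bare names under exact, case-sensitive equality: GTDB names are a
controlled vocabulary, and fuzzy matching would fabricate concordance.

An empty name means "unassigned at this rank". Such a name never matches
anything, including another empty name.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "Rank",
    "RANKS",
    "CONCORDANCE_RANKS",
    "HostLineage",
    "LineageParseError",
    "parse_lineage",
    "names_match_at",
    "NamespaceMap",
]


class Rank(enum.IntEnum):
    """The seven canonical ranks, ordered from shallowest to deepest."""

    DOMAIN = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6

    @property
    def prefix(self) -> str:
        return _RANK_PREFIX[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


RANKS: tuple[Rank, ...] = tuple(Rank)

#: Ranks at which concordance is reported (species is carried in the data
#: model but host predictions are not scored at species level).
CONCORDANCE_RANKS: tuple[Rank, ...] = (
    Rank.PHYLUM,
    Rank.CLASS,
    Rank.ORDER,
    Rank.FAMILY,
    Rank.GENUS,
)

_RANK_PREFIX: dict[Rank, str] = {
    Rank.DOMAIN: "d__",
    Rank.PHYLUM: "p__",
    Rank.CLASS: "c__",
    Rank.ORDER: "o__",
    Rank.FAMILY: "f__",
    Rank.GENUS: "g__",
    Rank.SPECIES: "s__",
}
_PREFIX_RANK = {v: k for k, v in _RANK_PREFIX.items()}


class LineageParseError(ValueError):
    """Raised when a lineage string cannot be interpreted."""


@dataclass(frozen=True)
class HostLineage:
    """An ordered rank -> name assignment for one host taxon.

    ``names`` holds one entry per rank in :data:`RANKS`; an empty string means
    the taxon is unassigned at that rank. A valid lineage has at least the
    domain name set.
    """

    names: tuple[str, ...]
    source_namespace: str = "gtdb"

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"expected {len(RANKS)} rank names, got {len(self.names)}"
            )

    def name_at(self, rank: Rank) -> str:
        return self.names[int(rank)]

    @property
    def domain(self) -> str:
        return self.names[int(Rank.DOMAIN)]

    @property
    def family(self) -> str:
        return self.names[int(Rank.FAMILY)]

    @property
    def genus(self) -> str:
        return self.names[int(Rank.GENUS)]

    def is_valid(self) -> bool:
        return bool(self.names[int(Rank.DOMAIN)])

    def serialize(self, dialect: str = "prefixed") -> str:
        """Render back to a semicolon-delimited string."""
        if dialect == "prefixed":
            return ";".join(r.prefix + n for r, n in zip(RANKS, self.names))
        if dialect == "bare":
            return ";".join(self.names)
        raise ValueError(f"unknown dialect: {dialect!r}")

    def replace(self, **rank_names: str) -> "HostLineage":
        """Return a copy with the named ranks (lowercase keys) replaced."""
        names = list(self.names)
        for key, value in rank_names.items():
            names[int(Rank[key.upper()])] = value
        return HostLineage(tuple(names), self.source_namespace)


def parse_lineage(
    lineage_string: str, dialect: str = "auto", source_namespace: str = "gtdb"
) -> HostLineage:
    """Parse a semicolon-delimited lineage string into a :class:`HostLineage`.

    Parameters
    ----------
    lineage_string:
        Either prefixed (``d__X;p__Y;...``) or bare names in rank order
        starting at domain. Trailing ranks may be omitted; omitted or empty
        segments are stored as empty names.
    dialect:
        ``"prefixed"``, ``"bare"``, or ``"auto"`` (prefixed iff the string
        contains ``"__"``).

    Raises
    ------
    LineageParseError
        On an unknown dialect, too many segments, an out-of-order or unknown
        rank prefix (the offending token is named), or an empty domain.
    """
    if dialect not in ("auto", "prefixed", "bare"):
        raise LineageParseError(f"unknown dialect: {dialect!r}")
    s = lineage_string.strip()
    if dialect == "auto":
        dialect = "prefixed" if "__" in s else "bare"
    segments = [seg.strip() for seg in s.split(";")]
    if len(segments) > len(RANKS):
        raise LineageParseError(
            f"too many segments ({len(segments)}) in {lineage_string!r}"
        )
    names = [""] * len(RANKS)
    if dialect == "prefixed":
        for i, seg in enumerate(segments):
            if seg == "":
                continue
            prefix = seg[:3]
            rank = _PREFIX_RANK.get(prefix)
            if rank is None:
                raise LineageParseError(
                    f"segment {seg!r} lacks a recognised rank prefix"
                )
            if int(rank) != i:
                raise LineageParseError(
                    f"segment {seg!r} at position {i} is out of rank order"
                )
            names[int(rank)] = seg[3:].strip()
    else:
        for i, seg in enumerate(segments):
            names[i] = seg
    lineage = HostLineage(tuple(names), source_namespace)
    if not lineage.is_valid():
        raise LineageParseError(
            f"lineage {lineage_string!r} has no domain name"
        )
    return lineage


def names_match_at(a: HostLineage, b: HostLineage, rank: Rank) -> bool:
    """True iff both lineages carry the same non-empty name at ``rank``.

    Exact, case-sensitive comparison. An empty name at ``rank`` on either
    side is never a match — unassigned ranks count against concordance
    rather than being excluded from the denominator.
    """
    na, nb = a.name_at(rank), b.name_at(rank)
    return bool(na) and na == nb


@dataclass
class NamespaceMap:
    """Name translations between two taxonomy namespaces at stated ranks.

    Each record carries a ``fraction_mapping`` in [0, 1]: the proportion of
    the source taxon's members that land in the target taxon. Lookups below
    the acceptance threshold return nothing; among passing records the one
    with the highest fraction wins (ties broken lexicographically on the
    target name, for determinism).
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["name_a", "name_b", "rank", "fraction"]
    ))

    def __post_init__(self) -> None:
        required = {"name_a", "name_b", "fraction"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"NamespaceMap missing columns: {sorted(missing)}")
        if "rank" not in self.records.columns:
            self.records = self.records.assign(rank="family")
        frac = pd.to_numeric(self.records["fraction"], errors="raise")
        if len(frac) and ((frac < 0) | (frac > 1)).any():
            raise ValueError("fraction_mapping values must lie in [0, 1]")
        self.records = self.records.assign(fraction=frac)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]], rank: Rank = Rank.FAMILY
    ) -> "NamespaceMap":
        df = pd.DataFrame(records, columns=["name_a", "name_b", "fraction"])
        df["rank"] = str(rank)
        return cls(df)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "NamespaceMap":
        df = pd.read_csv(path, sep=sep)
        return cls(df)

    def write(self, path, sep: str = "\t") -> None:
        self.records.to_csv(path, sep=sep, index=False)

    def map_name(
        self, name: str, rank: Rank = Rank.FAMILY, threshold: float = 0.6
    ) -> Optional[str]:
        """Best mapping for ``name`` at ``rank``, or None below ``threshold``."""
        if not 0 <= threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        hits = self.records[
            (self.records["name_a"] == name)
            & (self.records["rank"].astype(str) == str(rank))
            & (self.records["fraction"] >= threshold)
        ]
        if hits.empty:
            return None
        best = hits.sort_values(
            ["fraction", "name_b"], ascending=[False, True]
        ).iloc[0]
        return str(best["name_b"])


def map_name(
    nsmap: NamespaceMap, name: str, rank: Rank = Rank.FAMILY, threshold: float = 0.6
) -> Optional[str]:
    """Functional alias for :meth:`NamespaceMap.map_name`."""
    return nsmap.map_name(name, rank, threshold)
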