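"""Pipe-delimited clade lineages as emitted by MetaPhlAn-style profilers.

A lineage string looks like ``k__Bacteria|p__Firmicutes|...|s__Blautia_producta``,
with one-letter rank prefixes running from kingdom down to strain.
"""

from __future__ import annotations

from dataclasses import dataclass

# canonical rank order: kingdom, phylum, class, order, family, genus, species, strain
RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s", "t")

RANK_NAMES: dict[str, str] = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
    "strain": "t",
}


class LineageError(ValueError):
    """Raised when a clade lineage string is malformed."""


def rank_letter(rank: str) -> str:
    """Normalize a rank given as full name or one-letter prefix to its letter."""
    r = rank.lower().rstrip("_")
    if r in RANK_PREFIXES:
        return r
    try:
        return RANK_NAMES[r]
    except KeyError:
        raise LineageError(f"unknown taxonomic rank {rank!r}") from None


@dataclass(frozen=True)
class CladeLineage:
    """An ordered sequence of (rank-letter, clade-name) pairs.

    Invariants enforced at construction: prefixes appear in canonical
    kingdom-to-strain order without repetition and every name is non-empty.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise LineageError("empty lineage")
        positions = []
        for prefix, name in self.ranks:
            if prefix not in RANK_PREFIXES:
                raise LineageError(f"unknown rank prefix {prefix!r}")
            if not name:
                raise LineageError("empty clade name in lineage")
            positions.append(RANK_PREFIXES.index(prefix))
        if positions != sorted(set(positions)):
            raise LineageError(
                "rank prefixes out of canonical kingdom-to-strain order: "
                + self.serialize()
            )

    @classmethod
    def parse(cls, text: str) -> "CladeLineage":
        parts = text.strip().split("|")
        ranks = []
        for part in parts:
            if len(part) < 4 or part[1:3] != "__":
                raise LineageError(f"malformed lineage component {part!r}")
            ranks.append((part[0], part[3:]))
        return cls(tuple(ranks))

    def serialize(self) -> str:
        return "|".join(f"{p}__{n}" for p, n in self.ranks)

    @property
    def deepest_rank(self) -> str:
        """One-letter prefix of the terminal (most resolved) rank."""
        return self.ranks[-1][0]

    @property
    def terminal_name(self) -> str:
        return self.ranks[-1][1]

    @property
    def kingdom(self) -> str | None:
        for prefix, name in self.ranks:
            if prefix == "k":
                return name
        return None

    def name_at(self, rank: str) -> str | None:
        letter = rank_letter(rank)
        for prefix, name in self.ranks:
            if prefix == letter:
                return name
        return None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def is_unclassified_name(name: str) -> bool:
    """True for feature names the profiler could not resolve.

    Covers the standalone ``UNKNOWN`` bucket and any clade whose name
    carries an ``unclassified``/``unknown`` marker.
    """
    low = name.lower()
    return low == "unknown" or "unclassified" in low or "unknown" in low
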