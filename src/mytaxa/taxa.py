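"""Lineage handling for the three classification ranks (phylum, genus, species).

Intermediate ranks (class/order/family) are carried along for reporting but
play no role in scoring or novelty calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ranks used for classification, ordered from shallowest to deepest.
RANKS: tuple[str, ...] = ("phylum", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage of one genome.

    Empty strings mean "unranked at this level".  Taxon identity is decided
    on the full path down to a rank, so two species with the same name under
    different genera are distinct taxa.
    """

    phylum: str = ""
    genus: str = ""
    species: str = ""
    intermediate: tuple[tuple[str, str], ...] = field(default=())

    def taxon_at(self, rank: str) -> str:
        if rank in RANKS:
            return getattr(self, rank)
        for name, value in self.intermediate:
            if name == rank:
                return value
        raise KeyError(f"unknown rank: {rank!r}")

    def path_to(self, rank: str) -> tuple[str, ...]:
        """The (phylum, ..., taxon) path down to *rank* over the core ranks."""
        idx = RANKS.index(rank)
        return tuple(self.taxon_at(r) for r in RANKS[: idx + 1])

    def shares_taxon_at(self, other: "Lineage", rank: str) -> bool:
        """True when both lineages are ranked at *rank* and their full paths agree."""
        a, b = self.path_to(rank), other.path_to(rank)
        return a == b and a[-1] != ""

    def lowest_shared_rank(self, other: "Lineage") -> str | None:
        """Deepest core rank at which the two lineages agree, or None."""
        shared = None
        for rank in RANKS:
            if self.shares_taxon_at(other, rank):
                shared = rank
            else:
                break
        return shared
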