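"""Genome-aggregate average amino-acid identity (AAI).

AAI between two genomes is the arithmetic mean identity of their reciprocal
best matches.  It drives two things: the AAI distance tree standing in for
the species tree, and the rank bands that turn a best-match AAI into a
novel-taxon call (known species / novel species / novel genus / novel
phylum-level lineage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import squareform

from .clustering import RBMEdge
from .taxa import Lineage

KNOWN_SPECIES = "known species"
NOVEL_SPECIES = "novel species"
NOVEL_GENUS = "novel genus"
NOVEL_PHYLUM = "novel phylum"


class UndefinedAAIError(ValueError):
    """Raised when an operation needs an AAI value that has no RBM support."""


@dataclass(frozen=True)
class RankBands:
    """AAI decision bands.

    Intervals are half-open and lower-inclusive:
    [species_min, 100] known species; [genus_low, species_min) novel species
    of the matched genus; [phylum_max, genus_low) novel genus; below
    phylum_max a novel phylum-level lineage.  ``genus_high`` documents the
    top of the empirically observed genus band and is not a decision point.
    """

    species_min: float = 95.0
    genus_low: float = 60.0
    genus_high: float = 80.0
    phylum_max: float = 45.0

    def __post_init__(self) -> None:
        if not (self.phylum_max < self.genus_low <= self.genus_high < self.species_min):
            raise ValueError(
                "band ordering must satisfy "
                "phylum_max < genus_low <= genus_high < species_min"
            )


def novelty_rank(best_match_aai: float, bands: RankBands = RankBands()) -> str:
    """Novelty call for a query whose best reference match has the given AAI."""
    if not (0.0 <= best_match_aai <= 100.0):
        raise ValueError(f"AAI {best_match_aai} outside [0, 100]")
    if best_match_aai >= bands.species_min:
        return KNOWN_SPECIES
    if best_match_aai >= bands.genus_low:
        return NOVEL_SPECIES
    if best_match_aai >= bands.phylum_max:
        return NOVEL_GENUS
    return NOVEL_PHYLUM


class AAIMatrix:
    """Symmetric genome x genome percent-AAI matrix with RBM counts.

    Pairs with no RBM edges are NaN (explicitly undefined, never 0); the
    diagonal is 100 by definition.
    """

    def __init__(self, genome_ids: Sequence[str], values: np.ndarray, n_shared: np.ndarray):
        self.genome_ids = list(genome_ids)
        self.index = {g: i for i, g in enumerate(self.genome_ids)}
        self.values = np.asarray(values, dtype=float)
        self.n_shared = np.asarray(n_shared, dtype=int)
        n = len(self.genome_ids)
        if self.values.shape != (n, n) or self.n_shared.shape != (n, n):
            raise ValueError("matrix shape does not match genome list")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[RBMEdge],
        gene_to_genome: Mapping[str, str],
        genome_ids: Sequence[str],
        min_rbm: int = 1,
    ) -> "AAIMatrix":
        ids = list(genome_ids)
        idx = {g: i for i, g in enumerate(ids)}
        n = len(ids)
        total = np.zeros((n, n))
        count = np.zeros((n, n), dtype=int)
        for e in edges:
            i = idx[gene_to_genome[e.gene_a]]
            j = idx[gene_to_genome[e.gene_b]]
            if i == j:
                continue
            total[i, j] += e.identity
            total[j, i] += e.identity
            count[i, j] += 1
            count[j, i] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(count >= min_rbm, total / np.maximum(count, 1), np.nan)
        np.fill_diagonal(values, 100.0)
        np.fill_diagonal(count, 0)
        return cls(ids, values, count)

    def aai(self, a: str, b: str) -> float:
        v = self.values[self.index[a], self.index[b]]
        if np.isnan(v):
            raise UndefinedAAIError(f"AAI undefined for pair ({a}, {b}): no RBMs")
        return float(v)

    def n_rbm(self, a: str, b: str) -> int:
        return int(self.n_shared[self.index[a], self.index[b]])

    def defined(self, a: str, b: str) -> bool:
        return not np.isnan(self.values[self.index[a], self.index[b]])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.genome_ids)):
            for j in range(i + 1, len(self.genome_ids)):
                if np.isnan(self.values[i, j]):
                    out.append((self.genome_ids[i], self.genome_ids[j]))
        return out


def compute_aai(
    edges: Iterable[RBMEdge],
    gene_to_genome: Mapping[str, str],
    genome_pair: tuple[str, str],
) -> tuple[float, int] | None:
    """Arithmetic-mean AAI and RBM count for one genome pair.

    Returns None (not 0) when the pair shares no RBM edges.  A genome vs
    itself is 100 by definition.
    """
    a, b = genome_pair
    if a == b:
        return 100.0, 0
    identities = [
        e.identity
        for e in edges
        if {gene_to_genome[e.gene_a], gene_to_genome[e.gene_b]} == {a, b}
    ]
    if not identities:
        return None
    return float(np.mean(identities)), len(identities)


class SpeciesTree:
    """AAI distance tree over reference genomes.

    Built by average-linkage agglomerative clustering on d = (100 - AAI)/100
    (default) or by neighbour joining (``method="nj"``).  Exposes patristic
    distances, closest-pair queries for triplet concordance, and Newick
    serialization.
    """

    def __init__(self, leaves: Sequence[str], patristic: np.ndarray, newick: str):
        self.leaves = list(leaves)
        self.index = {g: i for i, g in enumerate(self.leaves)}
        self.patristic_matrix = np.asarray(patristic, dtype=float)
        self._newick = newick

    @classmethod
    def from_aai(cls, aai: AAIMatrix, method: str = "upgma") -> "SpeciesTree":
        bad = aai.undefined_pairs()
        if bad:
            shown = ", ".join(f"{a}~{b}" for a, b in bad[:10])
            raise UndefinedAAIError(
                f"cannot build species tree: {len(bad)} undefined AAI pair(s): {shown}"
            )
        dist = (100.0 - aai.values) / 100.0
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0  # enforce exact symmetry
        if method == "upgma":
            condensed = squareform(dist, checks=False)
            z = linkage(condensed, method="average")
            coph = squareform(cophenet(z), checks=False)
            newick = _linkage_to_newick(z, aai.genome_ids)
            return cls(aai.genome_ids, coph, newick)
        if method == "nj":
            from skbio import DistanceMatrix
            from skbio.tree import nj

            dm = DistanceMatrix(dist, ids=aai.genome_ids)
            tree = nj(dm)
            tip_dists = tree.tip_tip_distances(endpoints=aai.genome_ids)
            order = [list(tip_dists.ids).index(g) for g in aai.genome_ids]
            pat = tip_dists.data[np.ix_(order, order)]
            return cls(aai.genome_ids, pat, str(tree).strip())
        raise ValueError(f"unknown tree method: {method!r}")

    def patristic(self, a: str, b: str) -> float:
        return float(self.patristic_matrix[self.index[a], self.index[b]])

    def closest_pairs(
        self, trio: Sequence[str], epsilon: float = 1e-12
    ) -> set[frozenset[str]]:
        """The pair(s) within ``epsilon`` of the minimum patristic distance
        inside a genome triplet (ties yield multiple pairs)."""
        a, b, c = trio
        d = {
            frozenset((a, b)): self.patristic(a, b),
            frozenset((a, c)): self.patristic(a, c),
            frozenset((b, c)): self.patristic(b, c),
        }
        lo = min(d.values())
        return {p for p, v in d.items() if v <= lo + epsilon}

    def to_newick(self) -> str:
        return self._newick


def _linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        height = node.dist / 2.0  # ultrametric height of this node
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, height)
        right = render(node.right, height)
        return f"({left},{right}):{length:.6g}"

    root_height = tree.dist / 2.0
    left = render(tree.left, root_height)
    right = render(tree.right, root_height)
    return f"({left},{right});"


def rank_band_analysis(
    aai: AAIMatrix, taxonomy: Mapping[str, Lineage]
) -> dict[str, list[float]]:
    """AAI values of genome pairs grouped by their lowest shared rank.

    Returns {"species": [...], "genus": [...], "phylum": [...], "none": [...]}.
    Pairs with undefined AAI are skipped.  A genome missing from the taxonomy
    is an error.
    """
    missing = [g for g in aai.genome_ids if g not in taxonomy]
    if missing:
        raise KeyError(f"genomes missing from taxonomy: {missing[:10]}")
    out: dict[str, list[float]] = {"species": [], "genus": [], "phylum": [], "none": []}
    ids = aai.genome_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(aai.values[i, j]):
                continue
            shared = taxonomy[ids[i]].lowest_shared_rank(taxonomy[ids[j]])
            out[shared or "none"].append(float(aai.values[i, j]))
    return out
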