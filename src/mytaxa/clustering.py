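"""Reference gene clustering.

Orthologs are defined as reciprocal best matches (RBM) between two genomes
passing identity/coverage/e-value thresholds; clusters are the connected
components of the RBM graph.  Genes that never take part in an RBM edge
(paralogs) are merged into the cluster of their best-scoring above-threshold
match, or remain singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class InputValidationError(ValueError):
    """A malformed input row (out-of-range identity/coverage, etc.)."""


@dataclass(frozen=True)
class Gene:
    """One reference protein-coding gene."""

    accession: str
    genome_id: str
    sequence: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairMatch:
    """One row of an all-vs-all similarity search (undirected)."""

    gene_a: str
    gene_b: str
    identity: float  # percent amino-acid identity, [0, 100]
    coverage: float  # aligned fraction of the shorter gene, [0, 1]
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class RBMEdge:
    """A reciprocal-best-match gene pair between two distinct genomes."""

    gene_a: str
    gene_b: str
    identity: float
    bitscore: float = 0.0


@dataclass
class GeneCluster:
    cluster_id: str
    members: set[str] = field(default_factory=set)
    genome_ids: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OrthologThresholds:
    """Ortholog-candidate filter: identity strictly above ``min_identity``,
    coverage at least ``min_coverage``, e-value strictly below ``max_evalue``."""

    min_identity: float = 40.0
    min_coverage: float = 0.70
    max_evalue: float = 1e-12

    def passes(self, m: PairMatch) -> bool:
        return (
            m.identity > self.min_identity
            and m.coverage >= self.min_coverage
            and m.evalue < self.max_evalue
        )


def _validate_match(m: PairMatch, row: int) -> None:
    if not (0.0 <= m.identity <= 100.0):
        raise InputValidationError(
            f"match row {row} ({m.gene_a} vs {m.gene_b}): identity {m.identity} "
            "outside [0, 100]"
        )
    if not (0.0 <= m.coverage <= 1.0):
        raise InputValidationError(
            f"match row {row} ({m.gene_a} vs {m.gene_b}): coverage {m.coverage} "
            "outside [0, 1]"
        )
    if m.evalue < 0 or m.bitscore < 0:
        raise InputValidationError(
            f"match row {row} ({m.gene_a} vs {m.gene_b}): negative e-value/bit-score"
        )


def filter_ortholog_candidates(
    matches: Iterable[PairMatch],
    thresholds: OrthologThresholds = OrthologThresholds(),
) -> list[PairMatch]:
    """Keep exactly the matches passing the ortholog thresholds.

    Raises :class:`InputValidationError` naming the first malformed row.
    """
    kept = []
    for row, m in enumerate(matches):
        _validate_match(m, row)
        if thresholds.passes(m):
            kept.append(m)
    return kept


def _better(cand: tuple[float, float, str], best: tuple[float, float, str]) -> bool:
    """Deterministic best-match ordering: bit-score desc, identity desc,
    then lexicographically smallest partner accession."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def find_rbm_edges(
    matches: Sequence[PairMatch], genes: Mapping[str, Gene]
) -> list[RBMEdge]:
    """Reciprocal best matches between every genome pair.

    For each gene and each foreign genome, its best match is retained only if
    that match's own best match in the gene's genome points back at it.
    Same-genome matches are ignored (they are paralog evidence, not orthologs).
    """
    # best[(gene, other_genome)] = (bitscore, identity, partner_accession)
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    for m in matches:
        ga, gb = genes[m.gene_a], genes[m.gene_b]
        if ga.genome_id == gb.genome_id:
            continue
        for g, partner in ((ga, m.gene_b), (gb, m.gene_a)):
            other = genes[partner].genome_id
            cand = (m.bitscore, m.identity, partner)
            key = (g.accession, other)
            if key not in best or _better(cand, best[key]):
                best[key] = cand

    by_pair: dict[tuple[str, str], PairMatch] = {}
    for m in matches:
        ga, gb = genes[m.gene_a], genes[m.gene_b]
        if ga.genome_id == gb.genome_id:
            continue
        key = tuple(sorted((m.gene_a, m.gene_b)))
        prev = by_pair.get(key)
        if prev is None or _better(
            (m.bitscore, m.identity, key[1]), (prev.bitscore, prev.identity, key[1])
        ):
            by_pair[key] = m

    edges = []
    for (a, b), m in sorted(by_pair.items()):
        genome_a = genes[a].genome_id
        genome_b = genes[b].genome_id
        if best[(a, genome_b)][2] == b and best[(b, genome_a)][2] == a:
            edges.append(RBMEdge(a, b, identity=m.identity, bitscore=m.bitscore))
    return edges


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_by_components(
    edges: Sequence[RBMEdge], all_genes: Mapping[str, Gene]
) -> list[GeneCluster]:
    """One cluster per connected component of the RBM graph.

    Genes that appear in no edge become singleton clusters, so the output is
    always a partition of ``all_genes``.  Cluster ids are assigned in the
    lexicographic order of each component's smallest member accession, which
    makes the labelling independent of input row order.
    """
    for e in edges:
        if e.gene_a not in all_genes or e.gene_b not in all_genes:
            raise InputValidationError(
                f"edge {e.gene_a}--{e.gene_b} references an unknown gene"
            )
    uf = _UnionFind(all_genes)
    for e in edges:
        uf.union(e.gene_a, e.gene_b)
    components: dict[str, set[str]] = {}
    for acc in all_genes:
        components.setdefault(uf.find(acc), set()).add(acc)
    clusters = []
    for i, members in enumerate(sorted(components.values(), key=min)):
        clusters.append(
            GeneCluster(
                cluster_id=f"C{i:06d}",
                members=members,
                genome_ids={all_genes[a].genome_id for a in members},
            )
        )
    return clusters


def merge_paralogs(
    clusters: list[GeneCluster],
    paralogs: Sequence[Gene],
    matches: Iterable[PairMatch],
    genes: Mapping[str, Gene],
    thresholds: OrthologThresholds = OrthologThresholds(),
) -> list[GeneCluster]:
    """Merge each paralog into the cluster of its best above-threshold match.

    ``matches`` are paralog-vs-clustered comparisons (either orientation);
    best is highest bit-score, ties broken by identity then accession.
    Paralogs without a passing match are appended as singleton clusters.
    Returns a new cluster list; input clusters are not mutated.
    """
    gene_to_cluster = {a: c.cluster_id for c in clusters for a in c.members}
    paralog_ids = {g.accession for g in paralogs}
    best: dict[str, tuple[float, float, str]] = {}
    for m in filter_ortholog_candidates(matches, thresholds):
        for para, subject in ((m.gene_a, m.gene_b), (m.gene_b, m.gene_a)):
            if para in paralog_ids and subject in gene_to_cluster:
                cand = (m.bitscore, m.identity, subject)
                if para not in best or _better(cand, best[para]):
                    best[para] = cand

    out = {c.cluster_id: GeneCluster(c.cluster_id, set(c.members), set(c.genome_ids)) for c in clusters}
    leftovers = []
    for g in sorted(paralogs, key=lambda g: g.accession):
        if g.accession in best:
            target = out[gene_to_cluster[best[g.accession][2]]]
            target.members.add(g.accession)
            target.genome_ids.add(g.genome_id)
        else:
            leftovers.append(g)
    merged = [out[c.cluster_id] for c in clusters]
    next_id = len(merged)
    for g in leftovers:
        merged.append(
            GeneCluster(f"C{next_id:06d}", {g.accession}, {g.genome_id})
        )
        next_id += 1
    return merged


def build_clusters(
    matches: Sequence[PairMatch],
    genes: Mapping[str, Gene],
    thresholds: OrthologThresholds = OrthologThresholds(),
) -> tuple[list[GeneCluster], list[RBMEdge]]:
    """Full offline clustering: filter -> RBM edges -> components -> paralog merge.

    Returns the final partition of ``genes`` plus the RBM edge list (the basis
    for genome-aggregate AAI).
    """
    candidates = filter_ortholog_candidates(matches, thresholds)
    edges = find_rbm_edges(candidates, genes)
    in_rbm = {e.gene_a for e in edges} | {e.gene_b for e in edges}
    rbm_genes = {a: g for a, g in genes.items() if a in in_rbm}
    clusters = cluster_by_components(edges, rbm_genes)
    paralogs = [g for a, g in genes.items() if a not in in_rbm]
    clusters = merge_paralogs(clusters, paralogs, matches, genes, thresholds)
    return clusters, edges


def partition_check(clusters: Sequence[GeneCluster], genes: Mapping[str, Gene]) -> None:
    """Assert the cluster list partitions the gene catalog (debug helper)."""
    seen: set[str] = set()
    for c in clusters:
        dup = seen & c.members
        if dup:
            raise AssertionError(f"genes in two clusters: {sorted(dup)[:5]}")
        seen |= c.members
    if seen != set(genes):
        missing = set(genes) - seen
        raise AssertionError(f"genes missing from partition: {sorted(missing)[:5]}")


def pair_identity_map(
    matches: Iterable[PairMatch],
) -> dict[frozenset[str], float]:
    """Per unordered gene pair, the identity of the highest-bitscore match row."""
    out: dict[frozenset[str], tuple[float, float]] = {}
    for m in matches:
        key = frozenset((m.gene_a, m.gene_b))
        if len(key) < 2:
            continue
        prev = out.get(key)
        if prev is None or m.bitscore > prev[0]:
            out[key] = (m.bitscore, m.identity)
    return {k: v[1] for k, v in out.items()}
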