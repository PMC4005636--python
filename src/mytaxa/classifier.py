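"""Online classification engine.

Query gene hits are trimmed to the top N per gene, each hit contributes
bitscore x (w_d * D(identity) + w_m * M) to the taxon encoding its subject
gene, and per-rank likelihoods are the taxon's share of the total
contribution.  Classification descends phylum -> genus -> species, accepting
the top candidate while its likelihood clears the score cutoff; the first
rejection stops the descent and triggers an AAI-based novelty call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aai import RankBands, novelty_rank
from .taxa import RANKS, Lineage
from .weights import CombinedWeightConfig, RankWeights, combined_weight

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search row (BLAST outfmt-6 style)."""

    query_gene_id: str
    subject_accession: str
    identity: float
    aln_length: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"


@dataclass
class QueryContig:
    contig_id: str
    genes: list[GeneFeature] = field(default_factory=list)


@dataclass(frozen=True)
class ClassifierConfig:
    top_n: int = 5
    score_cutoff: float = 0.5
    weight_cfg: CombinedWeightConfig = field(default_factory=CombinedWeightConfig)
    bands: RankBands = field(default_factory=RankBands)
    #: Renormalize likelihoods within the accepted parent's subtree instead of
    #: keeping the global denominator (off by default: out-of-subtree hits
    #: dilute the likelihood).
    renormalize_within_parent: bool = False
    #: Identity summary for the novelty call over supporting hits.
    aai_summary: str = "mean"  # or "max"
    #: Subject genomes to ignore entirely (leave-out benchmarking).
    exclude_genomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.0 <= self.score_cutoff <= 1.0):
            raise ValueError("score_cutoff must lie in [0, 1]")


@dataclass
class CandidateScore:
    taxon: str
    rank: str
    raw_weight_sum: float
    likelihood: float
    supporting_matches: int


@dataclass
class ClassificationResult:
    contig_id: str
    accepted: dict[str, str] = field(default_factory=dict)  # rank -> taxon
    scores: dict[str, float] = field(default_factory=dict)  # rank -> likelihood
    lowest_resolved_rank: str | None = None
    novelty_call: str | None = None
    best_match_aai: float | None = None
    n_genes: int = 0
    n_hits_used: int = 0
    n_hits_skipped: int = 0
    status: str = "classified"
    reason: str = ""

    @property
    def is_classified(self) -> bool:
        return self.status == "classified" and bool(self.accepted)


def select_top_hits(hits: Iterable[HitRecord], top_n: int) -> list[HitRecord]:
    """Top ``top_n`` hits of one query gene.

    Sorted by bit-score descending, ties broken by identity then subject
    accession, so the selection is independent of input row order.
    """
    ranked = sorted(
        hits, key=lambda h: (-h.bitscore, -h.identity, h.subject_accession)
    )
    return ranked[:top_n]


def score_match(
    hit: HitRecord, weights: RankWeights, cfg: ClassifierConfig
) -> float:
    """Raw contribution of one hit at one rank: bitscore x combined weight.

    When the cluster has no D observations at this rank the hit contributes
    with the M value alone.
    """
    d = weights.evaluate_d(hit.identity)
    if d is None:
        w = weights.m_value
    else:
        w = combined_weight(d, weights.m_value, cfg.weight_cfg)
    return hit.bitscore * w


def rank_likelihoods(
    contributions: Mapping[str, float], rank: str, support: Mapping[str, int] | None = None
) -> list[CandidateScore]:
    """Normalize per-taxon contribution sums into likelihoods (sum to 1)."""
    total = sum(contributions.values())
    if total <= 0.0:
        return []
    support = support or {}
    out = [
        CandidateScore(
            taxon=t,
            rank=rank,
            raw_weight_sum=w,
            likelihood=w / total,
            supporting_matches=support.get(t, 0),
        )
        for t, w in contributions.items()
    ]
    out.sort(key=lambda c: (-c.likelihood, c.taxon))
    return out


def _usable_hits(
    contig: QueryContig,
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    weight_db,
    cfg: ClassifierConfig,
) -> tuple[list[tuple[HitRecord, str, str]], int]:
    """Top-N hits with resolvable subjects: (hit, cluster_id, subject_genome)."""
    usable: list[tuple[HitRecord, str, str]] = []
    skipped = 0
    for gene in contig.genes:
        gene_hits = hits_by_gene.get(gene.gene_id, ())
        for hit in select_top_hits(gene_hits, cfg.top_n):
            rec = weight_db.lookup(hit.subject_accession)
            if rec is None:
                skipped += 1
                continue
            cluster_id, genome_id = rec
            if genome_id in cfg.exclude_genomes:
                skipped += 1
                continue
            usable.append((hit, cluster_id, genome_id))
    return usable, skipped


def classify_contig(
    contig: QueryContig,
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    weight_db,
    taxonomy: Mapping[str, Lineage],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """Classify one contig by weighted-likelihood rank descent.

    ``weight_db`` must provide ``lookup(accession) -> (cluster_id, genome_id)
    | None`` and ``rank_weights(cluster_id, rank) -> RankWeights | None``.
    """
    result = ClassificationResult(contig_id=contig.contig_id, n_genes=len(contig.genes))
    usable, skipped = _usable_hits(contig, hits_by_gene, weight_db, cfg)
    result.n_hits_skipped = skipped
    result.n_hits_used = len(usable)
    if not usable:
        result.status = UNCLASSIFIED
        result.reason = "no usable hits"
        return result

    accepted_path: list[str] = []
    for rank in RANKS:
        contributions: dict[str, float] = {}
        support: dict[str, int] = {}
        taxon_paths: dict[str, tuple[str, ...]] = {}
        for hit, cluster_id, genome_id in usable:
            lin = taxonomy.get(genome_id)
            if lin is None or lin.taxon_at(rank) == "":
                continue
            path = lin.path_to(rank)
            key = "|".join(path)
            rw = weight_db.rank_weights(cluster_id, rank)
            if rw is None:
                continue
            contrib = score_match(hit, rw, cfg)
            contributions[key] = contributions.get(key, 0.0) + contrib
            support[key] = support.get(key, 0) + 1
            taxon_paths[key] = path

        if cfg.renormalize_within_parent and accepted_path:
            prefix = tuple(accepted_path)
            contributions = {
                k: v
                for k, v in contributions.items()
                if taxon_paths[k][: len(prefix)] == prefix
            }
        candidates = rank_likelihoods(contributions, rank, support)
        if accepted_path:
            prefix = tuple(accepted_path)
            eligible = [
                c for c in candidates if taxon_paths[c.taxon][: len(prefix)] == prefix
            ]
        else:
            eligible = candidates

        top = eligible[0] if eligible else None
        if top is not None and top.likelihood >= cfg.score_cutoff:
            accepted_path = list(taxon_paths[top.taxon])
            result.accepted[rank] = accepted_path[-1]
            result.scores[rank] = top.likelihood
            result.lowest_resolved_rank = rank
        else:
            break

    _attach_novelty(result, contig, hits_by_gene, weight_db, taxonomy, accepted_path, cfg)
    if not result.accepted:
        result.status = UNCLASSIFIED if result.best_match_aai is None else "classified"
    return result


def _attach_novelty(
    result: ClassificationResult,
    contig: QueryContig,
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    weight_db,
    taxonomy: Mapping[str, Lineage],
    accepted_path: list[str],
    cfg: ClassifierConfig,
) -> None:
    """Best-match AAI plus the novelty call when descent stopped above species.

    The AAI is estimated as the mean identity over *all* hits (not just the
    top-N scoring subset, whose truncation would bias the estimate upward)
    to reference genomes under the deepest accepted taxon; with nothing
    accepted, all hit genomes count.  ``aai_summary="max"`` reports the
    single best hit identity instead.
    """
    per_genome: dict[str, list[float]] = {}
    for gene in contig.genes:
        for hit in hits_by_gene.get(gene.gene_id, ()):
            rec = weight_db.lookup(hit.subject_accession)
            if rec is None:
                continue
            genome = rec[1]
            if genome in cfg.exclude_genomes or genome not in taxonomy:
                continue
            per_genome.setdefault(genome, []).append(hit.identity)
    if not per_genome:
        return
    if accepted_path:
        depth = len(accepted_path)
        supporting = {
            g: idents
            for g, idents in per_genome.items()
            if list(taxonomy[g].path_to(RANKS[depth - 1])) == accepted_path
        } or per_genome
    else:
        supporting = per_genome
    pooled = [v for idents in supporting.values() for v in idents]
    value = float(np.max(pooled) if cfg.aai_summary == "max" else np.mean(pooled))
    result.best_match_aai = min(max(value, 0.0), 100.0)
    if result.lowest_resolved_rank != "species":
        result.novelty_call = novelty_rank(result.best_match_aai, cfg.bands)


def group_hits_by_gene(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        grouped.setdefault(h.query_gene_id, []).append(h)
    return grouped


def classify_batch(
    contigs: Sequence[QueryContig],
    hits: Iterable[HitRecord],
    weight_db,
    taxonomy: Mapping[str, Lineage],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[ClassificationResult]:
    """Classify every contig; output order follows the input contig order."""
    hits_by_gene = group_hits_by_gene(hits)
    return [
        classify_contig(c, hits_by_gene, weight_db, taxonomy, cfg) for c in contigs
    ]
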