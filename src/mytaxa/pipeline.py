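"""Offline weight-DB builder: clustering -> AAI -> species tree -> weights."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .aai import AAIMatrix, SpeciesTree
from .clustering import (
    Gene,
    OrthologThresholds,
    PairMatch,
    build_clusters,
    pair_identity_map,
)
from .io import WeightDB
from .taxa import RANKS, Lineage
from .weights import (
    MAX_EXHAUSTIVE_DEFAULT,
    MC_SAMPLES_DEFAULT,
    genome_pair_gene_distance,
    m_weight,
    make_rank_weights,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildConfig:
    thresholds: OrthologThresholds = field(default_factory=OrthologThresholds)
    ranks: tuple[str, ...] = RANKS
    d_mode: str = "posterior"
    tree_method: str = "upgma"
    max_exhaustive: int = MAX_EXHAUSTIVE_DEFAULT
    mc_samples: int = MC_SAMPLES_DEFAULT
    min_rbm: int = 1
    seed: int = 0


@dataclass
class BuildResult:
    db: WeightDB
    aai: AAIMatrix
    species_tree: SpeciesTree
    n_clusters: int
    n_rbm_edges: int


def build_weight_db(
    genes: Mapping[str, Gene],
    matches: Sequence[PairMatch],
    taxonomy: Mapping[str, Lineage],
    cfg: BuildConfig = BuildConfig(),
) -> BuildResult:
    """Run the full offline pipeline on a reference set.

    The species tree requires every genome pair to have a defined AAI; an
    undefined pair raises with the offending genomes listed.  M is computed
    once per cluster (triplet concordance does not depend on the rank) and
    shared across the three rank records.
    """
    missing = sorted({g.genome_id for g in genes.values()} - set(taxonomy))
    if missing:
        raise KeyError(f"genomes missing from taxonomy: {missing[:10]}")

    clusters, edges = build_clusters(matches, genes, cfg.thresholds)
    gene_to_genome = {a: g.genome_id for a, g in genes.items()}
    genome_ids = sorted({g.genome_id for g in genes.values()})
    aai = AAIMatrix.from_edges(edges, gene_to_genome, genome_ids, min_rbm=cfg.min_rbm)
    tree = SpeciesTree.from_aai(aai, method=cfg.tree_method)

    identities = pair_identity_map(matches)
    weights = {}
    for cluster in clusters:
        gd = genome_pair_gene_distance(cluster, identities, gene_to_genome)
        m_est = m_weight(
            cluster, gd, tree,
            max_exhaustive=cfg.max_exhaustive,
            mc_samples=cfg.mc_samples,
            seed=cfg.seed,
        )
        for rank in cfg.ranks:
            weights[(cluster.cluster_id, rank)] = make_rank_weights(
                cluster, identities, gene_to_genome, taxonomy, tree, rank,
                d_mode=cfg.d_mode, m_estimate=m_est,
            )

    gene_to_cluster = {a: c.cluster_id for c in clusters for a in c.members}
    db = WeightDB(
        gene_to_cluster,
        gene_to_genome,
        weights,
        params={
            "min_identity": cfg.thresholds.min_identity,
            "min_coverage": cfg.thresholds.min_coverage,
            "max_evalue": cfg.thresholds.max_evalue,
            "d_mode": cfg.d_mode,
            "tree_method": cfg.tree_method,
            "max_exhaustive": cfg.max_exhaustive,
            "mc_samples": cfg.mc_samples,
            "seed": cfg.seed,
            "d_m_forms": "declared approximations (posterior D; genome-triplet M)",
        },
    )
    return BuildResult(
        db=db,
        aai=aai,
        species_tree=tree,
        n_clusters=len(clusters),
        n_rbm_edges=len(edges),
    )
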