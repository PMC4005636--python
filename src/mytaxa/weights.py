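"""Per-cluster, per-rank classifying-power weights.

D measures how well a cluster's pairwise identities separate same-taxon from
different-taxon genome pairs at a rank, via Gaussian KDEs (Scott's-rule
bandwidths) of the intra- and inter-group identity distributions.  M measures
agreement of the gene's phylogeny with the species (AAI) tree as the fraction
of concordant genome triplets; clusters above ``max_exhaustive`` members are
estimated by seeded Monte-Carlo sampling.  The final match weight is the
convex combination w_d * D(x) + w_m * M.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .aai import SpeciesTree
from .clustering import GeneCluster
from .taxa import Lineage

logger = logging.getLogger(__name__)

INTRA = "intra_group"
INTER = "inter_group"

#: Bandwidth (percent identity) used when Scott's rule is degenerate
#: (a single observation, or zero variance).
FALLBACK_BANDWIDTH = 0.5

#: Cluster membership above which M switches to Monte-Carlo estimation.
MAX_EXHAUSTIVE_DEFAULT = 5000

#: Default number of Monte-Carlo triplets.
MC_SAMPLES_DEFAULT = 10_000

#: Distance tolerance when comparing triplet topologies: pairs within this
#: margin of the minimum count as tied, and ties are scored concordant.
#: Distances are on the (100 - identity)/100 scale, so 0.02 = 2 identity
#: points — below it a triplet is effectively unresolved, not discordant.
TIE_EPSILON = 0.02


@dataclass(frozen=True)
class IdentityObservation:
    cluster_id: str
    gene_a: str
    gene_b: str
    identity: float
    category: str  # INTRA or INTER


@dataclass(frozen=True)
class CombinedWeightConfig:
    """Linear mixing of D and M; the two coefficients must sum to 1."""

    w_d: float = 0.5
    w_m: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_d <= 1.0 and 0.0 <= self.w_m <= 1.0):
            raise ValueError("w_d and w_m must lie in [0, 1]")
        if abs(self.w_d + self.w_m - 1.0) > 1e-9:
            raise ValueError("w_d + w_m must equal 1")

    @classmethod
    def from_wd(cls, w_d: float) -> "CombinedWeightConfig":
        return cls(w_d=w_d, w_m=1.0 - w_d)


def scott_bandwidth(points: Sequence[float], fallback: float = FALLBACK_BANDWIDTH) -> float:
    """Scott's rule for a 1-D Gaussian KDE: h = sigma * n^(-1/5).

    Falls back to ``fallback`` when the sample has no spread (n < 2 or zero
    sample standard deviation).
    """
    n = len(points)
    if n < 2:
        return fallback
    sigma = float(np.std(points, ddof=1))
    if sigma < 1e-9:  # effectively zero spread (incl. float noise)
        return fallback
    return sigma * n ** (-1.0 / 5.0)


def kde_density(points: Sequence[float], x, bandwidth: float | None = None):
    """Gaussian-kernel density estimate at ``x`` (scalar or array).

    f(x) = (1 / (n h)) * sum_i phi((x - p_i) / h), with h from Scott's rule
    unless given explicitly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("kde_density requires at least one point")
    h = scott_bandwidth(pts) if bandwidth is None else float(bandwidth)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    z = (xs[:, None] - pts[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (pts.size * h * math.sqrt(2.0 * math.pi))
    return float(dens[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else dens


@dataclass(frozen=True)
class DCurve:
    """Evaluable discriminative weight D(x) over percent identity.

    Stored as the raw intra/inter identity point sets plus their bandwidths,
    so evaluation at arbitrary x carries no interpolation error.  The default
    functional form is the two-class posterior f_intra / (f_intra + f_inter);
    ``mode="difference"`` gives the clamped literal difference instead.
    """

    intra: tuple[float, ...]
    inter: tuple[float, ...]
    h_intra: float
    h_inter: float
    mode: str = "posterior"

    @classmethod
    def from_points(
        cls,
        intra: Sequence[float],
        inter: Sequence[float],
        mode: str = "posterior",
    ) -> "DCurve":
        return cls(
            intra=tuple(float(v) for v in intra),
            inter=tuple(float(v) for v in inter),
            h_intra=scott_bandwidth(intra),
            h_inter=scott_bandwidth(inter),
            mode=mode,
        )

    def __call__(self, x: float) -> float:
        if not self.intra and not self.inter:
            raise ValueError("D curve has no observations in either category")
        if not self.intra:
            return 0.0
        if not self.inter:
            return 1.0
        fi = kde_density(self.intra, x, self.h_intra)
        fe = kde_density(self.inter, x, self.h_inter)
        if self.mode == "posterior":
            if fi + fe == 0.0:
                return 0.5  # both tails underflowed: uninformative
            return float(np.clip(fi / (fi + fe), 0.0, 1.0))
        if self.mode == "difference":
            return float(np.clip(fi - fe, 0.0, 1.0))
        raise ValueError(f"unknown D mode: {self.mode!r}")


def d_weight(
    observations: Iterable[IdentityObservation], x: float, mode: str = "posterior"
) -> float:
    """Convenience: build the D curve from observations and evaluate at x."""
    intra = [o.identity for o in observations if o.category == INTRA]
    inter = [o.identity for o in observations if o.category == INTER]
    return DCurve.from_points(intra, inter, mode=mode)(x)


def collect_identity_observations(
    cluster: GeneCluster,
    pair_identities: Mapping[frozenset[str], float],
    gene_to_genome: Mapping[str, str],
    taxonomy: Mapping[str, Lineage],
    rank: str,
) -> list[IdentityObservation]:
    """Pairwise identity observations for one cluster at one rank.

    One observation per unordered gene pair from distinct genomes whose
    identity is known; pairs are intra-group when the two genomes share the
    taxon at ``rank``.  Genes whose genome is unranked at ``rank`` are
    skipped with a warning.
    """
    eligible = []
    skipped = 0
    for acc in sorted(cluster.members):
        genome = gene_to_genome[acc]
        lin = taxonomy.get(genome)
        if lin is None or lin.taxon_at(rank) == "":
            skipped += 1
            continue
        eligible.append((acc, genome, lin))
    if skipped:
        warnings.warn(
            f"cluster {cluster.cluster_id}: {skipped} gene(s) skipped at rank "
            f"{rank} (genome unranked)",
            stacklevel=2,
        )
    obs = []
    for (a, ga, la), (b, gb, lb) in itertools.combinations(eligible, 2):
        if ga == gb:
            continue
        ident = pair_identities.get(frozenset((a, b)))
        if ident is None:
            continue
        category = INTRA if la.shares_taxon_at(lb, rank) else INTER
        obs.append(IdentityObservation(cluster.cluster_id, a, b, ident, category))
    return obs


def genome_pair_gene_distance(
    cluster: GeneCluster,
    pair_identities: Mapping[frozenset[str], float],
    gene_to_genome: Mapping[str, str],
) -> dict[frozenset[str], float]:
    """Gene-based distance d = (100 - identity)/100 per genome pair.

    When a genome contributes paralogs, the pair's highest-identity member
    pair is used.
    """
    best: dict[frozenset[str], float] = {}
    members = sorted(cluster.members)
    for a, b in itertools.combinations(members, 2):
        ga, gb = gene_to_genome[a], gene_to_genome[b]
        if ga == gb:
            continue
        ident = pair_identities.get(frozenset((a, b)))
        if ident is None:
            continue
        key = frozenset((ga, gb))
        if key not in best or ident > best[key]:
            best[key] = ident
    return {k: (100.0 - v) / 100.0 for k, v in best.items()}


def triplet_concordance(
    gene_distances: Mapping[frozenset[str], float],
    species_tree: SpeciesTree,
    trio: Sequence[str],
    epsilon: float = TIE_EPSILON,
) -> bool:
    """Is the gene-distance triplet topology consistent with the species tree?

    Concordant iff a closest pair under the gene distances matches a closest
    pair under species-tree patristic distances; near-ties (within
    ``epsilon`` on either side) count as concordant (benefit of the doubt:
    an unresolved triplet carries no discordance evidence).
    """
    a, b, c = trio
    for g in trio:
        if g not in species_tree.index:
            raise KeyError(f"genome {g} absent from species tree")
    gd = {
        frozenset((a, b)): gene_distances[frozenset((a, b))],
        frozenset((a, c)): gene_distances[frozenset((a, c))],
        frozenset((b, c)): gene_distances[frozenset((b, c))],
    }
    lo = min(gd.values())
    gene_pairs = {p for p, v in gd.items() if v <= lo + epsilon}
    return bool(gene_pairs & species_tree.closest_pairs(trio, epsilon))


def select_m_estimator(n_members: int, max_exhaustive: int = MAX_EXHAUSTIVE_DEFAULT) -> str:
    """Which M estimator runs for a cluster of ``n_members`` genes.

    Exhaustive enumeration of all C(n,3) genome triplets up to and including
    ``max_exhaustive`` members; Monte-Carlo sampling above it.
    """
    return "exhaustive" if n_members <= max_exhaustive else "monte_carlo"


@dataclass(frozen=True)
class MWeightEstimate:
    value: float
    se: float
    method: str  # "exhaustive" | "monte_carlo" | "default"
    n_triplets: int
    flagged_default: bool = False


def m_weight(
    cluster: GeneCluster,
    gene_distances: Mapping[frozenset[str], float],
    species_tree: SpeciesTree,
    max_exhaustive: int = MAX_EXHAUSTIVE_DEFAULT,
    mc_samples: int = MC_SAMPLES_DEFAULT,
    seed: int | None = None,
    concordance_fn: Callable[[Sequence[str]], bool] | None = None,
) -> MWeightEstimate:
    """Fraction of concordant genome triplets for one cluster.

    Clusters with fewer than 3 member genomes default to M = 1.0 (flagged).
    The estimator path is chosen on the cluster's *gene* membership count
    (``select_m_estimator``); triplets are enumerated over genomes.  The
    Monte-Carlo path samples uniformly with the given seed and reports a
    binomial standard error.  ``concordance_fn`` overrides the per-triplet
    concordance test (used for instrumentation/testing).
    """
    genomes = sorted({g for pair in gene_distances for g in pair} & set(species_tree.leaves))
    if not gene_distances:
        genomes = sorted(cluster.genome_ids & set(species_tree.leaves))
    if len(genomes) < 3:
        return MWeightEstimate(1.0, 0.0, "default", 0, flagged_default=True)
    if concordance_fn is None:
        def concordance_fn(trio):  # noqa: F811 - intentional default binding
            return triplet_concordance(gene_distances, species_tree, trio)

    method = select_m_estimator(len(cluster), max_exhaustive)
    if method == "exhaustive":
        total = 0
        concordant = 0
        for trio in itertools.combinations(genomes, 3):
            key_ok = all(
                frozenset(p) in gene_distances
                for p in itertools.combinations(trio, 2)
            )
            if not key_ok:
                continue
            total += 1
            if concordance_fn(trio):
                concordant += 1
        if total == 0:
            return MWeightEstimate(1.0, 0.0, "default", 0, flagged_default=True)
        m = concordant / total
        return MWeightEstimate(m, 0.0, "exhaustive", total)

    rng = np.random.default_rng(seed)
    n = len(genomes)
    concordant = 0
    evaluated = 0
    for _ in range(mc_samples):
        i, j, k = rng.choice(n, size=3, replace=False)
        trio = (genomes[i], genomes[j], genomes[k])
        if not all(
            frozenset(p) in gene_distances for p in itertools.combinations(trio, 2)
        ):
            continue
        evaluated += 1
        if concordance_fn(trio):
            concordant += 1
    if evaluated == 0:
        return MWeightEstimate(1.0, 0.0, "default", 0, flagged_default=True)
    m = concordant / evaluated
    se = math.sqrt(max(m * (1.0 - m), 1e-12) / evaluated)
    return MWeightEstimate(m, se, "monte_carlo", evaluated)


def combined_weight(d: float, m: float, cfg: CombinedWeightConfig) -> float:
    """Convex combination w_d * D + w_m * M."""
    return cfg.w_d * d + cfg.w_m * m


@dataclass
class RankWeights:
    """The weight record of one cluster at one rank."""

    cluster_id: str
    rank: str
    d_curve: DCurve | None
    m_value: float
    n_intra: int = 0
    n_inter: int = 0
    n_triplets: int = 0
    m_se: float = 0.0
    m_method: str = "exhaustive"

    @property
    def d_available(self) -> bool:
        return self.d_curve is not None and bool(self.d_curve.intra or self.d_curve.inter)

    def evaluate_d(self, identity: float) -> float | None:
        """D(identity), or None when no observations exist at this rank."""
        if not self.d_available:
            return None
        return self.d_curve(identity)


def make_rank_weights(
    cluster: GeneCluster,
    pair_identities: Mapping[frozenset[str], float],
    gene_to_genome: Mapping[str, str],
    taxonomy: Mapping[str, Lineage],
    species_tree: SpeciesTree,
    rank: str,
    d_mode: str = "posterior",
    m_estimate: MWeightEstimate | None = None,
    max_exhaustive: int = MAX_EXHAUSTIVE_DEFAULT,
    mc_samples: int = MC_SAMPLES_DEFAULT,
    seed: int | None = None,
) -> RankWeights:
    """Assemble the full weight record for one (cluster, rank).

    ``m_estimate`` lets the caller share one triplet-concordance computation
    across ranks (the concordance test itself is rank-independent).
    """
    obs = collect_identity_observations(
        cluster, pair_identities, gene_to_genome, taxonomy, rank
    )
    intra = [o.identity for o in obs if o.category == INTRA]
    inter = [o.identity for o in obs if o.category == INTER]
    curve = DCurve.from_points(intra, inter, mode=d_mode) if (intra or inter) else None
    if m_estimate is None:
        gd = genome_pair_gene_distance(cluster, pair_identities, gene_to_genome)
        m_estimate = m_weight(
            cluster, gd, species_tree,
            max_exhaustive=max_exhaustive, mc_samples=mc_samples, seed=seed,
        )
    return RankWeights(
        cluster_id=cluster.cluster_id,
        rank=rank,
        d_curve=curve,
        m_value=m_estimate.value,
        n_intra=len(intra),
        n_inter=len(inter),
        n_triplets=m_estimate.n_triplets,
        m_se=m_estimate.se,
        m_method=m_estimate.method,
    )
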