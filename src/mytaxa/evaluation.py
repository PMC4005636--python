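"""Benchmarking harness.

Predictions are scored per rank into five categories: TP (known taxon,
matching prediction), WP (known taxon, wrong prediction), FN (known taxon
predicted unknown), FP (unknown taxon predicted as some taxon), TN (unknown
taxon predicted unknown).  Sensitivity/specificity are macro-averages over
taxa by default; the w_d mixing coefficient is optimized by grid search over
replicated subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .taxa import RANKS, Lineage

TP, WP, FN, FP, TN = "TP", "WP", "FN", "FP", "TN"


@dataclass(frozen=True)
class RankTruth:
    """Ground truth for one query at one rank."""

    taxon: str  # true taxon name ("" if the source is unranked here)
    known: bool  # is this taxon present in the reference database?


@dataclass
class PredictionOutcome:
    query_id: str
    truth: Mapping[str, RankTruth]  # rank -> truth
    prediction: Mapping[str, str | None]  # rank -> predicted taxon or None
    categories: dict[str, str] = field(default_factory=dict)


def categorize(truth: RankTruth, predicted: str | None) -> str:
    """Five-way category for one (truth, prediction) pair at one rank."""
    if truth.known:
        if predicted is None:
            return FN
        return TP if predicted == truth.taxon else WP
    return FP if predicted is not None else TN


def categorize_outcomes(
    outcomes: Iterable[PredictionOutcome], ranks: Sequence[str] = RANKS
) -> list[PredictionOutcome]:
    out = list(outcomes)
    for o in out:
        for rank in ranks:
            o.categories[rank] = categorize(o.truth[rank], o.prediction.get(rank))
    return out


def sensitivity_specificity(
    outcomes: Sequence[PredictionOutcome],
    rank: str,
    average: str = "macro",
) -> tuple[float, float]:
    """(Sn, Sp) at a rank.

    macro (default): Sn is the mean over taxa of the per-taxon correct-call
    rate (TP rate for known taxa, TN rate for unknown taxa); Sp is the mean
    over known taxa of the per-taxon TP rate.  micro: pooled counts.
    """
    if not outcomes:
        raise ValueError("no outcomes to evaluate")
    per_taxon: dict[tuple[str, bool], list[str]] = {}
    for o in outcomes:
        t = o.truth[rank]
        cat = o.categories.get(rank) or categorize(t, o.prediction.get(rank))
        per_taxon.setdefault((t.taxon, t.known), []).append(cat)

    if average == "micro":
        cats = [c for group in per_taxon.values() for c in group]
        n = len(cats)
        sn = (cats.count(TP) + cats.count(TN)) / n
        known = [c for (_t, k), group in per_taxon.items() if k for c in group]
        sp = known.count(TP) / len(known) if known else float("nan")
        return sn, sp

    sn_rates, sp_rates = [], []
    for (taxon, known), cats in sorted(per_taxon.items()):
        if not cats:
            warnings.warn(f"taxon {taxon}: no outcomes at rank {rank}", stacklevel=2)
            continue
        if known:
            rate = cats.count(TP) / len(cats)
            sn_rates.append(rate)
            sp_rates.append(rate)
        else:
            sn_rates.append(cats.count(TN) / len(cats))
    sn = float(np.mean(sn_rates)) if sn_rates else float("nan")
    sp = float(np.mean(sp_rates)) if sp_rates else float("nan")
    return sn, sp


def accuracy(outcomes: Sequence[PredictionOutcome], rank: str) -> float:
    """(TP + TN) / total at a rank — the grid-search objective."""
    cats = [
        o.categories.get(rank) or categorize(o.truth[rank], o.prediction.get(rank))
        for o in outcomes
    ]
    return (cats.count(TP) + cats.count(TN)) / len(cats)


DEFAULT_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 20))


@dataclass(frozen=True)
class GridSearchSpec:
    grid: tuple[float, ...] = DEFAULT_GRID
    n_replicates: int = 10
    sample_fraction: float = 0.10
    seed: int = 0
    rank: str = "species"

    def __post_init__(self) -> None:
        if any(not (0.0 < w < 1.0) for w in self.grid):
            raise ValueError("grid values must lie in (0, 1)")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be sorted ascending")


@dataclass
class GridSearchResult:
    best_wd: float
    table: list[dict]  # per grid value: {"w_d", "mean_accuracy", "accuracies"}


def grid_search_wd(
    spec: GridSearchSpec,
    query_ids: Sequence[str],
    classify_fn: Callable[[Sequence[str], float], Sequence[PredictionOutcome]],
) -> GridSearchResult:
    """Pick the w_d grid value with the highest mean subsample accuracy.

    ``classify_fn(query_subset, w_d)`` must return categorized outcomes for
    the subset.  Ties go to the value closest to 0.5, then the smaller one.
    """
    rng = np.random.default_rng(spec.seed)
    n_sample = max(1, round(spec.sample_fraction * len(query_ids)))
    replicate_ids = [
        list(rng.choice(len(query_ids), size=n_sample, replace=False))
        for _ in range(spec.n_replicates)
    ]
    table = []
    for w_d in spec.grid:
        accs = []
        for idx in replicate_ids:
            subset = [query_ids[i] for i in idx]
            outcomes = classify_fn(subset, w_d)
            accs.append(accuracy(outcomes, spec.rank))
        table.append(
            {"w_d": w_d, "mean_accuracy": float(np.mean(accs)), "accuracies": accs}
        )
    best = max(
        table,
        key=lambda row: (row["mean_accuracy"], -abs(row["w_d"] - 0.5), -row["w_d"]),
    )
    return GridSearchResult(best_wd=best["w_d"], table=table)


# ---------------------------------------------------------------------------
# Novelty-stratified benchmark construction


@dataclass
class NoveltyBenchmark:
    novelty_fraction: float
    reference_genomes: list[str]
    held_out_genomes: list[str]
    realized_fraction: float


def novelty_stratified_benchmark(
    taxonomy: Mapping[str, Lineage],
    novelty_levels: Sequence[float],
    seed: int = 0,
    tolerance: float = 0.02,
) -> list[NoveltyBenchmark]:
    """Hold out whole species until the requested genome fraction is removed.

    For each requested novelty fraction, whole-species blocks are removed in
    random order until the held-out genome count is as close as possible to
    the target; the realized fraction must land within ``tolerance`` of the
    request, otherwise an error states the achievable fractions.
    """
    genomes = sorted(taxonomy)
    by_species: dict[tuple[str, ...], list[str]] = {}
    for g in genomes:
        by_species.setdefault(taxonomy[g].path_to("species"), []).append(g)
    out = []
    for level in novelty_levels:
        if not (0.0 <= level < 1.0):
            raise ValueError(f"novelty fraction {level} outside [0, 1)")
        rng = np.random.default_rng(seed)
        order = sorted(by_species)
        rng.shuffle(order)
        target = level * len(genomes)
        held: list[str] = []
        for key in order:
            block = by_species[key]
            if abs(len(held) + len(block) - target) < abs(len(held) - target):
                held.extend(block)
        realized = len(held) / len(genomes)
        if abs(realized - level) > tolerance:
            achievable = sorted(
                {len(by_species[k]) / len(genomes) for k in by_species}
            )
            raise ValueError(
                f"cannot realize novelty {level:.3f} within {tolerance}: got "
                f"{realized:.3f}; species-block granularity {achievable[:5]}"
            )
        out.append(
            NoveltyBenchmark(
                novelty_fraction=level,
                reference_genomes=sorted(set(genomes) - set(held)),
                held_out_genomes=sorted(held),
                realized_fraction=realized,
            )
        )
    return out


def truth_for_query(
    source_lineage: Lineage,
    reference_taxonomy: Mapping[str, Lineage],
    ranks: Sequence[str] = RANKS,
) -> dict[str, RankTruth]:
    """Per-rank truth for a query, with known = taxon present in the reference."""
    present: dict[str, set[tuple[str, ...]]] = {r: set() for r in ranks}
    for lin in reference_taxonomy.values():
        for r in ranks:
            path = lin.path_to(r)
            if path[-1]:
                present[r].add(path)
    truth = {}
    for r in ranks:
        path = source_lineage.path_to(r)
        truth[r] = RankTruth(taxon=path[-1], known=path in present[r])
    return truth


def expected_novelty_call(
    source_lineage: Lineage, reference_taxonomy: Mapping[str, Lineage]
) -> str:
    """The novelty rank a perfect classifier should report for a query."""
    from .aai import KNOWN_SPECIES, NOVEL_GENUS, NOVEL_PHYLUM, NOVEL_SPECIES

    truth = truth_for_query(source_lineage, reference_taxonomy)
    if truth["species"].known:
        return KNOWN_SPECIES
    if truth["genus"].known:
        return NOVEL_SPECIES
    if truth["phylum"].known:
        return NOVEL_GENUS
    return NOVEL_PHYLUM
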