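import itertools
import math

import numpy as np
import pytest

from mytaxa.aai import AAIMatrix, SpeciesTree
from mytaxa.clustering import GeneCluster
from mytaxa.taxa import Lineage
from mytaxa.weights import (
    INTER,
    INTRA,
    CombinedWeightConfig,
    DCurve,
    IdentityObservation,
    MWeightEstimate,
    collect_identity_observations,
    combined_weight,
    d_weight,
    genome_pair_gene_distance,
    kde_density,
    m_weight,
    scott_bandwidth,
    select_m_estimator,
    triplet_concordance,
)


class TestKDE:
    def test_single_point_closed_form(self):
        # degenerate sample -> fallback bandwidth h = 0.5
        h = 0.5
        assert kde_density([90.0], 90.0) == pytest.approx(1 / (h * math.sqrt(2 * math.pi)))

    def test_symmetry(self):
        assert kde_density([80.0, 100.0], 85.0) == pytest.approx(
            kde_density([80.0, 100.0], 95.0)
        )

    def test_scott_bandwidth_formula(self):
        pts = [10.0, 12.0, 15.0, 11.0, 19.0]
        expected = np.std(pts, ddof=1) * 5 ** (-0.2)
        assert scott_bandwidth(pts) == pytest.approx(expected)

    def test_zero_variance_uses_fallback(self):
        assert scott_bandwidth([7.0] * 10) == 0.5
        assert scott_bandwidth([5.0]) == 0.5

    def test_against_direct_summation_oracle(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(30, 100, size=20)
        h = np.std(pts, ddof=1) * 20 ** (-0.2)
        for x in rng.uniform(20, 110, size=7):
            direct = sum(
                math.exp(-((x - p) / h) ** 2 / 2) / (len(pts) * h * math.sqrt(2 * math.pi))
                for p in pts
            )
            assert kde_density(list(pts), float(x)) == pytest.approx(direct, abs=1e-12)

    def test_empty_points_raise(self):
        with pytest.raises(ValueError):
            kde_density([], 50.0)


def obs(identity, category, cluster="c"):
    return IdentityObservation(cluster, "a", "b", identity, category)


class TestDWeight:
    def test_no_inter_observations_gives_one(self):
        assert d_weight([obs(95, INTRA)], 60.0) == 1.0

    def test_no_intra_observations_gives_zero(self):
        assert d_weight([obs(60, INTER)], 95.0) == 0.0

    def test_equal_densities_give_half(self):
        observations = [obs(80, INTRA), obs(80, INTER)]
        assert d_weight(observations, 80.0) == pytest.approx(0.5)

    def test_well_separated_samples(self):
        rng = np.random.default_rng(4)
        intra = list(rng.normal(95, 1, size=100))
        inter = list(rng.normal(60, 1, size=100))
        curve = DCurve.from_points(intra, inter)
        assert curve(95.0) > 0.99
        assert curve(60.0) < 0.01
        # matches a direct KDE-ratio computation
        fi = kde_density(intra, 77.0, curve.h_intra)
        fe = kde_density(inter, 77.0, curve.h_inter)
        assert curve(77.0) == pytest.approx(fi / (fi + fe), abs=1e-12)

    def test_bounded_everywhere(self):
        rng = np.random.default_rng(5)
        curve = DCurve.from_points(
            list(rng.normal(90, 2, 30)), list(rng.normal(50, 5, 50))
        )
        for x in np.linspace(0, 100, 41):
            assert 0.0 <= curve(float(x)) <= 1.0

    def test_difference_mode_is_clamped(self):
        curve = DCurve.from_points([95.0, 96.0], [50.0, 51.0], mode="difference")
        assert 0.0 <= curve(95.5) <= 1.0
        assert curve(50.5) == 0.0

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            DCurve.from_points([], [])(50.0)


TAX = {
    "GA": Lineage("P1", "G1", "S1"),
    "GB": Lineage("P1", "G1", "S1"),
    "GC": Lineage("P1", "G1", "S2"),
    "GD": Lineage("P1", "G2", "S3"),
    "GE": Lineage("P2", "G3", "S4"),
    "GF": Lineage("P3", "G4", "S5"),
}


class TestCollectObservations:
    def _cluster_and_maps(self, genomes):
        members = {f"g_{g}" for g in genomes}
        cluster = GeneCluster("c1", members, set(genomes))
        gene_to_genome = {f"g_{g}": g for g in genomes}
        identities = {
            frozenset((a, b)): 77.0
            for a, b in itertools.combinations(sorted(members), 2)
        }
        return cluster, gene_to_genome, identities

    def test_two_genes_same_species_is_one_intra(self):
        cluster, g2g, ids = self._cluster_and_maps(["GA", "GB"])
        out = collect_identity_observations(cluster, ids, g2g, TAX, "species")
        assert len(out) == 1 and out[0].category == INTRA

    def test_three_phyla_all_inter_at_phylum(self):
        cluster, g2g, ids = self._cluster_and_maps(["GA", "GE", "GF"])
        out = collect_identity_observations(cluster, ids, g2g, TAX, "phylum")
        assert len(out) == 3
        assert all(o.category == INTER for o in out)

    def test_unranked_genome_skipped_with_warning(self):
        tax = dict(TAX)
        tax["GA"] = Lineage("P1", "G1", "")
        cluster, g2g, ids = self._cluster_and_maps(["GA", "GB", "GC"])
        with pytest.warns(UserWarning, match="unranked"):
            out = collect_identity_observations(cluster, ids, g2g, tax, "species")
        assert len(out) == 1  # only GB-GC

    def test_small_cluster_is_empty(self):
        cluster, g2g, ids = self._cluster_and_maps(["GA"])
        assert collect_identity_observations(cluster, ids, g2g, TAX, "genus") == []

    def test_twelve_genes_match_lineage_oracle(self):
        rng = np.random.default_rng(2)
        genomes = list(TAX) * 2
        members = [f"m{i}" for i in range(12)]
        gene_to_genome = dict(zip(members, genomes))
        cluster = GeneCluster("c9", set(members), set(genomes))
        identities = {
            frozenset(p): float(rng.uniform(40, 99))
            for p in itertools.combinations(members, 2)
        }
        for rank in ("phylum", "genus", "species"):
            out = collect_identity_observations(
                cluster, identities, gene_to_genome, TAX, rank
            )
            expected = {}
            for a, b in itertools.combinations(sorted(members), 2):
                ga, gb = gene_to_genome[a], gene_to_genome[b]
                if ga == gb:
                    continue
                la, lb = TAX[ga], TAX[gb]
                same = la.path_to(rank) == lb.path_to(rank)
                expected[(a, b)] = INTRA if same else INTER
            got = {(o.gene_a, o.gene_b): o.category for o in out}
            assert got == expected


def ultrametric_tree(ids, dist):
    n = len(ids)
    values = np.zeros((n, n))
    for (a, b), d in dist.items():
        i, j = ids.index(a), ids.index(b)
        values[i, j] = values[j, i] = d
    aai = AAIMatrix(ids, 100.0 - values * 100.0, np.ones((n, n), dtype=int))
    return SpeciesTree.from_aai(aai)


class TestTripletConcordance:
    def setup_method(self):
        self.tree = ultrametric_tree(
            ["A", "B", "C"],
            {("A", "B"): 0.1, ("A", "C"): 0.5, ("B", "C"): 0.5},
        )

    def test_proportional_distances_concordant(self):
        gd = {
            frozenset(("A", "B")): 0.05,
            frozenset(("A", "C")): 0.25,
            frozenset(("B", "C")): 0.25,
        }
        assert triplet_concordance(gd, self.tree, ("A", "B", "C"))

    def test_swapped_cherry_discordant(self):
        gd = {
            frozenset(("A", "B")): 0.5,
            frozenset(("A", "C")): 0.1,
            frozenset(("B", "C")): 0.5,
        }
        assert not triplet_concordance(gd, self.tree, ("A", "B", "C"))

    def test_tie_counts_as_concordant(self):
        gd = {
            frozenset(("A", "B")): 0.3,
            frozenset(("A", "C")): 0.3,
            frozenset(("B", "C")): 0.3,
        }
        assert triplet_concordance(gd, self.tree, ("A", "B", "C"))

    def test_unknown_genome_raises(self):
        with pytest.raises(KeyError):
            triplet_concordance({}, self.tree, ("A", "B", "Z"))


def make_cluster(genomes):
    members = {f"g_{g}" for g in genomes}
    return GeneCluster("cm", members, set(genomes)), {f"g_{g}": g for g in genomes}


def planted_tree(n):
    """Caterpillar-free ultrametric tree over n genomes with distinct heights."""
    ids = [f"T{i:02d}" for i in range(n)]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            # pair i,j merges at a height depending on their separation
            dist[(ids[i], ids[j])] = 0.1 + 0.05 * abs(i - j)
    return ids, ultrametric_tree(ids, dist)


class TestMWeight:
    def test_identical_trees_give_one(self):
        ids, tree = planted_tree(8)
        gd = {
            frozenset((a, b)): tree.patristic(a, b)
            for a, b in itertools.combinations(ids, 2)
        }
        cluster, _ = make_cluster(ids)
        est = m_weight(cluster, gd, tree)
        assert est.value == 1.0 and est.method == "exhaustive"
        assert est.n_triplets == math.comb(8, 3)

    def test_every_triplet_discordant_gives_zero(self):
        # species tree says (A,B) closest everywhere; gene distances invert it
        ids = ["A", "B", "C", "D"]
        tree = ultrametric_tree(
            ids,
            {
                ("A", "B"): 0.1, ("A", "C"): 0.6, ("A", "D"): 0.8,
                ("B", "C"): 0.6, ("B", "D"): 0.8, ("C", "D"): 0.4,
            },
        )
        gd = {  # reverse the closeness ordering decisively
            frozenset(("A", "B")): 0.9,
            frozenset(("A", "C")): 0.2,
            frozenset(("A", "D")): 0.9,
            frozenset(("B", "C")): 0.9,
            frozenset(("B", "D")): 0.2,
            frozenset(("C", "D")): 0.9,
        }
        cluster, _ = make_cluster(ids)
        est = m_weight(cluster, gd, tree)
        assert est.value == 0.0

    def test_fewer_than_three_genomes_defaults_flagged(self):
        ids, tree = planted_tree(5)
        cluster, _ = make_cluster(ids[:2])
        gd = {frozenset(ids[:2]): 0.2}
        est = m_weight(cluster, gd, tree)
        assert est.value == 1.0 and est.flagged_default

    def test_estimator_selection_boundary(self):
        assert select_m_estimator(5000) == "exhaustive"
        assert select_m_estimator(5001) == "monte_carlo"

    def test_monte_carlo_path_delegates_by_member_count(self):
        ids, tree = planted_tree(10)
        gd = {
            frozenset((a, b)): tree.patristic(a, b)
            for a, b in itertools.combinations(ids, 2)
        }
        cluster, _ = make_cluster(ids)
        calls = []

        def stub(trio):
            calls.append(trio)
            return True

        est = m_weight(
            cluster, gd, tree, max_exhaustive=5, mc_samples=200, seed=1,
            concordance_fn=stub,
        )
        assert est.method == "monte_carlo"
        assert est.value == 1.0
        assert len(calls) == 200

    def test_monte_carlo_matches_exhaustive_within_3_se(self):
        rng = np.random.default_rng(8)
        for n in (12, 16, 20):
            ids, tree = planted_tree(n)
            gd = {}
            for a, b in itertools.combinations(ids, 2):
                gd[frozenset((a, b))] = tree.patristic(a, b) * float(
                    rng.uniform(0.3, 1.7)
                )
            cluster, _ = make_cluster(ids)
            exact = m_weight(cluster, gd, tree)
            assert exact.method == "exhaustive"
            mc = m_weight(cluster, gd, tree, max_exhaustive=5, mc_samples=2000, seed=42)
            assert mc.method == "monte_carlo"
            se = max(mc.se, 1e-6)
            assert abs(mc.value - exact.value) < 3 * se + 1e-9

    def test_planted_hgt_fraction_recovered(self):
        # Move a fraction q of genomes' genes next to a distant donor and
        # compare against an independent exhaustive enumeration oracle.
        rng = np.random.default_rng(15)
        n, q = 12, 0.25
        ids, tree = planted_tree(n)
        moved = list(rng.choice(ids, size=int(q * n), replace=False))
        gd = {}
        for a, b in itertools.combinations(ids, 2):
            base = tree.patristic(a, b)
            if (a in moved) != (b in moved):
                base = 0.95  # transferred gene: decisively far from everything
            elif a in moved and b in moved:
                base = 0.05  # transferred genes huddle near the donor
            gd[frozenset((a, b))] = base

        def oracle():
            total = conc = 0
            for trio in itertools.combinations(ids, 2 + 1):
                total += 1
                conc += triplet_concordance(gd, tree, trio)
            return conc / total

        est = m_weight(cluster := make_cluster(ids)[0], gd, tree)
        assert est.value == pytest.approx(oracle(), abs=1e-12)
        mc = m_weight(cluster, gd, tree, max_exhaustive=5, mc_samples=2000, seed=0)
        assert abs(mc.value - est.value) < 3 * max(mc.se, 1e-6)


class TestCombinedWeight:
    def test_pure_d(self):
        cfg = CombinedWeightConfig(w_d=1.0, w_m=0.0)
        assert combined_weight(0.3, 0.9, cfg) == 0.3

    def test_equal_components_fixed_point(self):
        for wd in (0.1, 0.5, 0.9):
            cfg = CombinedWeightConfig(w_d=wd, w_m=1 - wd)
            assert combined_weight(0.42, 0.42, cfg) == pytest.approx(0.42)

    def test_worked_example(self):
        cfg = CombinedWeightConfig(w_d=0.6, w_m=0.4)
        assert combined_weight(0.5, 1.0, cfg) == pytest.approx(0.7)

    def test_convex_combination_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            d, m, wd = rng.uniform(0, 1, 3)
            w = combined_weight(d, m, CombinedWeightConfig.from_wd(round(wd, 3)))
            assert min(d, m) - 1e-12 <= w <= max(d, m) + 1e-12

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CombinedWeightConfig(w_d=0.5, w_m=0.6)


class TestConservedGeneAsymmetry:
    def test_16s_like_cluster_resolves_phylum_better_than_species(self):
        """Tiny intra/inter-species divergence, clear phylum separation."""
        rng = np.random.default_rng(3)
        intra_sp = list(rng.normal(99.0, 0.3, 40))
        inter_sp = list(rng.normal(98.7, 0.3, 60))  # species barely separated
        intra_ph = intra_sp + inter_sp
        inter_ph = list(rng.normal(75.0, 2.0, 60))  # phyla well separated
        d_species = DCurve.from_points(intra_sp, inter_sp)
        d_phylum = DCurve.from_points(intra_ph, inter_ph)
        probe = 98.9
        assert d_phylum(probe) > d_species(probe)
        assert d_phylum(probe) > 0.99
        assert d_species(probe) < 0.8


def test_genome_pair_gene_distance_uses_best_paralog():
    cluster = GeneCluster("c", {"a1", "a2", "b1"}, {"GA", "GB"})
    g2g = {"a1": "GA", "a2": "GA", "b1": "GB"}
    ids = {
        frozenset(("a1", "b1")): 80.0,
        frozenset(("a2", "b1")): 90.0,
        frozenset(("a1", "a2")): 99.0,  # same-genome pair ignored
    }
    gd = genome_pair_gene_distance(cluster, ids, g2g)
    assert gd == {frozenset(("GA", "GB")): pytest.approx(0.10)}
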