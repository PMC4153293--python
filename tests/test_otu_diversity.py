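"""Distances, furthest-neighbour OTUs, richness/diversity estimators."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from dnralink import otu_diversity as od
from dnralink._alignment import p_distance


class TestPDistance:
    def test_identical_zero(self):
        assert p_distance("ACDEFGHIKL", "ACDEFGHIKL") == 0.0

    def test_one_in_ten(self):
        assert p_distance("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            p_distance("", "ACD")

    @settings(max_examples=50, derandomize=True)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30),
    )
    def test_symmetric(self, a, b):
        assert p_distance(a, b) == pytest.approx(p_distance(b, a))

    def test_engines_agree_on_near_identical_sequences(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(aa[i] for i in rng.integers(0, 20, 60))
        for n_mut in (0, 1, 3, 6):
            other = list(base)
            for pos in rng.choice(60, size=n_mut, replace=False):
                other[pos] = aa[(aa.index(other[pos]) + 1) % 20]
            other = "".join(other)
            assert p_distance(base, other, engine="edlib") == pytest.approx(
                p_distance(base, other, engine="blosum")
            )


class TestKimura:
    def test_zero(self):
        assert od.kimura_protein_distance(0.0) == 0.0

    def test_printed_value(self):
        assert od.kimura_protein_distance(0.1) == pytest.approx(-math.log(0.898))

    def test_domain_edge_capped(self):
        assert od.kimura_protein_distance(0.9) == od.KIMURA_CAP

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            od.kimura_protein_distance(1.5)

    def test_monotone_on_domain(self):
        grid = np.linspace(0, 0.85, 200)
        vals = [od.kimura_protein_distance(p) for p in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


def random_distance_matrix(n, rng):
    d = rng.random((n, n)) * 0.5
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


class TestFurthestNeighbor:
    def test_cutoff_zero_is_dereplication(self):
        dm = DistanceMatrix(
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.1], [0.3, 0.1, 0]]), list("ABC")
        )
        assignment = od.cluster_furthest_neighbor(dm, 0.0)
        assert assignment.n_otus == 3

    def test_three_sequence_partition(self):
        dm = DistanceMatrix(
            np.array([[0, 0.05, 0.15], [0.05, 0, 0.12], [0.15, 0.12, 0]]), list("ABC")
        )
        assignment = od.cluster_furthest_neighbor(dm, 0.1)
        assert sorted(map(tuple, assignment.clusters)) == [("A", "B"), ("C",)]

    def test_agrees_with_scipy_complete_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(2, 7))
            dm = random_distance_matrix(n, rng)
            cutoff = float(rng.random() * 0.5)
            mine = od.cluster_furthest_neighbor(dm, cutoff)
            z = linkage(squareform(dm.data), method="complete")
            flat = fcluster(z, t=cutoff, criterion="distance")
            scipy_clusters = {
                tuple(sorted(np.array(dm.ids)[flat == k])) for k in set(flat)
            }
            assert {tuple(c) for c in mine.clusters} == scipy_clusters

    def test_within_cluster_constraint_holds(self):
        rng = np.random.default_rng(1)
        dm = random_distance_matrix(12, rng)
        assignment = od.cluster_furthest_neighbor(dm, 0.25)
        lookup = {lbl: i for i, lbl in enumerate(dm.ids)}
        for cluster in assignment.clusters:
            for a, b in itertools.combinations(cluster, 2):
                assert dm.data[lookup[a], lookup[b]] <= 0.25

    def test_representative_highest_count(self):
        dm = DistanceMatrix(np.array([[0, 0.05], [0.05, 0]]), ["A", "B"])
        assignment = od.cluster_furthest_neighbor(dm, 0.1, counts={"A": 1, "B": 9})
        assert assignment.representatives == ["B"]

    def test_negative_cutoff_rejected(self):
        dm = random_distance_matrix(3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            od.cluster_furthest_neighbor(dm, -0.1)


class TestEstimators:
    def test_chao1_example(self):
        assert od.chao1([5, 3, 1, 1, 1, 2]) == pytest.approx(10.5)

    def test_chao1_no_singletons_equals_s_obs(self):
        assert od.chao1([5, 3, 2, 2]) == 4.0

    def test_ace_example(self):
        assert od.ace([5, 3, 1, 1, 1, 2]) == pytest.approx(9.36, abs=0.005)

    def test_ace_matches_skbio(self):
        from skbio.diversity.alpha import ace as skbio_ace

        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(1, 30, size=rng.integers(3, 40)).tolist()
            assert od.ace(counts) == pytest.approx(float(skbio_ace(counts)))

    def test_ace_all_abundant_equals_s_obs(self):
        assert od.ace([20, 30, 40]) == 3.0

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=40))
    def test_estimators_at_least_richness(self, counts):
        s = len(counts)
        assert od.chao1(counts) >= s
        n1 = counts.count(1)
        n_rare = sum(c for c in counts if c <= 10)
        if n_rare == 0 or n1 < n_rare:  # C_ace > 0
            assert od.ace(counts) >= s - 1e-9
        assert od.shannon(counts) <= math.log(s) + 1e-12

    def test_shannon_uniform(self):
        assert od.shannon([7, 7, 7, 7]) == pytest.approx(math.log(4))

    def test_shannon_single_otu(self):
        assert od.shannon([12]) == 0.0

    @pytest.mark.parametrize(
        "h,s,expected", [(6.507, 1012, 0.940), (6.360, 1005, 0.920)]
    )
    def test_pielou_printed_values(self, h, s, expected):
        assert round(od.pielou_evenness(h, s), 3) == expected

    def test_pielou_uniform_is_one(self):
        counts = [5, 5, 5]
        assert od.pielou_evenness(od.shannon(counts), 3) == pytest.approx(1.0)

    def test_pielou_undefined_below_two(self):
        assert od.pielou_evenness(0.0, 1) is None


class TestRarefaction:
    def test_full_depth_gives_s_obs(self):
        counts = [5, 3, 1, 1]
        assert od.rarefaction_curve(counts, [10])[0] == pytest.approx(4.0)

    def test_depth_one_gives_one(self):
        assert od.rarefaction_curve([5, 3, 2], [1])[0] == pytest.approx(1.0)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            od.rarefaction_curve([2, 2], [5])

    def test_monotone_and_concave(self):
        counts = [9, 5, 4, 3, 1, 1, 1]
        depths = list(range(1, sum(counts) + 1))
        curve = od.rarefaction_curve(counts, depths)
        diffs = np.diff(curve)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_matches_monte_carlo_within_3_se(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 12, size=15)
        total = int(counts.sum())
        depth = total // 2
        analytic = od.rarefaction_curve(counts, [depth])[0]
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = np.array(
            [
                len(np.unique(rng.choice(pool, size=depth, replace=False)))
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(analytic - draws.mean()) <= 3 * se


class TestCalibration:
    def test_monotone_and_cutoff_zero(self, calibration_pool):
        cutoffs = [0.0, 0.05, 0.1, 0.2, 0.4]
        table = od.calibrate_cutoff(calibration_pool, cutoffs)
        assert (np.diff(table.n_otus) <= 0).all()
        n_distinct = len({e.protein for e in calibration_pool.entries})
        assert table.n_otus.iloc[0] == n_distinct

    def test_genus_level_cutoff_separates_genera(self, calibration_pool):
        table = od.calibrate_cutoff(calibration_pool, [0.05, 0.1, 0.2, 0.3, 0.5])
        flagged = table[table.genus_level].iloc[0]
        assignment = od.cluster_furthest_neighbor(
            od.build_distance_matrix({e.id: e.protein for e in calibration_pool.entries}),
            flagged.cutoff,
        )
        genus_of = {e.id: e.genus for e in calibration_pool.entries}
        # every OTU at the genus-level cutoff contains a single genus
        for cluster in assignment.clusters:
            assert len({genus_of[x] for x in cluster}) == 1
        assert assignment.n_otus == flagged.n_genera


class TestPhylipIO:
    def test_square_round_trip(self, tmp_path):
        dm = random_distance_matrix(5, np.random.default_rng(6))
        path = tmp_path / "dm.phylip"
        od.write_phylip(dm, path)
        back = od.read_phylip(path)
        assert list(back.ids) == list(dm.ids)
        assert np.allclose(back.data, dm.data, atol=1e-6)

    def test_lower_triangle_round_trip(self, tmp_path):
        dm = random_distance_matrix(4, np.random.default_rng(7))
        path = tmp_path / "dm.phylip"
        od.write_phylip(dm, path, lower=True)
        back = od.read_phylip(path)
        assert np.allclose(back.data, dm.data, atol=1e-6)
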