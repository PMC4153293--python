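"""Cross-site OTU table, abundance partition, NJ/UniFrac/PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from dnralink import community_structure as cs
from dnralink.read_processing import SiteLibrary


def library(site, records):
    return SiteLibrary(
        site_id=site,
        proteins=[(p, c, [f"{site}_{p[:3]}_{i}" for i in range(c)]) for p, c in records],
    )


PROT_A = "MKVLAAGHTRWQEDNPSCFY" * 3
PROT_B = PROT_A[:-3] + "AAA"  # 95% identical to A
PROT_C = "MWYHNPDECSAFGIKLQRTV" * 3  # far from both


class TestClusterCrossSite:
    def test_high_threshold_reduces_to_dereplication(self):
        libs = {
            "S1": library("S1", [(PROT_A, 5), (PROT_C, 2)]),
            "S2": library("S2", [(PROT_A, 3)]),
        }
        table = cs.cluster_cross_site(libs, identity_threshold=0.999)
        assert len(table.otu_ids) == 2
        assert table.counts.values.sum() == 10

    def test_similar_pair_joins_distant_singleton_apart(self):
        libs = {"S1": library("S1", [(PROT_A, 5), (PROT_B, 2), (PROT_C, 3)])}
        table = cs.cluster_cross_site(libs, identity_threshold=0.90)
        assert len(table.otu_ids) == 2
        # the abundant sequence founds the cluster and is its representative
        assert table.representatives["OTU1"] == PROT_A

    def test_count_conservation(self, small_dataset):
        from dnralink import read_processing as rp
        from dnralink import synthetic_data as syn

        pool = small_dataset["pool"]
        refs = {e.id: e.protein for e in pool.entries}
        barcodes = syn.default_barcodes([c.site_id for c in small_dataset["communities"]])
        libs, stats, _ = rp.process_reads(small_dataset["fastq"], barcodes, refs)
        table = cs.cluster_cross_site(libs)
        assert table.counts.values.sum() == sum(l.total for l in libs.values())

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            cs.cluster_cross_site({"S1": library("S1", [(PROT_A, 1)])}, identity_threshold=1.5)


def toy_table():
    counts = pd.DataFrame(
        {
            "S1": [11, 989, 0],
            "S2": [10, 989, 1],
        },
        index=["OTU1", "OTU2", "OTU3"],
    )
    reps = {"OTU1": PROT_A, "OTU2": PROT_B, "OTU3": PROT_C}
    return cs.OTUTable(counts=counts, representatives=reps)


class TestClassification:
    def test_thresholds(self):
        classes = cs.classify_abundance(toy_table())
        assert classes.classes.loc["OTU1", "S1"] == "dominant"  # 1.1% > 1%
        assert classes.classes.loc["OTU1", "S2"] == "low_abundance"  # exactly 1.0%
        assert classes.classes.loc["OTU3", "S2"] == "rare"  # exactly 0.1%
        assert classes.classes.loc["OTU3", "S1"] == "absent"

    def test_every_present_cell_in_exactly_one_class(self):
        classes = cs.classify_abundance(toy_table())
        assert set(np.unique(classes.classes.values)) <= {
            "dominant",
            "low_abundance",
            "rare",
            "absent",
        }

    def test_endemic_and_cosmopolitan_flags(self):
        classes = cs.classify_abundance(toy_table())
        assert classes.endemic == {"OTU3"}
        assert classes.cosmopolitan == {"OTU1", "OTU2"}

    def test_percentages_toy_example(self):
        counts = pd.DataFrame({"S1": [50, 50], "S2": [0, 100]}, index=["O1", "O2"])
        table = cs.OTUTable(counts=counts, representatives={"O1": PROT_A, "O2": PROT_C})
        classes = cs.classify_abundance(table)
        pcts = cs.endemic_and_dominant_percentages(table, classes)
        assert pcts.loc["S1", "pct_endemic"] == 50.0
        assert pcts.loc["S2", "pct_endemic"] == 0.0
        assert pcts.loc["S1", "pct_dominant"] == 100.0


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        source = TreeNode.read(["((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05,E:0.4);"])
        dm_src = source.tip_tip_distances()
        rebuilt = cs.nj_tree(DistanceMatrix(dm_src.data, list(dm_src.ids)), midpoint_root=False)
        dm_out = rebuilt.tip_tip_distances().filter(list(dm_src.ids))
        assert np.allclose(dm_out.data, dm_src.data, atol=1e-12)

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]), list("ABC")
        )
        tree = cs.nj_tree(d, midpoint_root=False)
        out = tree.tip_tip_distances().filter(list("ABC"))
        assert np.allclose(out.data, d.data, atol=1e-12)

    def test_too_few_labels_rejected(self):
        d = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
        with pytest.raises(ValueError):
            cs.nj_tree(d)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(2)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = cs.nj_tree(DistanceMatrix(m, [f"t{i}" for i in range(6)]))
        assert all((n.length or 0) >= 0 for n in tree.traverse() if n.parent is not None)


def clade_alignment():
    # two deeply separated clades with many diagnostic columns
    left, right = "A" * 30, "W" * 30
    return {
        "L1": left,
        "L2": left[:-1] + "C",
        "R1": right,
        "R2": right[:-1] + "Y",
    }


class TestBootstrap:
    def test_deep_split_gets_full_support(self):
        support = cs.bootstrap_support(clade_alignment(), n_reps=100, seed=0)
        (value,) = support.values()  # single non-trivial bipartition
        assert value == 100.0

    def test_single_replicate_support_is_all_or_nothing(self):
        support = cs.bootstrap_support(clade_alignment(), n_reps=1, threshold=0.0, seed=1)
        assert all(v in (0.0, 100.0) or v is None for v in support.values())

    def test_invariant_to_label_order(self):
        seqs = clade_alignment()
        a = cs.bootstrap_support(seqs, n_reps=50, seed=3)
        b = cs.bootstrap_support(dict(reversed(list(seqs.items()))), n_reps=50, seed=3)
        assert a == b


def random_tree_and_counts(rng, n_leaves):
    m = rng.random((n_leaves, n_leaves))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    labels = [f"x{i}" for i in range(n_leaves)]
    tree = cs.nj_tree(DistanceMatrix(m, labels))
    a = rng.integers(0, 20, n_leaves)
    b = rng.integers(0, 20, n_leaves)
    if a.sum() == 0:
        a[0] = 1
    if b.sum() == 0:
        b[-1] = 1
    return tree, labels, a, b


class TestUniFrac:
    def test_two_leaf_hand_value(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        d = cs.weighted_normalized_unifrac(tree, {"A": 0.5, "B": 0.5}, {"A": 1, "B": 0})
        assert d == pytest.approx(0.5)

    def test_identical_communities_zero(self):
        tree = TreeNode.read(["((A:1,B:2):0.5,(C:1.5,D:1):0.7);"])
        counts = {"A": 3, "B": 1, "C": 2, "D": 1}
        assert cs.weighted_normalized_unifrac(tree, counts, counts) == 0.0

    def test_disjoint_clades_one(self):
        tree = TreeNode.read(["((A:1,B:2):0.5,(C:1.5,D:1):0.7);"])
        d = cs.weighted_normalized_unifrac(
            tree, {"A": 3, "B": 1, "C": 0, "D": 0}, {"A": 0, "B": 0, "C": 2, "D": 5}
        )
        assert d == pytest.approx(1.0)

    def test_all_zero_community_rejected(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        with pytest.raises(ValueError):
            cs.weighted_normalized_unifrac(tree, {"A": 0, "B": 0}, {"A": 1, "B": 0})

    def test_matches_skbio_on_random_trees(self):
        from skbio.diversity.beta import weighted_unifrac

        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            tree, labels, a, b = random_tree_and_counts(rng, n)
            mine = cs.weighted_normalized_unifrac(
                tree, dict(zip(labels, a)), dict(zip(labels, b))
            )
            ref = float(weighted_unifrac(a, b, taxa=labels, tree=tree, normalized=True))
            assert mine == pytest.approx(ref, abs=1e-10)
            assert 0.0 <= mine <= 1.0 + 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        tree, labels, a, b = random_tree_and_counts(rng, 6)
        ab = cs.weighted_normalized_unifrac(tree, dict(zip(labels, a)), dict(zip(labels, b)))
        ba = cs.weighted_normalized_unifrac(tree, dict(zip(labels, b)), dict(zip(labels, a)))
        assert ab == pytest.approx(ba)


class TestPCoA:
    def test_two_points(self):
        dm = DistanceMatrix(np.array([[0, 0.8], [0.8, 0]]), ["A", "B"])
        res = cs.pcoa(dm)
        assert res.coordinates.shape[1] == 1
        assert sorted(np.round(res.coordinates.PC1.values, 10)) == [-0.4, 0.4]
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_euclidean_reconstruction(self):
        from scipy.spatial.distance import pdist, squareform

        pts = np.random.default_rng(2).random((6, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"p{i}" for i in range(6)])
        res = cs.pcoa(dm)
        rec = squareform(pdist(res.coordinates.values))
        assert np.allclose(rec, dm.data, atol=1e-10)

    def test_percents_sum_to_at_most_100(self):
        rng = np.random.default_rng(3)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = cs.pcoa(DistanceMatrix(m, [f"p{i}" for i in range(5)]))
        assert res.percent_variance.sum() <= 100.0 + 1e-9

    def test_asymmetric_rejected(self):
        class Fake:  # DistanceMatrix itself enforces symmetry, so fake one
            data = np.array([[0, 1.0], [2.0, 0]])
            ids = ["A", "B"]

        with pytest.raises(ValueError):
            cs.pcoa(Fake())


class TestHeatmap:
    def test_single_dominant_row(self):
        table = toy_table()
        classes = cs.classify_abundance(table)
        hm = cs.heatmap_matrix(table, classes)
        assert set(hm.index) == {"OTU1", "OTU2"}
        assert (hm.sum(axis=0) <= 100.0 + 1e-9).all()

    def test_no_dominant_warns_empty(self):
        counts = pd.DataFrame({"S1": [5, 995]}, index=["O1", "O2"])
        # O2 is dominant; construct a genuinely dominant-free table instead
        counts = pd.DataFrame(
            {"S1": [1] * 150}, index=[f"O{i}" for i in range(150)]
        )
        table = cs.OTUTable(
            counts=counts, representatives={f"O{i}": PROT_A + str(i) for i in range(150)}
        )
        classes = cs.classify_abundance(table)
        with pytest.warns(UserWarning, match="no dominant"):
            hm = cs.heatmap_matrix(table, classes)
        assert hm.empty
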