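import itertools

import numpy as np
import pandas as pd
import pytest

from pharmatrace import community
from pharmatrace.community import DistanceMatrix
from pharmatrace.tables_io import CountTable

from conftest import make_count_table


class TestRarefaction:
    def test_forced_single_asv(self):
        table = make_count_table([[6000]])
        out = community.rarefy_iterative(table, depth=5000, n_iter=3, seed=0)
        assert out.counts.iloc[0, 0] == 5000

    def test_shallow_sample_dropped_with_warning(self):
        table = make_count_table([[4999, 6000]])
        with pytest.warns(UserWarning, match="below rarefaction depth"):
            out = community.rarefy_iterative(table, depth=5000, n_iter=2, seed=0)
        assert out.sample_ids == ["s2"]

    def test_iterative_mean_matches_hypergeometric_expectation(self):
        # sample (9000, 1000): expected rarefied ASV1 count = 5000 * 0.9 = 4500
        table = make_count_table([[9000], [1000]])
        out = community.rarefy_iterative(table, depth=5000, n_iter=200, seed=1)
        assert abs(out.counts.loc["ASV1", "s1"] - 4500) <= 50

    def test_column_sums_conserved_within_rounding(self):
        rng = np.random.default_rng(5)
        table = make_count_table(rng.integers(0, 2000, size=(40, 6)))
        out = community.rarefy_iterative(table, depth=5000, n_iter=25, seed=2)
        for s in out.sample_ids:
            # exact before rounding; after half-up rounding, off by < 1/2 per ASV
            assert abs(out.counts[s].sum() - 5000) <= out.shape[0] / 2 + 1

    def test_seed_required_and_bad_iters_rejected(self):
        table = make_count_table([[6000]])
        with pytest.raises(ValueError, match="seed"):
            community.rarefy_iterative(table, depth=5000, n_iter=2)
        with pytest.raises(ValueError, match="n_iter"):
            community.rarefy_iterative(table, depth=5000, n_iter=0, seed=0)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "column, richness, shannon",
        [
            ([5000], 1, 0.0),
            ([2500, 2500], 2, np.log(2)),
            ([100, 100, 100, 100], 4, np.log(4)),
        ],
    )
    def test_closed_forms(self, column, richness, shannon):
        table = make_count_table([[c] for c in column])
        alpha = community.alpha_diversity(table)
        assert alpha.loc["s1", "richness"] == richness
        assert alpha.loc["s1", "shannon"] == pytest.approx(shannon, abs=1e-12)

    def test_all_zero_sample_rejected_by_name(self):
        table = make_count_table([[5, 0]])
        with pytest.raises(ValueError, match="s2"):
            community.alpha_diversity(table)

    def test_shannon_maximal_iff_uniform(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            counts = rng.integers(1, 500, size=(12, 1))
            table = make_count_table(counts)
            h = community.alpha_diversity(table).loc["s1", "shannon"]
            assert h <= np.log(12) + 1e-12
            if len(set(counts.ravel())) > 1:
                assert h < np.log(12) - 1e-12


class TestKruskalDunn:
    def test_label_symmetry(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        r1 = community.kruskal_dunn(values, groups)
        relabel = {"a": "b", "b": "c", "c": "a"}
        r2 = community.kruskal_dunn(values, np.vectorize(relabel.get)(groups))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_extreme_separation_attains_minimal_p(self):
        """For two groups of 3 with fully separated ranks the observed KW
        statistic equals the maximum over every possible rank allocation."""
        values = np.array([1, 2, 3, 101, 102, 103], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        obs = community.kruskal_dunn(values, groups)
        stats_all = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            stats_all.append(community.kruskal_dunn(values, lab).statistic)
        assert obs.statistic == pytest.approx(max(stats_all), rel=1e-12)
        assert obs.pairwise["p_adj"].iloc[0] <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            community.kruskal_dunn(np.arange(3.0), np.array(["a", "a", "b"]))

    def test_null_type_one_error_rate(self):
        """Identically distributed groups are rejected at about the nominal
        rate."""
        rng = np.random.default_rng(42)
        rejected = 0
        n_sim = 500
        for _ in range(n_sim):
            values = rng.normal(size=16)
            groups = np.array(["a"] * 8 + ["b"] * 8)
            if community.kruskal_dunn(values, groups).pvalue < 0.05:
                rejected += 1
        assert 0.02 <= rejected / n_sim <= 0.08


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        table = make_count_table([[5, 5, 5, 0], [3, 3, 0, 7]])
        d = community.bray_curtis(table)
        assert d.data[0, 1] == pytest.approx(0.0)
        assert d.data[2, 3] == pytest.approx(1.0)

    def test_hand_example(self):
        table = make_count_table([[6, 2], [4, 4], [0, 4]])
        d = community.bray_curtis(table)
        assert d.data[0, 1] == pytest.approx(0.4)

    def test_two_all_zero_samples_rejected(self):
        table = make_count_table([[0, 0, 5]])
        with pytest.raises(ValueError, match="all-zero"):
            community.bray_curtis(table)


class TestPcoa:
    def test_collinear_points_reconstruct_distances(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        ord_ = community.pcoa(DistanceMatrix(d, list("abcd")))
        coords = ord_.coords.to_numpy()
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.abs(recon - d).max() < 1e-9

    def test_equilateral_configuration(self):
        d = np.full((3, 3), 0.6) - 0.6 * np.eye(3)
        coords = community.pcoa(DistanceMatrix(d, list("abc"))).coords.to_numpy()
        dists = [np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.ptp(dists) < 1e-9

    def test_two_samples_closed_form(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        coords = community.pcoa(DistanceMatrix(d, ["a", "b"])).coords.to_numpy()
        assert sorted(np.round(coords[:, 0], 9)) == [-0.2, 0.2]

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(np.array([[0.0, 0.5], [0.4, 0.0]]), ["a", "b"])

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(9)
        table = make_count_table(rng.integers(0, 400, size=(20, 7)))
        d = community.bray_curtis(table)
        mine = community.pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.data, d.ids))
        k = mine.coords.shape[1]
        for ax in range(k):
            a = mine.coords.to_numpy()[:, ax]
            b = ref.samples.to_numpy()[:, ax]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)  # sign-free


class TestPermanova:
    # expected values computed with vegan::adonis2 (by='terms') on this fixture
    VEGAN = {
        "f1": (1, 0.052338, 0.085171, 0.926358),
        "f2": (1, 0.049582, 0.080686, 0.877582),
        "f1:f2": (1, 0.060597, 0.098611, 1.072535),
        "Residual": (8, 0.451992, 0.735532, np.nan),
        "Total": (11, 0.614509, 1.0, np.nan),
    }

    def _fixture(self):
        rng = np.random.default_rng(42)
        table = make_count_table(rng.integers(0, 500, size=(30, 12)))
        d = community.bray_curtis(table)
        design = pd.DataFrame(
            {"f1": ["u"] * 6 + ["v"] * 6, "f2": ["p", "q"] * 6}, index=d.ids
        )
        return d, design

    def test_sequential_partition_matches_adonis(self):
        d, design = self._fixture()
        res = community.permanova(d, design, terms=["f1", "f2", "f1:f2"],
                                  n_perm=99, seed=0)
        for term, (df, ss, r2, f) in self.VEGAN.items():
            row = res.table.loc[term]
            assert row["Df"] == df
            assert row["SS"] == pytest.approx(ss, abs=5e-6)
            assert row["R2"] == pytest.approx(r2, abs=5e-6)
            if not np.isnan(f):
                assert row["F"] == pytest.approx(f, abs=5e-6)

    def test_r2_partition_sums_to_one(self):
        d, design = self._fixture()
        res = community.permanova(d, design, terms=["f1", "f2"], n_perm=99, seed=0)
        terms_r2 = res.table.drop(index="Total")["R2"].sum()
        assert terms_r2 == pytest.approx(1.0, abs=1e-9)
        assert res.table.loc["f1", "EV"] == pytest.approx(
            100 * res.table.loc["f1", "R2"]
        )

    def test_separated_clusters_attain_minimum_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, size=(10, 3))
        b = rng.normal(5, 0.01, size=(10, 3))
        x = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(20)])
        design = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=d.ids)
        res = community.permanova(d, design, n_perm=999, seed=3)
        assert res.table.loc["g", "p"] == pytest.approx(1 / 1000)

    def test_constant_factor_rejected(self):
        d, design = self._fixture()
        design["flat"] = "x"
        with pytest.raises(ValueError, match="constant"):
            community.permanova(d, design, terms=["flat"], n_perm=99, seed=0)


class TestBetadisper:
    # distances computed with vegan::betadisper(type='median') on this fixture
    VEGAN_DISTANCES = [
        0.183843, 0.236023, 0.181922, 0.166355, 0.212623,
        0.237689, 0.214180, 0.209096, 0.207710, 0.225737,
    ]
    VEGAN_F = 2.758

    def _fixture(self):
        rng = np.random.default_rng(7)
        table = make_count_table(rng.integers(0, 300, size=(25, 10)))
        return community.bray_curtis(table)

    def test_distances_match_vegan(self):
        d = self._fixture()
        res = community.betadisper(d, ["g1"] * 5 + ["g2"] * 5, n_perm=199, seed=0)
        assert np.allclose(res.distances.to_numpy(), self.VEGAN_DISTANCES, atol=5e-7)
        assert res.statistic == pytest.approx(self.VEGAN_F, abs=5e-4)

    def test_mirror_groups_have_equal_dispersion(self):
        x = np.array([[0, 0], [1, 0], [0, 1], [3, 3], [4, 3], [3, 4]], dtype=float)
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(6)])
        res = community.betadisper(d, ["a"] * 3 + ["b"] * 3, n_perm=199, seed=0)
        means = res.group_means
        assert means["a"] == pytest.approx(means["b"], abs=1e-9)

    def test_inflated_cluster_detected(self):
        rng = np.random.default_rng(0)
        tight = rng.normal(0, 0.1, size=(8, 3))
        loose = rng.normal(0, 1.0, size=(8, 3)) + 5
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(np.vstack([tight, loose]))),
                           [f"s{i}" for i in range(16)])
        res = community.betadisper(d, ["t"] * 8 + ["l"] * 8, n_perm=499, seed=1)
        assert res.pvalue < 0.05

    def test_singleton_group_warned_and_distances_returned(self):
        d = self._fixture()
        with pytest.warns(UserWarning, match="size 1"):
            res = community.betadisper(d, ["a"] * 5 + ["b"] * 4 + ["c"], n_perm=99,
                                       seed=0)
        assert len(res.distances) == 10 and res.excluded_groups == ["c"]


class TestSharedAsvs:
    def test_disjoint_and_identical(self):
        table = make_count_table([[5, 5, 0, 0], [7, 7, 0, 0], [0, 0, 2, 2]])
        shared = community.shared_asvs(table, ["g1", "g1", "g2", "g2"])
        assert shared.loc["g1", "g2"] == 0
        assert shared.loc["g1", "g1"] == 2  # group richness on the diagonal
        assert shared.loc["g2", "g2"] == 1

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(13)
        table = make_count_table(rng.integers(0, 3, size=(100, 9)))
        grouping = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        shared = community.shared_asvs(table, grouping)
        sets = {}
        for g in ("x", "y", "z"):
            cols = [s for s, lab in zip(table.sample_ids, grouping) if lab == g]
            sets[g] = {a for a in table.asv_ids if (table.counts.loc[a, cols] > 0).any()}
        for g in sets:
            for h in sets:
                assert shared.loc[g, h] == len(sets[g] & sets[h])

    def test_empty_group_rejected(self):
        table = make_count_table([[1, 1]])
        grouping = pd.Series(
            pd.Categorical(["a", "a"], categories=["a", "b"]),
            index=table.sample_ids,
        )
        with pytest.raises(ValueError, match="empty"):
            community.shared_asvs(table, grouping)
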