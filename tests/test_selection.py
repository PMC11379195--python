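"""Entropy trees, masked iterative selection and the separation score."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methpanel as mp
from methpanel.selection import NodeStats, SiteGroupStats, TreeNode

from _util import best_root_oracle, labels_from_int, make_binary, make_matrix


class TestNodeEntropy:
    @pytest.mark.parametrize(
        "normal, cancer, expected",
        [
            (0.5, 0.5, 1.0),      # evenly mixed: maximum
            (1.0, 0.0, 0.0),      # pure: minimum
            (0.0, 1.0, 0.0),
            (0.75, 0.25, 0.8113),  # direct base-2 evaluation
        ],
    )
    def test_reference_values(self, normal, cancer, expected):
        value = mp.node_entropy(NodeStats(normal, cancer, 8))
        assert value == pytest.approx(expected, abs=5e-5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(mp.PipelineError, match="equal 1"):
            NodeStats(0.5, 0.6, 10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0))
    def test_bounded_and_symmetric(self, p):
        h = mp.node_entropy(NodeStats(p, 1 - p, 10))
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(mp.node_entropy(NodeStats(1 - p, p, 10)))


class TestFitDepth2Tree:
    def test_perfect_separator(self):
        calls = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        binary = make_binary(calls, labels_from_int([1, 1, 0, 0]))
        tree = mp.fit_depth2_tree(binary)
        assert tree.root.site == "S1"
        assert tree.root.left.entropy == 0.0
        assert tree.root.right.entropy == 0.0
        assert mp.tree_accuracy(tree, binary) == 1.0

    def test_root_maximizes_information_gain(self):
        # site B splits (C,C,C | N,N,N) perfectly (gain 1.0); site A leaves
        # one mistake (gain ~0.459)
        y = [1, 1, 1, 0, 0, 0]
        A = [1, 1, 1, 0, 0, 1]
        B = [1, 1, 1, 0, 0, 0]
        binary = make_binary(np.column_stack([A, B]), labels_from_int(y),
                             site_ids=["A", "B"])
        tree = mp.fit_depth2_tree(binary)
        assert tree.root.site == "B"

    def test_second_level_corrects_root_mistakes(self):
        # root separates 6/8 (gain ~0.189, the largest at the top); each
        # impure child is then fixed perfectly by a different weak site
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        root = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        fixer_r = np.array([1, 1, 1, 0, 1, 1, 0, 0])  # fixes the call-1 child
        fixer_l = np.array([0, 0, 1, 1, 0, 0, 0, 1])  # fixes the call-0 child
        binary = make_binary(
            np.column_stack([root, fixer_r, fixer_l]), labels_from_int(y),
            site_ids=["root", "fixer_r", "fixer_l"],
        )
        tree = mp.fit_depth2_tree(binary)
        assert tree.root.site == "root"
        assert set(tree.split_sites()) == {"root", "fixer_r", "fixer_l"}
        assert mp.tree_accuracy(tree, binary) == 1.0

    def test_depth_never_exceeds_two(self, small_split):
        binary = mp.binarize(small_split.train)
        tree = mp.fit_depth2_tree(binary)
        for child in (tree.root.left, tree.root.right):
            if child is not None and child.site is not None:
                for leaf in (child.left, child.right):
                    assert leaf.is_leaf

    def test_all_sites_excluded(self):
        binary = make_binary([[1, 0], [0, 1]], labels_from_int([1, 0]))
        with pytest.raises(mp.NoInformativeSplit):
            mp.fit_depth2_tree(binary, excluded={"S1", "S2"})

    def test_excluded_sites_never_split(self):
        calls = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        binary = make_binary(calls, labels_from_int([1, 1, 0, 0]))
        tree = mp.fit_depth2_tree(binary, excluded={"S1"})
        assert tree.root.site == "S2"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_root_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        p = int(rng.integers(2, 40))
        X = rng.integers(0, 2, size=(n, p))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        binary = make_binary(X, labels_from_int(y))
        j, gain = best_root_oracle(X, y)
        if j is None:
            with pytest.raises(mp.NoInformativeSplit):
                mp.fit_depth2_tree(binary)
        else:
            tree = mp.fit_depth2_tree(binary)
            assert tree.root.site == f"S{j + 1}"

    def test_root_agrees_with_sklearn_stump(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(77)
        X = rng.integers(0, 2, size=(40, 25))
        y = rng.integers(0, 2, size=40)
        y[:10] = X[:10, 3]  # give one site a clear, unique advantage
        binary = make_binary(X, labels_from_int(y))
        tree = mp.fit_depth2_tree(binary)
        clf = DecisionTreeClassifier(criterion="entropy", max_depth=1).fit(X, y)
        assert tree.root.site == f"S{clf.tree_.feature[0] + 1}"

    def test_majority_stump_accuracy(self):
        # hand-built stump predicting the 60% majority class everywhere
        stats = NodeStats(0.4, 0.6, 10)
        stump = mp.DecisionTree(
            root=TreeNode(stats=stats, entropy=mp.node_entropy(stats),
                          prediction=mp.CANCER)
        )
        calls = np.zeros((10, 1), dtype=int)
        binary = make_binary(calls, labels_from_int([1] * 6 + [0] * 4))
        assert mp.tree_accuracy(stump, binary) == pytest.approx(0.6)


class TestIterativeSelect:
    @staticmethod
    def independent_separators(n_sep, n_noise_const=5, n_per_class=12, seed=1):
        """n_sep mutually independent perfect separators + constant noise."""
        rng = np.random.default_rng(seed)
        y = np.array([1] * n_per_class + [0] * n_per_class)
        cols = [y.copy() for _ in range(n_sep)]
        cols += [np.zeros_like(y) for _ in range(n_noise_const)]
        X = np.column_stack(cols)
        order = rng.permutation(X.shape[1])
        site_ids = [f"sep{j}" if j < n_sep else f"const{j}" for j in order]
        return make_binary(X[:, order], labels_from_int(y), site_ids=site_ids)

    def test_twelve_separators_give_full_panel(self):
        binary = self.independent_separators(12)
        panel = mp.iterative_select(binary, min_panel=10)
        assert 10 <= len(panel) <= 12
        assert len(set(panel.site_ids)) == len(panel)
        assert all(s.startswith("sep") for s in panel.site_ids)

    def test_mask_grows_monotonically(self, small_split):
        binary = mp.binarize(small_split.train)
        panel = mp.iterative_select(binary, min_panel=8)
        orders = panel.table["selection_order"].tolist()
        assert orders == list(range(1, len(panel) + 1))
        runs = panel.table["run"].tolist()
        assert runs == sorted(runs)

    def test_exhausted_signal_stops_early_with_warning(self, caplog):
        binary = self.independent_separators(4)
        with caplog.at_level(logging.WARNING, logger="methpanel"):
            panel = mp.iterative_select(binary, min_panel=10)
        # each perfect-separator run yields one site; after 4 the only
        # remaining columns are constant and the loop must stop
        assert len(panel) == 4
        assert any("no informative split" in r.message.lower() for r in caplog.records)

    def test_empty_matrix_rejected(self):
        binary = make_binary(np.zeros((0, 3), dtype=int), [])
        with pytest.raises(mp.PipelineError, match="empty"):
            mp.iterative_select(binary)

    def test_planted_site_recovery_with_noise_background(self):
        # >= 10 planted opposite-side sites among pure same-side background:
        # selection + refinement recovers a panel dominated by planted sites
        cfg = mp.CohortConfig(
            n_cancer=60, n_normal=40, n_sites=400, n_informative=12,
            na_rate_base=0.0, n_bad_sites=0, n_bad_patients=0, n_unmapped=0,
            seed=23,
        )
        cohort = mp.generate_cohort(cfg)
        split = mp.split_dataset(cohort, seed=24)
        panel = mp.iterative_select(mp.binarize(split.train), min_panel=10)
        refined = mp.refine_panel(panel, split.train_validation())
        planted = set(mp.planted_site_ids(cfg))
        overlap = len(set(refined.site_ids) & planted)
        assert overlap / len(refined) >= 0.8


class TestSeparationScore:
    @pytest.mark.parametrize(
        "cm, nm, csd, nsd, expected",
        [
            (0.8, 0.1, 0.1, 0.1, 10.0),   # opposite sides: positive
            (0.2, 0.1, 0.1, 0.1, -2.0),   # both below cutoff: negative
            (0.3, 0.1, 0.1, 0.1, 0.0),    # median exactly at cutoff
        ],
    )
    def test_reference_values(self, cm, nm, csd, nsd, expected):
        score = mp.separation_score(SiteGroupStats(cm, nm, csd, nsd, cutoff=0.3))
        assert score == pytest.approx(expected)

    def test_zero_sd_is_undefined(self):
        with pytest.raises(mp.PipelineError, match="zero-SD"):
            mp.separation_score(SiteGroupStats(0.8, 0.1, 0.0, 0.1))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        cm=st.floats(0.0, 1.0), nm=st.floats(0.0, 1.0),
        csd=st.floats(0.01, 0.5), nsd=st.floats(0.01, 0.5),
    )
    def test_sign_iff_same_side(self, cm, nm, csd, nsd):
        score = mp.separation_score(SiteGroupStats(cm, nm, csd, nsd))
        same_side = (cm - 0.3) * (nm - 0.3) > 0
        opposite = (cm - 0.3) * (nm - 0.3) < 0
        if same_side:
            assert score < 0
        elif opposite:
            assert score > 0

    def test_swapping_group_sides_preserves_score(self):
        a = mp.separation_score(SiteGroupStats(0.8, 0.1, 0.1, 0.1))
        b = mp.separation_score(SiteGroupStats(0.1, 0.8, 0.1, 0.1))
        assert a == pytest.approx(b)


class TestRefinePanel:
    @staticmethod
    def continuous_fixture():
        # site good1: cancer high / normal low; site bad: both low;
        # site good2: cancer low / normal high
        values = np.array(
            [
                [0.85, 0.20, 0.10],
                [0.80, 0.25, 0.15],
                [0.90, 0.15, 0.05],
                [0.10, 0.10, 0.80],
                [0.15, 0.05, 0.85],
                [0.05, 0.12, 0.90],
            ]
        )
        return make_matrix(
            values, labels_from_int([1, 1, 1, 0, 0, 0]),
            site_ids=["good1", "bad", "good2"],
        )

    @staticmethod
    def raw_panel(matrix, sites):
        import pandas as pd

        return mp.CpGPanel(
            table=pd.DataFrame(
                {
                    "probe_id": sites,
                    "chromosome": "chr1",
                    "position": "1",
                    "cancer_median": np.nan,
                    "normal_median": np.nan,
                    "cancer_sd": np.nan,
                    "normal_sd": np.nan,
                    "separation_score": np.nan,
                    "selection_order": np.arange(1, len(sites) + 1),
                }
            )
        )

    def test_mixed_panel_keeps_positive_scores_only(self):
        m = self.continuous_fixture()
        panel = self.raw_panel(m, ["good1", "bad", "good2"])
        refined = mp.refine_panel(panel, m)
        assert refined.site_ids == ["good1", "good2"]
        assert (refined.table["separation_score"] > 0).all()
        assert refined.excluded["probe_id"].tolist() == ["bad"]
        assert (refined.excluded["separation_score"] < 0).all()

    def test_all_positive_panel_is_identity(self):
        m = self.continuous_fixture()
        panel = self.raw_panel(m, ["good1", "good2"])
        refined = mp.refine_panel(panel, m)
        assert refined.site_ids == ["good1", "good2"]
        assert len(refined.excluded) == 0

    def test_sample_sd_convention(self):
        m = self.continuous_fixture()
        refined = mp.refine_panel(self.raw_panel(m, ["good1"]), m)
        cancer_vals = m.values["good1"].iloc[:3]
        assert refined.table["cancer_sd"].iloc[0] == pytest.approx(
            cancer_vals.std(ddof=1)
        )

    def test_missing_site_rejected(self):
        m = self.continuous_fixture()
        with pytest.raises(mp.PipelineError, match="absent"):
            mp.refine_panel(self.raw_panel(m, ["ghost"]), m)
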