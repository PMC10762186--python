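"""Statistics helpers (log1p, CV, BH) against independent oracles, and
embedding/overlap behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pagvocal as pv
from pagvocal.embedding import EmbeddingResult
from pagvocal.synth import synth_feature_table


def brute_force_bh(p):
    """Step-up definition applied literally: adj_(i) = min_{k>=i} m*p_(k)/k."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * sorted_p[k] / (k + 1) for k in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestLog1p:
    def test_known_values(self):
        np.testing.assert_allclose(
            pv.log1p_transform([0.0, np.e - 1]), [0.0, 1.0]
        )

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 10, 50))
        y = pv.log1p_transform(x)
        assert np.all(np.diff(y) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pv.log1p_transform([-0.1])


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert pv.coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_arithmetic(self):
        # sd(1,3) = sqrt(2) = 1.4142; mean 2 -> 0.7071
        assert pv.coefficient_of_variation([1, 3]) == pytest.approx(
            0.7071, abs=1e-4
        )

    def test_scale_invariant(self):
        x = [1.0, 2.5, 4.0]
        assert pv.coefficient_of_variation(
            [3 * v for v in x]
        ) == pytest.approx(pv.coefficient_of_variation(x))

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -1.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            pv.coefficient_of_variation(bad)


class TestBHAdjust:
    def test_textbook_vector(self):
        np.testing.assert_allclose(
            pv.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pv.bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(pv.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pv.bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(pv.bh_adjust(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=15)
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(pv.bh_adjust(p), adj)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_preserved(self, p):
        adj = pv.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone: larger p never gets smaller adjusted p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


@pytest.fixture(scope="module")
def two_class_embedding():
    grunts = synth_feature_table(pv.GRUNT, 150, seed=11, source="grunt")
    hums = synth_feature_table(pv.HUM, 150, seed=12, source="hum")
    table = pd.concat([grunts, hums], ignore_index=True)
    return table, pv.embed_features(table, seed=0)


class TestEmbedFeatures:
    def test_one_coordinate_pair_per_row(self, two_class_embedding):
        table, emb = two_class_embedding
        assert emb.coords.shape == (len(table), 2)

    def test_classes_separate(self, two_class_embedding):
        table, emb = two_class_embedding
        a = emb.coords[(table["source"] == "grunt").to_numpy()]
        b = emb.coords[(table["source"] == "hum").to_numpy()]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = np.mean(
            [np.linalg.norm(x - a.mean(0)) for x in a]
            + [np.linalg.norm(x - b.mean(0)) for x in b]
        )
        assert between > within

    def test_reproducible_under_seed(self, two_class_embedding):
        table, emb = two_class_embedding
        again = pv.embed_features(table, seed=0)
        np.testing.assert_array_equal(emb.coords, again.coords)

    def test_too_few_rows_rejected(self):
        table = synth_feature_table(pv.GRUNT, 10, seed=0)
        with pytest.raises(ValueError, match="rows"):
            pv.embed_features(table, n_neighbors=15)


def make_embedding(coords):
    coords = np.asarray(coords, float)
    return EmbeddingResult(
        coords, 15, 0.1, 0, np.zeros(6), np.ones(6)
    )


def brute_force_overlap(coords, a_idx, b_idx, k):
    hits = 0
    is_b = np.zeros(len(coords), bool)
    is_b[b_idx] = True
    for i in a_idx:
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        neigh = np.argsort(d, kind="stable")[:k]
        hits += bool(is_b[neigh].any())
    return hits / len(a_idx)


class TestOverlapScore:
    def test_identical_clouds_full_overlap(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        emb = make_embedding(np.vstack([pts, pts]))
        a, b = np.arange(30), np.arange(30, 60)
        assert pv.overlap_score(emb, a, b) == 1.0

    def test_distant_clouds_no_overlap(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 2))
        emb = make_embedding(np.vstack([pts, pts + 1000.0]))
        a, b = np.arange(30), np.arange(30, 60)
        assert pv.overlap_score(emb, a, b) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(50, 2))
        a = np.arange(0, 25)
        b = np.arange(25, 50)
        emb = make_embedding(coords)
        for k in (3, 10):
            assert pv.overlap_score(emb, a, b, k=k) == pytest.approx(
                brute_force_overlap(coords, a, b, k)
            )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(40, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = coords @ rot.T + np.array([5.0, -3.0])
        a, b = np.arange(20), np.arange(20, 40)
        s1 = pv.overlap_score(make_embedding(coords), a, b)
        s2 = pv.overlap_score(make_embedding(moved), a, b)
        assert s1 == s2

    def test_small_group_reduces_k_with_warning(self):
        emb = make_embedding(np.random.default_rng(4).normal(size=(5, 2)))
        with pytest.warns(UserWarning, match="k reduced"):
            pv.overlap_score(emb, [0, 1], [2, 3, 4], k=10)

    def test_empty_group_rejected(self):
        emb = make_embedding(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            pv.overlap_score(emb, [], [0])


class TestCompareFeatureGroups:
    def test_single_group_rejected(self):
        table = synth_feature_table(pv.GRUNT, 20, seed=0, source="only")
        with pytest.raises(ValueError, match="two groups"):
            pv.compare_feature_groups(table, "duration")

    def test_one_animal_per_group_rejected(self):
        a = synth_feature_table(pv.GRUNT, 10, n_animals=1, seed=0, source="A")
        b = synth_feature_table(pv.GRUNT, 10, n_animals=1, seed=1, source="B")
        with pytest.raises(ValueError, match="animals"):
            pv.compare_feature_groups(pd.concat([a, b]), "duration")

    def test_detects_large_duration_effect(self):
        a = synth_feature_table(pv.GRUNT, 30, seed=0, source="A")
        b = synth_feature_table(
            pv.GRUNT, 30, seed=1, source="B", duration_scale=2.0
        )
        out = pv.compare_feature_groups(pd.concat([a, b]), "duration")
        assert len(out) == 1
        assert out[0].p_adjusted < 0.05
        assert out[0].estimate > 0  # B longer than A

    def test_three_groups_give_three_bh_adjusted_contrasts(self):
        frames = [
            synth_feature_table(pv.GRUNT, 15, seed=s, source=src)
            for s, src in enumerate(["A", "B", "C"])
        ]
        out = pv.compare_feature_groups(pd.concat(frames), "mean_prr")
        assert len(out) == 3
        raw = [c.p_value for c in out]
        np.testing.assert_allclose(
            [c.p_adjusted for c in out], pv.bh_adjust(raw)
        )
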