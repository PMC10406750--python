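"""Late fusion, AUC/DeLong, Kruskal-Wallis and feature significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gistgrf.evaluation import (
    auc_ci,
    delong_test,
    feature_significance,
    fuse_views,
    kruskal_wallis,
)

from conftest import make_noise_feature_table
import oracles


def score_table(case_scores, view, labels, image_scores=None):
    rows = []
    for i, (case, score) in enumerate(case_scores.items()):
        rows.append(
            {
                "case_id": case,
                "view": view,
                "score": score,
                "label": labels[case],
                "image_scores": image_scores[case] if image_scores else [score, score],
            }
        )
    return pd.DataFrame(rows)


class TestFuseViews:
    def test_median_of_pooled_image_scores(self):
        labels = {"c1": "difficult"}
        cc = score_table({"c1": 0.2}, "CC", labels, {"c1": [0.1, 0.3]})
        mlo = score_table({"c1": 0.8}, "MLO", labels, {"c1": [0.7, 0.9]})
        fused = fuse_views(cc, mlo)
        assert fused.iloc[0]["score"] == pytest.approx(0.5)  # median of 4
        assert fused.iloc[0]["view"] == "fused"

    def test_identical_views_identity(self):
        labels = {f"c{i}": ("difficult" if i % 2 else "easy") for i in range(6)}
        scores = {c: 0.1 * i for i, c in enumerate(labels)}
        cc = score_table(scores, "CC", labels)
        mlo = score_table(scores, "MLO", labels)
        fused = fuse_views(cc, mlo)
        merged = fused.set_index("case_id")["score"]
        for c, s in scores.items():
            assert merged[c] == pytest.approx(s)

    def test_case_median_mode_equals_mean_of_two(self):
        labels = {"c1": "easy"}
        cc = score_table({"c1": 0.2}, "CC", labels)
        mlo = score_table({"c1": 0.6}, "MLO", labels)
        fused = fuse_views(cc, mlo, mode="case-median")
        assert fused.iloc[0]["score"] == pytest.approx(0.4)

    def test_mismatched_case_sets_error(self):
        labels = {"c1": "easy", "c2": "easy"}
        cc = score_table({"c1": 0.2}, "CC", labels)
        mlo = score_table({"c2": 0.6}, "MLO", labels)
        with pytest.raises(ValueError, match="different case sets"):
            fuse_views(cc, mlo)


class TestAucCi:
    def test_perfect_separation(self):
        res = auc_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.n_pos == 2 and res.n_neg == 2

    def test_all_ties_gives_half(self):
        res = auc_ci([0.5] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        assert res.auc == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, dtype=int)
            y[: max(1, n // 2)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid to force ties
            res = auc_ci(scores, y)
            assert res.auc == pytest.approx(oracles.auc_by_pair_counting(scores, y))
            assert res.ci_low <= res.auc <= res.ci_high

    def test_matches_reference_delong_ci(self):
        # frozen values from pROC ci.auc(method="delong"), R 4.3 / pROC 1.19
        scores = [0.82, 0.71, 0.93, 0.45, 0.65, 0.30, 0.52, 0.18, 0.44, 0.28]
        res = auc_ci(scores, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert res.auc == pytest.approx(0.96)
        assert res.ci_low == pytest.approx(0.8491276941, abs=1e-9)
        assert res.ci_high == 1.0

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc_ci([0.1, 0.2], [1, 1])


# frozen reference example from pROC roc.test(method="delong"): R's set.seed(42),
# a = rnorm(30) + y*0.8, b = rnorm(30) + y*0.3, y = 15 positives then 15 negatives
PROC_A = np.array([
    2.1709584471, 0.2353018286, 1.1631284113, 1.4328626050, 1.2042683231,
    0.6938754839, 2.3115219974, 0.7053409616, 2.8184237139, 0.7372859009,
    2.1048696542, 3.0866453927, -0.5888607011, 0.5212112332, 0.6666786636,
    0.6359503981, -0.2842529214, -2.6564554209, -2.4404669286, 1.3201133457,
    -0.3066385941, -1.7813084340, -0.1719173558, 1.2146746992, 1.8951934613,
    -0.4304691316, -0.2572693828, -1.7631630852, 0.4600973548, -0.6399948760,
])
PROC_B = np.array([
    0.7554501232, 1.0048373372, 1.3351035220, -0.3089263754, 0.8049551233,
    -1.4170086791, -0.4844590084, -0.5509075942, -2.1142076499, 0.3361226069,
    0.5059986002, -0.0610572985, 1.0581632357, -0.4267048271, -1.0682810444,
    0.4328180259, -0.8113931762, 1.4441012617, -0.4314462026, 0.6556478834,
    0.3219252652, -0.7838389409, 1.5757275198, 0.6428993057, 0.0897606466,
    0.2765507473, 0.6792888161, 0.0898328866, -2.9930900832, 0.2848829535,
])
PROC_Y = np.array([1] * 15 + [0] * 15)


class TestDelongTest:
    def test_identical_scores_no_difference(self):
        a = [0.9, 0.7, 0.3, 0.2]
        res = delong_test(a, a, [1, 1, 0, 0])
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetric_z(self):
        res_ab = delong_test(PROC_A, PROC_B, PROC_Y)
        res_ba = delong_test(PROC_B, PROC_A, PROC_Y)
        assert res_ab.z == pytest.approx(-res_ba.z)
        assert res_ab.p == pytest.approx(res_ba.p)

    def test_matches_reference_implementation(self):
        # frozen z and p from pROC roc.test(method="delong")
        res = delong_test(PROC_A, PROC_B, PROC_Y)
        assert res.auc_a == pytest.approx(0.8311111111, abs=1e-9)
        assert res.auc_b == pytest.approx(0.4666666667, abs=1e-9)
        assert res.z == pytest.approx(2.5548483389, abs=1e-8)
        assert res.p == pytest.approx(0.0106234074, abs=1e-8)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 20 + [0] * 20)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            if delong_test(rng.normal(size=40), rng.normal(size=40), y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_agrees_with_permutation_oracle_when_effect_is_clear(self):
        # at n=10 the normal approximation tracks the exact within-case
        # permutation distribution in the strong-separation regime
        y = np.array([1] * 5 + [0] * 5)
        a = np.array([0.95, 0.9, 0.85, 0.8, 0.75, 0.3, 0.25, 0.2, 0.15, 0.1])
        b = np.array([0.55, 0.35, 0.6, 0.4, 0.5, 0.65, 0.45, 0.3, 0.7, 0.5])
        res = delong_test(a, b, y)

        import itertools

        def auc(s):
            return oracles.auc_by_pair_counting(s, y)

        obs = abs(auc(a) - auc(b))
        hits = total = 0
        for bits in itertools.product([0, 1], repeat=10):
            sw = np.array(bits, dtype=bool)
            aa = np.where(sw, b, a)
            bb = np.where(sw, a, b)
            if abs(auc(aa) - auc(bb)) >= obs - 1e-12:
                hits += 1
            total += 1
        assert abs(res.p - hits / total) <= 0.02

    def test_unpaired_inputs_error(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [1, 0])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_two_groups(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert res.H == pytest.approx(3.857, abs=5e-4)
        assert res.p == pytest.approx(0.0495, abs=5e-4)
        assert res.df == 1

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = list(np.round(rng.normal(size=15), 1))
            groups = list(rng.choice(["a", "b", "c"], size=15))
            if len(set(groups)) < 2:
                continue
            res = kruskal_wallis(values, groups)
            assert res.H == pytest.approx(
                oracles.kruskal_h_by_rank_formula(values, groups), rel=1e-9
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=20)
        groups = ["a"] * 10 + ["b"] * 10
        h1 = kruskal_wallis(values, groups).H
        h2 = kruskal_wallis(np.exp(values), groups).H
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestFeatureSignificance:
    def test_planted_feature_detected_null_features_calm(self):
        features, labels = make_noise_feature_table(30, seed=1, informative={0: 3.0})
        table = feature_significance(features, labels)
        assert len(table) == 34
        first = table.iloc[0]
        assert first["p"] < 0.01
        assert table["significant"].sum() <= 8  # planted + a few false positives

    def test_shuffled_feature_p_uniform(self):
        rng = np.random.default_rng(3)
        features, labels = make_noise_feature_table(20, seed=3)
        col = features.columns[3]
        ps = []
        for _ in range(200):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            table = feature_significance(shuffled, labels, feature_cols=[col])
            ps.append(table["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_labels_error(self):
        features, labels = make_noise_feature_table(4, seed=0)
        labels[:] = "difficult"
        with pytest.raises(ValueError):
            feature_significance(features, labels)
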