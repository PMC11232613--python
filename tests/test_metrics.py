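import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emovad.metrics import (
    DEFAULT_CENTROIDS,
    CentroidCategorizer,
    CentroidMap,
    assign_categories,
    assign_category,
    categorical_report,
    combined_vad_mse,
    combined_vad_r,
    evaluate,
    mse_per_dimension,
    pearson_per_dimension,
)

# 5-pair fixture for spreadsheet-style hand checks
PRED5 = np.array([
    [0.10, 0.20, 0.30],
    [0.40, 0.50, 0.60],
    [0.70, 0.80, 0.90],
    [0.25, 0.35, 0.45],
    [0.55, 0.65, 0.75],
])
GOLD5 = np.array([
    [0.20, 0.10, 0.40],
    [0.35, 0.55, 0.50],
    [0.80, 0.70, 0.95],
    [0.20, 0.40, 0.40],
    [0.60, 0.60, 0.80],
])


def brute_mse(pred, gold, j):
    return sum((p[j] - g[j]) ** 2 for p, g in zip(pred, gold)) / len(pred)


def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestMSE:
    def test_perfect_prediction_is_zero(self):
        assert mse_per_dimension(PRED5, PRED5) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        pred = np.full((4, 3), 0.5)
        gold = np.zeros((4, 3))
        assert mse_per_dimension(pred, gold) == (0.25, 0.25, 0.25)

    def test_matches_brute_force_on_fixture(self):
        got = mse_per_dimension(PRED5, GOLD5)
        for j in range(3):
            assert got[j] == pytest.approx(brute_mse(PRED5, GOLD5, j), abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_per_dimension(PRED5, GOLD5[:3])
        with pytest.raises(ValueError):
            mse_per_dimension(np.empty((0, 3)), np.empty((0, 3)))


class TestCombinedMSE:
    def test_zero_for_perfect_prediction_both_modes(self):
        for mode in ("scalar-average", "entrywise"):
            assert combined_vad_mse(PRED5, PRED5, mode) == 0.0

    def test_modes_differ_by_construction(self):
        pred = np.array([[1.0, 0.0, 0.5]])
        gold = np.array([[0.0, 1.0, 0.5]])
        assert combined_vad_mse(pred, gold, "scalar-average") == pytest.approx(0.0)
        assert combined_vad_mse(pred, gold, "entrywise") == pytest.approx(2 / 3)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_entrywise_equals_mean_of_per_dimension(self, seed, n):
        rng = np.random.default_rng(seed)
        pred, gold = rng.random((n, 3)), rng.random((n, 3))
        assert combined_vad_mse(pred, gold, "entrywise") == pytest.approx(
            np.mean(mse_per_dimension(pred, gold)), abs=1e-12
        )

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            combined_vad_mse(PRED5, GOLD5, "median")


class TestPearson:
    def test_identity_gives_one(self):
        r = pearson_per_dimension(PRED5, PRED5)
        assert all(x == pytest.approx(1.0) for x in r)

    def test_antisymmetry_gives_minus_one(self):
        r = pearson_per_dimension(1.0 - GOLD5, GOLD5)
        assert all(x == pytest.approx(-1.0) for x in r)

    def test_matches_textbook_formula_on_six_pairs(self):
        rng = np.random.default_rng(123)
        pred, gold = rng.random((6, 3)), rng.random((6, 3))
        got = pearson_per_dimension(pred, gold)
        for j in range(3):
            expect = brute_pearson(list(pred[:, j]), list(gold[:, j]))
            assert got[j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_is_an_explicit_error(self):
        const = np.full((5, 3), 0.5)
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_per_dimension(const, GOLD5)

    def test_combined_modes(self):
        rng = np.random.default_rng(7)
        pred, gold = rng.random((8, 3)), rng.random((8, 3))
        scalar = combined_vad_r(pred, gold, "scalar-average")
        expect = brute_pearson(list(pred.mean(axis=1)), list(gold.mean(axis=1)))
        assert scalar == pytest.approx(expect, abs=1e-12)
        concat = combined_vad_r(pred, gold, "concatenated")
        expect = brute_pearson(
            list(pred.ravel(order="F")), list(gold.ravel(order="F"))
        )
        assert concat == pytest.approx(expect, abs=1e-12)


class TestAssignCategory:
    def test_exact_centroid_hits_its_name(self):
        for name, v, a in DEFAULT_CENTROIDS.entries:
            assert assign_category((v, a, 0.77)) == name

    def test_cube_centre_is_rooted(self):
        # nearest default centroid to (0.5, 0.5): rooted at distance ~0.029
        assert assign_category((0.5, 0.5, 0.5)) == "rooted"

    def test_high_va_corner_is_excited(self):
        assert assign_category((0.9, 0.9, 0.1)) == "excited"

    def test_dominance_is_ignored(self):
        for d in (0.0, 0.5, 1.0):
            assert assign_category((0.188, 0.183, d)) == "empty"

    def test_agrees_with_exhaustive_argmin_on_10k_points(self):
        rng = np.random.default_rng(99)
        pts = rng.random((10_000, 2))
        got = assign_categories(pts)
        names = DEFAULT_CENTROIDS.names
        coords = DEFAULT_CENTROIDS.coordinates
        for p, g in zip(pts, got):
            dists = [np.hypot(*(p - c)) for c in coords]
            assert names[int(np.argmin(dists))] == g

    def test_tie_breaks_toward_earlier_centroid(self):
        cm = CentroidMap((("first", 0.4, 0.5), ("second", 0.6, 0.5)))
        assert assign_category((0.5, 0.5, 0.0), cm) == "first"

    def test_map_validation(self):
        with pytest.raises(ValueError):
            CentroidMap((("only", 0.5, 0.5),))
        with pytest.raises(ValueError):
            CentroidMap((("a", 0.5, 0.5), ("a", 0.6, 0.5)))
        with pytest.raises(ValueError):
            CentroidMap((("a", 0.5, 0.5), ("b", 1.5, 0.5)))

    def test_categorizer_estimator(self):
        est = CentroidCategorizer().fit()
        out = est.predict([[0.5, 0.5, 0.5], [0.9, 0.9, 0.1]])
        assert list(out) == ["rooted", "excited"]


class TestCategoricalReport:
    def test_perfect_prediction_all_f1_one(self):
        rng = np.random.default_rng(5)
        gold = rng.random((40, 3))
        rep = categorical_report(gold, gold)
        occupied = [c for c, m in rep["per_category"].items() if m["support"] > 0]
        assert occupied and all(
            rep["per_category"][c]["f1"] == 1.0 for c in occupied
        )
        assert rep["micro_f1"] == 1.0

    def test_total_miss(self):
        gold = np.tile([0.51, 0.527, 0.5], (6, 1))  # all "rooted"
        pred = np.tile([0.188, 0.183, 0.5], (6, 1))  # all "empty"
        rep = categorical_report(pred, gold)
        assert rep["per_category"]["rooted"]["recall"] == 0.0
        assert rep["micro_f1"] == 0.0

    def test_matches_hand_built_confusion_matrix(self):
        # 20 examples: place points exactly on centroids so categories are
        # unambiguous, then compare against by-hand one-vs-rest P/R/F1
        c = {n: (v, a) for n, v, a in DEFAULT_CENTROIDS.entries}
        def pt(name):
            return [*c[name], 0.5]
        gold_names = ["empty"] * 6 + ["rooted"] * 8 + ["excited"] * 6
        pred_names = (["empty"] * 4 + ["rooted"] * 2      # 4/6 empty right
                      + ["rooted"] * 6 + ["excited"] * 2  # 6/8 rooted right
                      + ["excited"] * 6)                  # 6/6 excited right
        gold = np.array([pt(n) for n in gold_names])
        pred = np.array([pt(n) for n in pred_names])
        rep = categorical_report(pred, gold)

        # hand counts -> empty: tp4 fp0 fn2 ; rooted: tp6 fp2 fn2 ; excited: tp6 fp2 fn0
        def prf(tp, fp, fn):
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            return p, r, f

        for name, (tp, fp, fn) in {
            "empty": (4, 0, 2), "rooted": (6, 2, 2), "excited": (6, 2, 0)
        }.items():
            p, r, f = prf(tp, fp, fn)
            got = rep["per_category"][name]
            assert got["precision"] == pytest.approx(p, abs=1e-12)
            assert got["recall"] == pytest.approx(r, abs=1e-12)
            assert got["f1"] == pytest.approx(f, abs=1e-12)

        f1s = {n: prf(*tfn)[2] for n, tfn in
               {"empty": (4, 0, 2), "rooted": (6, 2, 2), "excited": (6, 2, 0)}.items()}
        # macro over ALL five map categories (absent ones contribute 0)
        assert rep["macro_f1"] == pytest.approx(sum(f1s.values()) / 5, abs=1e-12)
        assert rep["micro_f1"] == pytest.approx(16 / 20, abs=1e-12)
        support = {"empty": 6, "rooted": 8, "excited": 6}
        weighted = sum(f1s[n] * support[n] for n in f1s) / 20
        assert rep["average_f1"] == pytest.approx(weighted, abs=1e-12)

    def test_micro_f1_equals_accuracy(self):
        rng = np.random.default_rng(11)
        pred, gold = rng.random((50, 3)), rng.random((50, 3))
        rep = categorical_report(pred, gold)
        acc = np.mean(
            np.array(assign_categories(pred)) == np.array(assign_categories(gold))
        )
        assert rep["micro_f1"] == pytest.approx(acc, abs=1e-12)

    def test_permutation_invariance_of_all_metrics(self):
        rng = np.random.default_rng(21)
        pred, gold = rng.random((30, 3)), rng.random((30, 3))
        rep1 = evaluate(pred, gold)
        perm = rng.permutation(30)
        rep2 = evaluate(pred[perm], gold[perm])

        def assert_close(a, b):
            if isinstance(a, dict):
                assert a.keys() == b.keys()
                for k in a:
                    assert_close(a[k], b[k])
            else:
                assert a == pytest.approx(b, abs=1e-12)

        assert_close(rep1.to_dict(), rep2.to_dict())


class TestEvaluateReport:
    def test_full_report_shape_and_perfect_limit(self):
        rng = np.random.default_rng(31)
        gold = rng.random((25, 3))
        rep = evaluate(gold, gold)
        assert rep.n_examples == 25
        assert all(v == 0.0 for v in rep.mse.values())
        assert rep.mse_combined == 0.0
        assert all(v == pytest.approx(1.0) for v in rep.pearson.values())
        assert rep.pearson_combined == pytest.approx(1.0)
        assert rep.micro_f1 == 1.0
        assert set(rep.to_dict()) >= {"mse", "pearson", "macro_f1", "n_examples"}
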