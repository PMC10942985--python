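"""Folds, aggregation, AUC, significance procedures, heatmaps — with oracles."""

import numpy as np
import pytest
from scipy import stats

from histomark.evaluation import (
    EvaluationResult,
    aggregate,
    biomarker_significance,
    compute_auc,
    correlate,
    group_significance,
    make_folds,
    render_heatmap,
    summarize,
)


def _brute_force_auc(scores, labels):
    """Pair-counting Mann-Whitney oracle, ties counted half."""
    pos = [scores[k] for k in scores if labels[k] == 1]
    neg = [scores[k] for k in scores if labels[k] == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _brute_force_bh(pvals, fdr):
    """Step-up rule executed literally: largest k with p_(k) <= k/m * fdr."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k / m * fdr:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestMakeFolds:
    def test_exact_stratification_30_patients_12_positive(self):
        labels = {f"P{i}": int(i < 12) for i in range(30)}
        fa = make_folds(labels, k=3, seed=1)
        for fold in range(3):
            members = fa.patients_in(fold)
            assert len(members) == 10
            assert sum(labels[p] for p in members) == 4

    def test_nine_positives_discard_signal(self):
        labels = {f"P{i}": int(i < 9) for i in range(40)}
        assert make_folds(labels, seed=0) is None

    def test_partition_disjoint_and_covering(self):
        labels = {f"P{i}": int(i % 3 == 0) for i in range(31)}
        fa = make_folds(labels, k=3, seed=2)
        all_members = [p for f in range(3) for p in fa.patients_in(f)]
        assert sorted(all_members) == sorted(labels)

    def test_positive_counts_within_one_of_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(25, 80))
            labels = {f"P{i}": int(rng.random() < 0.4) for i in range(n)}
            if sum(labels.values()) < 10:
                continue
            fa = make_folds(labels, k=3, seed=int(rng.integers(100)))
            counts = [sum(labels[p] for p in fa.patients_in(f))
                      for f in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_deterministic_under_seed(self):
        labels = {f"P{i}": int(i % 2) for i in range(40)}
        assert (make_folds(labels, seed=9).fold_of
                == make_folds(labels, seed=9).fold_of)


class TestAggregate:
    def test_slide_mean(self):
        ts = {("s1", 0): 0.2, ("s1", 1): 0.4, ("s1", 2): 0.9}
        ps = aggregate(ts, {"s1": "p1"})
        assert ps.slide_scores["s1"] == pytest.approx(0.5)

    def test_patient_mean_over_slides(self):
        ts = {("s1", 0): 0.4, ("s2", 0): 0.6}
        ps = aggregate(ts, {"s1": "p1", "s2": "p1"})
        assert ps.patient_scores["p1"] == pytest.approx(0.5)

    def test_matches_nested_mean_oracle(self, rng):
        tile_scores, mapping, per_slide = {}, {}, {}
        for pi in range(5):
            for si in range(int(rng.integers(1, 4))):
                slide = f"p{pi}_s{si}"
                mapping[slide] = f"p{pi}"
                vals = rng.random(int(rng.integers(1, 8)))
                per_slide[slide] = vals
                for ti, v in enumerate(vals):
                    tile_scores[(slide, ti)] = float(v)
        ps = aggregate(tile_scores, mapping)
        for pi in range(5):
            slides = [s for s, p in mapping.items() if p == f"p{pi}"]
            expected = np.mean([np.mean(per_slide[s]) for s in slides])
            assert ps.patient_scores[f"p{pi}"] == pytest.approx(expected)

    def test_unscored_slide_is_error(self):
        with pytest.raises(ValueError, match="no scored tiles"):
            aggregate({("s1", 0): 0.5}, {"s1": "p1", "s2": "p2"})

    def test_permutation_invariant(self, rng):
        items = [((f"s{i%3}", i), float(rng.random())) for i in range(30)]
        mapping = {"s0": "p0", "s1": "p0", "s2": "p1"}
        a = aggregate(dict(items), mapping)
        b = aggregate(dict(reversed(items)), mapping)
        assert a.patient_scores == b.patient_scores


class TestComputeAuc:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.2}
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        assert compute_auc(scores, labels) == 1.0

    def test_random_scores_near_half(self, rng):
        n = 4000
        scores = {f"p{i}": float(rng.random()) for i in range(n)}
        labels = {f"p{i}": int(rng.random() < 0.5) for i in range(n)}
        assert abs(compute_auc(scores, labels) - 0.5) < 0.05

    def test_matches_mann_whitney_oracle_200_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            # quantized scores force ties
            scores = {f"p{i}": float(np.round(rng.random(), 1))
                      for i in range(n)}
            labels = {f"p{i}": int(rng.random() < 0.5) for i in range(n)}
            if len(set(labels.values())) < 2:
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="one class"):
            compute_auc({"a": 0.5, "b": 0.6}, {"a": 1, "b": 1})


class TestSummarize:
    def _pred(self, scores, fold):
        from histomark.evaluation import PredictionSet
        return PredictionSet({}, {}, scores, fold)

    def test_mean_and_zero_std(self):
        labels = {"a": 1, "b": 0}
        preds = [self._pred({"a": 0.8, "b": 0.2}, f) for f in range(3)]
        res = summarize("b1", preds, labels)
        assert res.mean_auc == 1.0 and res.std_auc == 0.0

    def test_matches_oracle_mean_std(self, rng):
        labels = {f"p{i}": int(i % 2) for i in range(12)}
        preds = []
        for f in range(3):
            fold_pat = [f"p{i}" for i in range(12) if i % 3 == f]
            preds.append(self._pred(
                {p: float(rng.random()) for p in fold_pat}, f))
        res = summarize("b1", preds, labels)
        aucs = [compute_auc(ps.patient_scores,
                            {p: labels[p] for p in ps.patient_scores})
                for ps in preds]
        assert res.mean_auc == pytest.approx(np.mean(aucs))
        assert res.std_auc == pytest.approx(np.std(aucs, ddof=1))
        # pooled scores cover every patient exactly once
        assert sorted(res.pooled_scores) == sorted(labels)


class TestGroupSignificance:
    def test_null_group_rarely_significant(self):
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(40):
            aucs = rng.normal(0.5, 0.05, 20)
            if group_significance(aucs, seed=seed) < 0.05:
                hits += 1
        assert hits <= 4  # ~5% expected

    def test_strong_group_highly_significant(self):
        rng = np.random.default_rng(2)
        aucs = rng.normal(0.77, 0.09, 100)
        assert group_significance(aucs, seed=0) < 1e-5

    def test_null_p_distribution_uniform(self):
        """KS uniformity of p-values over simulated null groups at 1%."""
        rng = np.random.default_rng(3)
        pvals = [group_significance(rng.normal(0.5, 0.08, 15), seed=s)
                 for s in range(2000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_std_returns_one(self):
        with pytest.warns(UserWarning):
            assert group_significance([0.6, 0.6, 0.6]) == 1.0


class TestBiomarkerSignificance:
    def _result(self, bid, pos, neg):
        pooled = {f"p{i}": (float(v), 1) for i, v in enumerate(pos)}
        pooled.update({f"n{i}": (float(v), 0) for i, v in enumerate(neg)})
        return EvaluationResult(bid, [0.5] * 3, 0.5, 0.0, pooled)

    def test_hand_executed_bh_example(self):
        # p = {0.01, 0.02, 0.03, 0.5} at FDR 0.05 -> 3 rejections
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.5])
        expected = _brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(expected, [True, True, True, False])
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, expected)

    def test_pooled_score_pathway_matches_bh_oracle(self, rng):
        """p-values computed from pooled scores feed BH identically."""
        results = []
        for i in range(6):
            shift = 0.5 * (i % 3)
            pos = rng.normal(shift, 1.0, 25)
            neg = rng.normal(0.0, 1.0, 25)
            results.append(self._result(f"b{i}", pos, neg))
        out = biomarker_significance(results, fdr=0.05)
        pv = np.array([r.p_value for r in out])
        for r, expect in zip(out, _brute_force_bh(pv, 0.05)):
            assert r.significant == expect
            # the per-biomarker p is the plain two-sided t-test
            scores = np.array([s for s, _ in r.pooled_scores.values()])
            labs = np.array([l for _, l in r.pooled_scores.values()])
            assert r.p_value == pytest.approx(
                stats.ttest_ind(scores[labs == 1], scores[labs == 0]).pvalue)

    def test_all_p_one_no_rejections(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 40)
        results = [self._result(f"b{i}", vals[:20], vals[:20])
                   for i in range(4)]
        out = biomarker_significance(results)
        assert not any(r.significant for r in out)

    def test_bh_matches_brute_force_on_random_p_vectors(self):
        """statsmodels BH rejection sets equal the literal step-up, 1000x."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.3, 3)
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, _brute_force_bh(p, 0.05))

    def test_bh_monotone_in_fdr(self, rng):
        p = rng.random(20) ** 2
        results_hi = [self._result(f"b{i}", [], []) for i in range(0)]
        from statsmodels.stats.multitest import multipletests
        rej_lo, *_ = multipletests(p, alpha=0.01, method="fdr_bh")
        rej_hi, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert set(np.where(rej_lo)[0]) <= set(np.where(rej_hi)[0])

    def test_single_class_pooled_excluded_with_warning(self):
        r = self._result("b0", [0.5, 0.6], [])
        with pytest.warns(UserWarning, match="single-class"):
            out = biomarker_significance([r])
        assert np.isnan(out[0].p_value)


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlate(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0]
        r, _ = correlate(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        r, _ = correlate(x, y)
        oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRenderHeatmap:
    def test_constant_scores_uniform_image(self):
        scores = {(r, c): 0.5 for r in range(3) for c in range(4)}
        img, _ = render_heatmap(scores)
        assert (img == img[0, 0]).all()

    def test_single_max_tile_is_top1(self):
        scores = {(0, 0): 0.1, (0, 1): 0.95, (1, 0): 0.3}
        _, top = render_heatmap(scores, top_k=1)
        assert top[0][:2] == (0, 1)

    def test_topk_matches_sort_oracle(self, rng):
        scores = {(r, c): float(np.round(rng.random(), 2))
                  for r in range(5) for c in range(5)}
        _, top = render_heatmap(scores, top_k=10)
        expected = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        assert [(r, c, v) for (r, c), v in expected] == top

    def test_empty_error(self):
        with pytest.raises(ValueError):
            render_heatmap({})
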