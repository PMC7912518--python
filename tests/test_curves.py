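"""Curve stratification, corpus statistics, coverage and the sigmoid fit."""

import math
import random

import numpy as np
import pytest

from citeshare import (
    DegenerateFitError,
    OverlapRecord,
    SigmoidRecallModel,
    build_graph,
    corpus_recall,
    coverage,
    fit_sigmoid,
    fraction_full_recall,
    predict_recall,
    stratify,
)
from citeshare.curves import sigmoid

from conftest import make_store


def rec(focal="F", k=3, n_a=2, n_u=4, shared=1, recall=None, precision=None,
        ap=0.1):
    return OverlapRecord(
        focal=focal, n_annotated_neighbors=k, n_article_annots=n_a,
        n_neighborhood_annots=n_u, n_shared=shared,
        recall=shared / n_a if recall is None else recall,
        precision=shared / n_u if precision is None else precision, ap=ap)


class TestStratify:
    def test_bin_means(self):
        records = [rec("A", k=3, recall=0.5), rec("B", k=3, recall=1.0)]
        (point,) = stratify(records)
        assert point.bin == 3 and point.n_records == 2
        assert point.mean_recall == pytest.approx(0.75)

    def test_single_record_identity(self):
        (point,) = stratify([rec("A", k=5, recall=0.4, precision=0.2, ap=0.3)])
        assert (point.bin, point.n_records) == (5, 1)
        assert (point.mean_recall, point.mean_precision, point.map) == (
            0.4, 0.2, 0.3)

    def test_pooled_terminal_bin(self):
        records = [rec("A", k=2), rec("B", k=25), rec("C", k=30)]
        points = stratify(records, max_bin=20)
        assert [p.bin for p in points] == [2, 21]
        assert points[-1].open_ended and points[-1].n_records == 2
        assert not stratify(records, max_bin=20, include_pooled=False)[-1].open_ended

    def test_empty_records_give_empty_curve(self):
        assert stratify([]) == []

    def test_matches_group_by_mean_oracle(self):
        rng = random.Random(9)
        records = [rec(f"R{i}", k=rng.randrange(1, 26),
                       recall=rng.random(), precision=rng.random(),
                       ap=rng.random()) for i in range(500)]
        points = {p.bin: p for p in stratify(records, max_bin=20)}
        groups = {}
        for r in records:
            groups.setdefault(min(r.n_annotated_neighbors, 21), []).append(r)
        for b, rs in groups.items():
            assert points[b].n_records == len(rs)
            assert points[b].mean_recall == pytest.approx(
                sum(r.recall for r in rs) / len(rs))
            assert points[b].map == pytest.approx(
                sum(r.ap for r in rs) / len(rs))


class TestCorpusRecall:
    def test_annotation_weighted(self):
        records = [rec("A", n_a=2, shared=1), rec("B", n_a=3, shared=3)]
        assert corpus_recall(records) == pytest.approx(4 / 5)

    def test_all_recovered(self):
        assert corpus_recall([rec(n_a=4, shared=4)]) == 1.0

    def test_differs_from_mean_of_per_article_recalls(self):
        records = [rec("A", n_a=1, shared=0), rec("B", n_a=9, shared=9)]
        assert corpus_recall(records) == pytest.approx(0.9)
        assert np.mean([r.recall for r in records]) == pytest.approx(0.5)

    def test_zero_annotations_undefined(self):
        with pytest.raises(ValueError):
            corpus_recall([])

    def test_matches_flat_enumeration(self):
        rng = random.Random(12)
        records = [rec(f"R{i}", n_a=rng.randrange(1, 8),
                       shared=0) for i in range(200)]
        records = [rec(f"R{i}", n_a=r.n_article_annots,
                       shared=rng.randrange(0, r.n_article_annots + 1))
                   for i, r in enumerate(records)]
        total = sum(r.n_article_annots for r in records)
        hit = sum(r.n_shared for r in records)
        assert corpus_recall(records) == pytest.approx(hit / total)


class TestFractionFullRecall:
    def test_examples(self):
        records = [rec(n_a=2, shared=2), rec(n_a=2, shared=1),
                   rec(n_a=3, shared=3), rec(n_a=1, shared=0)]
        assert fraction_full_recall(records) == 0.5

    def test_exact_integer_comparison(self):
        # 3/3 recovered must count as full recall regardless of float repr
        assert fraction_full_recall([rec(n_a=3, shared=3)]) == 1.0
        assert fraction_full_recall([rec(n_a=3, shared=2)]) == 0.0

    def test_counting_oracle(self):
        rng = random.Random(77)
        records = []
        for i in range(200):
            n_a = rng.randrange(1, 6)
            records.append(rec(f"R{i}", n_a=n_a, shared=rng.randrange(0, n_a + 1)))
        expected = sum(1 for r in records
                       if r.n_shared == r.n_article_annots) / len(records)
        assert fraction_full_recall(records) == expected


class TestCoverage:
    def test_chain_single_annotated_end(self):
        # chain 1-2-3-4, only article 1 annotated: only 2 has an annotated neighbor
        g = build_graph([("1", "2"), ("2", "3"), ("3", "4")])
        store = make_store({"1": {"X"}})
        assert coverage(g, store, ["1", "2", "3", "4"]) == pytest.approx(1 / 4)

    def test_fully_annotated_connected_graph(self):
        g = build_graph([("1", "2"), ("2", "3")])
        store = make_store({"1": {"X"}, "2": {"X"}, "3": {"X"}})
        assert coverage(g, store, ["1", "2", "3"]) == 1.0

    def test_empty_universe_is_error(self):
        g = build_graph([("1", "2")])
        with pytest.raises(ValueError):
            coverage(g, make_store({"1": {"X"}}), [])

    def test_monotone_in_threshold_and_degree(self):
        rng = random.Random(14)
        nodes = [f"N{i}" for i in range(60)]
        pairs = [(rng.choice(nodes), rng.choice(nodes)) for _ in range(150)]
        g = build_graph(pairs)
        store = make_store({n: {"X"} for n in nodes if rng.random() < 0.3})
        prev = 1.0
        for k in (1, 2, 3, 4):
            c = coverage(g, store, nodes, min_annotated_neighbors=k)
            assert c <= prev
            prev = c
        assert coverage(g, store, nodes, degree=2) >= coverage(
            g, store, nodes, degree=1)

    def test_per_node_brute_force(self):
        rng = random.Random(15)
        nodes = [f"N{i}" for i in range(40)]
        pairs = [(rng.choice(nodes), rng.choice(nodes)) for _ in range(100)]
        g = build_graph(pairs)
        annotated = {n for n in nodes if rng.random() < 0.4}
        store = make_store({n: {"X"} for n in annotated})
        adj = {n: set() for n in nodes}
        for a, b in pairs:
            if a != b:
                adj[a].add(b)
                adj[b].add(a)
        expected = sum(
            1 for n in nodes if len(adj[n] & annotated) >= 2) / len(nodes)
        assert coverage(g, store, nodes, min_annotated_neighbors=2) == expected


class TestSigmoidFit:
    TRUE = dict(L=0.9, k=0.8, x0=4.0)

    def _noise_free(self):
        x = np.repeat(np.arange(1.0, 21.0), 5)
        return x, sigmoid(x, **self.TRUE)

    def test_noise_free_recovery(self):
        x, y = self._noise_free()
        fit = fit_sigmoid(x, y, n_boot=0)
        assert fit.L == pytest.approx(self.TRUE["L"], abs=1e-6)
        assert fit.k == pytest.approx(self.TRUE["k"], abs=1e-6)
        assert fit.x0 == pytest.approx(self.TRUE["x0"], abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_is_degenerate(self):
        with pytest.raises(DegenerateFitError, match="SS_tot"):
            fit_sigmoid([1, 2, 3, 4, 5], [0.5] * 5, n_boot=0)

    def test_requires_four_distinct_x(self):
        with pytest.raises(ValueError, match="4 distinct"):
            SigmoidRecallModel([1, 1, 2, 3], [0.1, 0.2, 0.3, 0.4])

    def test_binned_mode_fits_per_count_means(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = sigmoid(x, **self.TRUE)
        y_jitter = y + np.array([0.05, -0.05, 0.02, -0.02, 0, 0, 0, 0])
        model = SigmoidRecallModel(x, y_jitter, binned=True)
        assert len(model.x) == 6  # collapsed to unique counts
        assert model.y[0] == pytest.approx(y_jitter[:2].mean())

    def test_predict_midpoint_and_asymptote(self):
        x, y = self._noise_free()
        fit = fit_sigmoid(x, y, n_boot=0)
        assert predict_recall(fit, fit.x0) == pytest.approx(fit.L / 2, rel=1e-6)
        assert predict_recall(fit, 1e6) == pytest.approx(fit.L, rel=1e-9)

    def test_predict_closed_form_and_clipping(self):
        x, y = self._noise_free()
        fit = fit_sigmoid(x, y, n_boot=0)
        for xv in (0.0, 2.5, 5.0, 17.0):
            assert predict_recall(fit, xv) == pytest.approx(
                fit.L / (1 + math.exp(-fit.k * (xv - fit.x0))))
        assert 0.0 <= predict_recall(fit, -50.0) <= 1.0

    def test_prediction_monotone_with_sign_of_k(self):
        x, y = self._noise_free()
        fit = fit_sigmoid(x, y, n_boot=0)
        grid = np.linspace(0, 30, 100)
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) * np.sign(fit.k) >= 0)

    def test_bootstrap_ci_brackets_estimates(self):
        rng = np.random.default_rng(3)
        x = np.repeat(np.arange(1.0, 21.0), 10)
        y = sigmoid(x, **self.TRUE) + rng.normal(0, 0.05, size=len(x))
        fit = fit_sigmoid(x, y, seed=1, n_boot=60)
        assert set(fit.param_ci) == {"L", "k", "x0"}
        for name, value in zip(("L", "k", "x0"), fit.params):
            lo, hi = fit.param_ci[name]
            assert lo <= value <= hi
        est, lo, hi = fit.predict(5.0, ci=True)
        assert lo <= est <= hi

    def test_summary_mentions_parameters(self):
        x, y = self._noise_free()
        s = fit_sigmoid(x, y, n_boot=0).summary()
        assert "R-squared" in s and "x0" in s
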