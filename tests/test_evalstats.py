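import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from lexasd import synth
from lexasd.annotator import AnnotatorConfig
from lexasd.classify import ClassifierConfig
from lexasd.evalstats import (
    FoldRecord,
    auc_score,
    build_report,
    chi2_2x2,
    confusion_metrics,
    loocv_run,
    mcnemar_test,
    wald_ci,
)


def _records(pairs):
    return [
        FoldRecord(doc_id=f"d{i}", y_true=y, p_manual=p, p_auto=p, fold_seed=i)
        for i, (y, p) in enumerate(pairs)
    ]


class TestConfusionMetrics:
    def test_known_counts(self):
        # tp=3 fp=1 fn=2 tn=4
        pairs = (
            [("AS", 0.9)] * 3 + [("nonAS", 0.9)] + [("AS", 0.1)] * 2
            + [("nonAS", 0.1)] * 4
        )
        m = confusion_metrics(_records(pairs))
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 1, 2, 4)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)

    def test_perfect_predictions(self):
        pairs = [("AS", 0.99)] * 3 + [("nonAS", 0.01)] * 3
        m = confusion_metrics(_records(pairs))
        assert m.accuracy == m.precision == m.sensitivity == m.specificity == 1.0
        assert m.auc == 1.0

    def test_tied_scores_give_auc_half(self):
        m = confusion_metrics(_records([("AS", 0.6), ("nonAS", 0.6)]))
        assert m.auc == pytest.approx(0.5)

    def test_single_class_auc_missing(self):
        m = confusion_metrics(_records([("AS", 0.7), ("AS", 0.2)]))
        assert m.auc is None
        assert m.accuracy == pytest.approx(0.5)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 50))
    def test_auc_equals_all_pairs_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        wins = total = 0
        for i in np.flatnonzero(y):
            for j in np.flatnonzero(~y):
                total += 1
                if scores[i] > scores[j]:
                    wins += 1
                elif scores[i] == scores[j]:
                    wins += 0.5
        assert auc_score(y, scores) == pytest.approx(wins / total, abs=1e-12)


class TestWaldCi:
    def test_accuracy_078_n135(self):
        assert wald_ci(0.78, 135).rounded(2) == (0.71, 0.85)

    def test_accuracy_080_n135(self):
        assert wald_ci(0.80, 135).rounded(2) == (0.73, 0.87)

    def test_degenerate_proportion_clips(self):
        assert wald_ci(0.0, 50).rounded(2) == (0.0, 0.0)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)

    @given(st.floats(0.05, 0.95), st.integers(5, 500))
    def test_width_scales_inverse_sqrt_n(self, p, n):
        w1 = wald_ci(p, n)
        w4 = wald_ci(p, 4 * n)
        if w1.lower > 0 and w1.upper < 1:  # unclipped regime only
            width1 = w1.upper - w1.lower
            width4 = w4.upper - w4.lower
            assert width4 == pytest.approx(width1 / 2, rel=1e-9)


class TestMcNemar:
    def _vectors(self, b, c, both_right=5, both_wrong=2):
        v1 = [True] * both_right + [False] * both_wrong + [True] * b + [False] * c
        v2 = [True] * both_right + [False] * both_wrong + [False] * b + [True] * c
        return np.array(v1), np.array(v2)

    def test_statistic_550_gives_p_002(self):
        # a 1-df chi-square of 5.50 corresponds to p = 0.02 at 2 dp
        from lexasd.evalstats import chi2_pvalue_from_statistic

        assert round(chi2_pvalue_from_statistic(5.50), 2) == 0.02

    def test_equal_discordance_gives_null(self):
        v1, v2 = self._vectors(4, 4)
        for method in ("chi2", "chi2_corrected"):
            res = mcnemar_test(v1, v2, method=method)
            assert res.statistic == 0.0
            assert res.p_value == pytest.approx(1.0)

    def test_corrected_statistic_b10_c2(self):
        v1, v2 = self._vectors(10, 2)
        res = mcnemar_test(v1, v2, method="chi2_corrected")
        assert res.statistic == pytest.approx(49 / 12, abs=1e-12)
        # independent upper-tail oracle: P(chi2_1 > x) = erfc(sqrt(x/2))
        assert res.p_value == pytest.approx(math.erfc(math.sqrt(49 / 24)), abs=1e-12)
        assert res.p_value == pytest.approx(0.043, abs=5e-4)

    def test_no_discordance_convention(self):
        v = np.array([True, False, True])
        res = mcnemar_test(v, v, method="chi2")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_matches_enumeration_up_to_12(self):
        """Two-sided exact binomial p equals brute-force tail enumeration for
        every discordant split with b + c <= 12."""
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                v1, v2 = self._vectors(b, c)
                res = mcnemar_test(v1, v2, method="exact")
                pmf = [math.comb(n, k) * 0.5 ** n for k in range(n + 1)]
                expected = sum(p for p in pmf if p <= pmf[b] * (1 + 1e-12))
                assert res.p_value == pytest.approx(expected, abs=1e-12), (b, c)

    def test_agrees_with_statsmodels(self):
        v1, v2 = self._vectors(9, 3)
        table = [[5 + 0, 9], [3, 2]]  # both-right/b/c/both-wrong layout
        res_exact = mcnemar_test(v1, v2, method="exact")
        sm = sm_mcnemar(np.array([[5, 9], [3, 2]]), exact=True)
        assert res_exact.p_value == pytest.approx(sm.pvalue, abs=1e-12)
        res_chi2 = mcnemar_test(v1, v2, method="chi2_corrected")
        sm2 = sm_mcnemar(np.array([[5, 9], [3, 2]]), exact=False, correction=True)
        assert res_chi2.statistic == pytest.approx(sm2.statistic, abs=1e-12)
        assert res_chi2.p_value == pytest.approx(sm2.pvalue, abs=1e-12)

    def test_corrected_and_plain_agree_asymptotically(self):
        v1, v2 = self._vectors(550, 450)
        p1 = mcnemar_test(v1, v2, method="chi2").p_value
        p2 = mcnemar_test(v1, v2, method="chi2_corrected").p_value
        assert abs(p1 - p2) < 0.01

    def test_auto_method_switches_on_discordance(self):
        v1, v2 = self._vectors(5, 3)
        assert mcnemar_test(v1, v2).method == "exact"
        v1, v2 = self._vectors(20, 10)
        assert mcnemar_test(v1, v2).method == "chi2_corrected"


class TestChi2_2x2:
    def test_sex_table_with_yates(self):
        statistic, p = chi2_2x2([[24, 40], [39, 32]], yates=True)
        assert round(p, 2) == 0.06

    def test_sex_table_without_yates_brute_force(self):
        table = np.array([[24, 40], [39, 32]], dtype=float)
        statistic, _ = chi2_2x2(table, yates=False)
        expected = (
            table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
        )
        brute = ((table - expected) ** 2 / expected).sum()
        assert statistic == pytest.approx(brute, abs=1e-9)
        assert statistic == pytest.approx(4.11, abs=0.01)

    def test_independent_rows_give_zero(self):
        statistic, p = chi2_2x2([[10, 20], [30, 60]], yates=False)
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2([[0, 0], [3, 4]])


class TestLoocv:
    CLF = ClassifierConfig(variant="tag_linear", seed=0)

    def test_one_record_per_document(self, tiny_tagged_dataset):
        records = loocv_run(tiny_tagged_dataset, self.CLF, base_seed=3)
        assert len(records) == len(tiny_tagged_dataset)
        assert [r.doc_id for r in records] == [d.id for d in tiny_tagged_dataset]
        assert [r.fold_seed for r in records] == [3 + i for i in range(8)]

    def test_heldout_document_never_in_training_set(self, tiny_tagged_dataset):
        seen = []
        loocv_run(tiny_tagged_dataset, self.CLF,
                  fold_callback=lambda n, tr, held: seen.append((held, tr)))
        assert len(seen) == len(tiny_tagged_dataset)
        for held, train_ids in seen:
            assert held not in train_ids
            assert len(train_ids) == len(tiny_tagged_dataset) - 1

    def test_oracle_annotator_makes_paths_coincide(self, tiny_tagged_dataset):
        records = loocv_run(tiny_tagged_dataset, self.CLF, annotator_config="oracle")
        for r in records:
            assert r.p_manual == r.p_auto

    def test_nested_run_with_trained_annotator(self, tiny_tagged_dataset):
        ann = AnnotatorConfig(embedding_dim=8, hidden_dim=8, epochs=3,
                              batch_size=4, seed=0)
        records = loocv_run(tiny_tagged_dataset, self.CLF, annotator_config=ann)
        assert len(records) == len(tiny_tagged_dataset)
        assert all(0.0 <= r.p_auto <= 1.0 for r in records)

    def test_determinism_across_runs(self, tiny_tagged_dataset):
        r1 = loocv_run(tiny_tagged_dataset, self.CLF, base_seed=5)
        r2 = loocv_run(tiny_tagged_dataset, self.CLF, base_seed=5)
        assert [(a.p_manual, a.p_auto) for a in r1] == [
            (b.p_manual, b.p_auto) for b in r2
        ]

    def test_too_few_documents_rejected(self, tiny_tagged_dataset):
        with pytest.raises(ValueError, match="at least 3"):
            loocv_run(tiny_tagged_dataset.subset([0, 1]), self.CLF)

    def test_unlabeled_document_rejected(self, schema):
        docs = synth.generate_corpus(
            synth.null_config(schema, n_as=2, n_non_as=2, length_mean=10.0, seed=0),
            schema,
        )
        docs.documents[0].label = "unknown"
        with pytest.raises(ValueError, match="unlabeled"):
            loocv_run(docs, self.CLF)


class TestReport:
    def _fake_records(self, flip=0):
        pairs = [("AS", 0.9)] * 5 + [("nonAS", 0.1)] * 5
        recs = _records(pairs)
        for r in recs[:flip]:
            r.p_manual = 1.0 - r.p_manual
            r.p_auto = r.p_manual
        return recs

    def test_rows_and_mcnemar_block(self):
        fold_records = {
            ("interview", "tag_linear"): self._fake_records(flip=2),
            ("interview", "tag_dnn"): self._fake_records(),
        }
        metrics, tests = build_report(fold_records)
        # two variants x (manual, auto) rows
        assert len(metrics) == 4
        assert set(metrics["variant"]) == {"tag_linear", "tag_dnn"}
        # one configured pair present x two annotation sources
        assert len(tests) == 2
        assert (tests["model_1"] == "tag_linear").all()

    def test_proportions_rounded_to_2dp(self):
        metrics, _ = build_report(
            {("interview", "tag_linear"): self._fake_records(flip=1)}
        )
        for col in ("accuracy", "precision", "sensitivity", "specificity"):
            vals = metrics[col].dropna()
            assert all(v == round(v, 2) for v in vals)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no fold records"):
            build_report({})

    def test_text_dnn_has_single_annotation_row(self):
        metrics, _ = build_report(
            {("interview", "text_dnn"): self._fake_records()}
        )
        assert list(metrics["annotation"]) == ["manual"]
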