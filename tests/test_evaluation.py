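"""Metrics: closed forms, independent oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tcrpred as tp
from tcrpred.evaluation import RankCalibration


class TestAUC:
    def test_perfect_separation(self):
        assert tp.auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_hand_counted_pairs(self):
        # concordant pairs: (0.9,0.8), (0.9,0.1), (0.4,0.1) -> 3 of 4
        assert tp.auc([0.9, 0.4], [0.8, 0.1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert tp.auc([0.5] * 3, [0.5] * 7) == pytest.approx(0.5)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        for _ in range(10):
            pos = rng.normal(0.6, 0.3, size=25)
            neg = rng.normal(0.4, 0.3, size=40)
            y = np.r_[np.ones(25), np.zeros(40)]
            s = np.r_[pos, neg]
            assert tp.auc(pos, neg) == pytest.approx(
                sk.roc_auc_score(y, s), abs=1e-12)

    @given(st.lists(st.integers(0, 10 ** 6), min_size=2, max_size=30,
                    unique=True))
    def test_complement_symmetry_for_tie_free_scores(self, values):
        scores = np.array(values, dtype=float)
        half = len(scores) // 2
        pos, neg = scores[:half], scores[half:]
        if pos.size and neg.size:
            assert tp.auc(pos, neg) + tp.auc(neg, pos) == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            tp.auc([], [0.1])


class TestPartialAUC:
    def test_perfect_separation_is_one(self):
        assert tp.auc01([0.9, 0.8, 0.7], [0.2, 0.1]) == pytest.approx(1.0)

    def test_all_ties_diagonal_roc(self):
        # diagonal ROC: area below FPR=0.1 is 0.005, normalized 0.05
        assert tp.auc01([0.5] * 5, [0.5] * 5) == pytest.approx(0.05)

    def test_matches_independent_integration_oracle(self):
        # fine-grid integration of the empirical (step) ROC computed by
        # sklearn; agreement up to the grid-resolution quadrature error
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        grid = np.linspace(0.0, 0.1, 200001)
        for _ in range(30):
            pos = rng.normal(0.6, 0.25, size=rng.integers(5, 40))
            neg = rng.normal(0.4, 0.25, size=rng.integers(5, 40))
            fpr, tpr, _ = sk.roc_curve(
                np.r_[np.ones(pos.size), np.zeros(neg.size)],
                np.r_[pos, neg], drop_intermediate=False)
            step = tpr[np.searchsorted(fpr, grid, side="right") - 1]
            oracle = np.trapezoid(step, grid) / 0.1
            assert tp.auc01(pos, neg) == pytest.approx(oracle, abs=5e-6)

    def test_never_exceeds_full_auc_under_perfection(self):
        pos = [0.9, 0.85, 0.8]
        neg = [0.4, 0.3]
        assert tp.auc01(pos, neg) == tp.auc(pos, neg) == 1.0


class TestPPV:
    def test_perfect_ranking(self):
        assert tp.ppv([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_top_n(self):
        scores = [5, 4, 3, 2, 1]
        labels = [1, 1, 0, 1, 0]      # top 3 of n=3 positives: 1,1,0
        assert tp.ppv(scores, labels) == pytest.approx(2 / 3)

    def test_tie_break_is_stable_input_order(self):
        labels = [1, 1, 0, 0, 0, 0, 0, 0]
        assert tp.ppv([0.5] * 8, labels) == 1.0  # positives listed first

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            tp.ppv([0.5], [0])


class TestBootstrap:
    def test_self_comparison_is_exactly_half(self):
        rng = np.random.default_rng(3)
        preds = rng.random(40)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        assert tp.bootstrap_auc_test(preds, preds, labels, n_boot=200,
                                     seed=1) == pytest.approx(0.5)

    def test_perfect_vs_antiperfect(self):
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        perfect = np.r_[np.full(15, 0.9), np.full(15, 0.1)]
        anti = 1.0 - perfect
        p = tp.bootstrap_auc_test(perfect, anti, labels, n_boot=1000, seed=2)
        assert p <= 0.01  # the better first model is never smaller

    def test_reversal_p_values_sum_to_one(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        a, b = rng.random(40), rng.random(40)
        p_ab = tp.bootstrap_auc_test(a, b, labels, n_boot=300, seed=7)
        p_ba = tp.bootstrap_auc_test(b, a, labels, n_boot=300, seed=7)
        assert p_ab + p_ba == pytest.approx(1.0)

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        a, b = rng.random(20), rng.random(20)
        assert tp.bootstrap_auc_test(a, b, labels, seed=3, n_boot=100) == \
            tp.bootstrap_auc_test(a, b, labels, seed=3, n_boot=100)


class TestPercentileRank:
    def _calib(self, scores):
        cal = RankCalibration()
        cal.add("GILGFVFTL", scores)
        return cal

    def test_extremes(self):
        cal = self._calib(np.linspace(0, 0.9, 100))
        assert tp.percentile_rank(0.95, cal, "GILGFVFTL") == 0.0
        assert tp.percentile_rank(-0.1, cal, "GILGFVFTL") == 1.0

    def test_median_of_101_distinct(self):
        cal = self._calib(np.arange(101) / 101.0)
        median = 50 / 101.0
        assert tp.percentile_rank(median, cal, "GILGFVFTL") == \
            pytest.approx(50 / 101)

    def test_non_increasing_in_score(self):
        rng = np.random.default_rng(6)
        cal = self._calib(rng.random(57))
        xs = np.sort(rng.random(40))
        ranks = [tp.percentile_rank(float(x), cal, "GILGFVFTL") for x in xs]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_missing_peptide_rejected(self):
        with pytest.raises(ValueError):
            tp.percentile_rank(0.5, self._calib([0.1]), "RAKFKQLL")


class TestPeptideRanking:
    def _positives(self, peptides, n_each=50):
        recs = []
        for pi, pep in enumerate(peptides):
            for i in range(n_each):
                body = f"{pi}{i:03d}"
                loops = "".join("ACDEFGHIKLMNPQRSTVWY"[int(c)] for c in body)
                recs.append(tp.TCRRecord(
                    cdr3a="CAV" + loops + "LF", cdr3b="CAS" + loops + "QF",
                    peptide=pep))
        return tp.Repertoire(recs)

    def test_oracle_models_give_all_rank_one(self):
        peptides = ["GILGFVFTL", "RAKFKQLL", "NLVPMVATV"]
        positives = self._positives(peptides, n_each=20)

        def model_for(pep):
            return lambda rep: np.array(
                [0.9 if r.peptide == pep else 0.1 for r in rep])

        table = tp.peptide_rank_analysis(
            {p: model_for(p) for p in peptides}, positives)
        assert (table["rank"] == 1).all()
        assert (table["category"] == "top_TP").all()
        assert np.allclose(table["other_score"], 0.1)

    def test_uniform_random_scores_give_uniform_ranks(self):
        peptides = ["GILGFVFTL", "RAKFKQLL", "ELAGIGILTV",
                    "IVTDFSVIK", "GLCTLVAML", "NLVPMVATV"]
        positives = self._positives(peptides, n_each=1000 // len(peptides))
        rng = np.random.default_rng(8)

        def noise(pep):
            return lambda rep: rng.random(len(rep))

        table = tp.peptide_rank_analysis(
            {p: noise(p) for p in peptides}, positives)
        assert set(table["rank"]) <= set(range(1, 7))
        freqs = table["rank"].value_counts(normalize=True)
        for r in range(1, 7):
            assert freqs.get(r, 0.0) == pytest.approx(1 / 6, abs=0.04)

    def test_fn_category_when_wrong_peptide_wins(self):
        peptides = ["GILGFVFTL", "RAKFKQLL"]
        positives = self._positives(peptides, n_each=5)
        models = {
            "GILGFVFTL": lambda rep: np.full(len(rep), 0.2),
            "RAKFKQLL": lambda rep: np.full(len(rep), 0.8),
        }
        table = tp.peptide_rank_analysis(models, positives)
        gil = table[table["true_peptide"] == "GILGFVFTL"]
        assert (gil["category"] == "FN").all()
        assert (gil["other_category"] == "top_FP").all()
        assert (gil["rank"] == 2).all()


class TestDistanceCurve:
    def test_threshold_one_retains_everything(self, prepared):
        corpus = prepared["reduced"]
        pep = corpus.peptides()[0]
        pos = tp.Repertoire([r for r in corpus if r.peptide == pep])
        train = tp.Repertoire([r for r in pos if r.partition != 5])
        held = tp.Repertoire(
            [r for r in pos if r.partition == 5][:15]
            + [r.copy(peptide=pep, label=0, provenance="true_negative")
               for r in prepared["background"][3000:3030]])
        scores = np.linspace(1, 0, len(held))
        curve = tp.distance_performance_curve(
            train, held, scores, thresholds=[0.5, 1.0])
        full_auc = tp.auc(scores[:15], scores[15:])
        row = curve[curve["threshold"] == 1.0].iloc[0]
        assert row["n_retained_pos"] == 15
        assert row["auc"] == pytest.approx(full_auc)
        assert (curve.sort_values("threshold")["n_retained_pos"]
                .is_monotonic_increasing)

    def test_manual_filtering_on_constructed_similarities(self, small_records):
        train = tp.Repertoire(list(small_records)[:6])
        rng = np.random.default_rng(9)
        # eval: 3 exact copies (similarity 1.0) + 3 distant records
        copies = [r.copy() for r in train[:3]]
        distant = list(tp.perturb_positives(train[3:6], 8, rng))
        held = tp.Repertoire(
            copies + distant
            + [r.copy(peptide=r0.peptide, label=0, provenance="true_negative")
               for r, r0 in zip(small_records[6:12], copies * 2)])
        nn, _ = tp.nearest_neighbor_similarity(held, train)
        scores = rng.random(len(held))
        thr = 0.99
        curve = tp.distance_performance_curve(train, held, scores,
                                              thresholds=[thr, 1.0])
        expected_pos = int(((nn[:6] <= thr)).sum())
        row = curve[curve["threshold"] == thr].iloc[0]
        assert row["n_retained_pos"] == expected_pos == 3

    def test_undefined_points_are_nan_not_errors(self, small_records):
        train = tp.Repertoire(list(small_records)[:6])
        held = tp.Repertoire([r.copy() for r in train[:3]]
                             + [r.copy(label=0, provenance="true_negative")
                                for r in small_records[6:9]])
        curve = tp.distance_performance_curve(
            train, held, np.ones(6), thresholds=[0.2])
        assert np.isnan(curve["auc"].iloc[0])


class TestReport:
    def test_mean_and_weighted_mean_arithmetic(self):
        def scores_with_auc(auc_value, n_pos):
            # positives above fraction `auc_value` of negatives
            neg = np.linspace(0, 1, 100)
            pos = np.full(n_pos, np.quantile(neg, auc_value) + 1e-9)
            return (np.r_[pos, neg],
                    np.r_[np.ones(n_pos), np.zeros(100)].astype(int))

        report = tp.compute_report({
            "GILGFVFTL": {"true_negative": scores_with_auc(0.8, 10)},
            "RAKFKQLL": {"true_negative": scores_with_auc(0.6, 30)},
        })
        assert report.mean_auc["true_negative"] == pytest.approx(0.7)
        assert report.weighted_mean_auc["true_negative"] == pytest.approx(0.65)

    def test_single_peptide_mean_equals_weighted(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        rep = tp.compute_report(
            {"GILGFVFTL": {"true_negative": (scores, labels)}})
        assert rep.mean_auc == rep.weighted_mean_auc

    def test_json_roundtrip(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        rep = tp.compute_report(
            {"GILGFVFTL": {"true_negative": (scores, labels),
                           "swapped_negative": (scores, labels)}})
        back = tp.EvalReport.from_json(rep.to_json())
        assert back.per_peptide == rep.per_peptide
        assert back.weighted_mean_auc == rep.weighted_mean_auc
        assert {"auc", "auc01", "ppv"} <= set(back.to_frame().columns)
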