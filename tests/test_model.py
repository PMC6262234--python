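"""Classifier training, evaluation and SHAP interrogation."""

import numpy as np
import pandas as pd
import pytest

import targetox as tx

from conftest import FAST_HP


def pair_counting_auc(scores, labels):
    """Exhaustive positive-negative pair concordance; ties count 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def trained(small_pipeline):
    sp = small_pipeline
    model = tx.train(sp["X"], sp["y"], hyper_params=FAST_HP, seed=0)
    return model, sp["X"], sp["y"]


class TestStratifiedSplit:
    def test_exact_division(self):
        y = [1] * 100 + [0] * 100
        split = tx.stratified_split(y, seed=0)
        assert len(split.train_idx) == 160 and len(split.test_idx) == 40
        y = np.asarray(y)
        assert y[split.test_idx].sum() == 20

    def test_small_classes(self):
        y = [1] * 5 + [0] * 5
        split = tx.stratified_split(y, seed=0)
        y = np.asarray(y)
        assert y[split.test_idx].sum() == 1 and len(split.test_idx) == 2

    def test_deterministic_per_seed(self):
        y = [1] * 30 + [0] * 20
        a = tx.stratified_split(y, seed=5)
        b = tx.stratified_split(y, seed=5)
        c = tx.stratified_split(y, seed=6)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            tx.stratified_split([1] * 10, seed=0)


class TestTrain:
    def test_separable_toy_set_fits_perfectly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "f1": np.r_[rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)],
            "f2": rng.normal(size=60),
        })
        y = np.r_[np.zeros(30), np.ones(30)]
        model = tx.train(X, y, hyper_params=FAST_HP, seed=0)
        auc = pair_counting_auc(model.predict(X), y)
        assert auc == 1.0

    def test_shuffled_labels_near_chance(self, small_pipeline):
        sp = small_pipeline
        rng = np.random.default_rng(123)
        y_perm = pd.Series(
            rng.permutation(sp["y"].to_numpy()), index=sp["y"].index
        )
        report = tx.cross_validate(sp["X"], y_perm, k=5, seed=0,
                                   hyper_params=FAST_HP)
        assert 0.35 <= report.auc <= 0.65

    def test_reproducible_predictions_per_seed(self, small_pipeline):
        sp = small_pipeline
        a = tx.train(sp["X"], sp["y"], hyper_params=FAST_HP, seed=3)
        b = tx.train(sp["X"], sp["y"], hyper_params=FAST_HP, seed=3)
        assert np.array_equal(a.predict(sp["X"]), b.predict(sp["X"]))

    def test_all_missing_column_leaves_predictions_unchanged(self, small_pipeline):
        sp = small_pipeline
        X = sp["X"].copy()
        X["phantom"] = np.nan
        with_col = tx.train(X, sp["y"], hyper_params=FAST_HP, seed=0)
        without = tx.train(sp["X"], sp["y"], hyper_params=FAST_HP, seed=0)
        assert np.allclose(
            with_col.predict(X), without.predict(sp["X"]), atol=1e-9
        )

    def test_schema_mismatch_rejected(self, trained):
        model, X, _ = trained
        with pytest.raises(ValueError, match="schema"):
            model.predict(X[list(X.columns[:-1])])

    def test_single_class_rejected(self, small_pipeline):
        sp = small_pipeline
        with pytest.raises(ValueError, match="class"):
            tx.train(sp["X"], np.ones(len(sp["X"])), hyper_params=FAST_HP)

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, X, _ = trained
        model.save(tmp_path / "model.json")
        back = tx.ToxicityModel.load(tmp_path / "model.json")
        assert back.feature_names == model.feature_names
        assert np.allclose(back.predict(X), model.predict(X))


class TestEvaluation:
    def test_printed_example_auc(self):
        report = tx.evaluate_scores([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert report.auc == pytest.approx(0.75)

    def test_perfect_scores(self):
        report = tx.evaluate_scores([2.0, 1.5, -1.0, -2.0], [1, 1, 0, 0])
        assert report.auc == 1.0
        assert report.sensitivity == 100.0 and report.specificity == 100.0

    def test_constant_scores_auc_half(self):
        report = tx.evaluate_scores([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert report.auc == pytest.approx(0.5)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for n in (20, 100, 200):
            # duplicate some scores to exercise the tie rule
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            report = tx.evaluate_scores(scores, labels)
            assert report.auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_cross_validate_recovers_planted_signal(self, small_pipeline):
        sp = small_pipeline
        report = tx.cross_validate(sp["X"], sp["y"], k=5, seed=0,
                                   hyper_params=FAST_HP)
        assert report.auc >= 0.8
        assert len(report.scores) == len(sp["X"])
        assert set(report.folds) == set(range(5))

    def test_invalid_fold_count_rejected(self, small_pipeline):
        sp = small_pipeline
        with pytest.raises(ValueError, match="k must be"):
            tx.cross_validate(sp["X"], sp["y"], k=10_000)


class TestLeaveOneOut:
    def test_three_drugs_three_scores(self, small_pipeline):
        sp = small_pipeline
        X, y = sp["X"], sp["y"]
        # take 2 toxic + 2 safe for a minimal but two-class LOO
        tox = list(np.flatnonzero(y.to_numpy() == 1)[:2])
        safe = list(np.flatnonzero(y.to_numpy() == 0)[:2])
        sub = tox + safe
        scores = tx.loo_scores(X.iloc[sub], y.iloc[sub], seed=0,
                               hyper_params=FAST_HP)
        assert len(scores) == 4
        assert list(scores.index) == list(X.index[sub])

    def test_duplicated_rows_score_nearly_identically(self, small_pipeline):
        sp = small_pipeline
        X, y = sp["X"].iloc[:40], sp["y"].iloc[:40]
        X2 = pd.concat([X, X.iloc[[0]].set_axis(["dup"])])
        y2 = pd.concat([y, pd.Series([y.iloc[0]], index=["dup"])])
        scores = tx.loo_scores(X2, y2, seed=0, hyper_params=FAST_HP)
        assert abs(scores.iloc[0] - scores.loc["dup"]) < 0.05

    def test_hotspot_binders_score_higher(self):
        # drugs binding hot-spot proteins rank above safe ones in LOO
        from scipy.stats import mannwhitneyu

        hits = 0
        for seed in range(5):
            bundle = tx.generate(tx.GeneratorConfig(
                n_proteins=180, n_communities=3, n_binding_proteins=36,
                n_hotspot_communities=1, n_drugs=50, p_core=0.8,
                label_noise=0.0, seed=600 + seed))
            net = tx.main_component(tx.load_network(bundle.edges, 200))
            dm = tx.dsd_matrix(net)
            corpus = tx.propagate(bundle.dag, bundle.annotations)
            binding = sorted({p for d in bundle.drugs for p in d.targets
                              if p in dm.index})
            enr = tx.neighborhood_enrichment(dm, binding, dm.quantile(0.01))
            refs = tx.select_references(enr, dm, 1e-3, 3)
            X = tx.featurize(bundle.drugs, dm, refs, corpus, bundle.dag)
            y = tx.labels_vector(bundle.drugs)
            scores = tx.loo_scores(X, y, seed=seed, hyper_params=FAST_HP)
            tox = scores[y.to_numpy() == 1]
            safe = scores[y.to_numpy() == 0]
            p = mannwhitneyu(tox, safe, alternative="greater").pvalue
            hits += p < 0.05
        assert hits >= 4


class TestShap:
    def test_additivity_reconstructs_raw_scores(self, trained):
        model, X, _ = trained
        attr = model.shap_values(X)
        reconstructed = attr.sum(axis=1).to_numpy()
        assert np.allclose(reconstructed, model.predict(X), atol=1e-6)

    def test_constant_feature_gets_zero_attribution(self, small_pipeline):
        sp = small_pipeline
        X = sp["X"].copy()
        X["constant"] = 1.0
        model = tx.train(X, sp["y"], hyper_params=FAST_HP, seed=0)
        attr = model.shap_values(X)
        assert np.allclose(attr["constant"], 0.0)

    def test_network_features_dominate_attribution(self, trained):
        # only network position carries label signal in the generator
        model, X, y = trained
        tox = list(np.flatnonzero(y.to_numpy() == 1))
        safe = list(np.flatnonzero(y.to_numpy() == 0))
        report = tx.shap_report(model, X, tox, safe)
        net_cols = [c for c in X.columns if c.startswith("dsd_ref_")]
        cov_cols = ["oral", "parenteral", "topical", "ppb_lower", "ppb_upper"]
        alloc = report.allocation["group_a"]
        assert alloc[net_cols].sum() > alloc[cov_cols].sum()

    def test_groups_must_be_disjoint(self, trained):
        model, X, _ = trained
        with pytest.raises(ValueError, match="disjoint"):
            tx.shap_report(model, X, [0, 1], [1, 2])

    def test_unknown_indices_rejected(self, trained):
        model, X, _ = trained
        with pytest.raises(IndexError):
            tx.shap_report(model, X, [0], [10_000_000])
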