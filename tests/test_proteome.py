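"""Druggable-proteome scoring, top-decile clustering and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import targetox as tx

from conftest import FAST_HP


@pytest.fixture(scope="module")
def proteome_setup(small_pipeline):
    sp = small_pipeline
    model = tx.train(sp["X"], sp["y"], hyper_params=FAST_HP, seed=0)
    druggable = list(sp["dm"].ids)  # whole component as the druggable list
    return sp, model, druggable


class TestSimulatedDrugs:
    def test_reference_protein_has_zero_network_feature(self, proteome_setup):
        sp, model, _ = proteome_setup
        ref0 = sp["refs"].refs[0]
        X = tx.simulate_single_target_drugs(
            [ref0], sp["dm"], sp["refs"], sp["corpus"], sp["bundle"].dag
        )
        assert X.loc[ref0, f"dsd_ref_{ref0}"] == 0.0

    def test_parenteral_true_everything_else_missing(self, proteome_setup):
        sp, _, druggable = proteome_setup
        X = tx.simulate_single_target_drugs(
            druggable[:5], sp["dm"], sp["refs"], sp["corpus"], sp["bundle"].dag
        )
        assert (X["parenteral"] == 1.0).all()
        assert X[["oral", "topical", "ppb_lower", "ppb_upper"]].isna().all().all()

    def test_unannotated_protein_gets_fi_zero_with_warning(self, small_pipeline):
        sp = small_pipeline
        empty_corpus = tx.propagate(sp["bundle"].dag, [])
        with pytest.warns(UserWarning, match="no annotation"):
            X = tx.simulate_single_target_drugs(
                [sp["dm"].ids[0]], sp["dm"], sp["refs"], empty_corpus,
                sp["bundle"].dag,
            )
        assert X["functional_impact"].iloc[0] == 0.0

    def test_simulated_instance_equals_real_single_target_drug(self, proteome_setup):
        # a simulated instance is indistinguishable from featurizing an
        # actual single-target parenteral drug on the same protein
        sp, model, _ = proteome_setup
        protein = sp["bundle"].binding_proteins[0]
        sim = tx.simulate_single_target_drugs(
            [protein], sp["dm"], sp["refs"], sp["corpus"], sp["bundle"].dag
        )
        real = tx.featurize(
            [tx.DrugRecord(drug_id="x", label=None, targets=(protein,),
                           parenteral=True)],
            sp["dm"], sp["refs"], sp["corpus"], sp["bundle"].dag,
        )
        assert np.array_equal(
            sim.to_numpy(), real.to_numpy(), equal_nan=True
        )
        assert model.predict(sim)[0] == model.predict(
            real.set_axis(sim.index)
        )[0]


class TestScoreProteome:
    def test_decile_boundary_and_flags(self, proteome_setup):
        sp, model, druggable = proteome_setup
        table = tx.score_proteome(
            model, druggable, sp["dm"], sp["refs"], sp["corpus"],
            sp["bundle"].dag,
        )
        n = len(table)
        assert table["top_decile"].sum() == math.ceil(0.1 * n)
        assert table["decile_rank"].between(1, 10).all()
        # scores are sorted descending, ties broken by id
        s = table["score"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()

    def test_tie_break_lexicographic(self, proteome_setup):
        sp, model, druggable = proteome_setup
        table = tx.score_proteome(
            model, druggable, sp["dm"], sp["refs"], sp["corpus"],
            sp["bundle"].dag,
        )
        dup = table[table.duplicated("score", keep=False)]
        for _, grp in dup.groupby("score"):
            assert list(grp["protein"]) == sorted(grp["protein"])


class TestClusterTopDecile:
    @staticmethod
    def _blob_table(rng, centers, n_per, label_sep=True):
        pts = np.vstack([
            rng.normal(loc=c, scale=0.25, size=(n_per, len(centers[0])))
            for c in centers
        ])
        names = [f"P{i:04d}" for i in range(len(pts))]
        truth = np.repeat(np.arange(len(centers)), n_per)
        return pts, names, truth

    def _dm_from_vectors(self, pts, names, n_refs):
        # embed the blob coordinates as distances to synthetic landmarks:
        # build a fake distance matrix whose first n_refs rows reproduce the
        # coordinates (distances are only read via (ref, protein) lookups)
        refs = [f"R{j}" for j in range(n_refs)]
        ids = sorted(refs + names)
        values = np.zeros((len(ids), len(ids)))
        dm = tx.DistanceMatrix(metric="dsd", ids=tuple(ids), values=values)
        for j, r in enumerate(refs):
            for i, p in enumerate(names):
                values[dm.index[r], dm.index[p]] = pts[i, j]
                values[dm.index[p], dm.index[r]] = pts[i, j]
        return dm, refs

    def test_two_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        pts, names, truth = self._blob_table(
            rng, centers=[(0.0, 0.0), (4.0, 4.0)], n_per=30
        )
        dm, refs = self._dm_from_vectors(pts, names, n_refs=2)
        table = pd.DataFrame({
            "protein": names, "score": 0.0, "top_decile": True,
        })
        labels = tx.cluster_top_decile(table, dm, refs, seed=0)
        assert labels.nunique() == 2
        # agreement up to label permutation
        agreement = max(
            (labels.to_numpy() == truth).mean(),
            (labels.to_numpy() == 1 - truth).mean(),
        )
        assert agreement >= 0.95

    def test_single_blob_one_component(self):
        rng = np.random.default_rng(1)
        pts, names, _ = self._blob_table(rng, centers=[(0.0, 0.0)], n_per=40)
        dm, refs = self._dm_from_vectors(pts, names, n_refs=2)
        table = pd.DataFrame({"protein": names, "score": 0.0, "top_decile": True})
        labels = tx.cluster_top_decile(table, dm, refs, seed=0)
        assert labels.nunique() == 1

    def test_fixed_component_count(self):
        rng = np.random.default_rng(2)
        pts, names, _ = self._blob_table(
            rng, centers=[(0, 0), (3, 0), (0, 3), (3, 3)], n_per=20
        )
        dm, refs = self._dm_from_vectors(pts, names, n_refs=2)
        table = pd.DataFrame({"protein": names, "score": 0.0, "top_decile": True})
        labels = tx.cluster_top_decile(table, dm, refs, n_clusters=8, seed=0)
        assert labels.nunique() == 8

    def test_too_few_proteins_rejected(self, proteome_setup):
        sp, _, _ = proteome_setup
        table = pd.DataFrame({
            "protein": list(sp["dm"].ids[:5]), "score": 0.0, "top_decile": True,
        })
        with pytest.raises(ValueError, match=">= 20"):
            tx.cluster_top_decile(table, sp["dm"], sp["refs"])


class TestClusterEnrichment:
    def _setup(self):
        dag = tx.OntologyDAG({"r": [], "t": ["r"], "u": ["r"]})
        background = [f"P{i}" for i in range(12)]
        # P0..P3 annotated to t, P4..P11 to u
        pairs = [(p, "t") for p in background[:4]] + [
            (p, "u") for p in background[4:]
        ]
        corpus = tx.propagate(dag, pairs)
        return dag, corpus, background

    def test_exact_term_cluster_has_minimal_hypergeometric_p(self):
        dag, corpus, background = self._setup()
        assignment = pd.Series(
            [0] * 4, index=pd.Index(background[:4], name="protein")
        )
        table = tx.cluster_enrichment(assignment, corpus, dag, background,
                                      namespace=None)
        row = table[table["term"] == "t"].iloc[0]
        # drawing exactly the 4 t-annotated proteins out of 12
        expected = 1 / math.comb(12, 4)
        assert row["p_value"] == pytest.approx(expected, abs=1e-12)
        assert row["p_value"] == table["p_value"].min()

    def test_universal_term_p_one(self):
        dag, corpus, background = self._setup()
        assignment = pd.Series(
            [0] * 4, index=pd.Index(background[:4], name="protein")
        )
        table = tx.cluster_enrichment(assignment, corpus, dag, background,
                                      namespace=None)
        row = table[table["term"] == "r"].iloc[0]  # root annotates everyone
        assert row["p_value"] == pytest.approx(1.0)

    def test_sparse_terms_skipped(self):
        dag, corpus, background = self._setup()
        assignment = pd.Series(
            [0, 0, 1], index=pd.Index(["P0", "P1", "P4"], name="protein")
        )
        table = tx.cluster_enrichment(assignment, corpus, dag, background,
                                      namespace=None)
        # cluster 1 has a single member: all its terms fall below 2 members
        assert not (table["cluster"] == 1).any()

    def test_background_must_cover_clusters(self):
        dag, corpus, background = self._setup()
        assignment = pd.Series([0], index=pd.Index(["ghost"], name="protein"))
        with pytest.raises(ValueError, match="background"):
            tx.cluster_enrichment(assignment, corpus, dag, background)


class TestBenjaminiHochberg:
    def test_hand_computed_toy_list(self):
        q = tx.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    def test_never_decreases_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = tx.bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # order of q follows order of p
        assert np.array_equal(np.argsort(np.argsort(p)), np.argsort(np.argsort(q))) or (
            np.all(np.diff(q[np.argsort(p)]) >= -1e-15)
        )
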