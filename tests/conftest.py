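import numpy as np
import pandas as pd
import pytest

import targetox as tx

# fast boosted-tree settings for small test matrices
FAST_HP = {"n_estimators": 60, "min_child_samples": 5}


def make_network(edges, min_score=0):
    """Network from (a, b) pairs or (a, b, score) triples."""
    rows = [e if len(e) == 3 else (*e, 999) for e in edges]
    return tx.load_network(rows, min_score=min_score)


def path_network(n, prefix="n"):
    names = [f"{prefix}{i}" for i in range(n)]
    return make_network(list(zip(names[:-1], names[1:]))), names


def random_connected_network(n, p, seed):
    """Erdős–Rényi graph resampled until its main component spans all nodes."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    for _ in range(200):
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return make_network(
                [(f"n{a:03d}", f"n{b:03d}") for a, b in g.edges]
            )
    raise RuntimeError("could not sample a connected graph")


@pytest.fixture(scope="session")
def toy_dag():
    """c is_a a is_a r; b is_a r."""
    return tx.OntologyDAG({"r": [], "a": ["r"], "b": ["r"], "c": ["a"]})


@pytest.fixture(scope="session")
def toy_corpus(toy_dag):
    """Hand-propagated corpus: |k|=9, k_c=1, k_a=2, k_b=2, k_r=4."""
    return tx.propagate(
        toy_dag, [("e1", "c"), ("e2", "a"), ("e3", "b"), ("e4", "b")]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic bundle for fast model-level tests."""
    # denser cores than the full-size default: a smaller graph needs a
    # stronger planted signal at the same core-pair quantile
    return tx.generate(
        tx.GeneratorConfig(
            n_proteins=240,
            n_communities=4,
            n_binding_proteins=40,
            n_hotspot_communities=2,
            n_drugs=80,
            p_core=0.8,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    """Distances, corpus, references and features for the small bundle."""
    bundle = small_bundle
    net = tx.main_component(tx.load_network(bundle.edges, 200))
    dm = tx.dsd_matrix(net)
    corpus = tx.propagate(bundle.dag, bundle.annotations)
    binding = sorted({p for d in bundle.drugs for p in d.targets if p in dm.index})
    enr = tx.neighborhood_enrichment(dm, binding, dm.quantile(0.01))
    refs = tx.select_references(enr, dm, p_cutoff=1e-3, n_clusters=8)
    X = tx.featurize(bundle.drugs, dm, refs, corpus, bundle.dag)
    y = tx.labels_vector(bundle.drugs)
    return {
        "bundle": bundle,
        "net": net,
        "dm": dm,
        "corpus": corpus,
        "refs": refs,
        "X": X,
        "y": y,
    }
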