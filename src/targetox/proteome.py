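"""Druggable-proteome risk annotation.

Every protein in a supplied druggable list is turned into a simulated
single-target parenteral drug (real network distances to the reference
points, its own functional-impact score, all other covariates missing) and
scored by a trained toxicity model.  The top decile of proteins by score is
clustered in reference-distance space with a Gaussian mixture model
(component count by BIC unless fixed), and each cluster is profiled by
one-sided Fisher/hypergeometric enrichment of biological-process terms with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .features import feature_schema
from .graph import DistanceMatrix
from .model import ToxicityModel
from .ontology import AnnotationCorpus, OntologyDAG, functional_impact


def simulate_single_target_drugs(
    proteins: Sequence[str],
    dm: DistanceMatrix,
    refs,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
) -> pd.DataFrame:
    """Feature matrix of one simulated parenteral drug per mapped protein.

    Network features are the real distances from each reference point to the
    protein; FI is the protein's own score (0 with a warning when it has no
    annotation); parenteral is true and every other covariate is missing.
    """
    mapped = [p for p in proteins if p in dm.index]
    unmapped = sorted(set(proteins) - set(mapped))
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} protein(s) absent from the network",
            stacklevel=2,
        )
    if not mapped:
        raise ValueError("no protein maps to the network")
    columns = feature_schema(refs)
    ref_idx = np.array([dm.locate(r) for r in refs])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-protein empty-annotation warnings
        for p in mapped:
            net = dm.values[ref_idx, dm.locate(p)]
            fi = functional_impact(corpus, dag, [p])
            covs = [np.nan, 1.0, np.nan, np.nan, np.nan]  # parenteral only
            rows.append(list(net) + [fi] + covs)
    n_unannotated = sum(1 for p in mapped if p not in corpus)
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} protein(s) carry no annotation; their FI is 0",
            stacklevel=2,
        )
    return pd.DataFrame(rows, index=pd.Index(mapped, name="protein"), columns=columns)


def score_proteome(
    model: ToxicityModel,
    proteins: Sequence[str],
    dm: DistanceMatrix,
    refs,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
) -> pd.DataFrame:
    """Score table: protein, simulated-drug raw score, decile rank (1 = top)
    and a top-decile flag.

    The top decile contains exactly ``ceil(0.1 * n)`` proteins; ties at any
    boundary are broken by lexicographic protein id.
    """
    X = simulate_single_target_drugs(proteins, dm, refs, corpus, dag)
    scores = model.predict(X)
    table = pd.DataFrame({"protein": X.index, "score": scores})
    # sort by descending score, lexicographic id inside ties
    table = table.sort_values(["score", "protein"], ascending=[False, True])
    table = table.reset_index(drop=True)
    n = len(table)
    # rank 1..n -> decile 1..10
    table["decile_rank"] = (table.index * 10) // n + 1
    n_top = math.ceil(0.1 * n)
    table["top_decile"] = table.index < n_top
    return table


def cluster_top_decile(
    score_table: pd.DataFrame,
    dm: DistanceMatrix,
    refs,
    n_clusters: int | None = None,
    max_components: int = 10,
    seed: int = 0,
) -> pd.Series:
    """GMM/EM clustering of top-decile proteins in reference-distance space.

    Component count is chosen by BIC over 1..``max_components`` unless
    ``n_clusters`` fixes it.  Falls back to diagonal covariance with a
    warning when full covariance is degenerate.
    """
    top = score_table.loc[score_table["top_decile"], "protein"].tolist()
    if len(top) < 20:
        raise ValueError(f"need >= 20 proteins in the top decile, got {len(top)}")
    ref_idx = np.array([dm.locate(r) for r in refs])
    X = np.vstack([dm.values[ref_idx, dm.locate(p)] for p in top])

    def fit(k: int, cov: str) -> GaussianMixture:
        gm = GaussianMixture(
            n_components=k, covariance_type=cov, random_state=seed, n_init=3,
            reg_covar=1e-6,
        )
        gm.fit(X)
        return gm

    covariance = "full"
    try:
        if n_clusters is not None:
            best = fit(n_clusters, covariance)
        else:
            fits = [fit(k, covariance) for k in range(1, max_components + 1)]
            best = min(fits, key=lambda g: g.bic(X))
    except (ValueError, np.linalg.LinAlgError):
        warnings.warn(
            "full covariance degenerate; falling back to diagonal covariance",
            stacklevel=2,
        )
        covariance = "diag"
        if n_clusters is not None:
            best = fit(n_clusters, covariance)
        else:
            fits = [fit(k, covariance) for k in range(1, max_components + 1)]
            best = min(fits, key=lambda g: g.bic(X))
    labels = best.predict(X)
    return pd.Series(labels, index=pd.Index(top, name="protein"), name="cluster")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up FDR)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def cluster_enrichment(
    assignment: pd.Series,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    background: Sequence[str],
    namespace: str | None = "biological_process",
) -> pd.DataFrame:
    """Per cluster x term one-sided enrichment with BH correction.

    ``background`` must contain every clustered protein.  Terms annotated
    (after propagation) to fewer than 2 cluster members are skipped.
    """
    background = sorted(set(background))
    missing = set(assignment.index) - set(background)
    if missing:
        raise ValueError(
            f"background lacks clustered protein(s): {sorted(missing)[:5]}"
        )
    bg_terms: dict[str, frozenset[str]] = {p: corpus.terms_of(p) for p in background}
    term_bg_count: dict[str, int] = {}
    for terms in bg_terms.values():
        for t in terms:
            term_bg_count[t] = term_bg_count.get(t, 0) + 1
    M = len(background)
    rows = []
    for cluster in sorted(assignment.unique()):
        members = sorted(assignment.index[assignment == cluster])
        if not members:
            continue
        N = len(members)
        counts: dict[str, int] = {}
        for p in members:
            for t in bg_terms[p]:
                counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            if counts[t] < 2:
                continue
            if namespace is not None and dag.namespace(t) not in (None, namespace):
                continue
            K = term_bg_count[t]
            x = counts[t]
            p_val = float(hypergeom.sf(x - 1, M, K, N))
            rows.append(
                {
                    "cluster": cluster,
                    "term": t,
                    "term_name": dag.names.get(t, ""),
                    "n_cluster_annotated": x,
                    "cluster_size": N,
                    "n_background_annotated": K,
                    "fraction": x / N,
                    "p_value": min(p_val, 1.0),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "term",
            "term_name",
            "n_cluster_annotated",
            "cluster_size",
            "n_background_annotated",
            "fraction",
            "p_value",
        ],
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table
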