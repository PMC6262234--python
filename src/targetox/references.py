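"""Selection of reference (landmark) proteins.

Candidate reference nodes are centers of fixed-radius DSD neighborhoods
significantly enriched for drug-binding proteins (one-sided hypergeometric
test).  Redundant candidates are merged by average-linkage hierarchical
clustering of their DSD row-vectors, and each cluster contributes the center
of its densest neighborhood — the one containing the most drug-binding
proteins.  The three free parameters (radius, enrichment cutoff, number of
clusters) can be grid-searched against cross-validated classifier AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

from .errors import InfeasibleSelectionError
from .graph import DistanceMatrix


@dataclass(frozen=True)
class NeighborhoodEnrichment:
    """Enrichment of drug-binding proteins within radius of a center node."""

    center: str
    radius: float
    n_members: int
    n_binding: int
    p_value: float


@dataclass(frozen=True)
class ReferencePointSet:
    """Ordered landmark proteins plus the parameters that selected them."""

    refs: tuple[str, ...]
    radius: float | None = None
    p_cutoff: float | None = None
    n_clusters: int | None = None
    metric: str | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.refs)

    def __iter__(self):
        return iter(self.refs)


def neighborhood_enrichment(
    dm: DistanceMatrix, binding_set: Iterable[str], radius: float
) -> list[NeighborhoodEnrichment]:
    """One record per network node.

    The neighborhood of a center is every node within ``radius`` (the center
    itself included, d=0).  The p-value is the upper hypergeometric tail:
    the chance that a uniformly drawn node set of the neighborhood's size
    contains at least the observed number of binding proteins.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    binding = sorted(set(binding_set))
    if not binding:
        raise ValueError("binding_set must be nonempty")
    b_idx = np.array([dm.locate(b) for b in binding])
    n = len(dm.ids)
    is_binding = np.zeros(n, dtype=bool)
    is_binding[b_idx] = True
    K = int(is_binding.sum())
    within = dm.values <= radius
    n_members = within.sum(axis=1)
    n_binding = (within & is_binding[None, :]).sum(axis=1)
    p = hypergeom.sf(n_binding - 1, n, K, n_members)
    return [
        NeighborhoodEnrichment(
            center=dm.ids[i],
            radius=radius,
            n_members=int(n_members[i]),
            n_binding=int(n_binding[i]),
            p_value=float(min(p[i], 1.0)),
        )
        for i in range(n)
    ]


def select_references(
    enrichments: Sequence[NeighborhoodEnrichment],
    dm: DistanceMatrix,
    p_cutoff: float,
    n_clusters: int,
) -> ReferencePointSet:
    """Cluster significant neighborhood centers and keep one per cluster.

    Centers passing ``p <= p_cutoff`` are clustered by average-linkage on
    their DSD row-vectors (Euclidean), cut at ``n_clusters``; each cluster
    returns the center of its densest neighborhood (most binding members,
    ties by smaller p, then lexicographic id).
    """
    sig = sorted(
        (e for e in enrichments if e.p_value <= p_cutoff), key=lambda e: e.center
    )
    if len(sig) < n_clusters:
        raise InfeasibleSelectionError(
            f"only {len(sig)} neighborhoods pass p <= {p_cutoff}; "
            f"cannot form {n_clusters} clusters (achievable maximum: {len(sig)})"
        )
    vectors = np.vstack([dm.row(e.center) for e in sig])
    if n_clusters == len(sig):
        labels = np.arange(1, len(sig) + 1)
    else:
        Z = linkage(vectors, method="average", metric="euclidean")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    refs: list[str] = []
    for c in sorted(set(labels)):
        members = [e for e, l in zip(sig, labels) if l == c]
        best = min(members, key=lambda e: (-e.n_binding, e.p_value, e.center))
        refs.append(best.center)
    return ReferencePointSet(
        refs=tuple(refs),
        radius=sig[0].radius,
        p_cutoff=p_cutoff,
        n_clusters=n_clusters,
        metric=dm.metric,
    )


def tune_reference_parameters(
    dm: DistanceMatrix,
    drugs: Sequence,
    corpus,
    dag,
    grid: dict,
    seed: int = 0,
    hyper_params: dict | None = None,
    cv_folds: int = 5,
):
    """Grid search (radius x p_cutoff x n_clusters) against 5-fold CV AUC.

    ``grid`` maps ``radius`` / ``p_cutoff`` / ``n_clusters`` to value lists;
    radii are in DSD units (use :meth:`DistanceMatrix.quantile` to derive
    them from quantiles).  Infeasible cells are recorded as failed, not
    fatal.  Returns ``(best ReferencePointSet, report DataFrame)``.
    """
    import pandas as pd

    from .features import featurize, labels_vector
    from .model import cross_validate

    radii = list(grid.get("radius", []))
    cutoffs = list(grid.get("p_cutoff", []))
    ks = list(grid.get("n_clusters", []))
    if not (radii and cutoffs and ks):
        raise ValueError("grid must provide radius, p_cutoff and n_clusters lists")

    binding = sorted({p for d in drugs for p in d.targets if p in dm.index})
    y = labels_vector(drugs)
    rows = []
    best: tuple[float, ReferencePointSet] | None = None
    for radius in radii:
        enr = neighborhood_enrichment(dm, binding, radius)
        for p_cutoff in cutoffs:
            for k in ks:
                try:
                    refs = select_references(enr, dm, p_cutoff, k)
                    X = featurize(drugs, dm, refs, corpus, dag)
                    report = cross_validate(
                        X, y, k=cv_folds, seed=seed, hyper_params=hyper_params
                    )
                    auc = report.auc
                    status = "ok"
                except InfeasibleSelectionError as exc:
                    refs, auc, status = None, np.nan, f"infeasible: {exc}"
                rows.append(
                    {
                        "radius": radius,
                        "p_cutoff": p_cutoff,
                        "n_clusters": k,
                        "cv_auc": auc,
                        "status": status,
                    }
                )
                if status == "ok" and (best is None or auc > best[0]):
                    best = (auc, refs)
    if best is None:
        raise InfeasibleSelectionError("every grid cell was infeasible")
    return best[1], pd.DataFrame(rows)
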