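"""Ontology parsing, annotation propagation, information content and the
functional-impact score.

Annotations are propagated up the ``is_a`` hierarchy: an entity annotated to
a term is implicitly annotated to every ancestor of that term.  Information
content of a term is then

    ``IC(t) = -ln(|k_t| / |k|)``

where ``|k_t|`` counts unique (entity, term) pairs involving ``t`` after
propagation and ``|k|`` counts all unique pairs.  The functional-impact
score of a protein set is the sum of IC over the *leaf frontier* of the
union ``T`` of their propagated terms — the terms of ``T`` with no proper
descendant also in ``T``:

    ``FI(T) = sum_{t in T, descendants(t) ∩ T = ∅} IC(t)``

A focused drug hits few distinct processes and scores low; a promiscuous
one, or one touching a protein shared by many processes, scores high.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import obonet
import pandas as pd

from .errors import ParseError, UnknownIdError

BIOLOGICAL_PROCESS = "biological_process"


class OntologyDAG:
    """Directed acyclic ``is_a`` hierarchy of terms.

    Parameters
    ----------
    parents
        Mapping term -> iterable of direct ``is_a`` parents (empty for roots).
    names, namespaces
        Optional per-term metadata.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ):
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        # register parent-only terms
        for ps in list(self._parents.values()):
            for p in ps:
                self._parents.setdefault(p, frozenset())
        self.names = dict(names or {})
        self.namespaces = dict(namespaces or {})
        self._children: dict[str, set[str]] = {t: set() for t in self._parents}
        for t, ps in self._parents.items():
            for p in ps:
                self._children[p].add(t)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self._parents[t]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"is_a cycle through term '{p}'")
                if s == 0:
                    visit(p, stack)
            state[t] = 2

        for t in self._parents:
            if state.get(t, 0) == 0:
                visit(t, [])

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self._parents))

    def parents(self, term: str) -> frozenset[str]:
        try:
            return self._parents[term]
        except KeyError:
            raise UnknownIdError(f"term '{term}' is not in the ontology")

    def children(self, term: str) -> frozenset[str]:
        if term not in self._parents:
            raise UnknownIdError(f"term '{term}' is not in the ontology")
        return frozenset(self._children[term])

    def namespace(self, term: str) -> str | None:
        return self.namespaces.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors via is_a (excludes the term itself)."""
        if term not in self._parents:
            raise UnknownIdError(f"term '{term}' is not in the ontology")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self._parents[term]:
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All proper descendants (excludes the term itself)."""
        if term not in self._parents:
            raise UnknownIdError(f"term '{term}' is not in the ontology")
        cached = self._descendant_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for c in self._children[term]:
            out.add(c)
            out |= self.descendants(c)
        result = frozenset(out)
        self._descendant_cache[term] = result
        return result


def load_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO 1.2/1.4 file, keeping only ``is_a`` edges."""
    g = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {t: set() for t in g.nodes}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for t, data in g.nodes(data=True):
        if "name" in data:
            names[t] = data["name"]
        if "namespace" in data:
            namespaces[t] = data["namespace"]
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return OntologyDAG(parents, names=names, namespaces=namespaces)


def load_annotations(
    path: str | Path,
    namespace: str | None = None,
    evidence_allow: Sequence[str] | None = None,
) -> list[tuple[str, str]]:
    """Read a GAF-like TSV (entity_id, term_id, namespace, evidence).

    ``namespace`` and ``evidence_allow`` filter rows when given; by default
    all rows are kept.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["entity_id", "term_id"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(
            f"annotation table is missing column(s): {', '.join(missing)}"
        )
    if namespace is not None and "namespace" in frame.columns:
        frame = frame[frame["namespace"] == namespace]
    if evidence_allow is not None and "evidence" in frame.columns:
        frame = frame[frame["evidence"].isin(set(evidence_allow))]
    return list(zip(frame["entity_id"], frame["term_id"]))


@dataclass
class AnnotationCorpus:
    """Propagated unique entity-term pairs with per-term counts.

    ``total`` is |k|, the number of unique pairs; ``term_counts[t]`` is
    |k_t|.  Closed under ancestor propagation by construction.
    """

    entity_terms: dict[str, frozenset[str]]
    term_counts: Counter = field(init=False)
    total: int = field(init=False)

    def __post_init__(self):
        counts: Counter = Counter()
        for terms in self.entity_terms.values():
            counts.update(terms)
        self.term_counts = counts
        self.total = sum(counts.values())

    def __contains__(self, entity: str) -> bool:
        return entity in self.entity_terms

    def terms_of(self, entity: str) -> frozenset[str]:
        return self.entity_terms.get(entity, frozenset())


def propagate(
    dag: OntologyDAG, direct_annotations: Iterable[tuple[str, str]]
) -> AnnotationCorpus:
    """Close direct (entity, term) pairs under ancestor inheritance."""
    entity_terms: dict[str, set[str]] = {}
    for entity, term in direct_annotations:
        if term not in dag:
            raise UnknownIdError(f"annotated term '{term}' is not in the ontology")
        bucket = entity_terms.setdefault(entity, set())
        if term not in bucket:
            bucket.add(term)
            bucket |= dag.ancestors(term)
    return AnnotationCorpus(
        entity_terms={e: frozenset(ts) for e, ts in entity_terms.items()}
    )


def information_content(corpus: AnnotationCorpus, term: str) -> float:
    """``-ln(|k_t| / |k|)`` in nats; undefined (error) for unannotated terms."""
    k_t = corpus.term_counts.get(term, 0)
    if k_t == 0:
        raise ValueError(
            f"IC is undefined for term '{term}': no propagated annotation"
        )
    return -math.log(k_t / corpus.total)


def functional_impact(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    bound_proteins: Sequence[str],
) -> float:
    """Sum of IC over the leaf frontier of the proteins' propagated term set.

    Proteins absent from the corpus contribute nothing; if none of the
    proteins is annotated a warning is emitted and 0 is returned.
    """
    annotated = [p for p in bound_proteins if p in corpus]
    if not annotated:
        if bound_proteins:
            warnings.warn(
                "none of the bound proteins carries an annotation; FI = 0",
                stacklevel=2,
            )
        return 0.0
    term_set: set[str] = set()
    for p in annotated:
        term_set |= corpus.terms_of(p)
    frontier = [t for t in term_set if not (dag.descendants(t) & term_set)]
    return float(sum(information_content(corpus, t) for t in frontier))
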