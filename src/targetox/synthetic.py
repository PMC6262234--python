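"""Synthetic benchmark generator with planted structure.

Emulates the full input bundle the predictor consumes — a scored protein
association network, a GO-like ontology with protein annotations, and a
labeled drug table — with known ground truth so every pipeline stage can be
validated without external databases.

The network is a planted-partition (stochastic block model) graph: dense
communities joined by sparse between-community edges, giving a controllable
community scale against which the neighborhood radius of reference selection
can be tested.  Each community contains an even denser core block
(``core_fraction`` of its nodes wired at ``p_core``) around a planted
center; drug-binding proteins are the core nodes, so they concentrate in a
few distinctive network regions and the planted centers are recoverable by
neighborhood enrichment.  A subset of communities are "toxicity hot spots".
Each drug draws every bound protein from its home community's binding pool
with probability ``community_bias`` and uniformly from the whole component
otherwise; it is truly toxic iff it binds at least one hot-spot binding
protein, and the emitted label flips that truth with probability
``label_noise``.  Route and plasma-protein-binding covariates are
uninformative noise with configurable missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import DrugRecord, save_drugs
from .ontology import BIOLOGICAL_PROCESS, OntologyDAG


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark."""

    n_proteins: int = 600
    n_communities: int = 6
    p_within: float = 0.08
    p_between: float = 0.004
    core_fraction: float = 0.2
    p_core: float = 0.5
    n_binding_proteins: int = 80
    community_bias: float = 0.9
    n_hotspot_communities: int = 2
    n_drugs: int = 200
    targets_min: int = 1
    targets_max: int = 5
    label_noise: float = 0.05
    route_missing_rate: float = 0.3
    ppb_missing_rate: float = 0.4
    decoy_edge_fraction: float = 0.02
    ontology_depth: int = 4
    ontology_branching: int = 3
    annotation_bias: float = 0.7
    multi_parent: bool = False
    seed: int = 7

    def validate(self) -> None:
        for name in (
            "p_within",
            "p_between",
            "core_fraction",
            "p_core",
            "community_bias",
            "label_noise",
            "route_missing_rate",
            "ppb_missing_rate",
            "annotation_bias",
            "decoy_edge_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_hotspot_communities > self.n_communities:
            raise ValueError(
                "n_hotspot_communities cannot exceed n_communities "
                f"({self.n_hotspot_communities} > {self.n_communities})"
            )
        if self.n_hotspot_communities < 1:
            raise ValueError("need at least one hot-spot community")
        if self.n_binding_proteins > self.n_proteins:
            raise ValueError("more binding proteins than proteins")
        if not (1 <= self.targets_min <= self.targets_max):
            raise ValueError("invalid targets-per-drug range")
        if self.n_communities < 2 or self.n_proteins < 2 * self.n_communities:
            raise ValueError("too few proteins or communities")


@dataclass
class SyntheticBundle:
    """In-memory generated dataset plus its ground truth."""

    config: GeneratorConfig
    edges: pd.DataFrame  # protein1, protein2, combined_score
    obo_text: str
    dag: OntologyDAG
    annotations: list[tuple[str, str]]
    drugs: list[DrugRecord]
    protein_community: dict[str, int]
    hotspot_communities: tuple[int, ...]
    binding_proteins: tuple[str, ...]
    planted_centers: dict[int, str]  # community -> reference-recoverable center
    causal: dict[str, bool]  # drug id -> truly binds a hot-spot protein
    flipped: dict[str, bool]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five text artifacts; byte-identical given one seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": out / "edges.tsv",
            "obo": out / "ontology.obo",
            "annotations": out / "annotations.tsv",
            "drugs": out / "drugs.tsv",
            "ground_truth": out / "ground_truth.tsv",
        }
        self.edges.to_csv(paths["edges"], sep="\t", index=False)
        paths["obo"].write_text(self.obo_text, encoding="utf-8")
        pd.DataFrame(
            self.annotations, columns=["entity_id", "term_id"]
        ).assign(namespace=BIOLOGICAL_PROCESS, evidence="IEA").to_csv(
            paths["annotations"], sep="\t", index=False
        )
        save_drugs(self.drugs, paths["drugs"])
        self.ground_truth_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "hotspot_community", "id": str(c), "key": "", "value": ""}
            for c in self.hotspot_communities
        ]
        rows += [
            {
                "kind": "community",
                "id": str(c),
                "key": "center",
                "value": self.planted_centers[c],
            }
            for c in sorted(self.planted_centers)
        ]
        rows += [
            {
                "kind": "protein",
                "id": p,
                "key": "community",
                "value": str(self.protein_community[p]),
            }
            for p in sorted(self.protein_community)
        ]
        rows += [
            {"kind": "protein", "id": p, "key": "binding", "value": "1"}
            for p in self.binding_proteins
        ]
        rows += [
            {
                "kind": "drug",
                "id": d.drug_id,
                "key": "causal",
                "value": "1" if self.causal[d.drug_id] else "0",
            }
            for d in self.drugs
        ]
        rows += [
            {
                "kind": "drug",
                "id": d.drug_id,
                "key": "flipped",
                "value": "1" if self.flipped[d.drug_id] else "0",
            }
            for d in self.drugs
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "key", "value"])


# ---------------------------------------------------------------------------
# ontology


def _build_tree_ontology(
    depth: int, branching: int, multi_parent: bool, rng: np.random.Generator
) -> tuple[OntologyDAG, str, list[str]]:
    """Rooted is_a tree (optionally with extra parents); returns the DAG,
    the OBO text and the list of leaf terms."""
    counter = [0]

    def new_term() -> str:
        counter[0] += 1
        return f"GO:{counter[0]:07d}"

    root = new_term()
    parents: dict[str, set[str]] = {root: set()}
    levels: list[list[str]] = [[root]]
    for _ in range(depth):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                t = new_term()
                parents[t] = {parent}
                level.append(t)
        levels.append(level)
    if multi_parent:
        # a second is_a parent one level up, avoiding the term's own lineage
        for d_lvl in range(2, depth + 1):
            for t in levels[d_lvl]:
                if rng.random() < 0.2:
                    candidates = [
                        c for c in levels[d_lvl - 1] if c not in parents[t]
                    ]
                    if candidates:
                        parents[t].add(candidates[int(rng.integers(len(candidates)))])
    names = {t: f"synthetic process {t[3:].lstrip('0')}" for t in parents}
    namespaces = {t: BIOLOGICAL_PROCESS for t in parents}
    dag = OntologyDAG(parents, names=names, namespaces=namespaces)

    lines = ["format-version: 1.2", "ontology: synthetic-bp", ""]
    for t in sorted(parents):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: {names[t]}")
        lines.append(f"namespace: {BIOLOGICAL_PROCESS}")
        for p in sorted(parents[t]):
            lines.append(f"is_a: {p} ! {names[p]}")
        lines.append("")
    return dag, "\n".join(lines), levels[-1]


# ---------------------------------------------------------------------------
# main generator


def generate(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate the full bundle; deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- proteins and communities
    n, k = config.n_proteins, config.n_communities
    proteins = [f"P{i:05d}" for i in range(n)]
    base = n // k
    sizes = [base + (1 if i < n % k else 0) for i in range(k)]
    community = np.repeat(np.arange(k), sizes)
    protein_community = {p: int(c) for p, c in zip(proteins, community)}
    starts = np.concatenate([[0], np.cumsum(sizes)])

    # -- planted-partition edges, with a denser core block per community
    core_size = {
        c: max(4, int(round(config.core_fraction * sizes[c]))) for c in range(k)
    }
    edge_rows: list[tuple[str, str, int]] = []
    for ci in range(k):
        for cj in range(ci, k):
            i0, i1 = starts[ci], starts[ci + 1]
            j0, j1 = starts[cj], starts[cj + 1]
            if ci == cj:
                p_block = np.full((i1 - i0, j1 - j0), config.p_within)
                cs = core_size[ci]
                p_block[:cs, :cs] = config.p_core
                mask = np.triu(rng.random(p_block.shape) < p_block, k=1)
            else:
                mask = rng.random((i1 - i0, j1 - j0)) < config.p_between
            ii, jj = np.nonzero(mask)
            for a, b in zip(ii + i0, jj + j0):
                edge_rows.append((proteins[a], proteins[b], 0))
    scores = rng.integers(200, 1000, size=len(edge_rows))
    edge_rows = [(a, b, int(s)) for (a, b, _), s in zip(edge_rows, scores)]

    # decoy low-confidence edges, removed by the standard score filter
    n_decoys = int(config.decoy_edge_fraction * len(edge_rows))
    for _ in range(n_decoys):
        a, b = rng.choice(n, size=2, replace=False)
        edge_rows.append(
            (proteins[int(a)], proteins[int(b)], int(rng.integers(50, 200)))
        )
    edges = pd.DataFrame(edge_rows, columns=["protein1", "protein2", "combined_score"])

    # -- main component (score >= 200) constrains binding-protein choice
    g = nx.Graph()
    g.add_edges_from(
        (a, b) for a, b, s in edge_rows if s >= 200 and a != b
    )
    component = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))[0]
    in_component = sorted(component)

    # -- binding proteins live in the community cores; the planted center is
    # the best-connected core node, making it recoverable by enrichment.
    in_comp_set = set(in_component)
    planted_centers: dict[int, str] = {}
    binding: list[str] = []
    quota = config.n_binding_proteins // k
    extra = config.n_binding_proteins % k
    for c in range(k):
        core = [
            proteins[i]
            for i in range(starts[c], starts[c] + core_size[c])
            if proteins[i] in in_comp_set
        ]
        center = max(core, key=lambda p: (g.degree(p), p))
        planted_centers[c] = center
        hops = nx.single_source_shortest_path_length(g, center)
        ranked = sorted(core, key=lambda p: (hops.get(p, 10**6), p))
        take = min(quota + (1 if c < extra else 0), len(core))
        binding.extend(ranked[:take])
    binding = sorted(binding)
    binding_by_comm = {c: [p for p in binding if protein_community[p] == c] for c in range(k)}

    hotspots = tuple(range(config.n_hotspot_communities))
    hotspot_binding = {p for p in binding if protein_community[p] in hotspots}

    # -- ontology and annotations
    dag, obo_text, leaves = _build_tree_ontology(
        config.ontology_depth, config.ontology_branching, config.multi_parent, rng
    )
    # each community prefers one depth-1 subtree's leaves
    branch = config.ontology_branching
    leaves_per_subtree = len(leaves) // branch
    subtree_leaves = [
        leaves[i * leaves_per_subtree : (i + 1) * leaves_per_subtree]
        for i in range(branch)
    ]
    annotations: list[tuple[str, str]] = []
    for p in proteins:
        preferred = subtree_leaves[protein_community[p] % branch]
        n_terms = int(rng.integers(1, 5))
        terms: set[str] = set()
        for _ in range(n_terms):
            pool = preferred if rng.random() < config.annotation_bias else leaves
            terms.add(pool[int(rng.integers(len(pool)))])
        for t in sorted(terms):
            annotations.append((p, t))

    # -- drugs
    drugs: list[DrugRecord] = []
    causal: dict[str, bool] = {}
    flipped: dict[str, bool] = {}
    for d in range(config.n_drugs):
        drug_id = f"D{d:04d}"
        home = int(rng.integers(k))
        home_pool = binding_by_comm[home] or binding
        n_targets = int(rng.integers(config.targets_min, config.targets_max + 1))
        targets: set[str] = set()
        for _ in range(n_targets):
            if rng.random() < config.community_bias:
                targets.add(home_pool[int(rng.integers(len(home_pool)))])
            else:  # off-target pick, uniform over the whole component
                targets.add(in_component[int(rng.integers(len(in_component)))])
        is_causal = bool(targets & hotspot_binding)
        flip = bool(rng.random() < config.label_noise)
        label = "toxic" if (is_causal != flip) else "safe"

        def maybe_bool() -> bool | None:
            if rng.random() < config.route_missing_rate:
                return None
            return bool(rng.random() < 0.5)

        if rng.random() < config.ppb_missing_rate:
            ppb_lower = ppb_upper = None
        else:
            ppb_lower = round(float(rng.uniform(0, 95)), 1)
            ppb_upper = round(min(100.0, ppb_lower + float(rng.uniform(0, 30))), 1)
        drugs.append(
            DrugRecord(
                drug_id=drug_id,
                label=label,
                targets=tuple(sorted(targets)),
                oral=maybe_bool(),
                parenteral=maybe_bool(),
                topical=maybe_bool(),
                ppb_lower=ppb_lower,
                ppb_upper=ppb_upper,
            )
        )
        causal[drug_id] = is_causal
        flipped[drug_id] = flip

    labels = {d.label for d in drugs}
    if labels != {"toxic", "safe"}:
        raise ValueError(
            "generated drug set is single-class; adjust community/bias settings"
        )

    bundle = SyntheticBundle(
        config=config,
        edges=edges,
        obo_text=obo_text,
        dag=dag,
        annotations=annotations,
        drugs=drugs,
        protein_community=protein_community,
        hotspot_communities=hotspots,
        binding_proteins=tuple(binding),
        planted_centers=planted_centers,
        causal=causal,
        flipped=flipped,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def oracle_bayes_auc(
    bundle: SyntheticBundle, drug_ids: Sequence[str] | None = None
) -> float:
    """AUC of the generative rule itself against the emitted labels.

    Scores each drug by its true hot-spot indicator; the emitted labels are
    that indicator corrupted by the configured flip rate, so no feature-based
    classifier can beat this bound beyond sampling noise.  ``drug_ids``
    restricts the computation to a subset (e.g. a hold-out split).
    """
    drugs = bundle.drugs
    if drug_ids is not None:
        wanted = set(drug_ids)
        drugs = [d for d in drugs if d.drug_id in wanted]
    y = np.array([1 if d.label == "toxic" else 0 for d in drugs])
    s = np.array([1.0 if bundle.causal[d.drug_id] else 0.0 for d in drugs])
    return float(roc_auc_score(y, s))
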