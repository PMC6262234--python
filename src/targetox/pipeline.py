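"""End-to-end orchestration: network -> distances -> references -> features
-> cross-validated and hold-out evaluated classifier, with one config and
one seed driving every stochastic stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import StageError
from .features import (
    featurize,
    labels_vector,
    load_drugs,
    save_features,
)
from .graph import build_distance_matrix, load_network, main_component
from .model import cross_validate, evaluate_scores, stratified_split, train
from .ontology import BIOLOGICAL_PROCESS, load_annotations, load_obo, propagate
from .references import (
    ReferencePointSet,
    neighborhood_enrichment,
    select_references,
)

log = logging.getLogger("targetox")


@dataclass
class RunConfig:
    """Paths, method parameters and the seed for a full run."""

    edges: str
    obo: str
    annotations: str
    drugs: str
    out_dir: str
    min_score: int = 200
    metric: str = "dsd"
    radius_quantile: float = 0.02
    p_cutoff: float = 1e-3
    n_refs: int = 12
    refs_file: str | None = None
    namespace: str | None = BIOLOGICAL_PROCESS
    test_fraction: float = 0.2
    cv_folds: int = 5
    hyper_params: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("edges", "obo", "annotations", "drugs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input '{name}': {p}")


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return run

    return wrap


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the published workflow and write every artifact.

    Writes the distance matrix, the reference list, the feature matrix, the
    trained model and an evaluation JSON under ``config.out_dir``; returns
    the evaluation report as a dict.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("targetox %s, seed=%d", __version__, config.seed)

    net = _stage("load_network")(load_network)(config.edges, config.min_score)
    net = _stage("main_component")(main_component)(net)
    log.info("network: %d nodes, %d edges", net.n_nodes, net.n_edges)

    dm = _stage("distances")(build_distance_matrix)(net, config.metric)
    dm.save(out / "distances")

    dag = _stage("ontology")(load_obo)(config.obo)
    pairs = _stage("annotations")(load_annotations)(
        config.annotations, namespace=config.namespace
    )
    corpus = _stage("propagate")(propagate)(dag, pairs)

    drugs = _stage("load_drugs")(load_drugs)(config.drugs)
    binding = sorted({p for d in drugs for p in d.targets if p in dm.index})

    if config.refs_file:
        ref_ids = [
            line.strip()
            for line in Path(config.refs_file).read_text().splitlines()
            if line.strip()
        ]
        refs = ReferencePointSet(refs=tuple(ref_ids), metric=dm.metric)
    else:
        radius = dm.quantile(config.radius_quantile)
        enr = _stage("enrichment")(neighborhood_enrichment)(dm, binding, radius)
        refs = _stage("select_references")(select_references)(
            enr, dm, config.p_cutoff, config.n_refs
        )
    (out / "refs.txt").write_text("\n".join(refs.refs) + "\n", encoding="utf-8")

    X = _stage("featurize")(featurize)(drugs, dm, refs, corpus, dag)
    save_features(X, out / "features.tsv")
    y = labels_vector(drugs)

    split = _stage("split")(stratified_split)(
        y, test_fraction=config.test_fraction, seed=config.seed
    )
    hp = config.hyper_params or None
    cv = _stage("cross_validate")(cross_validate)(
        X.iloc[split.train_idx],
        y.iloc[split.train_idx],
        k=config.cv_folds,
        seed=config.seed,
        hyper_params=hp,
    )
    model = _stage("train")(train)(
        X.iloc[split.train_idx], y.iloc[split.train_idx],
        hyper_params=hp, seed=config.seed,
    )
    model.save(out / "model.json")
    holdout_scores = model.predict(X.iloc[split.test_idx])
    holdout = evaluate_scores(holdout_scores, y.iloc[split.test_idx])

    report = {
        "version": __version__,
        "seed": config.seed,
        "metric": config.metric,
        "n_drugs": len(drugs),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "references": list(refs.refs),
        "cv": cv.to_dict(),
        "holdout": holdout.to_dict(),
        "parameters": {
            "min_score": config.min_score,
            "radius_quantile": config.radius_quantile,
            "p_cutoff": config.p_cutoff,
            "n_refs": config.n_refs,
            "test_fraction": config.test_fraction,
            "cv_folds": config.cv_folds,
        },
    }
    (out / "evaluation.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    return report
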