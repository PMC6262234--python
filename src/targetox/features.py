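"""Drug records and model-ready feature vectors.

Each drug is encoded as: one minimum-DSD value per reference protein
(distance from the landmark to the closest bound protein), the
functional-impact score of the bound set, three tri-state route-of-
administration indicators (oral / parenteral / topical; missing is distinct
from false) and lower/upper plasma-protein-binding percentages.  Missing
covariates stay missing: the boosted-tree classifier consumes NaN natively,
so no imputation is ever performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .errors import FeaturizationError, ParseError
from .graph import DistanceMatrix, mean_pairwise_distance
from .ontology import AnnotationCorpus, OntologyDAG, functional_impact

COVARIATE_COLUMNS = ("oral", "parenteral", "topical", "ppb_lower", "ppb_upper")
FI_COLUMN = "functional_impact"


@dataclass(frozen=True)
class DrugRecord:
    """A drug's bound-protein set, class label and covariates.

    ``label`` is ``'toxic'``, ``'safe'`` or ``None`` (unlabeled).  Route
    booleans and plasma-protein-binding bounds may be ``None`` = missing.
    """

    drug_id: str
    label: str | None
    targets: tuple[str, ...]
    oral: bool | None = None
    parenteral: bool | None = None
    topical: bool | None = None
    ppb_lower: float | None = None
    ppb_upper: float | None = None

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug '{self.drug_id}' has no bound proteins")
        if (
            self.ppb_lower is not None
            and self.ppb_upper is not None
            and self.ppb_lower > self.ppb_upper
        ):
            raise ValueError(
                f"drug '{self.drug_id}': ppb_lower exceeds ppb_upper"
            )
        for v, name in ((self.ppb_lower, "ppb_lower"), (self.ppb_upper, "ppb_upper")):
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"drug '{self.drug_id}': {name} outside [0, 100]")


def _parse_bool(cell: str) -> bool | None:
    if cell == "" or cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    s = str(cell).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ParseError(f"cannot parse boolean cell '{cell}'")


def load_drugs(path: str | Path) -> list[DrugRecord]:
    """Read the drug TSV: drug_id, label, targets (semicolon-separated),
    oral, parenteral, topical, ppb_lower, ppb_upper; empty cell = missing."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["drug_id", "label", "targets"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"drug table is missing column(s): {', '.join(missing)}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                DrugRecord(
                    drug_id=row["drug_id"],
                    label=row["label"] or None,
                    targets=tuple(t for t in row["targets"].split(";") if t),
                    oral=_parse_bool(row.get("oral", "")),
                    parenteral=_parse_bool(row.get("parenteral", "")),
                    topical=_parse_bool(row.get("topical", "")),
                    ppb_lower=float(row["ppb_lower"]) if row.get("ppb_lower") else None,
                    ppb_upper=float(row["ppb_upper"]) if row.get("ppb_upper") else None,
                )
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(f"drug table line {i + 2}: {exc}") from exc
    return records


def save_drugs(drugs: Sequence[DrugRecord], path: str | Path) -> None:
    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        return str(v)

    rows = [
        {
            "drug_id": d.drug_id,
            "label": d.label or "",
            "targets": ";".join(d.targets),
            "oral": cell(d.oral),
            "parenteral": cell(d.parenteral),
            "topical": cell(d.topical),
            "ppb_lower": cell(d.ppb_lower),
            "ppb_upper": cell(d.ppb_upper),
        }
        for d in drugs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# featurization


def network_features(
    dm: DistanceMatrix, refs, bound: Sequence[str]
) -> np.ndarray:
    """Entry j = min over the drug's mapped bound proteins of d(ref_j, p).

    Bound proteins absent from the matrix are dropped with a warning; if
    none maps the drug cannot be featurized.
    """
    mapped = [p for p in bound if p in dm.index]
    unmapped = [p for p in bound if p not in dm.index]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} bound protein(s) absent from the "
            f"network: {', '.join(sorted(unmapped)[:5])}"
            + ("..." if len(unmapped) > 5 else ""),
            stacklevel=2,
        )
    if not mapped:
        raise FeaturizationError(
            "no bound protein maps to the network: " + ", ".join(sorted(unmapped))
        )
    ref_idx = np.array([dm.locate(r) for r in refs])
    bound_idx = np.array([dm.locate(p) for p in mapped])
    return dm.values[np.ix_(ref_idx, bound_idx)].min(axis=1)


def feature_schema(refs) -> list[str]:
    return [f"dsd_ref_{r}" for r in refs] + [FI_COLUMN] + list(COVARIATE_COLUMNS)


def featurize(
    drugs: Sequence[DrugRecord],
    dm: DistanceMatrix,
    refs,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
) -> pd.DataFrame:
    """Feature matrix, one row per drug in input order, indexed by drug id.

    Missing covariates become NaN (tri-state routes: 1.0 / 0.0 / NaN); the
    network and FI blocks are always dense.
    """
    ids = [d.drug_id for d in drugs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate drug id(s): {', '.join(dupes)}")
    columns = feature_schema(refs)
    rows = []
    for d in drugs:
        net = network_features(dm, refs, d.targets)
        fi = functional_impact(corpus, dag, [p for p in d.targets if p in dm.index])
        covs = [
            np.nan if d.oral is None else float(d.oral),
            np.nan if d.parenteral is None else float(d.parenteral),
            np.nan if d.topical is None else float(d.topical),
            np.nan if d.ppb_lower is None else float(d.ppb_lower),
            np.nan if d.ppb_upper is None else float(d.ppb_upper),
        ]
        rows.append(list(net) + [fi] + covs)
    return pd.DataFrame(rows, index=pd.Index(ids, name="drug_id"), columns=columns)


def labels_vector(drugs: Sequence[DrugRecord]) -> pd.Series:
    """0/1 labels (toxic = 1) indexed by drug id; unlabeled drugs get NaN."""
    mapping = {"toxic": 1.0, "safe": 0.0}
    return pd.Series(
        [mapping.get(d.label, np.nan) if d.label else np.nan for d in drugs],
        index=pd.Index([d.drug_id for d in drugs], name="drug_id"),
        name="label",
    )


def save_features(X: pd.DataFrame, path: str | Path) -> None:
    """TSV with header; NaN serialized as an empty cell (missing marker)."""
    X.to_csv(path, sep="\t", na_rep="")


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="drug_id")


# ---------------------------------------------------------------------------
# compactness of bound-protein sets


@dataclass
class CompactnessReport:
    """Per-drug observed vs size-matched random mean pairwise distances and
    the paired two-sided Wilcoxon signed-ranks test across drugs."""

    per_drug: pd.DataFrame
    statistic: float
    p_value: float
    n_drugs: int


def target_compactness_test(
    dm: DistanceMatrix,
    drugs: Sequence[DrugRecord],
    n_random: int = 1,
    seed: int = 0,
) -> CompactnessReport:
    """Are each drug's bound proteins closer together than random sets?

    For every drug with >= 2 mapped bound proteins, the mean pairwise
    distance of its bound set is paired with the average over ``n_random``
    uniformly drawn node sets of the same size; the paired two-sided
    Wilcoxon signed-ranks test is applied across drugs.
    """
    rng = np.random.default_rng(seed)
    nodes = np.asarray(dm.ids)
    rows = []
    for d in drugs:
        mapped = sorted({p for p in d.targets if p in dm.index})
        if len(mapped) < 2:
            continue
        observed = mean_pairwise_distance(dm, mapped)
        rand_means = [
            mean_pairwise_distance(
                dm, rng.choice(nodes, size=len(mapped), replace=False)
            )
            for _ in range(n_random)
        ]
        rows.append(
            {
                "drug_id": d.drug_id,
                "set_size": len(mapped),
                "observed_mean": observed,
                "random_mean": float(np.mean(rand_means)),
            }
        )
    if len(rows) < 2:
        raise ValueError(
            "compactness test needs at least two drugs with >= 2 mapped targets"
        )
    per_drug = pd.DataFrame(rows)
    diffs = per_drug["observed_mean"] - per_drug["random_mean"]
    if np.allclose(diffs, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(diffs, alternative="two-sided")
    return CompactnessReport(
        per_drug=per_drug,
        statistic=float(stat),
        p_value=float(p),
        n_drugs=len(per_drug),
    )
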