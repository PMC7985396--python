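"""Discriminating individual- from ecosystem-level datasets.

Can the statistical signature of a degree distribution tell a genome from a
metagenome?  Two experimental protocols answer this, both operating on one
feature vector per network projection:

* **balanced single-predictor logistic regression** — per repeat, a training
  set balanced across the two levels and sized at 80% of the minority level's
  projection count is drawn, a logistic model is fit on one predictor alone,
  and per-class accuracy is measured on the held-out data; 100 repeats are
  averaged.  Accuracy at or below 50% means the predictor carries no level
  signal.
* **random forest** — 100 trees, 3 features per split (~sqrt(11)), data split
  into equal train/test halves; out-of-bag error comes from the training
  half.  Three scenarios: all 11 predictors; without the three size
  predictors (n, n_tail, n_edges); and the size-blind forest run on each
  projection type independently.

The 11 predictors per projection: power-law exponent ``alpha``; normalised
log-likelihood-ratio outcomes against the four alternatives (``dexp``,
``dln``, ``dplwc``, ``dstrexp`` — signed, negative when the alternative is
favored, 0 when inconclusive); mean degree; node count ``n``; tail size
``n_tail``; edge count ``n_edges``; goodness-of-fit ``p``; and the tail
cutoff ``xmin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .altmodels import AltFamily, Verdict
from .assess import ProjectionAssessment
from .projections import ProjectionKind
from .reactions import LEVELS

__all__ = [
    "PREDICTORS",
    "SIZE_PREDICTORS",
    "FeatureVector",
    "ClassifierReport",
    "extract_features",
    "features_frame",
    "balanced_logistic",
    "random_forest_experiment",
]

#: the 11 predictors, in a stable column order
PREDICTORS: tuple[str, ...] = (
    "alpha", "dexp", "dln", "dplwc", "dstrexp",
    "mean_degree", "n", "n_tail", "n_edges", "p", "xmin",
)
#: predictors that directly measure network size
SIZE_PREDICTORS: tuple[str, ...] = ("n", "n_tail", "n_edges")

Scenario = Literal["all_predictors", "no_size", "per_projection"]

_D_COLUMN: dict[AltFamily, str] = {
    AltFamily.EXPONENTIAL: "dexp",
    AltFamily.LOGNORMAL: "dln",
    AltFamily.POWERLAW_CUTOFF: "dplwc",
    AltFamily.STRETCHED_EXPONENTIAL: "dstrexp",
}


@dataclass(frozen=True)
class FeatureVector:
    """One projection's 11 predictors plus its level label and kind."""

    alpha: float
    dexp: float
    dln: float
    dplwc: float
    dstrexp: float
    mean_degree: float
    n: int
    n_tail: int
    n_edges: int
    p: float
    xmin: int
    label: str
    projection_kind: ProjectionKind
    dataset_id: str = ""


@dataclass
class ClassifierReport:
    """Outcome of one discrimination experiment."""

    scenario: str | None
    per_class_accuracy: dict[str, float]
    n_repeats: int = 1
    oob_error: float | None = None
    predictor: str | None = None
    importances: dict[str, float] | None = None
    train_size: int | None = None
    per_kind: dict[str, "ClassifierReport"] | None = None


def extract_features(assessment: ProjectionAssessment, label: str,
                     dataset_id: str = "") -> FeatureVector:
    """Feature vector for one assessed projection.

    Failed or degenerate fits are missing-coded (NaN) and later imputed
    inside each training split; inconclusive likelihood-ratio verdicts encode
    as 0, conclusive ones as the signed normalised ratio.  ``dataset_id``
    groups the eight projections of one dataset so train/test splits can keep
    them on the same side.
    """
    d: dict[str, float] = {c: float("nan") for c in _D_COLUMN.values()}
    for lr in assessment.lr_results:
        col = _D_COLUMN[lr.family]
        if lr.error is not None or not np.isfinite(lr.normalized):
            d[col] = float("nan")
        elif lr.verdict is Verdict.INCONCLUSIVE:
            d[col] = 0.0
        else:
            d[col] = lr.normalized
    fit = assessment.fit
    return FeatureVector(
        alpha=fit.alpha if fit else float("nan"),
        dexp=d["dexp"], dln=d["dln"], dplwc=d["dplwc"], dstrexp=d["dstrexp"],
        mean_degree=assessment.mean_degree,
        n=assessment.n,
        n_tail=fit.n_tail if fit else 0,
        n_edges=assessment.n_edges,
        p=(fit.gof_p if fit and fit.gof_p is not None else float("nan")),
        xmin=fit.xmin if fit else 0,
        label=label,
        projection_kind=assessment.kind,
        dataset_id=dataset_id,
    )


def features_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabular view: 11 predictor columns plus label and kind."""
    rows = [
        {**{c: getattr(v, c) for c in PREDICTORS},
         "label": v.label, "kind": str(v.projection_kind),
         "dataset": v.dataset_id}
        for v in vectors
    ]
    return pd.DataFrame(rows, columns=[*PREDICTORS, "label", "kind", "dataset"])


def _as_frame(vectors) -> pd.DataFrame:
    if isinstance(vectors, pd.DataFrame):
        return vectors
    return features_frame(vectors)


def _impute_train_median(train: pd.DataFrame, other: pd.DataFrame,
                         cols: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    med = train[list(cols)].median(numeric_only=True)
    med = med.fillna(0.0)  # all-NaN training column
    xtr = train[list(cols)].fillna(med).to_numpy(dtype=float)
    xte = other[list(cols)].fillna(med).to_numpy(dtype=float)
    return xtr, xte


def _per_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out = {}
    for level in LEVELS:
        mask = y_true == level
        out[level] = float(np.mean(y_pred[mask] == level)) if mask.any() else float("nan")
    return out


def balanced_logistic(
    vectors, predictor: str, n_repeats: int = 100,
    seed: int | None = 0, normalize_by_n: bool = False,
) -> ClassifierReport:
    """Balanced single-predictor logistic discrimination of the two levels.

    The training set holds an equal number of projections per level, totalling
    80% of the minority level's projection count; evaluation uses everything
    held out.  Mean per-class accuracy over ``n_repeats`` repeats is reported.

    ``normalize_by_n`` divides the non-size predictors by node count ``n``
    before fitting (an optional control for network size).
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    df = _as_frame(vectors).reset_index(drop=True)
    counts = df["label"].value_counts()
    if set(counts.index) != set(LEVELS):
        raise ValueError("both levels must be present")
    if normalize_by_n and predictor not in SIZE_PREDICTORS:
        df = df.copy()
        df[predictor] = df[predictor] / df["n"].clip(lower=1)
    minority = int(counts.min())
    train_total = int(0.8 * minority)
    per_class = train_total // 2
    train_total = 2 * per_class
    rng = np.random.default_rng(seed)
    accs = {lvl: [] for lvl in LEVELS}
    for _ in range(n_repeats):
        train_idx = np.concatenate([
            rng.choice(df.index[df["label"] == lvl].to_numpy(), size=per_class,
                       replace=False)
            for lvl in LEVELS
        ])
        test_mask = np.ones(len(df), dtype=bool)
        test_mask[train_idx] = False
        train, test = df.iloc[train_idx], df.loc[test_mask]
        xtr, xte = _impute_train_median(train, test, [predictor])
        clf = LogisticRegression(max_iter=1000)
        clf.fit(xtr, train["label"].to_numpy())
        acc = _per_class_accuracy(test["label"].to_numpy(), clf.predict(xte))
        for lvl in LEVELS:
            accs[lvl].append(acc[lvl])
    return ClassifierReport(
        scenario=None,
        per_class_accuracy={lvl: float(np.mean(a)) for lvl, a in accs.items()},
        n_repeats=n_repeats,
        predictor=predictor,
        train_size=train_total,
    )


def _forest_once(df: pd.DataFrame, cols: Sequence[str], scenario: str,
                 rng: np.random.Generator, n_trees: int, mtry: int) -> ClassifierReport:
    # split into halves by dataset when grouping information is available, so
    # the correlated projections of one dataset never straddle the split (a
    # row-level split lets the forest memorise datasets instead of levels)
    groups = df["dataset"].to_numpy() if "dataset" in df.columns else None
    if groups is not None and len(np.unique(groups[groups != ""])) > 1:
        uniq = np.unique(groups)
        uniq = uniq[rng.permutation(uniq.size)]
        train_groups = set(uniq[: uniq.size // 2])
        in_train = np.array([g in train_groups for g in groups])
        train, test = df.loc[in_train], df.loc[~in_train]
        half = int(in_train.sum())
    else:
        idx = rng.permutation(len(df))
        half = len(df) // 2
        train, test = df.iloc[idx[:half]], df.iloc[idx[half:]]
    if train["label"].nunique() < 2 or len(train) < 4:
        raise ValueError("insufficient data for a train/test split")
    xtr, xte = _impute_train_median(train, test, cols)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, len(cols)),
        oob_score=True,
        bootstrap=True,
        random_state=int(rng.integers(2**31)),
    )
    clf.fit(xtr, train["label"].to_numpy())
    acc = _per_class_accuracy(test["label"].to_numpy(), clf.predict(xte))
    return ClassifierReport(
        scenario=scenario,
        per_class_accuracy=acc,
        oob_error=float(1.0 - clf.oob_score_),
        importances=dict(zip(cols, (float(v) for v in clf.feature_importances_))),
        train_size=half,
    )


def random_forest_experiment(
    vectors, scenario: Scenario = "all_predictors",
    seed: int | None = 0, n_trees: int = 100, mtry: int = 3,
) -> ClassifierReport:
    """Random-forest discrimination of the two levels under one scenario.

    ``all_predictors`` uses the 11 predictors; ``no_size`` drops n, n_tail
    and n_edges; ``per_projection`` additionally runs the size-blind forest
    on each projection type independently (results in ``per_kind``).
    """
    df = _as_frame(vectors).reset_index(drop=True)
    if df["label"].nunique() < 2:
        raise ValueError("both levels must be present")
    rng = np.random.default_rng(seed)
    if scenario == "all_predictors":
        return _forest_once(df, PREDICTORS, scenario, rng, n_trees, mtry)
    cols = [c for c in PREDICTORS if c not in SIZE_PREDICTORS]
    if scenario == "no_size":
        return _forest_once(df, cols, scenario, rng, n_trees, mtry)
    if scenario != "per_projection":
        raise ValueError(f"unknown scenario {scenario!r}")
    per_kind: dict[str, ClassifierReport] = {}
    for kind, sub in df.groupby("kind", sort=True):
        per_kind[str(kind)] = _forest_once(
            sub.reset_index(drop=True), cols, scenario, rng, n_trees, mtry)
    overall = {
        lvl: float(np.nanmean([r.per_class_accuracy[lvl] for r in per_kind.values()]))
        for lvl in LEVELS
    }
    return ClassifierReport(scenario=scenario, per_class_accuracy=overall,
                            per_kind=per_kind)
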