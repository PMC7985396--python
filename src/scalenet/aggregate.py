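"""Ensemble summaries: pass proportions, 2SD error bars, indicator correlations.

Reported proportions treat each category as a binomial: the error bar on a
sample proportion ``p_hat = k/n`` is two standard deviations,
``2*sqrt(p_hat*(1-p_hat)/n)``, i.e. an approximate 95% interval.  Because the
per-projection pass/fail indicators of one dataset are far from independent,
the summary also exposes Pearson correlation matrices (phi coefficients)
between projection types computed on the boolean pass/fail indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assess import CRITERIA, Ladder, ScaleFreeCall
from .projections import PROJECTION_KINDS

__all__ = [
    "ProportionEstimate",
    "proportion_ci",
    "build_pass_matrix",
    "criterion_correlation",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class ProportionEstimate:
    p_hat: float
    two_sd: float
    k: int
    n: int


def proportion_ci(k: int, n: int) -> ProportionEstimate:
    """Sample proportion with the binomial 2SD error bar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    return ProportionEstimate(p_hat=p, two_sd=2.0 * np.sqrt(p * (1 - p) / n),
                              k=k, n=n)


def build_pass_matrix(calls: Sequence[ScaleFreeCall]) -> pd.DataFrame:
    """Dataset x (criterion, projection-kind) boolean indicator matrix.

    Rows are datasets (indexed by dataset_id, with a ``level`` column);
    columns are a MultiIndex of the four per-graph criteria by the eight
    projection kinds.
    """
    if not calls:
        raise ValueError("no calls supplied")
    cols = pd.MultiIndex.from_product(
        [CRITERIA, [str(k) for k in PROJECTION_KINDS]],
        names=["criterion", "kind"],
    )
    rows, ids, levels = [], [], []
    for call in calls:
        by_kind = {a.kind: a for a in call.per_projection}
        row = []
        for crit in CRITERIA:
            for kind in PROJECTION_KINDS:
                row.append(bool(getattr(by_kind[kind], crit)))
        rows.append(row)
        ids.append(call.dataset_id)
        levels.append(call.level)
    df = pd.DataFrame(rows, columns=cols, index=ids)
    df.insert(0, "level", levels, allow_duplicates=True)
    return df


def criterion_correlation(matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pearson (phi) correlation between projection types, per criterion.

    Indicators are cast to {0, 1}; constant columns have undefined
    correlation and are reported as missing (NaN), not zero.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 datasets")
    out: dict[str, pd.DataFrame] = {}
    for crit in CRITERIA:
        block = matrix[crit].astype(float)
        out[crit] = block.corr(method="pearson")
    return out


def summarize_ensemble(calls: Sequence[ScaleFreeCall]) -> dict[str, pd.DataFrame]:
    """Per-level report tables for an ensemble of classified datasets.

    Returns three tables:

    * ``counts_hist`` — per level and criterion, the histogram (bins 0..8) of
      how many of a dataset's eight projections meet that criterion,
      normalised to the number of datasets in the level;
    * ``projection_pass`` — per level, criterion and projection kind, the
      pass proportion with its 2SD error bar;
    * ``ladder`` — per level, the proportion of datasets in each ladder
      category (plus the non-nested Super-Weak share), with 2SD error bars.
    """
    if not calls:
        raise ValueError("no calls supplied")
    matrix = build_pass_matrix(calls)
    levels = sorted(set(matrix["level"]))

    hist_rows = []
    for level in levels:
        sub = matrix[matrix["level"] == level]
        for crit in CRITERIA:
            counts = sub[crit].sum(axis=1).astype(int)  # 0..8 per dataset
            binned = np.bincount(counts, minlength=9)[:9]
            for n_proj, k in enumerate(binned):
                est = proportion_ci(int(k), len(sub))
                hist_rows.append({
                    "level": level, "criterion": crit,
                    "n_projections": n_proj,
                    "proportion": est.p_hat, "two_sd": est.two_sd,
                    "k": est.k, "n": est.n,
                })
    counts_hist = pd.DataFrame(hist_rows)

    pass_rows = []
    for level in levels:
        sub = matrix[matrix["level"] == level]
        for crit in CRITERIA:
            for kind in (str(k) for k in PROJECTION_KINDS):
                k = int(sub[(crit, kind)].sum())
                est = proportion_ci(k, len(sub))
                pass_rows.append({
                    "level": level, "criterion": crit, "kind": kind,
                    "proportion": est.p_hat, "two_sd": est.two_sd,
                    "k": est.k, "n": est.n,
                })
    projection_pass = pd.DataFrame(pass_rows)

    ladder_rows = []
    by_level: dict[str, list[ScaleFreeCall]] = {}
    for call in calls:
        by_level.setdefault(call.level, []).append(call)
    for level in levels:
        group = by_level[level]
        n = len(group)
        for cat in Ladder:
            k = sum(1 for c in group if c.ladder is cat)
            est = proportion_ci(k, n)
            ladder_rows.append({
                "level": level, "category": cat.value,
                "proportion": est.p_hat, "two_sd": est.two_sd,
                "k": est.k, "n": est.n,
            })
        k_sw = sum(1 for c in group if c.super_weak)
        est = proportion_ci(k_sw, n)
        ladder_rows.append({
            "level": level, "category": "super_weak",
            "proportion": est.p_hat, "two_sd": est.two_sd,
            "k": est.k, "n": est.n,
        })
    ladder = pd.DataFrame(ladder_rows)

    return {"counts_hist": counts_hist, "projection_pass": projection_pass,
            "ladder": ladder}
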