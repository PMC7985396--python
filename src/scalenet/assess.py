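"""Per-projection assessment and the Super-Weak -> Strongest ladder.

Each of a dataset's eight projections is assessed on four per-graph criteria:

* ``no_alt_favored`` — no alternative family beats the power law in the
  likelihood-ratio test;
* ``pass_p``       — the bootstrap goodness-of-fit p-value is >= 0.1;
* ``pass_tail``    — at least 50 observations in the fitted tail;
* ``pass_alpha``   — the fitted exponent lies in (2, 3).

The dataset-level categories (Broido & Clauset's scheme) are evaluated over
the eight graphs with percentage thresholds applied as ``>=`` counts (50% ->
4 of 8; 90% and 95% -> 8 of 8):

* Super-Weak — >=50% of graphs have no alternative favored (not nested);
* Weakest    — >=50% of graphs pass the p >= 0.1 rule;
* Weak       — >=50% of graphs pass p >= 0.1 *and* n_tail >= 50;
* Strong     — Weak, Super-Weak, and >=50% of graphs additionally have
  2 < alpha_hat < 3;
* Strongest  — the Strong per-graph criteria for >=90% of graphs and no
  alternative favored for >=95% of graphs.

Degenerate projections (fewer than two distinct positive degrees) count as
failing every criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .altmodels import LRResult, any_alternative_favored, compare_all
from .powerlaw import (
    DegenerateSequenceError,
    PowerLawFit,
    gof_pvalue,
    select_xmin,
)
from .projections import (
    PROJECTION_KINDS,
    ProjectionGraph,
    ProjectionKind,
    degree_sequence,
    expand_dataset,
)
from .reactions import ReactionDataset

__all__ = [
    "GOF_P_THRESHOLD",
    "TAIL_THRESHOLD",
    "ALPHA_RANGE",
    "Ladder",
    "CRITERIA",
    "ProjectionAssessment",
    "ScaleFreeCall",
    "assess_projection",
    "assess_dataset",
    "classify_dataset",
    "classify_from_flags",
]

GOF_P_THRESHOLD = 0.1  #: p < 0.1 rules the power law out
TAIL_THRESHOLD = 50  #: minimum tail size for a reliable fit
ALPHA_RANGE = (2.0, 3.0)  #: the canonical scale-free exponent range
N_GRAPHS = 8

#: per-graph criterion names, in the flag-vector column order used throughout
CRITERIA: tuple[str, ...] = ("no_alt_favored", "pass_p", "pass_tail", "pass_alpha")


class Ladder(str, Enum):
    NOT_SCALE_FREE = "not_scale_free"
    WEAKEST = "weakest"
    WEAK = "weak"
    STRONG = "strong"
    STRONGEST = "strongest"


_LADDER_ORDER = [Ladder.NOT_SCALE_FREE, Ladder.WEAKEST, Ladder.WEAK,
                 Ladder.STRONG, Ladder.STRONGEST]


@dataclass
class ProjectionAssessment:
    """One projection's fit, goodness-of-fit and model-comparison results."""

    kind: ProjectionKind
    n: int
    n_edges: int
    fit: PowerLawFit | None = None
    lr_results: list[LRResult] = field(default_factory=list)
    degenerate: bool = False
    error: str | None = None

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n if self.n else 0.0

    @property
    def pass_p(self) -> bool:
        return (not self.degenerate and self.fit is not None
                and self.fit.gof_p is not None
                and self.fit.gof_p >= GOF_P_THRESHOLD)

    @property
    def pass_tail(self) -> bool:
        return (not self.degenerate and self.fit is not None
                and self.fit.n_tail >= TAIL_THRESHOLD)

    @property
    def pass_alpha(self) -> bool:
        return (not self.degenerate and self.fit is not None
                and ALPHA_RANGE[0] < self.fit.alpha < ALPHA_RANGE[1])

    @property
    def no_alt_favored(self) -> bool:
        return (not self.degenerate and bool(self.lr_results)
                and not any_alternative_favored(self.lr_results))

    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.no_alt_favored, self.pass_p, self.pass_tail,
                self.pass_alpha)


@dataclass
class ScaleFreeCall:
    """Dataset-level classification over its eight projections."""

    dataset_id: str
    level: str
    super_weak: bool
    ladder: Ladder
    per_projection: list[ProjectionAssessment]


def assess_projection(
    graph: ProjectionGraph, n_boot: int = 1000, seed: int | None = 0
) -> ProjectionAssessment:
    """Full per-projection pipeline: cutoff-selected power-law fit, bootstrap
    goodness-of-fit, and the four likelihood-ratio comparisons."""
    degrees = degree_sequence(graph)
    assessment = ProjectionAssessment(
        kind=graph.kind, n=graph.n_nodes, n_edges=graph.n_edges
    )
    try:
        fit = select_xmin(degrees)
    except DegenerateSequenceError as exc:
        assessment.degenerate = True
        assessment.error = str(exc)
        return assessment
    p = gof_pvalue(degrees, fit, n_boot=n_boot, seed=seed)
    assessment.fit = fit.with_gof(p, n_boot)
    assessment.lr_results = compare_all(degrees, fit)
    return assessment


def classify_from_flags(flags: np.ndarray) -> tuple[bool, Ladder]:
    """Ladder classification from an (8, 4) boolean flag matrix.

    Columns follow :data:`CRITERIA` order: no_alt_favored, pass_p, pass_tail,
    pass_alpha.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (N_GRAPHS, len(CRITERIA)):
        raise ValueError(f"expected an (8, 4) flag matrix, got {flags.shape}")
    no_alt, pass_p, pass_tail, pass_alpha = flags.T
    need_50 = math.ceil(0.50 * N_GRAPHS)  # 4
    need_90 = math.ceil(0.90 * N_GRAPHS)  # 8
    need_95 = math.ceil(0.95 * N_GRAPHS)  # 8

    super_weak = int(no_alt.sum()) >= need_50
    weakest_graphs = pass_p
    weak_graphs = pass_p & pass_tail
    strong_graphs = weak_graphs & pass_alpha

    weakest = int(weakest_graphs.sum()) >= need_50
    weak = int(weak_graphs.sum()) >= need_50
    strong = weak and super_weak and int(strong_graphs.sum()) >= need_50
    strongest = (strong
                 and int(strong_graphs.sum()) >= need_90
                 and int(no_alt.sum()) >= need_95)

    if strongest:
        ladder = Ladder.STRONGEST
    elif strong:
        ladder = Ladder.STRONG
    elif weak:
        ladder = Ladder.WEAK
    elif weakest:
        ladder = Ladder.WEAKEST
    else:
        ladder = Ladder.NOT_SCALE_FREE
    return super_weak, ladder


def classify_dataset(
    assessments: Sequence[ProjectionAssessment],
    dataset_id: str = "",
    level: str = "",
) -> ScaleFreeCall:
    """Apply the ladder to exactly eight projection assessments."""
    if len(assessments) != N_GRAPHS:
        raise ValueError(f"expected {N_GRAPHS} assessments, got {len(assessments)}")
    flags = np.array([a.flags() for a in assessments], dtype=bool)
    super_weak, ladder = classify_from_flags(flags)
    return ScaleFreeCall(dataset_id=dataset_id, level=level,
                         super_weak=super_weak, ladder=ladder,
                         per_projection=list(assessments))


def assess_dataset(
    dataset: ReactionDataset, n_boot: int = 1000, seed: int | None = 0
) -> ScaleFreeCall:
    """Expand a reaction dataset into its eight projections and classify it."""
    expanded = expand_dataset(dataset)
    streams = np.random.SeedSequence(seed).spawn(N_GRAPHS)
    assessments = []
    for kind, ss in zip(PROJECTION_KINDS, streams):
        graph, _ = expanded[kind]
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        assessments.append(assess_projection(graph, n_boot=n_boot, seed=sub_seed))
    return classify_dataset(assessments, dataset.dataset_id, dataset.level)
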