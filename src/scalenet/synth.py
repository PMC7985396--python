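"""Synthetic reaction datasets and degree sequences.

Real inputs to this kind of analysis are genome- and metagenome-derived
reaction inventories: hundreds to thousands of reactions, with a few hub
compounds participating in very many reactions while most compounds appear in
only one or two.  The generator emulates those statistics without claiming
chemical realism:

* reactions are built sequentially with 1-3 compounds per side (configurable);
* under ``preferential`` reuse, an established compound is drawn with weight
  (its current participation count − ``discount``) while a brand-new compound
  enters with weight (``reuse_strength`` + ``discount`` × compounds so far) —
  a rich-get-richer scheme of the Pitman–Yor type whose participation counts
  are power-law tailed and whose compound inventory grows polynomially with
  the number of reactions, the canonical preferential-attachment route to
  heavy-tailed degree structure;
* under ``uniform`` reuse, compounds are drawn uniformly from a fixed pool,
  producing near-homogeneous (binomial-like) participation — the negative
  control.  Note that free cutoff selection can still rescue a power law on
  such data by retreating into the short upper tail; pin the cutoff when a
  decisive rejection is the point.

Ensembles pair an individual level (genome scale) with an ecosystem level
(metagenome scale, ``size_ratio`` times larger), with switchable planted
differences so level-discrimination experiments can be run against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .altmodels import AltFamily, alt_logpmf
from .powerlaw import sample_discrete_powerlaw
from .reactions import Reaction, ReactionDataset

__all__ = [
    "GeneratorConfig",
    "EnsembleConfig",
    "generate_reaction_dataset",
    "generate_ensemble",
    "sample_degree_sequence",
]

ReuseMode = Literal["preferential", "uniform"]


@dataclass
class GeneratorConfig:
    """Configuration for a single synthetic reaction dataset."""

    n_reactions: int
    arity_range: tuple[int, int] = (1, 3)  #: compounds per reaction side
    compound_reuse: ReuseMode = "preferential"
    reuse_strength: float = 1.0  #: innovation weight of the reuse process
    discount: float = 0.75  #: Pitman-Yor discount; 0 = plain rich-get-richer
    pool_size: int | None = None  #: fixed pool for uniform reuse
    level: str = "individual"
    seed: int = 0
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        lo, hi = self.arity_range
        if lo < 1 or hi < lo:
            raise ValueError("arity bounds must satisfy 1 <= lo <= hi")
        if self.reuse_strength < 0:
            raise ValueError("reuse_strength must be >= 0")
        if not 0 <= self.discount < 1:
            raise ValueError("discount must lie in [0, 1)")


@dataclass
class EnsembleConfig:
    """Two-level ensemble: individuals at base scale, ecosystems scaled up.

    ``planted_effects`` lists which level differences exist: ``"size"``
    multiplies ecosystem reaction counts by ``size_ratio``; ``"mean_degree"``
    widens ecosystem reaction arity by ``arity_shift`` compounds per side.
    An empty tuple makes the two levels statistically exchangeable.
    """

    n_individual: int
    n_ecosystem: int
    base_reactions: int = 200
    size_ratio: float = 3.0
    planted_effects: tuple[str, ...] = ("size",)
    arity_range: tuple[int, int] = (1, 3)
    arity_shift: int = 1
    reuse_strength: float = 1.0
    size_jitter: float = 0.35  #: lognormal sd of per-dataset size multipliers
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individual < 0 or self.n_ecosystem < 0:
            raise ValueError("dataset counts must be >= 0")
        if self.n_individual + self.n_ecosystem == 0:
            raise ValueError("ensemble must contain at least one dataset")
        if self.size_ratio <= 1:
            raise ValueError("size_ratio must exceed 1")
        unknown = set(self.planted_effects) - {"size", "mean_degree"}
        if unknown:
            raise ValueError(f"unknown planted effects: {sorted(unknown)}")


def _draw_side_preferential(
    rng: np.random.Generator,
    arity: int,
    compounds: list[str],
    counts: list[float],
    strength: float,
    discount: float,
) -> set[str]:
    """Draw one reaction side under rich-get-richer compound reuse.

    An established compound is drawn with weight (participation count -
    discount); a brand-new compound enters with weight (reuse_strength +
    discount * number of established compounds).  With discount 0 this is the
    plain participation-proportional scheme; a positive discount makes the
    compound inventory grow polynomially and its participation counts
    power-law tailed, which is what genome-scale reaction sets look like.
    Compounds created within the current reaction carry no weight until the
    reaction completes and participation counts are updated.
    """
    side: set[str] = set()
    for _ in range(arity):
        for _attempt in range(200):
            m = len(compounds)
            weights = np.maximum(np.asarray(counts) - discount, 1e-9) \
                if m else np.array([])
            new_w = strength + discount * m
            if m == 0:
                new_w = max(new_w, 1.0)
            total = weights.sum() + new_w
            r = rng.random() * total
            if r < new_w or m == 0:
                cid = f"C{len(compounds):06d}"
                compounds.append(cid)
                counts.append(0.0)
            else:
                idx = int(np.searchsorted(np.cumsum(weights), r - new_w,
                                          side="right"))
                idx = min(idx, m - 1)
                cid = compounds[idx]
            if cid not in side:
                side.add(cid)
                break
        else:  # pathological config; force a fresh compound
            cid = f"C{len(compounds):06d}"
            compounds.append(cid)
            counts.append(0.0)
            side.add(cid)
    return side


def generate_reaction_dataset(config: GeneratorConfig) -> ReactionDataset:
    """Generate one synthetic reaction dataset, reproducibly from its seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.arity_range
    dataset_id = config.dataset_id or f"synth-{config.level}-{config.seed}"

    if config.compound_reuse == "uniform":
        pool_size = config.pool_size
        if pool_size is None:
            pool_size = max(2 * hi + 2, int(np.ceil(config.n_reactions / 2)))
        if pool_size < 2 * hi:
            raise ValueError(
                f"pool_size={pool_size} cannot supply two disjoint sides of "
                f"arity up to {hi}"
            )
        pool = np.array([f"C{i:06d}" for i in range(pool_size)])

    compounds: list[str] = []
    counts: list[float] = []
    reactions: list[Reaction] = []
    for i in range(config.n_reactions):
        for _attempt in range(50):
            a_sub = int(rng.integers(lo, hi + 1))
            a_prod = int(rng.integers(lo, hi + 1))
            if config.compound_reuse == "uniform":
                both = rng.choice(pool, size=a_sub + a_prod, replace=False)
                subs, prods = set(both[:a_sub]), set(both[a_sub:])
            else:
                subs = _draw_side_preferential(
                    rng, a_sub, compounds, counts, config.reuse_strength,
                    config.discount)
                prods = _draw_side_preferential(
                    rng, a_prod, compounds, counts, config.reuse_strength,
                    config.discount)
            if subs != prods:
                break
        if config.compound_reuse == "preferential":
            # compound ids are "C<index>", so the suffix addresses counts
            for c in subs | prods:
                counts[int(c[1:])] += 1.0
        reactions.append(
            Reaction(f"R{i:06d}", frozenset(subs), frozenset(prods)))
    return ReactionDataset(dataset_id, config.level, reactions)  # type: ignore[arg-type]


def generate_ensemble(config: EnsembleConfig) -> list[ReactionDataset]:
    """Generate a labelled two-level ensemble of reaction datasets."""
    master = np.random.SeedSequence(config.master_seed)
    streams = master.spawn(config.n_individual + config.n_ecosystem)
    lo, hi = config.arity_range
    eco_arity = (lo, hi + config.arity_shift) \
        if "mean_degree" in config.planted_effects else (lo, hi)
    eco_scale = config.size_ratio if "size" in config.planted_effects else 1.0

    datasets: list[ReactionDataset] = []
    specs = (
        [("individual", 1.0, (lo, hi))] * config.n_individual
        + [("ecosystem", eco_scale, eco_arity)] * config.n_ecosystem
    )
    for i, ((level, scale, arity), ss) in enumerate(zip(specs, streams)):
        rng = np.random.default_rng(ss)
        jitter = float(np.exp(rng.normal(0.0, config.size_jitter)))
        n_rxn = max(5, int(round(config.base_reactions * scale * jitter)))
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        datasets.append(generate_reaction_dataset(GeneratorConfig(
            n_reactions=n_rxn,
            arity_range=arity,
            reuse_strength=config.reuse_strength,
            level=level,
            seed=sub_seed,
            dataset_id=f"synth-{level}-{i:05d}",
        )))
    return datasets


def sample_degree_sequence(
    family: str | AltFamily,
    params: dict[str, float],
    n: int,
    seed: int | None = None,
    xmin: int = 1,
) -> np.ndarray:
    """Draw n i.i.d. integers from a tail family's discrete form on {xmin,...}.

    The pmf is the same zeta/summation-normalised form the fitters use, so
    samplers and likelihoods agree by construction.  ``family="powerlaw"``
    delegates to :func:`scalenet.powerlaw.sample_discrete_powerlaw`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if family == "powerlaw":
        return sample_discrete_powerlaw(params["alpha"], xmin, n, rng=rng)
    fam = AltFamily(family)
    # adaptive inverse-CDF table: extend until the tail mass is negligible
    size = 4096
    while True:
        xs = np.arange(xmin, xmin + size)
        pmf = np.exp(alt_logpmf(xs, fam, params, xmin))
        cdf = np.cumsum(pmf)
        if 1.0 - cdf[-1] < 1e-12 or size >= 2**24:
            break
        size *= 4
    u = rng.random(n)
    idx = np.minimum(np.searchsorted(cdf, u, side="left"), size - 1)
    return (xmin + idx).astype(np.int64)
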