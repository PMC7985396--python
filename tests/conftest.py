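import numpy as np
import pytest

from scalenet.reactions import Reaction, ReactionDataset


@pytest.fixture
def toy_dataset() -> ReactionDataset:
    """Two connected reactions: R1: {A,B}->{C}, R2: {C}->{D,E}."""
    return ReactionDataset(
        "toy", "individual",
        [Reaction("R1", {"A", "B"}, {"C"}), Reaction("R2", {"C"}, {"D", "E"})],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_small_dataset(rng: np.random.Generator, max_reactions: int = 6
                         ) -> ReactionDataset:
    """A random dataset with few reactions over a small compound alphabet."""
    n_rxn = int(rng.integers(1, max_reactions + 1))
    alphabet = [f"c{i}" for i in range(int(rng.integers(3, 9)))]
    reactions = []
    for i in range(n_rxn):
        k_s = int(rng.integers(1, 4))
        k_p = int(rng.integers(0, 4))
        subs = set(rng.choice(alphabet, size=k_s, replace=False))
        prods = set(rng.choice(alphabet, size=k_p, replace=False)) if k_p else set()
        if not subs | prods:
            subs = {alphabet[0]}
        reactions.append(Reaction(f"r{i}", frozenset(subs), frozenset(prods)))
    return ReactionDataset(f"rand", "individual", reactions)
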