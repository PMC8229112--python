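import numpy as np
import pytest

from lesiondag import SyntheticImageSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticImageSpec:
    """A tiny but fully separable three-class image spec."""
    return SyntheticImageSpec(n_per_class=(5, 5, 5), image_size=(32, 32), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_score_set(rng: np.random.Generator, K: int):
    """A random complete PairwiseScoreSet over K classes."""
    from lesiondag import PairwiseScoreSet

    scores = {}
    for i in range(K):
        for j in range(i + 1, K):
            p = float(rng.uniform(0.0, 1.0))
            scores[(i, j)] = (p, 1.0 - p)
    return PairwiseScoreSet(scores=scores)


def condorcet_score_set(rng: np.random.Generator, K: int):
    """A random score set with a forced Condorcet winner; returns (set, winner)."""
    from lesiondag import PairwiseScoreSet

    winner = int(rng.integers(K))
    scores = {}
    for i in range(K):
        for j in range(i + 1, K):
            if winner in (i, j):
                p_win = float(rng.uniform(0.501, 1.0))
                scores[(i, j)] = (p_win, 1.0 - p_win) if winner == i else (1.0 - p_win, p_win)
            else:
                p = float(rng.uniform(0.0, 1.0))
                scores[(i, j)] = (p, 1.0 - p)
    return PairwiseScoreSet(scores=scores), winner


def ddag_oracle(score_set, class_order) -> int:
    """Independent sequential-champion formulation of the DDAG elimination.

    Comparing the first two classes of the remaining list and dropping the
    loser is equivalent to a left fold: the current champion plays the next
    class in the order, ties survive to the smaller index.
    """
    champion = class_order[0]
    for challenger in class_order[1:]:
        p_champ = score_set.confidence(champion, challenger)
        p_chall = score_set.confidence(challenger, champion)
        if p_chall > p_champ:
            champion = challenger
        elif p_chall == p_champ:
            champion = min(champion, challenger)
    return champion
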