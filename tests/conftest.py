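import numpy as np
import pytest

from relclock import simulate, treeio


@pytest.fixture
def balanced4():
    """Clock-like 4-taxon tree."""
    return treeio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def uneven4():
    """4-taxon tree with one accelerated terminal branch (A)."""
    return treeio.read_newick("((A:2,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar4():
    return treeio.read_newick("(((A:1,B:1):1,C:2):1,D:3);")


def random_timetrees(n_trees, n_tips_range=(4, 12), seed=0):
    """Seeded stream of birth-death timetrees (root age 1)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n_tips = int(rng.integers(*n_tips_range))
        cfg = simulate.SimulationConfig(n_tips=n_tips, root_age=1.0,
                                        seed=int(rng.integers(2**31)))
        yield simulate.simulate_timetree(cfg)


def clock_tree(n_tips, seed, rate=1.0):
    """Phylogeny whose branch lengths are exactly rate x duration."""
    cfg = simulate.SimulationConfig(n_tips=n_tips, root_age=1.0, seed=seed,
                                    clock="strict", noise="none")
    truth = simulate.simulate_dataset(cfg)
    lengths = truth.true_lengths * rate
    tree = truth.timetree.tree.with_lengths(np.nan_to_num(lengths))
    tree.branch_length[treeio.ROOT] = np.nan
    return tree, truth.timetree
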