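import numpy as np
import pandas as pd
import pytest

import ppmbite as pb


@pytest.fixture(scope="session")
def three_tip_tree():
    return pb.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sim_59():
    """One seeded 59-tip fossil-style dataset, shared across tests."""
    spec = pb.SimSpec(n_tips=59, tree_style="fossil", seed=11)
    tree = pb.simulate_tree(spec)
    data, truth = pb.simulate_dataset(tree, spec)
    return tree, data, truth


@pytest.fixture(scope="session")
def fitted_59(sim_59):
    tree, data, truth = sim_59
    posterior = pb.fit_ppm(tree, data, pb.McmcConfig(seed=5))
    return tree, data, truth, posterior


def star_tree(n: int, depth: float = 1.0) -> pb.TimeTree:
    tips = ",".join(f"t{i}:{depth}" for i in range(1, n + 1))
    return pb.parse_newick(f"({tips});")


@pytest.fixture(scope="session")
def star_20():
    return star_tree(20)
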