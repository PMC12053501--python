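import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plastaudit import SimulationConfig, simulate_cohort, simulate_tree


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """8-tip cohort with all four states planted; returns
    (tree, config, genbank paths, truth table)."""
    tree = simulate_tree(8, seed=11)
    tips = tree.tip_names
    config = SimulationConfig(
        genes=(("ndhE", 306), ("ndhJ", 477), ("ndhB", 2241)),
        tree_seed=11,
        mutation_seed=11,
        state_scenario=(
            ((tips[0], tips[1]), "ndhE", "lost"),
            (tips[2], "ndhJ", "truncated"),
            (tips[3], "ndhB", "pseudogenized"),
        ),
        ir_duplicate_genes=("ndhB",),
    )
    out = tmp_path_factory.mktemp("small_cohort")
    paths, truth = simulate_cohort(tree, config, out)
    return tree, config, paths, truth


@pytest.fixture()
def rng():
    return random.Random(20240901)
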