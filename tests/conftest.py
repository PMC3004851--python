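import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from airmic.io import CountTable
from airmic.simulate import SimulationDesign, simulate_bundle


@pytest.fixture(scope="session")
def four_tip_tree() -> TreeNode:
    from io import StringIO

    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def four_tip_table() -> CountTable:
    counts = pd.DataFrame(
        [[1, 1, 0, 0], [0, 0, 1, 1], [5, 0, 0, 0], [0, 0, 3, 0], [2, 2, 0, 0]],
        index=["ab", "cd", "a_only", "c_only", "ab2"],
        columns=list("ABCD"),
    )
    return CountTable(counts)


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete simulated study shared across tests."""
    design = SimulationDesign(
        n_subjects_per_group=(12, 12),
        n_taxa=80,
        n_genera=16,
        depth_mean=800.0,
        depth_sd=200.0,
        seed=20260930,
    )
    return design, simulate_bundle(design)
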