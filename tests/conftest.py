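import numpy as np
import pytest

from ampliconbench.core import CountTable, PhyloTree
from ampliconbench.spike import LabelAssignment
from ampliconbench.synth import SynthConfig, generate_table

import skbio
import io


# 12 OTUs x 6 samples; used for frozen cross-implementation checks
ORACLE_COUNTS = np.array([
    [50, 40, 30, 60, 55, 45],
    [37, 19, 21, 8, 0, 29],
    [0, 9, 10, 0, 0, 73],
    [22, 26, 60, 0, 0, 0],
    [0, 29, 7, 12, 36, 0],
    [22, 0, 0, 55, 74, 33],
    [35, 64, 0, 2, 6, 32],
    [37, 14, 0, 25, 0, 39],
    [32, 0, 36, 13, 29, 76],
    [21, 0, 0, 0, 0, 27],
    [0, 19, 45, 29, 41, 4],
    [33, 0, 22, 0, 0, 0],
])

ORACLE_TREE_NEWICK = (
    "(((((O0:0.41441876076746015,O1:0.41441876076746015):0.21661522741886338,"
    "O2:0.6310339881863235):1.1895600077274808,O3:1.8205939959138042)"
    ":0.42339932478254355,O4:2.243993320696348):1.1136440497756903,"
    "(((((O5:0,O6:0):0.5188412242380477,O7:0.5188412242380477)"
    ":0.39715991875388607,O8:0.9160011429919337):0.27428832323420976,"
    "(O9:0.6633638594797192,O10:0.6633638594797192):0.5269256067464243)"
    ":1.044739053243435,O11:2.2350285194695787):1.1226088510024597);"
)


@pytest.fixture
def tiny_table():
    """The 3x2 example table: library sizes [3, 6]."""
    return CountTable(["a", "b", "c"], ["s1", "s2"],
                      np.array([[2, 0], [0, 5], [1, 1]]))


@pytest.fixture
def oracle_table():
    return CountTable([f"O{i}" for i in range(12)],
                      [f"S{j}" for j in range(6)], ORACLE_COUNTS)


@pytest.fixture
def oracle_tree():
    return PhyloTree(skbio.TreeNode.read(io.StringIO(ORACLE_TREE_NEWICK)))


@pytest.fixture(scope="session")
def small_synth():
    """A 120 OTU x 40 sample synthetic table shared across tests."""
    return generate_table(SynthConfig(n_otus=120, n_samples=40, seed=11))


def make_labels(table, case_mask):
    case_mask = np.asarray(case_mask, dtype=bool)
    return LabelAssignment(list(table.sample_ids), case_mask,
                           float(case_mask.mean()), seed=0)


@pytest.fixture
def labels_factory():
    return make_labels
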