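from __future__ import annotations

import numpy as np
import pytest

from tehorizon.timetree import TimeTree
from tehorizon.synthetic_data import random_ultrametric_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20230614)


@pytest.fixture(scope="session")
def tree64():
    """A fixed random 64-tip ultrametric tree, 100 My deep."""
    return TimeTree(random_ultrametric_newick(64, 100.0, seed=64))


@pytest.fixture
def small_tree():
    return TimeTree("((A:1,B:1):1,C:2);")


RM_OUT_FIXTURE = """\
   SW   perc perc perc  query     position in query    matching repeat
score   div. del. ins.  sequence  begin end   (left)   repeat   class/family begin end (left) ID

 1306 12.50 0.00 0.00 scf1 100 199 (0) + cons1 LINE/CR1 1 100 (0) 1
  900  5.00 0.10 0.00 scf1 300 899 (0) C cons2 DNA/TcMar 1 600 (0) 2
  800  1.20 0.00 0.00 scf2 1000 1499 (0) + cons3 LTR/Gypsy 1 500 (0) 3
  500 22.10 0.00 0.00 scf2 2000 2099 (0) + (TA)n Simple_repeat 1 100 (0) 4
  450  9.90 0.00 0.00 scf3 10 409 (0) + cons4 Unknown 1 400 (0) 5
"""


@pytest.fixture
def rm_out_file(tmp_path):
    path = tmp_path / "speciesX.out"
    path.write_text(RM_OUT_FIXTURE)
    return path
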