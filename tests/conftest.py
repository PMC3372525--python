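import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import longsel as ls


@pytest.fixture(scope="session")
def b80():
    return ls.load_builtin_matrix("BLOSUM80")


@pytest.fixture(scope="session")
def b62():
    return ls.load_builtin_matrix("BLOSUM62")


@pytest.fixture()
def three_tip_tree():
    return ls.PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);", "time")


@pytest.fixture()
def star_tree():
    return ls.PhylogeneticTree.from_newick("(A:2,B:2,C:2,D:2);", "time")


def make_panel(msa: dict[str, str], aln_id: str = "toy") -> ls.AlignmentPanel:
    return ls.AlignmentPanel({aln_id: msa})


@pytest.fixture()
def make_panel_f():
    return make_panel
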