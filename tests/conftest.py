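import dendropy
import pytest

from secal.io import _timetree_from_dendropy
from secal.pipeline import preset, run_experiment
from secal.seqsim import HKYParams
from secal.treesim import TimeTree


def tree_from_newick(s: str) -> TimeTree:
    """Build a TimeTree from an ultrametric Newick string (test helper)."""
    dtree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    return _timetree_from_dendropy(dtree)


@pytest.fixture(scope="session")
def hky() -> HKYParams:
    return HKYParams(kappa=2.0, freqs=(0.30, 0.26, 0.23, 0.21))


@pytest.fixture
def balanced4() -> TimeTree:
    return tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def ladder4() -> TimeTree:
    return tree_from_newick("(((a:1,b:1):1,c:2):1,d:3);")


@pytest.fixture(scope="session")
def experiment_result():
    """One full scaled-down run of the four-arm experiment, shared by the
    acceptance tests (uniform/normal/two-node/relaxed secondary analyses
    against a 120-tip primary study)."""
    return run_experiment(preset("test", master_seed=1))
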