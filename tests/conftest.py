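import pytest
import dendropy

from naturadist.phylo import TreeIndex
from naturadist.pipeline import PipelineConfig, run_pipeline
from naturadist.synthetic_world import WorldConfig, simulate_world


@pytest.fixture(scope="session")
def toy_tree():
    """((A:1,B:1):1,C:2); — the hand-checkable three-tip tree."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def toy_index(toy_tree):
    return TreeIndex(toy_tree)


@pytest.fixture(scope="session")
def small_world():
    """A small but fully featured synthetic world shared across tests."""
    cfg = WorldConfig(n_regions=25, n_cells_per_region=8, n_species=80, seed=3)
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One default-configuration pipeline run (the package's demo world)."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(seed=11, bootstrap_reps=5, bootstrap_size=3000)
    run_pipeline(cfg, out)
    return out
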