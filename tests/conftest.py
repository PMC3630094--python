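import pytest

import opsinphylo as op


@pytest.fixture(scope="session")
def tree():
    """The composite whale/hippo/bovid species tree."""
    return op.composite_tree()


@pytest.fixture(scope="session")
def fixture_genes():
    """The packaged three-gene synthetic history at a fixed seed."""
    return op.opsin_history_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Fixture materialized as files, with a ready-to-run config."""
    outdir = tmp_path_factory.mktemp("fixture")
    op.write_fixture(outdir, seed=1)
    return outdir


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir):
    """One full pipeline run over the three simulated genes (shared: the
    ancestral-reconstruction stage dominates runtime)."""
    config = op.RunConfig.load(fixture_dir / "config.yaml")
    result = op.run_pipeline(config)
    assert result.ok, {g.gene: g.error for g in result.genes.values()}
    return result


def in_subtree(tree, nid, top) -> bool:
    """True when nid lies in the subtree rooted at top (inclusive)."""
    while nid is not None:
        if nid == top:
            return True
        nid = tree.nodes[nid].parent
    return False
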