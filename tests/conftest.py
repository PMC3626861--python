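import pandas as pd
import pytest

from co_atlas import fixtures
from co_atlas.network import InteractionNetwork, fuse_networks


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The emitted study-table fixture bundle, written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return fixtures.emit_paper_fixtures(out)


def edges_frame(pairs, scores=None, source=None) -> pd.DataFrame:
    data = {"gene_a": [a for a, _ in pairs], "gene_b": [b for _, b in pairs]}
    if scores is not None:
        data["score"] = scores
    if source is not None:
        data["source"] = [source] * len(pairs)
    return pd.DataFrame(data)


def make_network(pairs, scores=None) -> InteractionNetwork:
    return fuse_networks([edges_frame(pairs, scores=scores)], ["test"])


@pytest.fixture
def path_graph() -> InteractionNetwork:
    return make_network([("A", "B"), ("B", "C"), ("C", "D")])
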