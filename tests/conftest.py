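import pytest

from strongpaths import ConfidenceNetwork


@pytest.fixture
def triangle() -> ConfidenceNetwork:
    """A->B 0.9, B->C 0.9, A->C 0.7: the two-hop detour wins under D=0.95."""
    return ConfidenceNetwork(
        directed=True,
        labels=["A", "B", "C"],
        edges={(0, 1): 0.9, (1, 2): 0.9, (0, 2): 0.7},
    )


@pytest.fixture
def diamond() -> ConfidenceNetwork:
    """A->X->B at 0.9 and A->Y->B at 0.8: distinct dual lengths for V_eps."""
    return ConfidenceNetwork(
        directed=True,
        labels=["A", "X", "Y", "B"],
        edges={(0, 1): 0.9, (1, 3): 0.9, (0, 2): 0.8, (2, 3): 0.8},
    )


@pytest.fixture
def annotation_file(tmp_path):
    path = tmp_path / "nodes.tsv"
    path.write_text("TP53\tP04637,p53\nMDM2\tQ00987\n", encoding="utf-8")
    return path


@pytest.fixture
def network_file(tmp_path):
    path = tmp_path / "net.tsv"
    path.write_text("A\tB\t0.9\nB\tC\t0.8\n", encoding="utf-8")
    return path
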