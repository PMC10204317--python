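import io

import pytest

import graphloci as gl


@pytest.fixture(scope="session")
def truth7() -> gl.TruthSet:
    """The default desk-scale simulation: 200 kb, 5 assemblies, 20 TR loci."""
    return gl.simulate(gl.default_spec(seed=7))


@pytest.fixture(scope="session")
def base_graph(truth7):
    graph, _ = gl.build_graph(truth7, level="base")
    return graph


@pytest.fixture(scope="session")
def sv_bundle(truth7):
    """(graph, per-assembly call records) at SV resolution."""
    return gl.build_graph(truth7, level="sv")


@pytest.fixture()
def tiny_gfa_text() -> str:
    return (
        "H\tVN:Z:1.0\n"
        "S\ts1\tACGT\tSN:Z:ref#0#chr1\tSO:i:0\tSR:i:0\n"
        "S\ts2\tGGTT\tSN:Z:ref#0#chr1\tSO:i:4\tSR:i:0\n"
        "L\ts1\t+\ts2\t+\t0M\n"
        "P\tref\ts1+,s2+\t*\n"
    )


@pytest.fixture()
def tiny_graph(tiny_gfa_text) -> gl.Graph:
    return gl.parse_gfa(io.StringIO(tiny_gfa_text))
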