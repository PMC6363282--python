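import math

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from epareg.model_io import hrbc_fixture, read_tsv
from epareg.pipeline import build_context


@pytest.fixture(scope="session")
def hrbc():
    net, regulated, currency = hrbc_fixture()
    return net, regulated, currency


@pytest.fixture(scope="session")
def hrbc_ctx(hrbc):
    net, _, _ = hrbc
    return build_context(net)


@pytest.fixture(scope="session")
def hrbc_em_ctx(hrbc):
    net, _, _ = hrbc
    return build_context(net, basis="elementary_mode")


@pytest.fixture()
def chain_net(tmp_path):
    """EX_A -> A -> B -> EX_B, all irreversible: exactly one route."""
    p = tmp_path / "chain.tsv"
    p.write_text("EX_A: -> A\nR1: A -> B\nEX_B: B ->\n")
    return read_tsv(p)


@pytest.fixture()
def branched_net(tmp_path):
    """Two routes from A to C plus a reversible pair, small enough for
    brute-force oracles."""
    p = tmp_path / "branch.tsv"
    p.write_text(
        "EX_A: -> A\n"
        "R1: A -> B\n"
        "R2: B <-> C\n"
        "R3: A -> C\n"
        "EX_C: C ->\n"
    )
    return read_tsv(p)
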