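import numpy as np
import pytest

from motiffold.grammar import build_layer_grammar, build_r3d_grammar, build_rbgj3j4, default_params
from motiffold.motifs import expand_variants, parse_descriptor_text

TEST_LIBRARY = """
HL GNRA   L1=G Loop=N R1=RA
IL K-turn Lo= Loop1= Li=GA Ri=GA Loop2=RNN Ro=
BS CsrA   S1=AGGA
"""


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rbg(params):
    return build_rbgj3j4(params)


@pytest.fixture(scope="session")
def motif_grammar(rbg):
    """Motif-extended grammar over a compact three-motif library covering
    hairpin, internal-loop and branch-segment attachments."""
    variants = expand_variants(parse_descriptor_text(TEST_LIBRARY))
    return build_r3d_grammar(rbg, variants)


@pytest.fixture(scope="session")
def layer_grammar(params):
    return build_layer_grammar(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_stockholm(tmp_path):
    path = tmp_path / "toy.sto"
    path.write_text(
        "# STOCKHOLM 1.0\n\n"
        "seq1         GGGAAACCCA\n"
        "seq2         GGCAAAGCCA\n"
        "#=GC SS_cons <<<...>>>.\n"
        "//\n"
    )
    return path
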