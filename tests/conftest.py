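import logging

import pytest

from driveways.io_formats import MutationProfile, PPINetwork

logging.getLogger("driveways").setLevel(logging.ERROR)


@pytest.fixture
def triangle():
    """Triangle a-b-c, each gene mutated in its own single sample."""
    net = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
    prof = MutationProfile(
        {"a": {"s1"}, "b": {"s2"}, "c": {"s3"}}, {"s1", "s2", "s3"}
    )
    return net, prof


@pytest.fixture
def write_file(tmp_path):
    def _write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: depth1
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: depth2
namespace: biological_process
is_a: GO:0000002 ! depth1

[Term]
id: GO:0000004
name: depth3
namespace: biological_process
is_a: GO:0000003 ! depth2

[Term]
id: GO:0000005
name: depth4
namespace: biological_process
is_a: GO:0000004 ! depth3

[Term]
id: GO:0000006
name: depth5-a
namespace: biological_process
is_a: GO:0000005 ! depth4

[Term]
id: GO:0000008
name: depth5-b
namespace: biological_process
is_a: GO:0000005 ! depth4

[Term]
id: GO:0000009
name: depth6-a
namespace: biological_process
is_a: GO:0000006 ! depth5-a

[Term]
id: GO:0000010
name: depth6-b
namespace: biological_process
is_a: GO:0000008 ! depth5-b

[Term]
id: GO:0000011
name: depth7-diamond
namespace: biological_process
is_a: GO:0000009 ! depth6-a
is_a: GO:0000010 ! depth6-b
"""


@pytest.fixture
def toy_dag(write_file):
    import obonet

    return obonet.read_obo(write_file("toy.obo", TOY_OBO))
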