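import numpy as np
import pytest
from hypothesis import settings

import connclust as cc
from connclust.model import Connector, NeuronSkeleton, SkeletonNode

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_connectome(neurons, connectors, dcvs=(), regions=None):
    """Assemble a Connectome from terse tuples.

    neurons: (skid, class_label, side, homolog_id)
    connectors: (cid, (x, y, z), pre_skid, [post_skid, ...]); pre may be None
    dcvs: (skid, (x, y, z))
    """
    skeletons = {}
    soma = {}
    for skid, label, side, homolog in neurons:
        pos = (1000.0 * skid, 0.0, 0.0)
        soma[skid] = pos
        skeletons[skid] = NeuronSkeleton(
            skeleton_id=skid,
            name=f"n{skid}",
            class_label=label,
            side=side,
            homolog_id=homolog,
            nodes={1: SkeletonNode(1, None, pos)},
        )
    next_node = {skid: 2 for skid in skeletons}

    def new_node(skid, pos):
        nid = next_node[skid]
        next_node[skid] += 1
        skeletons[skid].nodes[nid] = SkeletonNode(nid, 1, pos)
        return nid

    conns = []
    for cid, pos, pre, posts in connectors:
        pos = tuple(float(v) for v in pos)
        pre_link = None if pre is None else (pre, new_node(pre, pos))
        post_links = tuple((t, new_node(t, pos)) for t in posts)
        conns.append(Connector(cid, pos, pre_link, post_links))
    c = cc.Connectome(
        skeletons=skeletons,
        connectors=conns,
        dcvs=[cc.DcvRecord(s, tuple(map(float, p))) for s, p in dcvs],
        regions=regions or {},
    )
    c.validate()
    return c


@pytest.fixture
def toy_connectome():
    """Hand-built microcircuit with known tallies.

    Focal homolog pair 1/2 ("hugin-PC"); partner pair 3/4 with 4 and 1
    links to the focal set, pair 5/6 with 2 and 2, unpaired neuron 7 with
    5 links, exempt sensory neuron 8 with 2 links.
    """
    neurons = [
        (1, "hugin-PC", "left", 2),
        (2, "hugin-PC", "right", 1),
        (3, "interneuron", "left", 4),
        (4, "interneuron", "right", 3),
        (5, "interneuron", "left", 6),
        (6, "interneuron", "right", 5),
        (7, "interneuron", "left", None),
        (8, "sensory-0", "medial", None),
    ]
    connectors = [
        (1, (0, 0, 0), 1, [3, 3]),
        (2, (0, 0, 1000), 3, [1, 1]),
        (3, (0, 0, 2000), 2, [4]),
        (4, (0, 0, 3000), 1, [5, 5]),
        (5, (0, 0, 4000), 2, [6, 6]),
        (6, (0, 0, 5000), 7, [1, 1, 1, 2, 2]),
        (7, (0, 0, 6000), 8, [1]),
        (8, (0, 0, 7000), 1, [8]),
    ]
    return make_connectome(neurons, connectors)


SMALL_CONFIG = cc.SynthConfig(
    seed=42,
    neurons_per_class_per_side=1,
    partner_pool_per_class=4,
    n_sensory_groups=3,
    sensory_neurons_per_group=4,
    synapses_per_sensory_neuron=10,
    partners_per_block=20,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A scaled-down synthetic connectome for fast structural tests."""
    return cc.generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def full_fixture():
    """The shipped reference configuration at the documented seed."""
    return cc.default_fixture()
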