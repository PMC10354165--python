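import numpy as np
import pytest

from cxlineage.backbone import BackboneParams, backbone_polylines, extract_backbone
from cxlineage.synth import (connector_positions_for, default_config,
                             generate_avp_scenario, generate_brain,
                             generate_fb_scenario)


@pytest.fixture(scope="session")
def small_brain():
    """Three-lineage miniature brain, 10 fibers per tract."""
    return generate_brain(default_config(seed=3, n_per_lineage=10))


@pytest.fixture(scope="session")
def avp():
    return generate_avp_scenario(seed=7)


@pytest.fixture(scope="session")
def fb():
    return generate_fb_scenario(seed=11)


@pytest.fixture(scope="session")
def fb_noiseless():
    return generate_fb_scenario(seed=11, locus_sd=0.0)


def extract_all_backbones(ds, params=None):
    """Backbone polylines + soma positions for every neuron of a dataset."""
    p = params or BackboneParams()
    backbones, somas, results = {}, {}, {}
    for nid, skel in ds.skeletons.items():
        pos = connector_positions_for(ds.connectors, nid)
        res = extract_backbone(skel, pos, p)
        results[nid] = res
        backbones[nid] = backbone_polylines(skel, res)
        somas[nid] = skel.soma_position()
    return backbones, somas, results


@pytest.fixture(scope="session")
def small_brain_backbones(small_brain):
    return extract_all_backbones(small_brain)
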