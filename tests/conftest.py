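import pytest

import fluvialnet as fn


def records_for(segments, **kwargs):
    """Topology + attribute emission in one step (the standard conversion)."""
    _, incidences = fn.build_junctions(segments)
    inc = {i.seg_id: (i.from_node, i.to_node) for i in incidences}
    return fn.to_osm_records(segments, inc, **kwargs)


@pytest.fixture
def y_segments():
    return fn.y_network()


@pytest.fixture
def y_records(y_segments):
    return records_for(y_segments)


@pytest.fixture
def archipelago_fixture():
    """Rivers, roads, facilities and ground-truth labels for the mixed scenario."""
    return fn.archipelago(seed=0)
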