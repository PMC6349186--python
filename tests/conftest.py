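import pytest

from cernapath.kgml import parse_kgml, reconstruct_graph
from cernapath.pipeline import PipelineConfig, run_from_objects
from cernapath.simulate import ScenarioSpec, make_inputs


@pytest.fixture(scope="session")
def default_bundle():
    """Default planted scenario, generated once per session."""
    return make_inputs(ScenarioSpec(seed=7))


@pytest.fixture(scope="session")
def default_graphs(default_bundle):
    return [
        reconstruct_graph(parse_kgml(text), default_bundle.id_map)
        for text in default_bundle.kgml_texts
    ]


@pytest.fixture(scope="session")
def default_result(default_bundle, default_graphs):
    """Full pipeline run on the default planted scenario."""
    return run_from_objects(
        default_graphs,
        default_bundle.target_map,
        default_bundle.expr,
        default_bundle.labels,
        PipelineConfig(seed=7),
        default_bundle.survival,
    )
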