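import pytest
from hypothesis import HealthCheck, settings

from splicescope.pipeline import RunConfig, run_pipeline
from splicescope.synthetic_data import SimulationConfig, generate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# one fixed synthetic study shared by the whole suite; the seed is part of
# the study conditions, not a tunable
BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic study bundle (two groups x 5 samples, depth 200)."""
    root = tmp_path_factory.mktemp("bundle")
    return generate_study(SimulationConfig(seed=BUNDLE_SEED), root)


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    """Full pipeline run over the session bundle."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig.for_bundle(bundle.root, outdir, seed=BUNDLE_SEED)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def bundle_annotation(bundle):
    from splicescope.core_io import read_annotation

    return read_annotation(bundle.annotation, fasta_path=bundle.genome)


@pytest.fixture(scope="session")
def bundle_events(bundle_annotation):
    from splicescope.splice_quant import infer_events

    return {e.event_id: e for e in infer_events(bundle_annotation)}
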