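import pytest

from tilapia_gh.pipeline import RunConfig, run_pipeline
from tilapia_gh.simulate import ScenarioConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default-scenario fixture bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(ScenarioConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """A full end-to-end run on the default scenario."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(outdir, seed=7)), outdir
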