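import pytest

from splicemod import pipeline, simulate


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Small truth-annotated bundle shared by the whole session."""
    return simulate.small_fixture(tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def pipeline_result(fixture_bundle):
    cfg = pipeline.PipelineConfig(
        bundle_dir=fixture_bundle.out_dir,
        out_dir=fixture_bundle.out_dir / "out",
    )
    return pipeline.run_all(cfg)
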