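import pytest

from lnckit import pipeline, synthetic
from lnckit.pipeline import PipelineOptions, SampleInput


@pytest.fixture(scope="session")
def truth():
    """Default synthetic bundle: 3 samples, planted novels + decoys."""
    return synthetic.generate()


@pytest.fixture(scope="session")
def samples(truth):
    return [SampleInput(sid, truth.assembled[sid], truth.fragments[sid])
            for sid in truth.params.sample_ids]


@pytest.fixture(scope="session")
def scorers(truth):
    return pipeline.train_scorers_from_annotation(truth.known, truth.genome, seed=0)


@pytest.fixture(scope="session")
def pipeline_result(truth, samples, scorers):
    return pipeline.run_pipeline(truth.known, truth.repeats, samples,
                                 genome=truth.genome, scorers=scorers,
                                 options=PipelineOptions(mode="stranded"))


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
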