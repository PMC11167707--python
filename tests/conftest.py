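import numpy as np
import pytest

import cernet


@pytest.fixture(scope="session")
def default_truth_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort (seed 7)."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = cernet.PipelineConfig(
        outdir=str(out), seed=7, simulate=cernet.default_config(seed=7)
    )
    report = cernet.run_pipeline(cfg)
    truth = cernet.TruthSet.from_json((out / "inputs" / "truth.json").read_text())
    return cfg, report, truth, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
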