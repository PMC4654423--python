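import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def survey_run(tmp_path_factory):
    """One survey-shaped dataset, run through the pipeline twice.

    Returns (dataset, outdir_first, outdir_second); the two runs use the
    same config so their summaries must be byte-identical.
    """
    from wrky.pipeline import PipelineConfig, run_survey
    from wrky.synthetic_data import paper_shaped

    base = tmp_path_factory.mktemp("survey")
    data = base / "data"
    dataset = paper_shaped(seed=7)
    dataset.write(data)

    outs = []
    for tag in ("run1", "run2"):
        out = base / tag
        cfg = PipelineConfig(
            proteins=str(data / "proteins.fa"),
            gff=str(data / "genes.gff3"),
            genome=str(data / "genome.fa"),
            cds=str(data / "cds.fa"),
            counts=str(data / "counts.tsv"),
            ct=str(data / "ct.tsv"),
            outdir=str(out),
            seed=7,
            bootstrap=0,
        )
        run_survey(cfg)
        outs.append(out)
    return dataset, outs[0], outs[1]
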