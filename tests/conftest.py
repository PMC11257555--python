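import pathlib

import pandas as pd
import pytest

from pedcns.fixtures import generate_cohort
from pedcns.pipeline import run_pipeline


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """One generated fixture cohort shared across the session."""
    d = tmp_path_factory.mktemp("cohort") / "in"
    cohort = generate_cohort(d, seed=11)
    return cohort


@pytest.fixture(scope="session")
def pipeline_out(cohort_dir, tmp_path_factory):
    """Pipeline outputs for the shared cohort."""
    out = tmp_path_factory.mktemp("cohort_out")
    manifest = run_pipeline(cohort_dir.directory, out)
    return out, manifest


def read_tsv(path):
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
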