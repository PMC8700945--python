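import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from zratio import ExpressionMatrix, SampleMetadata, make_fixture_files

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The small fixed-seed fixture files (series matrix, metadata, annotations)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixture_files(outdir, seed=7)


@pytest.fixture
def random_matrix():
    """A seeded 20-gene x 10-sample log2 matrix with metadata, half DS half control."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8.0, 1.5, (20, 10)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{j:02d}" for j in range(10)],
    )
    matrix = ExpressionMatrix(values, scale_tag="log2")
    metadata = [
        SampleMetadata(
            f"s{j:02d}",
            "DS" if j < 5 else "control",
            "HIP",
            20.0 + (j % 5),
            "Y",
            "F" if j % 2 else "M",
        )
        for j in range(10)
    ]
    return matrix, metadata
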