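import hypothesis
import pandas as pd
import pytest

from luadsig.datasets import load_table1_de, load_table1_evidence

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_de():
    return load_table1_de()


@pytest.fixture(scope="session")
def table1_ev():
    return load_table1_evidence()


def make_plate(rows):
    """Plate table from (cell_line, target, sirna_id, replicate_id, count) tuples."""
    return pd.DataFrame(
        rows, columns=["cell_line", "target", "sirna_id", "replicate_id", "nuclei_count"]
    )


@pytest.fixture
def plate_builder():
    return make_plate
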