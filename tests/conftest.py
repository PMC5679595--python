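import numpy as np
import pandas as pd
import pytest

from isescreen.descriptors import compute_descriptors
from isescreen.synthetic import PlantedSpec, generate_planted, toy_records


@pytest.fixture(scope="session")
def toy_recs():
    return toy_records()


@pytest.fixture(scope="session")
def toy_table(toy_recs):
    return compute_descriptors(toy_recs)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset shared by cheap algorithm tests."""
    table, labels, truth = generate_planted(
        PlantedSpec(n_active=80, n_inactive=400, d_informative=2, d_noise=4, seed=7)
    )
    return table, labels, truth


@pytest.fixture
def smi_file(tmp_path):
    p = tmp_path / "mols.smi"
    p.write_text(
        "CCO ethanol\n"
        "C1CC1 cyclopropane\n"
        "# a comment line\n"
        "\n"
        "CC(=O)O acetic acid\n"
    )
    return p
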