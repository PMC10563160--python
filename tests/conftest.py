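import pandas as pd
import pytest

from ptm_integrator import run_pipeline
from ptm_integrator.fixtures import FixtureSpec, generate
from ptm_integrator.ptms import builtin_ptm_table, table_by_name


@pytest.fixture(scope="session")
def ptm_table():
    return builtin_ptm_table()


@pytest.fixture(scope="session")
def ptm(ptm_table):
    return table_by_name(ptm_table)


@pytest.fixture(scope="session")
def e2e_paths(tmp_path_factory):
    """The bundled end-to-end synthetic data set (fixed seed)."""
    out = tmp_path_factory.mktemp("e2e")
    return generate(FixtureSpec(seed=7), out)


@pytest.fixture(scope="session")
def e2e_run(e2e_paths):
    result = run_pipeline(e2e_paths["config"])
    truth = pd.read_csv(e2e_paths["truth"], sep="\t")
    return result, truth
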