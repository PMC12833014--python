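import numpy as np
import pytest

from pvsignal import ingest, synth


@pytest.fixture(scope="session")
def study_bundle():
    """One mid-sized study-profile database shared across tests.

    Returns (config, raw tables, ground truth, cleaned database).
    """
    cfg = synth.default_config(n_cases=20_000, seed=123)
    tables, truth = synth.generate_reports(cfg)
    db = ingest.clean_pipeline(
        tables, drug_map=synth.drug_name_map(cfg.drug_catalog))
    return cfg, tables, truth, db


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
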