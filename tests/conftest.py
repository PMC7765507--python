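import numpy as np
import pandas as pd
import pytest

from neurocoopt.synthetic_data import (SimConfig, sim_annotations,
                                       sim_cellline_counts, sim_coexpression,
                                       sim_stage_counts, sim_survival)


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_ann(cfg):
    return sim_annotations(cfg)


@pytest.fixture(scope="session")
def sim_lines(cfg):
    return sim_cellline_counts(cfg)


@pytest.fixture(scope="session")
def sim_surv(cfg):
    return sim_survival(cfg, n_null_genes=20)


@pytest.fixture(scope="session")
def sim_stages(cfg):
    return sim_stage_counts(cfg)


@pytest.fixture(scope="session")
def sim_coexpr(cfg):
    return sim_coexpression(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_annotation_file(tmp_path):
    """Three well-formed rows plus one with a malformed MP id."""
    path = tmp_path / "annotations.tsv"
    rows = [
        ("Gene1", "MP:0003861", "abnormal nervous system development", "EMAPA:17544"),
        ("Gene2", "MP:0004924", "abnormal behavior", ""),
        ("Gene3", "MP:0002882", "abnormal neuron morphology", "EMAPA:17544|EMAPA:16894"),
        ("Gene4", "MP_123", "wrong separator", ""),
    ]
    frame = pd.DataFrame(rows, columns=["gene_symbol", "mp_id", "mp_description",
                                        "emapa_ids"])
    frame.to_csv(path, sep="\t", index=False)
    return path
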