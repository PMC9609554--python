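import logging

import numpy as np
import pytest

from metaboselect import (
    PretreatmentConfig,
    SimulationConfig,
    assign_metabolome_labels,
    pretreat_study,
    simulate_study,
)

logging.getLogger("metaboselect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A paper-mimicking design at reduced feature count, strong markers."""
    cfg = SimulationConfig(
        n_features_pos=40, n_features_neg=40, n_markers=12,
        marker_log2_effect=2.0, seed=3,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def pretreated_small(small_study):
    pos, neg, _ = small_study
    return pretreat_study(
        pos, neg,
        PretreatmentConfig(imputation_n_estimators=30, imputation_max_iter=3),
    )


@pytest.fixture(scope="session")
def labeled_small(small_study, pretreated_small):
    res = pretreated_small
    assignment = assign_metabolome_labels(res.table_scaled,
                                          raw_table=res.table_raw)
    return assignment


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
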