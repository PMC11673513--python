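import numpy as np
import pytest

import phenonet as pn

#: The study's unbalanced 2x2 design (LeanLow, LeanHigh, ObeseLow, ObeseHigh).
STUDY_CELLS = (13, 7, 20, 9)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete simulated study used across modules."""
    return pn.SimConfig(
        n_per_cell=STUDY_CELLS,
        n_features=120,
        n_qc=6,
        n_affected_bmi=15,
        n_affected_ipaq=5,
        n_affected_interaction=10,
        n_fail_rsd=20,
        effect_size=1.5,
        block_rho=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    meta, table = pn.generate_cohort(small_config)
    table = pn.add_qc_samples(table, small_config)
    return meta, table


@pytest.fixture(scope="session")
def processed_small(small_study):
    _, table = small_study
    return pn.preprocess_pipeline(table)


@pytest.fixture(scope="session")
def records_small(small_study, processed_small):
    meta, _ = small_study
    processed, _ = processed_small
    return pn.run_anova(processed, meta)


def study_factors(rng=None):
    """Factor-level arrays for the 13/7/20/9 design, optionally shuffled."""
    cells = np.repeat(list(pn.CELLS), STUDY_CELLS)
    if rng is not None:
        rng.shuffle(cells)
    bmi = np.where(
        np.char.startswith(cells.astype(str), "Obese"), "overweight_obese", "lean"
    )
    ipaq = np.where(np.char.endswith(cells.astype(str), "High"), "high", "low")
    return cells, bmi, ipaq
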