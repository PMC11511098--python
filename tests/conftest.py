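import numpy as np
import pytest

from emghoa.pipeline import extract_tables
from emghoa.synthetic_data import CohortConfig, GroupEffect, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny null-effect cohort plus its feature tables (shared, read-only)."""
    cfg = CohortConfig(
        n_healthy=6,
        n_patients=6,
        n_sensors=3,
        n_shft_tasks=4,
        n_mvc_tasks=2,
        n_grasp_tasks=2,
        task_duration_s=1.0,
        seed=11,
        effect=GroupEffect.null(),
    )
    recordings, truth = generate_cohort(cfg)
    tables = extract_tables(recordings)
    return {"config": cfg, "recordings": recordings, "truth": truth, "tables": tables}


@pytest.fixture(scope="session")
def halved_mvc_cohort():
    """Cohort where patients' maximal-effort amplitude is halved on all sensors."""
    cfg = CohortConfig(
        n_healthy=6,
        n_patients=6,
        n_sensors=2,
        n_shft_tasks=3,
        n_mvc_tasks=2,
        n_grasp_tasks=2,
        task_duration_s=1.0,
        seed=21,
        effect=GroupEffect(mvc_amplitude_scale=0.5),
    )
    recordings, truth = generate_cohort(cfg)
    tables = extract_tables(recordings)
    return {"config": cfg, "recordings": recordings, "truth": truth, "tables": tables}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
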