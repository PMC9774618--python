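import numpy as np
import pandas as pd
import pytest

import moralcan as mc
from moralcan.core import CELL_ORDER


@pytest.fixture(scope="session")
def table2_counts() -> pd.DataFrame:
    return mc.load_table2_counts()


@pytest.fixture(scope="session")
def scenario_bank() -> dict:
    return mc.load_scenario_bank()


def decisions_frame(profiles: dict, n_frameworks: int = 6,
                    accept_fn=None) -> pd.DataFrame:
    """Deterministic decisions table: one row per participant/framework/cell.

    ``profiles`` maps participant_id -> (p1, p2, p3, p4); accepts are laid
    down deterministically so that the within-cell mean equals p exactly
    (p * n_frameworks must be an integer).
    """
    rows = []
    for pid, p in profiles.items():
        for k, cell in enumerate(CELL_ORDER):
            n_accept = round(p[k] * n_frameworks)
            assert abs(n_accept - p[k] * n_frameworks) < 1e-9
            for j in range(n_frameworks):
                rows.append(
                    {
                        "participant_id": pid,
                        "framework_id": f"F{j + 1}",
                        "cell": cell.name,
                        "accept": 1 if j < n_accept else 0,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort() -> dict:
    """A small but fully structured synthetic cohort (seeded, ~150 people)."""
    cfg = mc.PopulationConfig(n_participants=150, latency_outlier_rate=0.02,
                              imc_fail_rate=0.04, seed=20240)
    return mc.generate_study2_dataset(cfg)
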