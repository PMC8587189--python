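from pathlib import Path

import numpy as np
import pytest
from scipy.optimize import brentq

import hct_options as h

DATA_DIR = Path(h.__file__).parent / "data"

# Study conditions for the parameter-recovery check: a 20,000-patient cohort
# with two independent binary factors (true hazard ratios 1.5 and 2.0, equal
# level fractions) and a baseline hazard calibrated so the cohort-level event
# risk is 0.12 at the 36-month follow-up.
RECOVERY_N = 20_000
RECOVERY_FOLLOW_UP = 36.0
RECOVERY_HRS = {"stem_cell_source": (1.0, 1.5), "conditioning": (1.0, 2.0)}
RECOVERY_COHORT_RISK = 0.12


def recovery_baseline_rate() -> float:
    """Monthly baseline rate giving the target cohort event risk at follow-up."""
    products = [
        ha * hb for ha in RECOVERY_HRS["stem_cell_source"]
        for hb in RECOVERY_HRS["conditioning"]
    ]

    def mean_risk(r0: float) -> float:
        return float(np.mean([
            1.0 - np.exp(-r0 * p * RECOVERY_FOLLOW_UP) for p in products
        ])) - RECOVERY_COHORT_RISK

    return brentq(mean_risk, 1e-8, 1.0)


def make_recovery_config(seed: int) -> h.SimConfig:
    return h.SimConfig(
        n=RECOVERY_N,
        follow_up_months=RECOVERY_FOLLOW_UP,
        baseline_rate=recovery_baseline_rate(),
        factor_specs={
            "stem_cell_source": h.FactorSpec(
                ("bone_marrow", "cord_blood"), (0.5, 0.5),
                RECOVERY_HRS["stem_cell_source"],
            ),
            "conditioning": h.FactorSpec(
                ("myeloablative", "reduced_intensity"), (0.5, 0.5),
                RECOVERY_HRS["conditioning"],
            ),
        },
        age_range=(0.0, 25.0),
        seed=seed,
        outcome="OS",
        donor_type="simulated",
    )


def recovery_combos() -> list[dict[str, str]]:
    return [
        {"stem_cell_source": s, "conditioning": c}
        for s in ("bone_marrow", "cord_blood")
        for c in ("myeloablative", "reduced_intensity")
    ]


@pytest.fixture(scope="session")
def recovery_setup():
    """Simulated registry + oracle-HR aggregation under the study conditions."""
    cfg = make_recovery_config(seed=20_160_915)
    d = h.simulate_cohort(cfg)
    cohort, hr_tables = h.aggregate_to_tables(d, 3, "oracle", cfg)
    return {"cfg": cfg, "data": d, "cohort": cohort, "hr_tables": hr_tables}


@pytest.fixture(scope="session")
def table1_cohort() -> h.CohortTable:
    return h.load_cohort_table(DATA_DIR / "matched_sibling_cohort.json")


@pytest.fixture(scope="session")
def example_registry():
    return h.load_registry(DATA_DIR / "example_registry_synthetic.json")


@pytest.fixture(scope="session")
def example_grid(example_registry) -> h.ModelGrid:
    cohort, hr_tables = example_registry
    return h.build_model_grid([cohort], hr_tables)
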