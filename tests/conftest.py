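import numpy as np
import pandas as pd
import pytest

from flcea import (
    AdverseEventRates,
    ArmRates,
    CostInputs,
    LifeTable,
    ModelConfig,
    ModelInputs,
    TrialArmData,
    UtilityInputs,
    fixture_inputs,
)


def flat_life_table(qx: float, start: int = 40, end: int = 100,
                    sex: str = "male") -> LifeTable:
    """Life table with a constant annual death probability at every age."""
    ages = np.arange(start, end + 1)
    return LifeTable(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))


@pytest.fixture(scope="session")
def base_inputs() -> ModelInputs:
    """The packaged base-case parameter set."""
    return fixture_inputs()


@pytest.fixture
def immortal_inputs() -> ModelInputs:
    """Three-strategy inputs with zero background mortality and a single
    shared set of disease rates — handy for symmetry and closed-form checks."""
    arms = {
        name: TrialArmData(name, n=100, progressions=20, transformations=5,
                           deaths=5, median_followup=10.0)
        for name in ("RT", "RT+CVP", "RT+R-CVP")
    }
    return ModelInputs(
        config=ModelConfig(),
        costs=CostInputs(),
        utilities=UtilityInputs(),
        arms=arms,
        adverse_events={name: AdverseEventRates() for name in arms},
        life_table=flat_life_table(0.0),
        post_failure_death_rate=0.02,
    )


def absorbing_ffs_inputs(discount_rate: float = 0.0,
                         u_ffs: float = 0.88) -> ModelInputs:
    """Degenerate model: nobody ever leaves FFS, no treatment effects."""
    arms = {
        "RT": TrialArmData("RT", n=100, progressions=0, transformations=0,
                           deaths=0, median_followup=10.0)
    }
    return ModelInputs(
        config=ModelConfig(discount_rate=discount_rate),
        costs=CostInputs(
            rt_simulation=0, rt_planning=0, rt_fraction=0, rt_verification=0,
            drug_rituximab=0, drug_rcvp=0, drug_cvp=0, drug_rchop=0,
            day_care=0, asct=0, adverse_event_admission=0, pegfilgrastim=0,
        ),
        utilities=UtilityInputs(u_ffs=u_ffs, u_progressed=0.74,
                                d_rt=0, d_systemic=0, d_asct=0),
        arms=arms,
        adverse_events={"RT": AdverseEventRates()},
        life_table=flat_life_table(0.0),
        post_failure_death_rate=0.0,
    )
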