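"""Shared fixtures: synthetic bundles and small closed-form toy models."""

import numpy as np
import pytest

from pdl1_impact.cohort_engine import MixSlice
from pdl1_impact.param_model import (
    ArmTransitionModel,
    Demographics,
    LifeTable,
    ModelConfig,
    Stratum,
    SurvivalSpec,
    Tumor,
)
from pdl1_impact.synthetic_data import DEMO_SEED, generate_parameter_set


@pytest.fixture(scope="session")
def demo_bundle():
    return generate_parameter_set(DEMO_SEED)


def make_zero_life_table():
    """No background mortality below the closing row."""
    q = np.zeros(101)
    q[-1] = 1.0
    return LifeTable(q_female=q.copy(), q_male=q.copy())


@pytest.fixture(scope="session")
def zero_life_table():
    return make_zero_life_table()


@pytest.fixture
def demographics():
    return Demographics(mean_entry_age=30.0, fraction_female=0.5, mean_weight_kg=75.0)


@pytest.fixture
def config():
    return ModelConfig()


# exact zero-hazard law (degenerate hazard-ratio limit)
ZERO = SurvivalSpec("exponential", (1.0,), hazard_ratio=0.0)


def toy_arm(
    rf_to_lr=ZERO,
    rf_to_met=ZERO,
    rf_to_death=ZERO,
    lr_to_met=ZERO,
    lr_to_death=ZERO,
    m1l_to_m2l=None,
    m1l_to_death=None,
    m2l_to_death=ZERO,
    tumor=Tumor.MELANOMA,
    arm_label="toy",
):
    """Single-1L-treatment arm with near-zero defaults for unused exits."""
    return ArmTransitionModel(
        tumor=tumor,
        arm_label=arm_label,
        rf_to_lr=rf_to_lr,
        rf_to_met=rf_to_met,
        rf_to_death=rf_to_death,
        lr_to_met=lr_to_met,
        lr_to_death=lr_to_death,
        m1l_to_m2l=m1l_to_m2l or {"tx": ZERO},
        m1l_to_death=m1l_to_death or {"tx": ZERO},
        m2l_to_death=m2l_to_death,
    )


def toy_mixes(labels_1l=("tx",), labels_2l=("tx2",)):
    mix1 = {lab: 1.0 / len(labels_1l) for lab in labels_1l}
    mix2 = {lab: 1.0 / len(labels_2l) for lab in labels_2l}
    return MixSlice(
        mix_1l={s: dict(mix1) for s in Stratum},
        mix_2l={s: dict(mix2) for s in Stratum},
    )
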