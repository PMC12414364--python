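import pytest

from calfsim.engine import Scenario
from calfsim.intake import LiquidDiet, MilkPlan
from calfsim.starter_energy import StarterComposition, StarterForm


@pytest.fixture
def liquid_diet() -> LiquidDiet:
    return LiquidDiet(dm_fraction=0.125, me_density=4.6, cost_per_litre=0.45)


@pytest.fixture
def starter() -> StarterComposition:
    # CP .22, NDF .15, fat .04, ash .07 -> NFC .52 on a DM basis
    return StarterComposition(
        dm_fraction=0.90,
        cp_fraction=0.22,
        ndf_fraction=0.15,
        fat_fraction=0.04,
        ash_fraction=0.07,
        form=StarterForm.TEXTURIZED,
        cost_per_kg=0.50,
    )


@pytest.fixture
def milk_plan() -> MilkPlan:
    return MilkPlan(allowance_by_day=[(1, 6.0), (43, 3.0)], weaning_age=56)


@pytest.fixture
def scenario(liquid_diet, starter, milk_plan) -> Scenario:
    return Scenario(
        initial_bw=40.0,
        temperature=20.0,
        liquid=liquid_diet,
        starter=starter,
        plan=milk_plan,
        horizon=70,
        label="base",
    )


def make_scenario(**overrides) -> Scenario:
    """Build a valid scenario with selective overrides (plan pieces included)."""
    plan_kwargs = {"allowance_by_day": [(1, 6.0)], "weaning_age": 56}
    plan_kwargs.update(overrides.pop("plan_kwargs", {}))
    kwargs = {
        "initial_bw": 40.0,
        "temperature": 20.0,
        "plan": MilkPlan(**plan_kwargs),
        "horizon": 70,
        "label": "s",
    }
    kwargs.update(overrides)
    return Scenario(**kwargs)
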