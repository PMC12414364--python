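"""Liquid-diet consumption and starter (solid feed) intake prediction.

Liquid allowances are assumed fully consumed up to a physiologic ceiling of
14 L/d (ad libitum milk-fed calves do not exceed this volume).  Starter
intake is predicted by two empirical regressions — one for temperate
conditions (ambient temperature <= 35 degC) and one for semitropical
conditions (> 35 degC) — as functions of body weight, ME intake from the
liquid diet (MEiLD, Mcal/d) and time since starter was first offered
(FPstarter).

A note on the FPstarter unit: the regressions' source declares days, but at
day scale the temperate quadratic term dominates within two weeks and
yields implausible intakes (tens of kg/d by weaning).  The coefficient
magnitudes are biologically plausible at week scale, so this package
measures FPstarter in weeks by default (days since first offer / 7); an
``fp_unit`` switch preserves the literal day-scale reading for anyone who
wants it.
"""

from __future__ import annotations

import enum
from typing import Literal

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "LiquidDietKind",
    "LiquidDiet",
    "MilkPlan",
    "StarterIntakeInputs",
    "LIQUID_INTAKE_CAP_L",
    "STARTER_EQUATION_SWITCH_C",
    "liquid_consumed",
    "liquid_dm_and_me",
    "starter_intake_temperate",
    "starter_intake_semitropical",
    "select_starter_equation",
]

#: Biologically relevant maximum daily liquid consumption, L/d.
LIQUID_INTAKE_CAP_L = 14.0

#: Ambient temperature above which the semitropical starter equation applies.
STARTER_EQUATION_SWITCH_C = 35.0

#: Approximate density of whole milk, kg/L (converts DM fraction to kg DM/L).
WHOLE_MILK_DENSITY_KG_PER_L = 1.03


class LiquidDietKind(str, enum.Enum):
    WHOLE_MILK = "whole_milk"
    MILK_REPLACER = "milk_replacer"


class LiquidDiet(BaseModel):
    """Composition and cost of the liquid diet (whole milk or milk replacer).

    ``solids_per_litre`` (kg DM/L) is derived if not given: whole milk uses
    DM fraction x a 1.03 kg/L density; milk replacer uses the declared
    mixing rate (g powder/L).
    """

    kind: LiquidDietKind = LiquidDietKind.WHOLE_MILK
    dm_fraction: float = Field(gt=0.0, lt=1.0, default=0.125)
    me_density: float = Field(gt=0.0, default=4.6, description="Mcal/kg DM")
    cost_per_litre: float = Field(ge=0.0, default=0.45)
    mixing_rate_g_per_l: float | None = Field(default=None, gt=0.0)
    solids_per_litre: float | None = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _derive_solids(self) -> "LiquidDiet":
        if self.solids_per_litre is None:
            if self.kind is LiquidDietKind.MILK_REPLACER:
                rate = self.mixing_rate_g_per_l
                if rate is None:
                    raise ValueError(
                        "milk replacer requires mixing_rate_g_per_l (g powder/L) "
                        "or an explicit solids_per_litre"
                    )
                object.__setattr__(self, "solids_per_litre", rate / 1000.0)
            else:
                object.__setattr__(
                    self,
                    "solids_per_litre",
                    self.dm_fraction * WHOLE_MILK_DENSITY_KG_PER_L,
                )
        return self


class MilkPlan(BaseModel):
    """Daily liquid-diet allowance schedule until weaning.

    ``allowance_by_day`` is a stepwise schedule: each (day, offered L/d)
    pair applies from that day of age until the next breakpoint.  Allowance
    is forced to zero from ``weaning_age`` onward.
    """

    allowance_by_day: list[tuple[int, float]] = Field(min_length=1)
    weaning_age: int = Field(ge=10, le=120)
    first_starter_offer_day: int = Field(ge=1, default=3)

    @model_validator(mode="after")
    def _check_plan(self) -> "MilkPlan":
        days = [d for d, _ in self.allowance_by_day]
        if any(d < 1 for d in days):
            raise ValueError("plan days must be >= 1")
        if days != sorted(days) or len(set(days)) != len(days):
            raise ValueError("plan breakpoints must be strictly increasing")
        if any(v < 0 for _, v in self.allowance_by_day):
            raise ValueError("offered allowance must be non-negative")
        return self

    def offered(self, day: int) -> float:
        """Litres offered on a given day of age (0 at/after weaning)."""
        if day >= self.weaning_age:
            return 0.0
        out = 0.0
        for d, v in self.allowance_by_day:
            if day >= d:
                out = v
            else:
                break
        return out


class StarterIntakeInputs(BaseModel):
    """Inputs to the starter-intake regressions.

    ``fp_starter`` is time since starter was first offered, in the unit
    given by ``fp_unit`` (weeks by default; see module docstring).
    """

    bw: float = Field(gt=0.0)
    me_i_ld: float = Field(ge=0.0, description="ME intake from liquid diet, Mcal/d")
    fp_starter: float = Field(ge=0.0)
    temperature: float = Field(ge=-30.0, le=50.0, default=20.0)
    fp_unit: Literal["weeks", "days"] = "weeks"


def liquid_consumed(offered: float) -> float:
    """Litres actually consumed: offered, capped at 14 L/d."""
    if offered < 0:
        raise ValueError(f"offered volume must be non-negative, got {offered}")
    return min(offered, LIQUID_INTAKE_CAP_L)


def liquid_dm_and_me(consumed: float, diet: LiquidDiet) -> tuple[float, float]:
    """(DM intake kg/d, ME intake Mcal/d) from consumed litres of liquid diet."""
    if consumed < 0:
        raise ValueError(f"consumed volume must be non-negative, got {consumed}")
    dm = consumed * float(diet.solids_per_litre)
    return dm, dm * diet.me_density


def starter_intake_temperate(x: StarterIntakeInputs) -> float:
    """Predicted starter intake (g DM/d) under temperate conditions (<=35 degC).

    SI = -652.525 + 14.734*BW + 18.896*MEiLD + 73.303*FP + 13.496*FP^2
         - 29.614*FP*MEiLD, clamped at >= 0.
    """
    fp = x.fp_starter
    si = (
        -652.525
        + 14.734 * x.bw
        + 18.896 * x.me_i_ld
        + 73.303 * fp
        + 13.496 * fp**2
        - 29.614 * fp * x.me_i_ld
    )
    return max(si, 0.0)


def starter_intake_semitropical(x: StarterIntakeInputs) -> float:
    """Predicted starter intake (g DM/d) under semitropical conditions (>35 degC).

    SI = 600.053 * {1 + 14863.651 * exp(-1.553*FP)}^-1 + 9.951*BW
         - 130.434*MEiLD, clamped at >= 0.
    """
    import math

    fp = x.fp_starter
    logistic = 600.053 / (1.0 + 14863.651 * math.exp(-1.553 * fp))
    si = logistic + 9.951 * x.bw - 130.434 * x.me_i_ld
    return max(si, 0.0)


def select_starter_equation(temperature: float) -> str:
    """'semitropical' iff ambient temperature exceeds 35 degC, else 'temperate'."""
    if not (-30.0 <= temperature <= 50.0):
        raise ValueError(
            f"temperature {temperature} degC outside the acceptable range -30 to 50 degC"
        )
    return "semitropical" if temperature > STARTER_EQUATION_SWITCH_C else "temperate"


def starter_intake(x: StarterIntakeInputs) -> float:
    """Starter intake (g DM/d) via the climate-appropriate regression."""
    if select_starter_equation(x.temperature) == "semitropical":
        return starter_intake_semitropical(x)
    return starter_intake_temperate(x)
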