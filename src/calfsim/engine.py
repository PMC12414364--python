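"""Daily time-step simulation engine: state transitions, weaning, KPIs, economics.

Each simulated day proceeds in a fixed order: liquid allowance is consumed
(capped at 14 L), the climate-appropriate starter-intake regression is
evaluated, starter digestibility and ME density are computed at the current
cumulative NFC intake, the energy budget (NEM, k_m by stage, MEm, NE for
gain) is assembled, the retained-energy inverse converts net energy to
empty-body-weight gain, and body weight and cumulative NFC are updated at
day end (explicit forward recurrence).  The model is fully deterministic.

The fully-weaned equation set (EBW factor 0.85, NEM coefficient 97.0,
diet-density-dependent k_m) takes over on the first day the milk allowance
is zero at or after the declared weaning age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd
from pydantic import BaseModel, Field, ConfigDict

from calfsim import requirements as req
from calfsim import intake as intk
from calfsim import starter_energy as se
from calfsim.requirements import FeedingStage
from calfsim.intake import LiquidDiet, MilkPlan, StarterIntakeInputs
from calfsim.starter_energy import StarterComposition

__all__ = [
    "Scenario",
    "CalfState",
    "DailyRecord",
    "Trajectory",
    "KPISet",
    "step",
    "simulate",
    "kpis",
    "compare",
    "MAX_SCENARIOS",
]

MAX_SCENARIOS = 4


class Scenario(BaseModel):
    """Complete input bundle for one milk-plan simulation.

    Ranges mirror the tool's acceptable input ranges: initial BW 20-60 kg,
    ambient temperature -30 to 50 degC, weaning age 10-120 d (held on the
    plan), horizon up to 100 d.  ``k_g`` is the ME-above-maintenance to
    net-energy-for-gain efficiency (an unprinted convention, surfaced here
    deliberately).
    """

    model_config = ConfigDict(frozen=True)

    initial_bw: float = Field(ge=20.0, le=60.0)
    temperature: float = Field(ge=-30.0, le=50.0, default=20.0)
    liquid: LiquidDiet = Field(default_factory=LiquidDiet)
    starter: StarterComposition = Field(default_factory=StarterComposition)
    plan: MilkPlan
    horizon: int = Field(ge=1, le=100, default=100)
    k_g: float = Field(gt=0.0, le=1.0, default=req.DEFAULT_KG)
    fp_unit: str = Field(default="weeks", pattern="^(weeks|days)$")
    label: str = "scenario"

    @property
    def weaning_age(self) -> int:
        return self.plan.weaning_age


@dataclass
class CalfState:
    """Mutable daily recurrence state of the simulated calf."""

    day: int
    bw: float
    cum_nfc: float = 0.0
    weaned: bool = False


@dataclass(frozen=True)
class DailyRecord:
    """One simulated day: intakes, requirements, gain and cost.

    ``bw`` is end-of-day body weight (after the day's gain); ``total_dmi``
    is the sum of liquid and starter DM intake.
    """

    day: int
    bw: float
    liquid_offered: float
    liquid_consumed: float
    liquid_dm: float
    starter_dm: float
    total_dmi: float
    me_liquid: float
    me_starter: float
    me_total: float
    nem: float
    mem: float
    ne_gain: float
    ebw_gain: float
    bw_gain: float
    cum_nfc: float
    cost: float
    negative_balance: bool
    weaned: bool


Trajectory = list[DailyRecord]


@dataclass(frozen=True)
class KPISet:
    """Weaning-horizon summary indicators.

    ``age_at_15kg_nfc`` and ``cost_per_kg_gain`` are None when the calf
    never reaches 15 kg cumulative NFC / when total gain is not positive.
    """

    window: str
    final_bw: float
    adg: float
    age_at_15kg_nfc: int | None
    total_cost: float
    cost_per_kg_gain: float | None


def _stage(day: int, scenario: Scenario, offered: float) -> FeedingStage:
    # Fully weaned from the first day the allowance is zero at/after weaning age;
    # step-down milk before weaning age keeps the preweaning coefficient set.
    if day >= scenario.plan.weaning_age and offered == 0.0:
        return FeedingStage.WEANED
    return FeedingStage.PREWEANING


def step(state: CalfState, scenario: Scenario) -> tuple[CalfState, DailyRecord]:
    """Advance the simulation by one day; returns the new state and the day's record."""
    if state.day >= scenario.horizon:
        raise ValueError(f"day {state.day} already at horizon {scenario.horizon}")
    day = state.day + 1

    offered = scenario.plan.offered(day)
    consumed = intk.liquid_consumed(offered)
    liquid_dm, me_liquid = intk.liquid_dm_and_me(consumed, scenario.liquid)

    stage = _stage(day, scenario, offered)

    days_since_offer = max(0, day - scenario.plan.first_starter_offer_day)
    fp = days_since_offer / 7.0 if scenario.fp_unit == "weeks" else float(days_since_offer)
    si_inputs = StarterIntakeInputs(
        bw=state.bw,
        me_i_ld=me_liquid,
        fp_starter=fp,
        temperature=scenario.temperature,
        fp_unit=scenario.fp_unit,
    )
    starter_dm = intk.starter_intake(si_inputs) / 1000.0  # g/d -> kg/d

    dig = se.digestibilities(se.ln_ccs_nfci(state.cum_nfc), scenario.starter.form)
    me_density_starter = se.starter_me_density(scenario.starter, dig)
    me_starter = starter_dm * me_density_starter
    me_total = me_liquid + me_starter

    ebw = req.empty_body_weight(state.bw, stage)
    nem_value = req.nem(ebw, stage)
    if stage is FeedingStage.WEANED:
        k_m = req.km_weaned(me_density_starter) if me_density_starter > 0 else req.km_preweaning()
    else:
        k_m = req.km_preweaning()
    mem_value = req.mem(nem_value, k_m)
    ne_gain = (me_total - mem_value) * scenario.k_g
    ebw_gain = req.ebw_gain_from_ne(ne_gain, ebw)
    stage_factor = 0.85 if stage is FeedingStage.WEANED else 0.91
    bw_gain = ebw_gain / stage_factor

    new_bw = state.bw + bw_gain
    new_cum_nfc = se.nfc_accumulate(state.cum_nfc, starter_dm, scenario.starter)

    starter_as_fed = starter_dm / scenario.starter.dm_fraction
    cost = consumed * scenario.liquid.cost_per_litre + starter_as_fed * scenario.starter.cost_per_kg

    record = DailyRecord(
        day=day,
        bw=new_bw,
        liquid_offered=offered,
        liquid_consumed=consumed,
        liquid_dm=liquid_dm,
        starter_dm=starter_dm,
        total_dmi=liquid_dm + starter_dm,
        me_liquid=me_liquid,
        me_starter=me_starter,
        me_total=me_total,
        nem=nem_value,
        mem=mem_value,
        ne_gain=ne_gain,
        ebw_gain=ebw_gain,
        bw_gain=bw_gain,
        cum_nfc=new_cum_nfc,
        cost=cost,
        negative_balance=ne_gain < 0,
        weaned=stage is FeedingStage.WEANED,
    )
    new_state = CalfState(
        day=day,
        bw=new_bw,
        cum_nfc=new_cum_nfc,
        weaned=state.weaned or stage is FeedingStage.WEANED,
    )
    return new_state, record


def simulate(scenario: Scenario) -> Trajectory:
    """Run the full horizon; deterministic (the model has no randomness)."""
    state = CalfState(day=0, bw=scenario.initial_bw)
    trajectory: Trajectory = []
    for _ in range(scenario.horizon):
        state, record = step(state, scenario)
        trajectory.append(record)
    return trajectory


def bw_at_age(trajectory: Trajectory, scenario: Scenario, age: int) -> float:
    """Predicted BW (kg) at a given age in days (age 0 = initial BW)."""
    if age == 0:
        return scenario.initial_bw
    if age < 0 or age > len(trajectory):
        raise ValueError(f"age {age} outside the simulated horizon 0-{len(trajectory)}")
    return trajectory[age - 1].bw


def kpis(trajectory: Trajectory, scenario: Scenario, window: str = "weaning") -> KPISet:
    """Summary KPIs over a reporting window.

    ``window='weaning'`` covers days 1..weaning_age (weaning day inclusive,
    truncated to the horizon); ``'full'`` covers the whole trajectory.
    """
    if not trajectory:
        raise ValueError("trajectory is empty")
    if window == "weaning":
        end = min(scenario.plan.weaning_age, len(trajectory))
    elif window == "full":
        end = len(trajectory)
    else:
        raise ValueError(f"unknown KPI window {window!r}")
    records = trajectory[:end]

    final_bw = records[-1].bw
    elapsed = records[-1].day
    gain = final_bw - scenario.initial_bw
    adg = gain / elapsed
    total_cost = sum(r.cost for r in records)
    age_at_15 = next((r.day for r in records if r.cum_nfc >= 15.0), None)
    cost_per_kg = total_cost / gain if gain > 0 else None
    return KPISet(
        window=window,
        final_bw=final_bw,
        adg=adg,
        age_at_15kg_nfc=age_at_15,
        total_cost=total_cost,
        cost_per_kg_gain=cost_per_kg,
    )


def trajectory_frame(trajectory: Trajectory, label: str | None = None) -> pd.DataFrame:
    """Trajectory as a tidy DataFrame, one row per day."""
    df = pd.DataFrame([asdict(r) for r in trajectory])
    if label is not None:
        df.insert(0, "scenario", label)
    return df


def compare(scenarios: list[Scenario]) -> dict:
    """Simulate up to four scenarios side by side.

    Returns ``{"kpis": DataFrame, "trajectories": {label: Trajectory}}``;
    the KPI table has one column per scenario label and covers both the
    until-weaning and full-horizon windows.
    """
    if not 1 <= len(scenarios) <= MAX_SCENARIOS:
        raise ValueError(
            f"between 1 and {MAX_SCENARIOS} scenarios allowed, got {len(scenarios)}"
        )
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")

    trajectories = {s.label: simulate(s) for s in scenarios}
    rows = {}
    for s in scenarios:
        traj = trajectories[s.label]
        col = {}
        for window in ("weaning", "full"):
            k = kpis(traj, s, window=window)
            prefix = "weaning" if window == "weaning" else "full"
            col[f"{prefix}_final_bw_kg"] = k.final_bw
            col[f"{prefix}_adg_kg_d"] = k.adg
            col[f"{prefix}_total_cost"] = k.total_cost
            col[f"{prefix}_cost_per_kg_gain"] = (
                k.cost_per_kg_gain if k.cost_per_kg_gain is not None else math.nan
            )
        kw = kpis(traj, s, window="weaning")
        col["age_at_15kg_nfc_d"] = (
            kw.age_at_15kg_nfc
            if kw.age_at_15kg_nfc is not None
            else (kpis(traj, s, window="full").age_at_15kg_nfc or math.nan)
        )
        rows[s.label] = col
    table = pd.DataFrame(rows)
    return {"kpis": table, "trajectories": trajectories}
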