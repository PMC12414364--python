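"""Simulate one milk plan day by day and summarize the weaning KPIs.

A 40-kg calf on 6 L/d of whole milk, stepped down to 3 L/d two weeks
before weaning at 56 d, simulated to 80 d of age.
"""

from calfsim import MilkPlan, Scenario, kpis, simulate

scenario = Scenario(
    initial_bw=40.0,
    temperature=20.0,
    plan=MilkPlan(allowance_by_day=[(1, 6.0), (43, 3.0)], weaning_age=56),
    horizon=80,
    label="stepdown-6L",
)
trajectory = simulate(scenario)

print("day  BW(kg)  milk(L)  starter(kg DM)  ME total(Mcal)  weaned")
for day in (1, 14, 28, 42, 55, 56, 70, 80):
    r = trajectory[day - 1]
    print(
        f"{r.day:3d}  {r.bw:6.1f}  {r.liquid_consumed:7.1f}  "
        f"{r.starter_dm:14.2f}  {r.me_total:14.2f}  {r.weaned}"
    )

k = kpis(trajectory, scenario, window="weaning")
k_full = kpis(trajectory, scenario, window="full")
print(f"\nKPIs until weaning (day {scenario.plan.weaning_age}):")
print(f"  final BW          {k.final_bw:.1f} kg")
print(f"  ADG               {k.adg:.3f} kg/d")
print(f"  age at 15 kg NFC  {k_full.age_at_15kg_nfc} d  (gut maturity marker)")
print(f"  feed cost         {k.total_cost:.2f} / {k.cost_per_kg_gain:.2f} per kg gain")
print("Starter intake ramps up as milk steps down; after weaning the calf grows")
print("on solid feed alone with the weaned-stage requirement equations.")
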