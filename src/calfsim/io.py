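"""Scenario configuration parsing, trajectory/report output, logging helpers.

Configurations are human-editable YAML mirroring the three input groups a
user supplies — animal/environment/liquid diet, starter composition, and
milk-allowance plans — validated field by field against the model's
acceptable ranges (initial BW 20-60 kg, temperature -30 to 50 degC,
weaning age 10-120 d, at most 4 scenarios per comparison).  All violations
in a file are reported at once.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from calfsim.engine import (
    MAX_SCENARIOS,
    KPISet,
    Scenario,
    Trajectory,
    kpis,
    trajectory_frame,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "write_trajectories_csv",
    "write_kpis_json",
    "render_report",
    "log_effective_defaults",
]

logger = logging.getLogger("calfsim")


class ConfigError(ValueError):
    """Raised when a configuration file violates the documented schema/ranges."""


class RunConfig(BaseModel):
    """A validated run: 1-4 scenarios plus output options."""

    scenarios: list[Scenario] = Field(min_length=1, max_length=MAX_SCENARIOS)
    output_dir: Path = Path("calfsim_output")
    report: bool = False


def _format_validation_error(err: ValidationError) -> str:
    lines = ["configuration invalid:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        lines.append(f"  - {loc}: {e['msg']}")
    lines.append(
        "acceptable ranges: initial_bw 20-60 kg; temperature -30 to 50 degC; "
        f"weaning_age 10-120 d; horizon <= 100 d; at most {MAX_SCENARIOS} scenarios"
    )
    return "\n".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Every violated bound is reported with the offending field and the
    acceptable range; labels are defaulted to scenario-1..n when absent.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    scenarios = raw.get("scenarios")
    if isinstance(scenarios, list):
        for i, sc in enumerate(scenarios):
            if isinstance(sc, dict):
                sc.setdefault("label", f"scenario-{i + 1}")
                plan = sc.get("plan")
                if isinstance(plan, dict) and isinstance(plan.get("allowance_by_day"), list):
                    plan["allowance_by_day"] = [tuple(p) for p in plan["allowance_by_day"]]
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    data = config.model_dump(mode="json")
    for sc in data["scenarios"]:
        sc["plan"]["allowance_by_day"] = [list(p) for p in sc["plan"]["allowance_by_day"]]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_trajectories_csv(
    trajectories: dict[str, Trajectory], path: str | Path
) -> pd.DataFrame:
    """Serialize trajectories to RFC-4180 CSV, one row per scenario-day."""
    frames = [trajectory_frame(traj, label) for label, traj in trajectories.items()]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    return df


def write_kpis_json(kpi_table: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(json.loads(kpi_table.to_json()), indent=2) + "\n")


def _fmt(v, nd=2):
    if v is None or (isinstance(v, float) and v != v):
        return "n/a"
    return f"{v:.{nd}f}" if isinstance(v, float) else str(v)


def render_report(
    comparison: dict,
    scenarios: list[Scenario],
    plots_dir: str | Path | None = None,
) -> str:
    """Render a markdown comparison report.

    Side-by-side until-weaning KPIs (final BW, ADG, feeding cost, cost per
    kg gain) per scenario plus, when ``plots_dir`` is given, BW / starter
    intake / ME intake time-series figures written as PNG and referenced
    from the document.  The body is deterministic for identical inputs.
    """
    by_label = {s.label: s for s in scenarios}
    lines = ["# Feeding-plan comparison report", "", "## KPIs until weaning", ""]
    header = "| metric | " + " | ".join(by_label) + " |"
    lines += [header, "|---" * (len(by_label) + 1) + "|"]
    kpi_rows: dict[str, list[str]] = {
        "final BW (kg)": [],
        "ADG (kg/d)": [],
        "feeding cost": [],
        "cost per kg gain": [],
        "age at 15 kg cumulative NFC (d)": [],
    }
    for label, s in by_label.items():
        k: KPISet = kpis(comparison["trajectories"][label], s, window="weaning")
        kfull: KPISet = kpis(comparison["trajectories"][label], s, window="full")
        kpi_rows["final BW (kg)"].append(_fmt(k.final_bw))
        kpi_rows["ADG (kg/d)"].append(_fmt(k.adg, 3))
        kpi_rows["feeding cost"].append(_fmt(k.total_cost))
        kpi_rows["cost per kg gain"].append(_fmt(k.cost_per_kg_gain))
        kpi_rows["age at 15 kg cumulative NFC (d)"].append(
            _fmt(k.age_at_15kg_nfc if k.age_at_15kg_nfc is not None else kfull.age_at_15kg_nfc)
        )
    for metric, vals in kpi_rows.items():
        lines.append("| " + metric + " | " + " | ".join(vals) + " |")

    if plots_dir is not None:
        plots_dir = Path(plots_dir)
        plots_dir.mkdir(parents=True, exist_ok=True)
        lines += ["", "## Time series", ""]
        for var, ylabel in (
            ("bw", "BW (kg)"),
            ("starter_dm", "starter intake (kg DM/d)"),
            ("me_total", "ME intake (Mcal/d)"),
        ):
            fname = plots_dir / f"{var}.png"
            _plot_variable(comparison["trajectories"], var, ylabel, fname)
            lines.append(f"![{ylabel}]({fname.name})")
    return "\n".join(lines) + "\n"


def _plot_variable(trajectories, var, ylabel, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for label, traj in trajectories.items():
        ax.plot([r.day for r in traj], [getattr(r, var) for r in traj], label=label)
    ax.set_xlabel("age (d)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def log_effective_defaults(scenario: Scenario) -> None:
    """Log the unprinted defaults in force so every run is auditable."""
    logger.info(
        "effective defaults for %s: k_g=%.3f, FPstarter unit=%s, "
        "first starter offer day=%d, liquid cap=14 L/d",
        scenario.label,
        scenario.k_g,
        scenario.fp_unit,
        scenario.plan.first_starter_offer_day,
    )
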