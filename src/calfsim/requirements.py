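"""Energy requirement and energy-allowable-growth equations.

This module is the bioenergetic core of the simulator.  It computes, for a
calf of known body weight and feeding stage:

* empty body weight (EBW), the gut-fill-free mass driving allometric
  requirements (stage-specific BW factors 0.91 preweaning / 0.85 weaned);
* net energy for maintenance, ``NEM = coefficient * EBW^0.75`` with
  coefficient 76.9 kcal/kg^0.75 preweaning and 97.0 kcal/kg^0.75 once fully
  weaned (returned in Mcal/d);
* metabolizable energy for maintenance ``MEm = NEM / k_m``, where ``k_m`` is
  fixed at 0.69 for milk-fed calves and, after weaning, estimated from the
  dietary ME density by a cubic-over-ME expression;
* the retained-energy relation ``RE = EBW_gain^1.1 * EBW^0.205`` and its
  exact algebraic inverse, which converts net energy available for gain
  into daily empty-body-weight gain (energy-allowable growth).

All energies are in Mcal/d; masses in kg.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

__all__ = [
    "FeedingStage",
    "EnergyBudget",
    "DEFAULT_KG",
    "empty_body_weight",
    "nem",
    "km_preweaning",
    "km_weaned",
    "mem",
    "retained_energy",
    "ebw_gain_from_ne",
]

#: Efficiency of converting ME above maintenance into net energy for gain.
#: A published-convention value; configurable on :class:`~calfsim.engine.Scenario`.
DEFAULT_KG = 0.60

# kcal/kg^0.75 NEM coefficients and EBW/BW factors by stage
_NEM_COEF_KCAL = {"preweaning_milk_plus_solid": 76.9, "fully_weaned": 97.0}
_EBW_FACTOR = {"preweaning_milk_plus_solid": 0.91, "fully_weaned": 0.85}

_KM_PREWEANING = 0.69
_RE_GAIN_EXP = 1.1
_RE_EBW_EXP = 0.205


class FeedingStage(str, enum.Enum):
    """Feeding stage of the calf; selects the stage-specific coefficient set."""

    PREWEANING = "preweaning_milk_plus_solid"
    WEANED = "fully_weaned"


@dataclass(frozen=True)
class EnergyBudget:
    """One day's energy bookkeeping (all Mcal/d except the efficiencies).

    ``ne_gain = (me_intake_total - mem) * k_g`` — negative when intake does
    not cover maintenance.
    """

    nem: float
    mem: float
    me_intake_total: float
    ne_gain: float
    k_m: float
    k_g: float

    def __post_init__(self) -> None:
        if not (0.0 < self.k_m <= 1.0):
            raise ValueError(f"k_m must lie in (0, 1], got {self.k_m}")
        if not (0.0 < self.k_g <= 1.0):
            raise ValueError(f"k_g must lie in (0, 1], got {self.k_g}")


def empty_body_weight(bw: float, stage: FeedingStage) -> float:
    """Empty body weight (kg) from live body weight.

    0.91 x BW for calves receiving milk (plus solid feed); 0.85 x BW for
    fully weaned calves.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    return _EBW_FACTOR[FeedingStage(stage).value] * bw


def ebw_to_bw(ebw: float, stage: FeedingStage) -> float:
    """Inverse of :func:`empty_body_weight` (used for BW updates from EBW gain)."""
    if ebw <= 0:
        raise ValueError(f"empty body weight must be positive, got {ebw}")
    return ebw / _EBW_FACTOR[FeedingStage(stage).value]


def nem(ebw: float, stage: FeedingStage) -> float:
    """Net energy for maintenance (Mcal/d) at a given EBW (kg).

    ``NEM = c * EBW^0.75`` with c = 76.9 kcal preweaning, 97.0 kcal weaned;
    converted to Mcal.
    """
    if ebw <= 0:
        raise ValueError(f"empty body weight must be positive, got {ebw}")
    coef = _NEM_COEF_KCAL[FeedingStage(stage).value]
    return coef * ebw**0.75 / 1000.0


def km_preweaning() -> float:
    """Efficiency of ME use for maintenance on a liquid diet (constant 0.69)."""
    return _KM_PREWEANING


def km_weaned(me_density: float) -> float:
    """Efficiency of ME use for maintenance on a solid diet.

    ``k_m = (1.1104*ME - 0.0946*ME^2 + 0.0065*ME^3 - 0.7783) / ME`` with ME
    the dietary energy density (Mcal/kg DM).  The cubic is only sensible
    over typical starter densities (roughly 2.9-3.6 Mcal/kg DM); outside
    that range the result is clamped to (0, 1] with a warning.
    """
    if me_density <= 0:
        raise ValueError(f"ME density must be positive, got {me_density}")
    raw = (
        1.1104 * me_density
        - 0.0946 * me_density**2
        + 0.0065 * me_density**3
        - 0.7783
    ) / me_density
    if not (0.0 < raw <= 1.0):
        warnings.warn(
            f"k_m cubic evaluated to {raw:.4f} at ME = {me_density} Mcal/kg DM, "
            "outside (0, 1]; clamping. The expression is only validated for "
            "typical starter energy densities.",
            RuntimeWarning,
            stacklevel=2,
        )
        return min(max(raw, 1e-6), 1.0)
    return raw


def mem(nem_value: float, k_m: float) -> float:
    """Metabolizable energy for maintenance (Mcal/d): ``NEM / k_m``."""
    if nem_value < 0:
        raise ValueError(f"NEM must be non-negative, got {nem_value}")
    if not (0.0 < k_m <= 1.0):
        raise ValueError(f"k_m must lie in (0, 1], got {k_m}")
    return nem_value / k_m


def retained_energy(ebw_gain: float, ebw: float) -> float:
    """Retained energy (Mcal/d): ``RE = EBW_gain^1.1 * EBW^0.205``.

    Forward form of the retention relation; :func:`ebw_gain_from_ne` is its
    exact inverse.
    """
    if ebw <= 0:
        raise ValueError(f"empty body weight must be positive, got {ebw}")
    if ebw_gain < 0:
        raise ValueError(f"EBW gain must be non-negative here, got {ebw_gain}")
    return ebw_gain**_RE_GAIN_EXP * ebw**_RE_EBW_EXP


def ebw_gain_from_ne(ne_gain: float, ebw: float) -> float:
    """Daily EBW gain (kg/d) allowed by net energy available for gain.

    Exact inverse of :func:`retained_energy`:
    ``gain = (NE / EBW^0.205)^(1/1.1)``.  Negative NE (intake below
    maintenance) is mapped through the odd-symmetric extension
    ``-(|NE| / EBW^0.205)^(1/1.1)``, allowing body-weight loss under
    restrictive plans.
    """
    if ebw <= 0:
        raise ValueError(f"empty body weight must be positive, got {ebw}")
    scaled = abs(ne_gain) / ebw**_RE_EBW_EXP
    magnitude = scaled ** (1.0 / _RE_GAIN_EXP)
    return magnitude if ne_gain >= 0 else -magnitude
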