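"""Digestibility maturation of starter nutrients and starter ME density.

Young calves cannot extract the full energy of solid feed: the
reticulorumen matures with fermentable substrate exposure.  Apparent
digestibility of each starter nutrient (CP, fat, NDF, NFC) is therefore
modelled as a linear function of the natural log of cumulative starter NFC
intake, with physical-form indicator terms (pelleted PEL, texturized TEX;
total mixed ration is the zero baseline).  Digestibility plateaus once
cumulative NFC intake reaches 15 kg — the conventional marker of a
functionally mature gastrointestinal tract.

Starter ME density is then assembled from the digestible fractions with a
summative digestible-energy equation (Mcal/kg DM):

    DE = 4.2*(dNFC*NFC) + 4.2*(dNDF*NDF) + 5.6*(dCP*CP) + 9.4*(dFat*Fat) - 0.3
    ME = 1.01*DE - 0.45

These DE/ME coefficients follow the classical summative convention for
cattle feeds; they are stated here so the computation is self-contained.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "StarterForm",
    "StarterComposition",
    "DigestibilitySet",
    "NFC_PLATEAU_KG",
    "NFC_LN_FLOOR_KG",
    "ln_ccs_nfci",
    "digestibilities",
    "starter_me_density",
    "nfc_accumulate",
]

#: Cumulative starter-NFC intake (kg) at which digestibility reaches its maximum.
NFC_PLATEAU_KG = 15.0

#: Floor (kg) applied before the logarithm: ln -> -inf at zero intake, and
#: first-days digestibility is deliberately poor (limited fermentative capacity).
NFC_LN_FLOOR_KG = 0.1


class StarterForm(str, enum.Enum):
    TEXTURIZED = "texturized"
    PELLETED = "pelleted"
    TMR = "tmr"


class StarterComposition(BaseModel):
    """Starter chemical composition (kg/kg DM), physical form and cost."""

    dm_fraction: float = Field(gt=0.0, le=1.0, default=0.90)
    cp_fraction: float = Field(ge=0.0, le=1.0, default=0.22)
    ndf_fraction: float = Field(ge=0.0, le=1.0, default=0.15)
    fat_fraction: float = Field(ge=0.0, le=1.0, default=0.04)
    ash_fraction: float = Field(ge=0.0, le=1.0, default=0.07)
    form: StarterForm = StarterForm.TEXTURIZED
    cost_per_kg: float = Field(ge=0.0, default=0.50, description="currency/kg as-fed")

    @model_validator(mode="after")
    def _check_fractions(self) -> "StarterComposition":
        total = self.cp_fraction + self.ndf_fraction + self.fat_fraction + self.ash_fraction
        if total >= 1.0:
            raise ValueError(
                f"CP + NDF + fat + ash = {total:.3f} must be < 1 (NFC must be positive)"
            )
        return self

    @property
    def nfc_fraction(self) -> float:
        """Non-fibrous carbohydrate by difference: 1 - CP - NDF - fat - ash."""
        return 1.0 - self.cp_fraction - self.ndf_fraction - self.fat_fraction - self.ash_fraction


@dataclass(frozen=True)
class DigestibilitySet:
    """Apparent digestibilities of the starter nutrient fractions, each in [0, 1]."""

    d_cp: float
    d_fat: float
    d_ndf: float
    d_nfc: float
    ln_ccs_nfci: float


def ln_ccs_nfci(cum_nfc: float) -> float:
    """ln of cumulative starter NFC intake (kg), clamped to [0.1, 15] kg.

    The 15-kg ceiling enforces the digestibility plateau; the 0.1-kg floor
    keeps the logarithm finite at first exposure.
    """
    if cum_nfc < 0:
        raise ValueError(f"cumulative NFC intake must be non-negative, got {cum_nfc}")
    return math.log(min(max(cum_nfc, NFC_LN_FLOOR_KG), NFC_PLATEAU_KG))


# (intercept, ln coef, PEL, TEX, PEL*ln, TEX*ln) per nutrient
_DIG_COEFS = {
    "d_cp": (0.707, 0.0268, -0.329, -0.042, 0.107, -0.013),
    "d_fat": (0.883, -0.021, -0.212, -0.380, 0.091, 0.122),
    "d_ndf": (0.390, 0.026, -0.090, -0.263, 0.078, 0.082),
    "d_nfc": (0.935, 0.004, -0.348, -0.322, 0.134, 0.127),
}


def digestibilities(ln_val: float, form: StarterForm) -> DigestibilitySet:
    """Evaluate the four digestibility equations at a given ln(cumulative NFC).

    Indicator coding: PEL = 1 for pelleted, TEX = 1 for texturized, both 0
    for TMR.  Each result is clamped to [0, 1] (the linear forms can stray
    outside physical bounds at extreme ln values).
    """
    form = StarterForm(form)
    pel = 1.0 if form is StarterForm.PELLETED else 0.0
    tex = 1.0 if form is StarterForm.TEXTURIZED else 0.0
    values = {}
    for name, (b0, b_ln, b_pel, b_tex, b_pel_ln, b_tex_ln) in _DIG_COEFS.items():
        v = (
            b0
            + b_ln * ln_val
            + b_pel * pel
            + b_tex * tex
            + b_pel_ln * pel * ln_val
            + b_tex_ln * tex * ln_val
        )
        values[name] = min(max(v, 0.0), 1.0)
    return DigestibilitySet(ln_ccs_nfci=ln_val, **values)


def starter_me_density(comp: StarterComposition, d: DigestibilitySet) -> float:
    """Starter ME density (Mcal/kg DM) from digestible nutrient fractions.

    Summative DE with the stated coefficients, then ME = 1.01*DE - 0.45,
    clamped at >= 0.
    """
    de = (
        4.2 * d.d_nfc * comp.nfc_fraction
        + 4.2 * d.d_ndf * comp.ndf_fraction
        + 5.6 * d.d_cp * comp.cp_fraction
        + 9.4 * d.d_fat * comp.fat_fraction
        - 0.3
    )
    return max(1.01 * de - 0.45, 0.0)


def nfc_accumulate(cum_nfc: float, si_dm: float, comp: StarterComposition) -> float:
    """Updated cumulative NFC intake (kg) after a day's starter DM intake."""
    if si_dm < 0:
        raise ValueError(f"starter DM intake must be non-negative, got {si_dm}")
    return cum_nfc + si_dm * comp.nfc_fraction
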