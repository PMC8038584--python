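"""Closed-form blood-gas arithmetic.

Everything here is a pure function: the Henderson-Hasselbalch pH, the van
Slyke estimate of standard base excess, the anion gap and its albumin
correction, the delta ratio with its diagnostic bands, and the expected
secondary (compensatory) response for each primary disorder under the
physiological (HCO3-based) and chemical (SBE-based) rule sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .core_types import (
    Approach,
    BloodGasPanel,
    Chronicity,
    DisorderKind,
    METABOLIC_ACIDOSIS_KINDS,
    ReferenceRanges,
)

#: Henderson-Hasselbalch constants: carbonic-acid pK and the CO2 solubility
#: coefficient in (mmol/L) per mm Hg.
HH_PK = 6.1
HH_CO2_SOLUBILITY = 0.03

#: van Slyke coefficients for estimating standard base excess from actual
#: bicarbonate and pH.
VAN_SLYKE_SCALE = 0.9287
VAN_SLYKE_HCO3_REF = 24.4
VAN_SLYKE_PH_SLOPE = 14.83

#: Albumin correction: the anion gap falls ~0.25 mEq/L per g/L of albumin
#: below normal.
AG_ALBUMIN_SLOPE = 0.25


def hh_ph(paco2: float, hco3: float) -> float:
    """pH from PaCO2 (mm Hg) and HCO3- (mmol/L) by Henderson-Hasselbalch.

    pH = 6.1 + log10(HCO3- / (0.03 x PaCO2)).  Raises ``ValueError`` for
    non-positive inputs (the logarithm is undefined there).
    """
    if paco2 <= 0 or hco3 <= 0:
        raise ValueError(f"paco2 and hco3 must be positive, got {paco2}, {hco3}")
    return HH_PK + math.log10(hco3 / (HH_CO2_SOLUBILITY * paco2))


def van_slyke_sbe(ph: float, hco3: float) -> float:
    """Standard base excess (mmol/L) estimated from pH and actual HCO3-.

    SBE = 0.9287 x (HCO3- - 24.4 + 14.83 x (pH - 7.4)).  Used only when
    the analyzer's own SBE was not supplied; different analyzers use
    different SBE formulas, so a supplied value always takes precedence.
    """
    return VAN_SLYKE_SCALE * (
        hco3 - VAN_SLYKE_HCO3_REF + VAN_SLYKE_PH_SLOPE * (ph - 7.4)
    )


def anion_gap(sodium: float, chloride: float, hco3: float) -> float:
    """AG = Na+ - (Cl- + HCO3-), the potassium-free simplification."""
    return sodium - (chloride + hco3)


def corrected_ag(ag: float, albumin: float, alb_normal: float = 40.0) -> float:
    """Albumin-corrected anion gap: AGc = AG + 0.25 x (normal - observed).

    Hypoalbuminemia lowers the measured gap and can mask a high-AG
    metabolic acidosis; the correction restores it.
    """
    return ag + AG_ALBUMIN_SLOPE * (alb_normal - albumin)


class RatioBand(str, Enum):
    """Diagnostic bands of the delta ratio (ΔAG/ΔHCO3-)."""

    BELOW_0P8 = "below_0p8"
    B0P8_1P2 = "b0p8_1p2"
    B1P2_2 = "b1p2_2"
    ABOVE_2 = "above_2"


@dataclass(frozen=True)
class DeltaRatioBand:
    value: float
    band: RatioBand


def delta_ratio(
    ag_used: float, hco3: float, ranges: Optional[ReferenceRanges] = None
) -> Optional[DeltaRatioBand]:
    """Delta ratio (AG - 7)/(24 - HCO3-) with its band.

    Band edges: value < 0.8 -> BELOW_0P8; 0.8 <= value <= 1.2 -> B0P8_1P2;
    1.2 < value <= 2 -> B1P2_2; value > 2 -> ABOVE_2.  When bicarbonate has
    not fallen (denominator <= 0) but the gap is elevated, the excess acid
    is entirely unexplained by bicarbonate loss, which reads as an infinite
    ratio (ABOVE_2).  If additionally the gap is at or below baseline the
    ratio carries no information and ``None`` ("not applicable") is
    returned.
    """
    ranges = ranges or ReferenceRanges()
    numerator = ag_used - ranges.ag_baseline
    denominator = ranges.hco3_baseline - hco3
    if denominator <= 0:
        if numerator > 0:
            return DeltaRatioBand(math.inf, RatioBand.ABOVE_2)
        return None
    value = numerator / denominator
    if value < 0.8:
        band = RatioBand.BELOW_0P8
    elif value <= 1.2:
        band = RatioBand.B0P8_1P2
    elif value <= 2.0:
        band = RatioBand.B1P2_2
    else:
        band = RatioBand.ABOVE_2
    return DeltaRatioBand(value, band)


@dataclass
class CompensationRules:
    """Coefficients of the secondary-response (compensation) formulas.

    Physiological (Boston) rules predict the partner value from HCO3-:

    - metabolic acidosis: expected PaCO2 = 1.5 x HCO3- + 8, ±2 mm Hg
      (Winter-type);
    - metabolic alkalosis: expected PaCO2 = 0.7 x (HCO3- - 24) + 40,
      ±2 mm Hg;
    - respiratory acidosis: expected HCO3- = 24 + 0.1 x ΔPaCO2 (acute) or
      24 + 0.4 x ΔPaCO2 (chronic), with ΔPaCO2 = PaCO2 - 40;
    - respiratory alkalosis: expected HCO3- = 24 - 0.2 x |ΔPaCO2| (acute)
      or 24 - 0.4 x |ΔPaCO2| (chronic).

    Chemical (Copenhagen) rules predict from SBE:

    - metabolic acidosis: expected PaCO2 = 40 + 1.0 x SBE (point);
    - metabolic alkalosis: expected PaCO2 = 40 + 0.6 x SBE (point);
    - respiratory, acute: expected SBE = 0 ± 2 mmol/L;
    - respiratory, chronic: expected SBE = 0.4 x ΔPaCO2 ± 2 mmol/L.
    """

    met_acid_slope: float = 1.5
    met_acid_intercept: float = 8.0
    met_acid_band: float = 2.0
    met_alk_slope: float = 0.7
    met_alk_band: float = 2.0
    resp_acid_acute_slope: float = 0.1
    resp_acid_chronic_slope: float = 0.4
    resp_alk_acute_slope: float = 0.2
    resp_alk_chronic_slope: float = 0.4
    chem_met_acid_slope: float = 1.0
    chem_met_alk_slope: float = 0.6
    chem_resp_band: float = 2.0
    chem_resp_chronic_slope: float = 0.4

    def replace(self, **overrides) -> "CompensationRules":
        return replace(self, **overrides)


DEFAULT_RULES = CompensationRules()


@dataclass(frozen=True)
class CompensationExpectation:
    """Expected partner value (point or band) for a primary disorder.

    ``direction_if_low``/``direction_if_high`` name the additional disorder
    implied when the measured partner falls below/above the band.
    """

    target: str  # "paco2", "hco3" or "sbe"
    center: float
    band_halfwidth: float
    direction_if_low: DisorderKind
    direction_if_high: DisorderKind

    def __post_init__(self) -> None:
        if self.band_halfwidth < 0:
            raise ValueError("band_halfwidth must be >= 0")

    @property
    def lo(self) -> float:
        return self.center - self.band_halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.band_halfwidth


def expected_compensation(
    kind: DisorderKind,
    chronicity: Chronicity,
    panel: BloodGasPanel,
    approach: Approach,
    ranges: Optional[ReferenceRanges] = None,
    rules: Optional[CompensationRules] = None,
) -> CompensationExpectation:
    """Expected secondary response for a single primary disorder.

    ``approach`` selects the physiological (HCO3-based) or chemical
    (SBE-based) rule family; the AGc variants share their parent family's
    rules.  For chemical rules ``panel.sbe`` must be resolved (supplied or
    van Slyke-derived).  ``chronicity`` is required for respiratory
    primaries and ignored for metabolic ones.
    """
    ranges = ranges or ReferenceRanges()
    rules = rules or DEFAULT_RULES
    chemical = approach in (Approach.CHEMICAL, Approach.CHEMICAL_AGC)
    dpaco2 = panel.paco2 - ranges.paco2_baseline

    if kind in METABOLIC_ACIDOSIS_KINDS or kind is DisorderKind.METABOLIC_ALKALOSIS:
        if chemical:
            if panel.sbe is None:
                raise ValueError("chemical compensation rules require a resolved SBE")
            slope = (
                rules.chem_met_acid_slope
                if kind in METABOLIC_ACIDOSIS_KINDS
                else rules.chem_met_alk_slope
            )
            center = ranges.paco2_baseline + slope * panel.sbe
            band = 0.0
        elif kind in METABOLIC_ACIDOSIS_KINDS:
            center = rules.met_acid_slope * panel.hco3 + rules.met_acid_intercept
            band = rules.met_acid_band
        else:
            center = (
                rules.met_alk_slope * (panel.hco3 - ranges.hco3_baseline)
                + ranges.paco2_baseline
            )
            band = rules.met_alk_band
        return CompensationExpectation(
            target="paco2",
            center=center,
            band_halfwidth=band,
            direction_if_low=DisorderKind.RESPIRATORY_ALKALOSIS,
            direction_if_high=DisorderKind.RESPIRATORY_ACIDOSIS,
        )

    if kind in (DisorderKind.RESPIRATORY_ACIDOSIS, DisorderKind.RESPIRATORY_ALKALOSIS):
        if chronicity not in (Chronicity.ACUTE, Chronicity.CHRONIC):
            raise ValueError("respiratory compensation needs acute or chronic chronicity")
        if chemical:
            if chronicity is Chronicity.ACUTE:
                center = 0.0
            else:
                center = rules.chem_resp_chronic_slope * dpaco2
            return CompensationExpectation(
                target="sbe",
                center=center,
                band_halfwidth=rules.chem_resp_band,
                direction_if_low=DisorderKind.METABOLIC_ACIDOSIS,
                direction_if_high=DisorderKind.METABOLIC_ALKALOSIS,
            )
        if kind is DisorderKind.RESPIRATORY_ACIDOSIS:
            slope = (
                rules.resp_acid_acute_slope
                if chronicity is Chronicity.ACUTE
                else rules.resp_acid_chronic_slope
            )
            center = ranges.hco3_baseline + slope * dpaco2
        else:
            slope = (
                rules.resp_alk_acute_slope
                if chronicity is Chronicity.ACUTE
                else rules.resp_alk_chronic_slope
            )
            center = ranges.hco3_baseline - slope * abs(dpaco2)
        return CompensationExpectation(
            target="hco3",
            center=center,
            band_halfwidth=0.0,
            direction_if_low=DisorderKind.METABOLIC_ACIDOSIS,
            direction_if_high=DisorderKind.METABOLIC_ALKALOSIS,
        )

    raise ValueError(f"no compensation rule for primary kind {kind!r}")
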