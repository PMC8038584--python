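"""Pre-analysis screening of a blood-gas panel.

Three layers of checks run before any interpretation: required fields
(missing pH/PaCO2/HCO3- or an underivable anion gap reject the panel),
plausibility windows (extreme values draw a warning but never a reject),
and internal consistency of pH, PaCO2 and HCO3- against the
Henderson-Hasselbalch equation with graded severity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .blood_gas_math import hh_ph, van_slyke_sbe
from .core_types import (
    BloodGasPanel,
    ReferenceRanges,
    Severity,
    ValidationFinding,
)


@dataclass
class PlausibilityWindows:
    """Survivable-extreme windows; values outside them indicate false data.

    These are deliberately generous physiologic extremes, not reference
    ranges: a value outside its window almost certainly reflects a typo or
    unit mix-up rather than a patient.
    """

    ph_lo: float = 6.5
    ph_hi: float = 8.0
    paco2_lo: float = 10.0
    paco2_hi: float = 150.0
    hco3_lo: float = 1.0
    hco3_hi: float = 60.0
    sbe_lo: float = -35.0
    sbe_hi: float = 35.0
    ag_lo: float = -5.0
    ag_hi: float = 60.0
    albumin_lo: float = 5.0
    albumin_hi: float = 70.0

    def replace(self, **overrides) -> "PlausibilityWindows":
        return replace(self, **overrides)


#: Tolerated difference (mmol/L) between a supplied SBE and the van Slyke
#: estimate before an informational note is raised.  Analyzers legitimately
#: use different SBE formulas, so this never escalates beyond info.
SBE_AGREEMENT_TOL = 3.0


def check_required(panel: BloodGasPanel) -> list[ValidationFinding]:
    """Reject findings for missing/non-finite required inputs; info notes
    for optional inputs whose absence narrows the analysis."""
    findings: list[ValidationFinding] = []
    for name in ("ph", "paco2", "hco3"):
        value = getattr(panel, name)
        if value is None or not math.isfinite(value):
            findings.append(
                ValidationFinding(
                    code=f"missing_{name}",
                    severity=Severity.REJECT,
                    message=f"{name} is required but missing or not finite",
                )
            )
    if panel.ag is None and (panel.sodium is None or panel.chloride is None):
        findings.append(
            ValidationFinding(
                code="missing_ag",
                severity=Severity.REJECT,
                message=(
                    "an anion gap is required: supply ag, or sodium and "
                    "chloride so it can be derived"
                ),
            )
        )
    for name in ("sbe", "ag", "sodium", "chloride", "albumin"):
        value = getattr(panel, name)
        if value is not None and not math.isfinite(value):
            findings.append(
                ValidationFinding(
                    code=f"nonfinite_{name}",
                    severity=Severity.REJECT,
                    message=f"{name} is not a finite number",
                )
            )
    if panel.albumin is None:
        findings.append(
            ValidationFinding(
                code="albumin_absent",
                severity=Severity.INFO,
                message=(
                    "albumin absent - the anion gap will not be corrected; "
                    "results for 2 of 4 approaches"
                ),
            )
        )
    if panel.sbe is None:
        findings.append(
            ValidationFinding(
                code="sbe_derived",
                severity=Severity.INFO,
                message="SBE absent - estimated from pH and HCO3- (van Slyke)",
            )
        )
    return findings


def check_plausibility(
    panel: BloodGasPanel, windows: Optional[PlausibilityWindows] = None
) -> list[ValidationFinding]:
    """Warning per present value outside its plausibility window."""
    windows = windows or PlausibilityWindows()
    findings: list[ValidationFinding] = []
    for name in ("ph", "paco2", "hco3", "sbe", "ag", "albumin"):
        value = getattr(panel, name)
        if value is None or not math.isfinite(value):
            continue
        lo = getattr(windows, f"{name}_lo")
        hi = getattr(windows, f"{name}_hi")
        if not lo <= value <= hi:
            findings.append(
                ValidationFinding(
                    code=f"extreme_{name}",
                    severity=Severity.WARNING,
                    message=(
                        f"extreme value: {name} = {value:g} is outside the "
                        f"plausible window [{lo:g}, {hi:g}]"
                    ),
                    measured=value,
                )
            )
    return findings


def check_hh_consistency(
    panel: BloodGasPanel, ranges: Optional[ReferenceRanges] = None
) -> Optional[ValidationFinding]:
    """Grade |entered pH - Henderson-Hasselbalch pH|.

    d <= 0.02 -> None; 0.02 < d <= 0.1 -> warning ("result may be
    incorrect"); d > 0.1 -> reject ("incorrect data").  Comparison is at
    full floating precision.
    """
    ranges = ranges or ReferenceRanges()
    computed = hh_ph(panel.paco2, panel.hco3)
    d = abs(panel.ph - computed)
    if d <= ranges.ph_warn:
        return None
    severity = Severity.WARNING if d <= ranges.ph_reject else Severity.REJECT
    message = (
        f"entered pH {panel.ph:g} differs from the Henderson-Hasselbalch "
        f"value {computed:.4f} by {d:.4f}"
    )
    if severity is Severity.REJECT:
        message = "incorrect data: " + message
    else:
        message = "result may be incorrect: " + message
    return ValidationFinding(
        code="hh_consistency",
        severity=severity,
        message=message,
        measured=panel.ph,
        computed=computed,
    )


def check_sbe_agreement(panel: BloodGasPanel) -> Optional[ValidationFinding]:
    """Info note when a supplied SBE disagrees with the van Slyke estimate.

    Never more than informational: analyzers use different base-excess
    formulas and some disagreement is expected.
    """
    if panel.sbe is None:
        return None
    estimate = van_slyke_sbe(panel.ph, panel.hco3)
    if abs(panel.sbe - estimate) <= SBE_AGREEMENT_TOL:
        return None
    return ValidationFinding(
        code="sbe_disagreement",
        severity=Severity.INFO,
        message=(
            f"supplied SBE {panel.sbe:g} differs from the van Slyke estimate "
            f"{estimate:.2f}; the supplied value is used"
        ),
        measured=panel.sbe,
        computed=estimate,
    )


def validate_panel(
    panel: BloodGasPanel,
    ranges: Optional[ReferenceRanges] = None,
    windows: Optional[PlausibilityWindows] = None,
) -> list[ValidationFinding]:
    """Run all screening layers in order; later layers are skipped if a
    required value is missing (they could not be computed)."""
    findings = check_required(panel)
    if any(f.severity is Severity.REJECT for f in findings):
        return findings
    findings.extend(check_plausibility(panel, windows))
    hh = check_hh_consistency(panel, ranges)
    if hh is not None:
        findings.append(hh)
    sbe = check_sbe_agreement(panel)
    if sbe is not None:
        findings.append(sbe)
    return findings
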