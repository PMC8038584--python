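"""The four-approach acid-base classifier and cross-approach aggregation.

A panel is interpreted up to four times: with the physiological (Boston,
HCO3-based) and chemical (Copenhagen, SBE-based) rule sets, each with the
plain and the albumin-corrected anion gap.  Each run follows the same
decision procedure:

1. pH status against its reference interval.
2. Component status of PaCO2 and the metabolic marker (HCO3- or SBE).
3. Branching:
   - abnormal pH explained by exactly one component -> that component's
     disorder is primary and the secondary (compensatory) response of the
     other axis is graded;
   - abnormal pH explained by both components (concordant double
     derangement) -> both disorders are reported without compensation
     grading;
   - normal pH with abnormal components -> the disturbance cannot be a
     fully compensated simple disorder (no disorder compensates completely),
     so every component-supported disorder is reported as part of a mixed
     picture;
   - all normal -> anion-gap screen only.
4. Anion-gap logic: typing of metabolic acidosis as high- or normal-gap,
   occult high-gap acidosis behind a normal panel, the AG >= 25 / >= 30
   escalations, and delta-ratio screening for coexisting normal-gap
   acidosis or metabolic alkalosis.

Finally the per-approach label sets are compared and the compliance
percentage (largest agreeing fraction) is reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional

from .blood_gas_math import (
    CompensationExpectation,
    CompensationRules,
    DEFAULT_RULES,
    RatioBand,
    anion_gap,
    corrected_ag,
    delta_ratio,
    expected_compensation,
    van_slyke_sbe,
)
from .core_types import (
    AnalysisReport,
    Approach,
    ApproachResult,
    BloodGasPanel,
    Certainty,
    Chronicity,
    DisorderKind,
    DisorderLabel,
    METABOLIC_ACIDOSIS_KINDS,
    ReferenceRanges,
    Severity,
)
from .validation import PlausibilityWindows, validate_panel

logger = logging.getLogger("abgkit")

_LOW, _NORMAL, _HIGH = -1, 0, 1


def _status(value: float, lo: float, hi: float) -> int:
    if value < lo:
        return _LOW
    if value > hi:
        return _HIGH
    return _NORMAL


@dataclass
class ApproachContext:
    """Everything one classification run needs besides the panel."""

    approach: Approach
    marker_name: str  # "hco3" or "sbe"
    marker_value: float
    marker_lo: float
    marker_hi: float
    ag_used: float
    ranges: ReferenceRanges
    rules: CompensationRules


def resolve_panel(
    panel: BloodGasPanel, ranges: Optional[ReferenceRanges] = None
) -> BloodGasPanel:
    """Fill in derivable quantities: AG from Na/Cl and SBE by van Slyke.

    A supplied SBE always takes precedence over the van Slyke estimate.
    """
    ranges = ranges or ReferenceRanges()
    ag = panel.ag
    if ag is None and panel.sodium is not None and panel.chloride is not None:
        ag = anion_gap(panel.sodium, panel.chloride, panel.hco3)
    sbe = panel.sbe
    if sbe is None:
        sbe = van_slyke_sbe(panel.ph, panel.hco3)
    return replace(panel, ag=ag, sbe=sbe)


def build_contexts(
    panel: BloodGasPanel,
    ranges: ReferenceRanges,
    rules: CompensationRules,
) -> tuple[list[ApproachContext], dict[Approach, str]]:
    """Contexts for every runnable approach plus reasons for skipped ones.

    ``panel`` must already be resolved (AG and SBE present).  The AGc
    approaches require albumin; without it they are skipped.
    """
    assert panel.ag is not None and panel.sbe is not None
    contexts: list[ApproachContext] = []
    skipped: dict[Approach, str] = {}
    agc = (
        corrected_ag(panel.ag, panel.albumin, ranges.alb_normal)
        if panel.albumin is not None
        else None
    )
    for approach in Approach:
        with_agc = approach in (Approach.PHYSIOLOGICAL_AGC, Approach.CHEMICAL_AGC)
        if with_agc and agc is None:
            skipped[approach] = "albumin not entered - anion gap not corrected"
            continue
        chemical = approach in (Approach.CHEMICAL, Approach.CHEMICAL_AGC)
        contexts.append(
            ApproachContext(
                approach=approach,
                marker_name="sbe" if chemical else "hco3",
                marker_value=panel.sbe if chemical else panel.hco3,
                marker_lo=ranges.sbe_lo if chemical else ranges.hco3_lo,
                marker_hi=ranges.sbe_hi if chemical else ranges.hco3_hi,
                ag_used=agc if with_agc else panel.ag,
                ranges=ranges,
                rules=rules,
            )
        )
    return contexts, skipped


def _near(value: float, lo: float, hi: float, margin_frac: float) -> bool:
    """Within [lo, hi] extended by margin_frac of each edge's magnitude."""
    return (lo - margin_frac * abs(lo)) <= value <= (hi + margin_frac * abs(hi))


def evaluate_secondary(
    primary: DisorderLabel,
    panel: BloodGasPanel,
    ctx: ApproachContext,
) -> tuple[list[DisorderLabel], Chronicity, dict, list[str]]:
    """Grade the secondary response to a single primary disorder.

    Metabolic primary: the measured PaCO2 is compared with the expected
    compensation interval; a value beyond an edge by at most the probable
    margin (5% of the edge) yields a *probable* additional respiratory
    disorder, beyond that a *definite* one.

    Respiratory primary: the metabolic marker is compared with the acute
    and chronic expectations (acute checked first).  Near acute -> acute;
    near chronic -> chronic; beyond chronic in the compensation direction
    -> chronic plus a definite metabolic disorder in that direction; short
    of acute toward baseline -> no chronicity plus the opposing metabolic
    disorder; in the gap between the two expectations -> chronicity left
    indeterminate.
    """
    margin = ctx.ranges.probable_margin
    additional: list[DisorderLabel] = []
    notes: list[str] = []
    evidence: dict = {}

    if primary.kind in METABOLIC_ACIDOSIS_KINDS or primary.kind is DisorderKind.METABOLIC_ALKALOSIS:
        exp = expected_compensation(
            primary.kind, Chronicity.NONE, panel, ctx.approach, ctx.ranges, ctx.rules
        )
        measured = panel.paco2
        evidence.update(
            expected_paco2_lo=exp.lo, expected_paco2_hi=exp.hi, measured_paco2=measured
        )
        if measured > exp.hi:
            certainty = (
                Certainty.PROBABLE
                if measured <= exp.hi * (1 + margin)
                else Certainty.DEFINITE
            )
            additional.append(DisorderLabel(exp.direction_if_high, certainty=certainty))
        elif measured < exp.lo:
            certainty = (
                Certainty.PROBABLE
                if measured >= exp.lo * (1 - margin)
                else Certainty.DEFINITE
            )
            additional.append(DisorderLabel(exp.direction_if_low, certainty=certainty))
        return additional, Chronicity.NONE, evidence, notes

    # Respiratory primary: locate the marker relative to the acute and
    # chronic expectations along the compensation direction.
    acute = expected_compensation(
        primary.kind, Chronicity.ACUTE, panel, ctx.approach, ctx.ranges, ctx.rules
    )
    chronic = expected_compensation(
        primary.kind, Chronicity.CHRONIC, panel, ctx.approach, ctx.ranges, ctx.rules
    )
    measured = ctx.marker_value
    evidence.update(
        expected_acute_lo=acute.lo,
        expected_acute_hi=acute.hi,
        expected_chronic_lo=chronic.lo,
        expected_chronic_hi=chronic.hi,
        measured_marker=measured,
    )
    # s = +1 when compensation raises the marker (respiratory acidosis),
    # -1 when it lowers it (respiratory alkalosis).
    s = 1 if primary.kind is DisorderKind.RESPIRATORY_ACIDOSIS else -1
    compensatory = (
        DisorderKind.METABOLIC_ALKALOSIS if s > 0 else DisorderKind.METABOLIC_ACIDOSIS
    )
    opposing = (
        DisorderKind.METABOLIC_ACIDOSIS if s > 0 else DisorderKind.METABOLIC_ALKALOSIS
    )
    if _near(measured, acute.lo, acute.hi, margin):
        return additional, Chronicity.ACUTE, evidence, notes
    if _near(measured, chronic.lo, chronic.hi, margin):
        return additional, Chronicity.CHRONIC, evidence, notes
    chronic_outer = chronic.hi if s > 0 else chronic.lo  # far edge of chronic band
    acute_inner = acute.lo if s > 0 else acute.hi  # baseline-side edge of acute band
    if s * measured > s * chronic_outer:
        additional.append(DisorderLabel(compensatory))
        return additional, Chronicity.CHRONIC, evidence, notes
    if s * measured < s * acute_inner:
        additional.append(DisorderLabel(opposing))
        return additional, Chronicity.NONE, evidence, notes
    notes.append("indeterminate chronicity: marker between acute and chronic expectations")
    return additional, Chronicity.NONE, evidence, notes


def apply_ag_logic(
    labels: list[DisorderLabel],
    panel: BloodGasPanel,
    ctx: ApproachContext,
) -> tuple[list[DisorderLabel], dict, list[str]]:
    """Anion-gap typing, occult-acidosis detection and delta-ratio screen.

    - A metabolic acidosis already on the list is typed HAGMA when the gap
      exceeds its upper reference bound, NAGMA otherwise.
    - An elevated gap with no metabolic disorder on the list reveals an
      occult HAGMA.  When metabolic alkalosis is present, moderate gap
      elevation is expected and tolerated: only AG >= 25 draws a
      consider-additional-disorder note and AG >= 30 asserts HAGMA.
    - Whenever HAGMA is present the delta ratio (AG-7)/(24-HCO3-) screens
      for a third disorder: < 0.8 suggests coexisting NAGMA (probable),
      1.2-2 suggests coexisting metabolic alkalosis (probable), > 2
      asserts it.  The ratio always uses HCO3-, also in chemical
      approaches.
    """
    ranges = ctx.ranges
    ag = ctx.ag_used
    notes: list[str] = []
    evidence: dict = {"ag_used": ag}
    by_kind = {lbl.kind: lbl for lbl in labels}

    met_acid = by_kind.pop(DisorderKind.METABOLIC_ACIDOSIS, None)
    if met_acid is not None:
        typed = DisorderKind.HAGMA if ag > ranges.ag_hi else DisorderKind.NAGMA
        by_kind[typed] = DisorderLabel(typed, certainty=met_acid.certainty)
    elif (
        ag > ranges.ag_hi
        and DisorderKind.METABOLIC_ALKALOSIS not in by_kind
        and DisorderKind.HAGMA not in by_kind
        and DisorderKind.NAGMA not in by_kind
    ):
        by_kind[DisorderKind.HAGMA] = DisorderLabel(DisorderKind.HAGMA)

    if ag >= ranges.ag_consider_threshold:
        notes.append(
            f"anion gap {ag:g} >= {ranges.ag_consider_threshold:g}: "
            "consider the presence of an additional disorder"
        )
    if ag >= ranges.ag_certain_threshold and DisorderKind.HAGMA not in by_kind:
        by_kind[DisorderKind.HAGMA] = DisorderLabel(DisorderKind.HAGMA)

    if DisorderKind.HAGMA in by_kind:
        ratio = delta_ratio(ag, panel.hco3, ranges)
        if ratio is None:
            notes.append("delta ratio not applicable")
        else:
            evidence["delta_ratio"] = ratio.value
            evidence["delta_ratio_band"] = ratio.band.value
            suggestion: Optional[DisorderLabel] = None
            if ratio.band is RatioBand.BELOW_0P8:
                suggestion = DisorderLabel(DisorderKind.NAGMA, certainty=Certainty.PROBABLE)
            elif ratio.band is RatioBand.B1P2_2:
                suggestion = DisorderLabel(
                    DisorderKind.METABOLIC_ALKALOSIS, certainty=Certainty.PROBABLE
                )
            elif ratio.band is RatioBand.ABOVE_2:
                suggestion = DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS)
            if suggestion is not None:
                existing = by_kind.get(suggestion.kind)
                if existing is None or (
                    existing.certainty is Certainty.PROBABLE
                    and suggestion.certainty is Certainty.DEFINITE
                ):
                    # never downgrade a definite finding to probable
                    by_kind[suggestion.kind] = suggestion

    return list(by_kind.values()), evidence, notes


def classify(panel: BloodGasPanel, ctx: ApproachContext) -> ApproachResult:
    """Run the full decision procedure for one approach.

    ``panel`` must be resolved and must have passed validation (no reject
    findings).
    """
    ranges = ctx.ranges
    labels: list[DisorderLabel] = []
    notes: list[str] = []
    evidence: dict = {}

    ph_status = _status(panel.ph, ranges.ph_lo, ranges.ph_hi)
    paco2_status = _status(panel.paco2, ranges.paco2_lo, ranges.paco2_hi)
    marker_status = _status(ctx.marker_value, ctx.marker_lo, ctx.marker_hi)

    resp_kind = (
        DisorderKind.RESPIRATORY_ACIDOSIS
        if paco2_status == _HIGH
        else DisorderKind.RESPIRATORY_ALKALOSIS
        if paco2_status == _LOW
        else None
    )
    met_kind = (
        DisorderKind.METABOLIC_ALKALOSIS
        if marker_status == _HIGH
        else DisorderKind.METABOLIC_ACIDOSIS
        if marker_status == _LOW
        else None
    )

    if ph_status != _NORMAL:
        # A component "explains" the pH when its derangement acts in the
        # pH's direction.
        resp_explains = (ph_status == _LOW and paco2_status == _HIGH) or (
            ph_status == _HIGH and paco2_status == _LOW
        )
        met_explains = (ph_status == _LOW and marker_status == _LOW) or (
            ph_status == _HIGH and marker_status == _HIGH
        )
        if resp_explains and met_explains:
            labels = [DisorderLabel(resp_kind), DisorderLabel(met_kind)]
        elif met_explains or resp_explains:
            primary = DisorderLabel(met_kind if met_explains else resp_kind)
            additional, chronicity, sec_evidence, sec_notes = evaluate_secondary(
                primary, panel, ctx
            )
            labels = [replace(primary, chronicity=chronicity), *additional]
            evidence.update(sec_evidence)
            notes.extend(sec_notes)
        else:
            # Deranged pH that no measured component accounts for: list any
            # counter-acting component disorders and flag the discrepancy.
            labels = [DisorderLabel(k) for k in (resp_kind, met_kind) if k is not None]
            notes.append(
                "pH derangement is not explained by the measured PaCO2 or "
                "metabolic marker"
            )
    else:
        # Normal pH: no disorder can be fully compensated, so any abnormal
        # component marks a mixed disturbance; each one is listed.
        labels = [DisorderLabel(k) for k in (resp_kind, met_kind) if k is not None]

    labels, ag_evidence, ag_notes = apply_ag_logic(labels, panel, ctx)
    evidence.update(ag_evidence)
    notes.extend(ag_notes)
    return ApproachResult(
        approach=ctx.approach,
        labels=frozenset(labels),
        evidence=evidence,
        notes=notes,
    )


def compliance(results: list[ApproachResult]) -> float:
    """100 x (largest group of identical label sets) / (approaches run)."""
    if not results:
        raise ValueError("compliance needs at least one result")
    counts = Counter(result.label_set() for result in results)
    return 100.0 * max(counts.values()) / len(results)


def run_all(
    panel: BloodGasPanel,
    ranges: Optional[ReferenceRanges] = None,
    rules: Optional[CompensationRules] = None,
    windows: Optional[PlausibilityWindows] = None,
) -> AnalysisReport:
    """Validate, classify with every runnable approach, and aggregate."""
    ranges = ranges or ReferenceRanges()
    rules = rules or DEFAULT_RULES
    findings = validate_panel(panel, ranges, windows)
    if any(f.severity is Severity.REJECT for f in findings):
        logger.info("panel rejected by validation")
        return AnalysisReport(panel=panel, validation=findings)
    resolved = resolve_panel(panel, ranges)
    contexts, skipped = build_contexts(resolved, ranges, rules)
    results = [classify(resolved, ctx) for ctx in contexts]
    pct = compliance(results)
    logger.debug(
        "ran %d approaches, compliance %.0f%%", len(results), pct
    )
    return AnalysisReport(
        panel=resolved,
        validation=findings,
        results=results,
        skipped=skipped,
        compliance_pct=pct,
    )
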