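"""Domain vocabulary for arterial blood-gas (ABG) interpretation.

An ABG panel is interpreted along two axes: the respiratory axis (PaCO2,
mm Hg) and the metabolic axis, measured either by bicarbonate (HCO3-,
mmol/L; the "physiological"/Boston school) or by standard base excess
(SBE, mmol/L; the "chemical"/Copenhagen school).  The anion gap (AG,
mEq/L), optionally corrected for albumin (AGc), separates high- from
normal-anion-gap metabolic acidosis.

This module defines the panel, the configurable reference ranges and rule
constants, disorder labels with chronicity and certainty grades, the result
of a single diagnostic approach, and the aggregated multi-approach report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Mapping, Optional, Sequence


class DisorderKind(str, Enum):
    """Acid-base disturbance categories.

    ``METABOLIC_ACIDOSIS`` is a provisional kind used while classifying:
    the anion-gap logic always refines it to ``HAGMA`` or ``NAGMA`` before
    a result is emitted.
    """

    RESPIRATORY_ACIDOSIS = "respiratory_acidosis"
    RESPIRATORY_ALKALOSIS = "respiratory_alkalosis"
    METABOLIC_ALKALOSIS = "metabolic_alkalosis"
    METABOLIC_ACIDOSIS = "metabolic_acidosis"
    HAGMA = "hagma"
    NAGMA = "nagma"


RESPIRATORY_KINDS = frozenset(
    {DisorderKind.RESPIRATORY_ACIDOSIS, DisorderKind.RESPIRATORY_ALKALOSIS}
)
METABOLIC_ACIDOSIS_KINDS = frozenset(
    {DisorderKind.METABOLIC_ACIDOSIS, DisorderKind.HAGMA, DisorderKind.NAGMA}
)


class Chronicity(str, Enum):
    NONE = "none"
    ACUTE = "acute"
    CHRONIC = "chronic"


class Certainty(str, Enum):
    DEFINITE = "definite"
    PROBABLE = "probable"


class Approach(str, Enum):
    PHYSIOLOGICAL = "physiological"
    PHYSIOLOGICAL_AGC = "physiological_agc"
    CHEMICAL = "chemical"
    CHEMICAL_AGC = "chemical_agc"


APPROACH_TITLES = {
    Approach.PHYSIOLOGICAL: "physiological approach",
    Approach.PHYSIOLOGICAL_AGC: "physiological approach with AGc",
    Approach.CHEMICAL: "chemical approach",
    Approach.CHEMICAL_AGC: "chemical approach with AGc",
}


class Severity(str, Enum):
    INFO = "info"
    WARNING = "warning"
    REJECT = "reject"


_KIND_TEXT = {
    DisorderKind.RESPIRATORY_ACIDOSIS: "respiratory acidosis",
    DisorderKind.RESPIRATORY_ALKALOSIS: "respiratory alkalosis",
    DisorderKind.METABOLIC_ALKALOSIS: "metabolic alkalosis",
    DisorderKind.METABOLIC_ACIDOSIS: "metabolic acidosis",
    DisorderKind.HAGMA: "high anion gap metabolic acidosis",
    DisorderKind.NAGMA: "normal anion gap metabolic acidosis",
}

# Canonical presentation order.  The comparison semantics are set-based;
# this order only makes renderings deterministic.
_KIND_ORDER = {
    DisorderKind.RESPIRATORY_ACIDOSIS: 0,
    DisorderKind.RESPIRATORY_ALKALOSIS: 1,
    DisorderKind.HAGMA: 2,
    DisorderKind.NAGMA: 3,
    DisorderKind.METABOLIC_ACIDOSIS: 4,
    DisorderKind.METABOLIC_ALKALOSIS: 5,
}


@dataclass(frozen=True, order=False)
class DisorderLabel:
    """One disturbance, e.g. (chronic respiratory alkalosis, definite)."""

    kind: DisorderKind
    chronicity: Chronicity = Chronicity.NONE
    certainty: Certainty = Certainty.DEFINITE

    def __post_init__(self) -> None:
        if self.chronicity is not Chronicity.NONE and self.kind not in RESPIRATORY_KINDS:
            raise ValueError(
                f"chronicity {self.chronicity.value} is only valid for "
                f"respiratory disorders, not {self.kind.value}"
            )

    @property
    def sort_key(self) -> tuple:
        return (
            0 if self.certainty is Certainty.DEFINITE else 1,
            _KIND_ORDER[self.kind],
            self.chronicity.value,
        )

    def text(self) -> str:
        """Render the label the way the report phrases it.

        Probable respiratory disturbances arise from borderline secondary
        responses and read "probably with ..."; probable metabolic ones come
        from the delta-ratio screen and read "possible additional ...".
        """
        base = _KIND_TEXT[self.kind]
        if self.chronicity is not Chronicity.NONE:
            base = f"{self.chronicity.value} {base}"
        if self.certainty is Certainty.PROBABLE:
            if self.kind in RESPIRATORY_KINDS:
                return f"probably with {base}"
            return f"possible additional {base}"
        return base


@dataclass
class BloodGasPanel:
    """A single patient's measured blood-gas values.

    Units: ``ph`` dimensionless, ``paco2`` mm Hg, ``hco3``/``sbe`` mmol/L,
    ``ag``/``sodium``/``chloride`` mEq/L, ``albumin`` g/L.  ``ph``,
    ``paco2`` and ``hco3`` are always required; ``ag`` may instead be
    derived from sodium and chloride.  Standard HCO3- is preferred, but
    actual HCO3- is accepted in its place.
    """

    ph: float
    paco2: float
    hco3: float
    sbe: Optional[float] = None
    ag: Optional[float] = None
    sodium: Optional[float] = None
    chloride: Optional[float] = None
    albumin: Optional[float] = None

    def present_values(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def finite(self) -> bool:
        return all(math.isfinite(v) for v in self.present_values().values())


@dataclass
class ReferenceRanges:
    """Normal intervals and rule constants (all configurable).

    Intervals are closed: a value equal to either bound is normal.  The
    baselines are the mid-range anchor points used by the compensation and
    delta-ratio formulas; ``ag_baseline`` is the numerator offset of the
    delta ratio (AG - 7)/(24 - HCO3-).
    """

    ph_lo: float = 7.34
    ph_hi: float = 7.44
    paco2_lo: float = 36.0
    paco2_hi: float = 44.0
    hco3_lo: float = 22.0
    hco3_hi: float = 26.0
    sbe_lo: float = -2.0
    sbe_hi: float = 2.0
    ag_lo: float = 3.0
    ag_hi: float = 11.0
    alb_lo: float = 35.0
    alb_hi: float = 50.0
    alb_normal: float = 40.0
    hco3_baseline: float = 24.0
    paco2_baseline: float = 40.0
    ag_baseline: float = 7.0
    ag_consider_threshold: float = 25.0
    ag_certain_threshold: float = 30.0
    probable_margin: float = 0.05
    ph_warn: float = 0.02
    ph_reject: float = 0.1

    def __post_init__(self) -> None:
        for axis in ("ph", "paco2", "hco3", "sbe", "ag", "alb"):
            lo, hi = getattr(self, f"{axis}_lo"), getattr(self, f"{axis}_hi")
            if not lo < hi:
                raise ValueError(f"{axis}: lower bound {lo} must be < upper bound {hi}")
        for name in (
            "alb_normal",
            "hco3_baseline",
            "paco2_baseline",
            "ag_consider_threshold",
            "ag_certain_threshold",
            "probable_margin",
            "ph_warn",
            "ph_reject",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ph_warn >= self.ph_reject:
            raise ValueError("ph_warn must be below ph_reject")

    def replace(self, **overrides) -> "ReferenceRanges":
        return replace(self, **overrides)


@dataclass
class ValidationFinding:
    """One pre-analysis screening result.

    A ``reject`` finding suppresses all interpretation output; ``warning``
    and ``info`` findings are reported alongside results.
    """

    code: str
    severity: Severity
    message: str
    measured: Optional[float] = None
    computed: Optional[float] = None


@dataclass
class ApproachResult:
    """One approach's disorder label set plus numeric evidence.

    An empty label set means "correct results".  ``evidence`` holds the
    named intermediates that drove the decision (ag_used, expected
    compensation interval, delta ratio, ...); ``notes`` carries advisory
    strings such as the AG >= 25 "consider additional disorder" hint.
    """

    approach: Approach
    labels: frozenset[DisorderLabel] = frozenset()
    evidence: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        kinds = [lbl.kind for lbl in self.labels]
        if len(kinds) != len(set(kinds)):
            raise ValueError("each disorder kind may appear at most once per result")

    def label_set(self) -> frozenset[tuple]:
        """The comparison key: labels as (kind, chronicity, certainty) triples."""
        return frozenset(
            (lbl.kind, lbl.chronicity, lbl.certainty) for lbl in self.labels
        )


def canonical_label_set(result: ApproachResult) -> list[str]:
    """Deterministically ordered rendered label strings for one result.

    Definite labels come first, then probable ones, each group in a fixed
    kind order, so equal label sets always render identically regardless of
    construction order.  An empty set renders as ``["correct results"]``.
    """
    if not result.labels:
        return ["correct results"]
    return [lbl.text() for lbl in sorted(result.labels, key=lambda l: l.sort_key)]


def render_sentence(result: ApproachResult) -> str:
    """Join a result's labels into the report's one-line diagnosis.

    Definite labels are joined with " and "; probable labels are appended
    after a comma, e.g. "high anion gap metabolic acidosis and respiratory
    acidosis, possible additional normal anion gap metabolic acidosis".
    """
    if not result.labels:
        return "correct results"
    ordered = sorted(result.labels, key=lambda l: l.sort_key)
    definite = [l.text() for l in ordered if l.certainty is Certainty.DEFINITE]
    probable = [l.text() for l in ordered if l.certainty is Certainty.PROBABLE]
    sentence = " and ".join(definite) if definite else ""
    for phrase in probable:
        sentence = f"{sentence}, {phrase}" if sentence else phrase
    return sentence


@dataclass
class AnalysisReport:
    """The full outcome for one panel.

    ``results`` holds 4 approaches when albumin was supplied, otherwise 2;
    ``skipped`` explains each approach that could not run.  If validation
    rejected the panel, ``results`` is empty and ``compliance_pct`` is None.
    ``compliance_pct`` is 100 x (largest group of approaches returning an
    identical label set) / (number of approaches run).
    """

    panel: BloodGasPanel
    validation: list[ValidationFinding] = field(default_factory=list)
    results: list[ApproachResult] = field(default_factory=list)
    skipped: dict[Approach, str] = field(default_factory=dict)
    compliance_pct: Optional[float] = None

    @property
    def rejected(self) -> bool:
        return any(f.severity is Severity.REJECT for f in self.validation)
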