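"""Packaged reference cases and a seedable synthetic panel generator.

Two test-data sources ship with the package:

* :func:`printed_cases` — a curated collection of blood-gas panels with
  established expected diagnoses (literature comparison cases, survey
  cases, worked examples and two application-comparison regressions),
  stored as CSV plus a JSON expectations file so every pipeline stage is
  testable without downloads.

* :func:`generate` — a constructive generator that inverts the
  compensation formulas: given a ground-truth specification (primary
  disorder, chronicity, compensation adequacy zone, anion-gap scenario) it
  builds a panel whose pH is derived exactly from PaCO2 and HCO3- via
  Henderson-Hasselbalch, so the classifier's output can be checked against
  the construction labels.
"""

from __future__ import annotations

import csv
import io
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .blood_gas_math import DEFAULT_RULES, hh_ph
from .core_types import (
    Approach,
    BloodGasPanel,
    Certainty,
    Chronicity,
    DisorderKind,
    DisorderLabel,
    ReferenceRanges,
)

_KIND_TOKENS = {
    "resp_acid": DisorderKind.RESPIRATORY_ACIDOSIS,
    "resp_alk": DisorderKind.RESPIRATORY_ALKALOSIS,
    "met_alk": DisorderKind.METABOLIC_ALKALOSIS,
    "hagma": DisorderKind.HAGMA,
    "nagma": DisorderKind.NAGMA,
}


def parse_label_token(token: str) -> DisorderLabel:
    """Decode the compact label syntax used by the expectations file.

    ``kind[/chronicity][?]`` — a trailing ``?`` marks certainty probable,
    e.g. ``met_alk?`` or ``resp_alk/chronic``.
    """
    certainty = Certainty.DEFINITE
    if token.endswith("?"):
        certainty = Certainty.PROBABLE
        token = token[:-1]
    kind_token, _, chron_token = token.partition("/")
    kind = _KIND_TOKENS[kind_token]
    chronicity = Chronicity(chron_token) if chron_token else Chronicity.NONE
    return DisorderLabel(kind, chronicity=chronicity, certainty=certainty)


@dataclass(frozen=True)
class PrintedCase:
    """One packaged case: the raw record, per-approach expected labels,
    whether validation must reject it, and which approaches are known to
    diverge from the published output (asserted nowhere)."""

    case_id: str
    record: dict[str, str]
    expected: dict[Approach, frozenset[DisorderLabel]]
    reject: bool = False
    known_divergent: tuple[Approach, ...] = ()
    compliance: Optional[float] = None


def _data_text(name: str) -> str:
    return resources.files("abgkit").joinpath("data", name).read_text()


def printed_cases() -> list[PrintedCase]:
    """All packaged cases, in file order."""
    reader = csv.DictReader(io.StringIO(_data_text("printed_cases.csv")))
    records = {row["case_id"]: dict(row) for row in reader}
    expectations = json.loads(_data_text("expected_labels.json"))
    cases = []
    for case_id, record in records.items():
        meta = expectations.get(case_id, {})
        expected = {
            Approach(name): frozenset(parse_label_token(t) for t in tokens)
            for name, tokens in meta.get("expected", {}).items()
        }
        cases.append(
            PrintedCase(
                case_id=case_id,
                record=record,
                expected=expected,
                reject=bool(meta.get("reject", False)),
                known_divergent=tuple(
                    Approach(name) for name in meta.get("known_divergent", [])
                ),
                compliance=meta.get("compliance"),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

class GenerationError(ValueError):
    """The requested ground-truth specification cannot be realized."""


@dataclass(frozen=True)
class TruthSpec:
    """Construction recipe for a synthetic panel.

    ``primary`` is None for an acid-base-normal panel (anion-gap scenarios
    only).  ``adequacy`` places the compensating partner value relative to
    the expected secondary response: ``in_band`` (simple disorder),
    ``probable_zone`` (just beyond the band, within the 5% margin) or
    ``definite_zone`` (clearly beyond).  For metabolic primaries
    ``direction`` says which side of the band ("high" adds respiratory
    acidosis, "low" respiratory alkalosis); for respiratory primaries the
    definite zone is realized as a metabolic-marker shortfall toward (or
    past) baseline, which adds the opposing metabolic disorder.
    ``ph_offset`` injects a Henderson-Hasselbalch inconsistency.
    """

    primary: Optional[DisorderKind] = None
    chronicity: Chronicity = Chronicity.NONE
    adequacy: str = "in_band"
    direction: Optional[str] = None
    ag_mode: str = "normal"
    include_albumin: bool = False
    ph_offset: float = 0.0


@dataclass(frozen=True)
class SyntheticCase:
    """A generated panel plus the labels its construction implies.

    ``expected_labels`` is what the physiological approach (plain anion
    gap) must report; ``expected_labels_agc`` is set when a low-albumin
    scenario makes the corrected-gap approaches diverge.
    """

    panel: BloodGasPanel
    truth: TruthSpec
    seed: int
    expected_labels: frozenset[DisorderLabel]
    expected_labels_agc: Optional[frozenset[DisorderLabel]] = None
    expects_reject: bool = False


_RANGES = ReferenceRanges()
# pH-status boundaries expressed as the HCO3-/PaCO2 ratio: below _K_LOW the
# Henderson-Hasselbalch pH is acidemic, above _K_HIGH alkalemic.
_K_LOW = 0.03 * 10 ** (_RANGES.ph_lo - 6.1)
_K_HIGH = 0.03 * 10 ** (_RANGES.ph_hi - 6.1)

_MET_KINDS = {DisorderKind.NAGMA, DisorderKind.HAGMA, DisorderKind.METABOLIC_ALKALOSIS}
_RESP_KINDS = {DisorderKind.RESPIRATORY_ACIDOSIS, DisorderKind.RESPIRATORY_ALKALOSIS}


def _normal_ag(rng: random.Random) -> float:
    return rng.uniform(3.5, 10.5)


def _met_acid_panel(rng: random.Random, spec: TruthSpec) -> tuple[float, float, float, set]:
    """(hco3, paco2, ag, additional labels) for a metabolic-acidosis primary."""
    rules = DEFAULT_RULES
    if spec.adequacy in ("probable_zone", "definite_zone") and spec.direction == "low":
        hco3 = rng.uniform(4.0, 10.0)
    elif spec.primary is DisorderKind.HAGMA:
        hco3 = rng.uniform(4.0, 16.0)
    else:
        hco3 = rng.uniform(4.0, 20.0)
    center = rules.met_acid_slope * hco3 + rules.met_acid_intercept
    lo, hi = center - rules.met_acid_band, center + rules.met_acid_band
    additional: set = set()
    if spec.adequacy == "in_band":
        # avoid the corner where the pH lands normal while PaCO2 is below
        # its reference range (that would read as an extra disorder)
        eff_lo = max(lo, min(36.0, hco3 / _K_LOW + 0.01))
        paco2 = rng.uniform(eff_lo, hi)
    elif spec.direction == "high":
        u = rng.uniform(0.005, 0.045) if spec.adequacy == "probable_zone" else rng.uniform(0.07, 0.25)
        paco2 = hi * (1 + u)
        certainty = Certainty.PROBABLE if spec.adequacy == "probable_zone" else Certainty.DEFINITE
        additional.add(DisorderLabel(DisorderKind.RESPIRATORY_ACIDOSIS, certainty=certainty))
    elif spec.direction == "low":
        if spec.adequacy == "probable_zone":
            paco2 = lo * (1 - rng.uniform(0.005, 0.045))
        else:
            paco2 = rng.uniform(max(hco3 / _K_LOW * 1.01, 10.1), lo * 0.93)
        certainty = Certainty.PROBABLE if spec.adequacy == "probable_zone" else Certainty.DEFINITE
        additional.add(DisorderLabel(DisorderKind.RESPIRATORY_ALKALOSIS, certainty=certainty))
    else:
        raise GenerationError("metabolic zones need direction 'high' or 'low'")
    if spec.primary is DisorderKind.HAGMA:
        # place the delta ratio inside [0.8, 1.2] so no third disorder is implied
        ag = 7.0 + rng.uniform(0.85, 1.15) * (24.0 - hco3)
    else:
        ag = _normal_ag(rng)
    return hco3, paco2, ag, additional


def _met_alk_panel(rng: random.Random, spec: TruthSpec) -> tuple[float, float, float, set]:
    rules = DEFAULT_RULES
    if spec.adequacy != "in_band" and spec.direction == "high":
        hco3 = rng.uniform(35.0, 50.0) if spec.adequacy == "probable_zone" else rng.uniform(42.0, 50.0)
    else:
        hco3 = rng.uniform(30.0, 50.0)
    center = rules.met_alk_slope * (hco3 - 24.0) + 40.0
    lo, hi = center - rules.met_alk_band, center + rules.met_alk_band
    additional: set = set()
    if spec.adequacy == "in_band":
        # avoid normal pH with PaCO2 above range (would read as mixed)
        eff_hi = min(hi, max(44.0, hco3 / _K_HIGH - 0.01))
        paco2 = rng.uniform(lo, eff_hi)
    elif spec.direction == "low":
        u = rng.uniform(0.005, 0.045) if spec.adequacy == "probable_zone" else rng.uniform(0.07, 0.3)
        paco2 = lo * (1 - u)
        certainty = Certainty.PROBABLE if spec.adequacy == "probable_zone" else Certainty.DEFINITE
        additional.add(DisorderLabel(DisorderKind.RESPIRATORY_ALKALOSIS, certainty=certainty))
    elif spec.direction == "high":
        u = rng.uniform(0.005, 0.045) if spec.adequacy == "probable_zone" else rng.uniform(0.07, 0.14)
        paco2 = hi * (1 + u)
        certainty = Certainty.PROBABLE if spec.adequacy == "probable_zone" else Certainty.DEFINITE
        additional.add(DisorderLabel(DisorderKind.RESPIRATORY_ACIDOSIS, certainty=certainty))
    else:
        raise GenerationError("metabolic zones need direction 'high' or 'low'")
    return hco3, paco2, _normal_ag(rng), additional


def _resp_panel(rng: random.Random, spec: TruthSpec) -> tuple[float, float, float, set]:
    rules = DEFAULT_RULES
    acid = spec.primary is DisorderKind.RESPIRATORY_ACIDOSIS
    additional: set = set()
    if spec.adequacy == "probable_zone":
        raise GenerationError(
            "probable_zone is a point-margin construct for metabolic primaries "
            "only; respiratory chronicity margins admit no probable grade"
        )
    if spec.adequacy == "in_band":
        if spec.chronicity is Chronicity.ACUTE:
            paco2 = rng.uniform(50.0, 80.0) if acid else rng.uniform(18.0, 32.0)
            slope = rules.resp_acid_acute_slope if acid else rules.resp_alk_acute_slope
            u = rng.uniform(-0.03, 0.03)
        elif spec.chronicity is Chronicity.CHRONIC:
            paco2 = rng.uniform(80.0, 95.0) if acid else rng.uniform(18.0, 26.0)
            slope = rules.resp_acid_chronic_slope if acid else rules.resp_alk_chronic_slope
            u = rng.uniform(-0.04, 0.03)
        else:
            raise GenerationError("respiratory in_band specs need acute or chronic chronicity")
        delta = paco2 - 40.0
        center = 24.0 + slope * delta if acid else 24.0 - slope * abs(delta)
        hco3 = center * (1 + u)
    else:  # definite_zone: marker short of the acute expectation
        if acid:
            paco2 = rng.uniform(55.0, 80.0)
            acute = 24.0 + rules.resp_acid_acute_slope * (paco2 - 40.0)
            hco3 = acute * (1 - rng.uniform(0.08, 0.25))
            additional.add(DisorderLabel(DisorderKind.NAGMA))
        else:
            paco2 = rng.uniform(20.0, 30.0)
            acute = 24.0 - rules.resp_alk_acute_slope * (40.0 - paco2)
            hco3 = min(acute * (1 + rng.uniform(0.08, 0.2)), 25.5)
            additional.add(DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS))
    return hco3, paco2, _normal_ag(rng), additional


def _normal_panel(rng: random.Random, spec: TruthSpec) -> tuple[float, float, float, Optional[float], set, Optional[set]]:
    """(hco3, paco2, ag, albumin, labels, agc labels) for primary=None."""
    paco2 = rng.uniform(37.0, 43.0)
    restrict = spec.ag_mode in ("occult_hagma", "ge25", "ge30", "low_albumin")
    h_hi = min(23.5 if restrict else 25.8, 0.645 * paco2)
    hco3 = rng.uniform(max(22.2, 0.53 * paco2), h_hi)
    albumin: Optional[float] = 40.0 if spec.include_albumin else None
    agc_labels: Optional[set] = None
    if spec.ag_mode == "normal":
        ag, labels = _normal_ag(rng), set()
    elif spec.ag_mode == "occult_hagma":
        # bicarbonate barely moved, gap clearly up: the ratio is always > 2
        ag = rng.uniform(14.0, 22.0)
        labels = {DisorderLabel(DisorderKind.HAGMA), DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS)}
    elif spec.ag_mode == "ge25":
        ag = rng.uniform(25.0, 29.0)
        labels = {DisorderLabel(DisorderKind.HAGMA), DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS)}
    elif spec.ag_mode == "ge30":
        ag = rng.uniform(30.0, 40.0)
        labels = {DisorderLabel(DisorderKind.HAGMA), DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS)}
    elif spec.ag_mode == "low_albumin":
        ag = rng.uniform(9.5, 10.5)
        albumin = rng.uniform(20.0, 28.0)
        labels = set()
        agc_labels = {DisorderLabel(DisorderKind.HAGMA), DisorderLabel(DisorderKind.METABOLIC_ALKALOSIS)}
    else:
        raise GenerationError(f"unknown ag_mode {spec.ag_mode!r}")
    return hco3, paco2, ag, albumin, labels, agc_labels


def generate(spec: TruthSpec, seed: int) -> SyntheticCase:
    """Build a panel realizing ``spec``; deterministic for a fixed seed.

    The pH is computed exactly from the generated PaCO2 and HCO3- (plus
    ``ph_offset`` when an inconsistency is injected), so generated panels
    never trip the Henderson-Hasselbalch screen by accident.
    """
    if spec.chronicity is not Chronicity.NONE and spec.primary not in _RESP_KINDS:
        raise GenerationError("chronicity is only meaningful for respiratory primaries")
    if spec.ag_mode != "normal" and spec.primary is not None:
        raise GenerationError("anion-gap scenarios are generated on acid-base-normal panels")
    rng = random.Random(seed)
    albumin: Optional[float] = 40.0 if spec.include_albumin else None
    agc_labels: Optional[frozenset] = None

    if spec.primary is None:
        hco3, paco2, ag, albumin, labels, agc_set = _normal_panel(rng, spec)
        if agc_set is not None:
            agc_labels = frozenset(agc_set)
    elif spec.primary in (DisorderKind.NAGMA, DisorderKind.HAGMA):
        hco3, paco2, ag, additional = _met_acid_panel(rng, spec)
        labels = {DisorderLabel(spec.primary)} | additional
    elif spec.primary is DisorderKind.METABOLIC_ALKALOSIS:
        hco3, paco2, ag, additional = _met_alk_panel(rng, spec)
        labels = {DisorderLabel(spec.primary)} | additional
    elif spec.primary in _RESP_KINDS:
        hco3, paco2, ag, additional = _resp_panel(rng, spec)
        chronicity = spec.chronicity if spec.adequacy == "in_band" else Chronicity.NONE
        labels = {DisorderLabel(spec.primary, chronicity=chronicity)} | additional
    else:
        raise GenerationError(f"unsupported primary {spec.primary!r}")

    ph = hh_ph(paco2, hco3) + spec.ph_offset
    panel = BloodGasPanel(
        ph=ph, paco2=paco2, hco3=hco3, ag=ag, albumin=albumin
    )
    return SyntheticCase(
        panel=panel,
        truth=spec,
        seed=seed,
        expected_labels=frozenset(labels),
        expected_labels_agc=agc_labels,
        expects_reject=abs(spec.ph_offset) > _RANGES.ph_reject,
    )
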