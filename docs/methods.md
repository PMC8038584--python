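# Methods

## Scope and model

`abgkit` implements a deterministic rule engine for single arterial
blood-gas panels. It is not a physicochemical (Stewart) model: the four
approaches it runs are the classical physiological (Boston, HCO₃⁻-based)
and chemical (Copenhagen, SBE-based) interpretations, each with and without
albumin correction of the anion gap. The engine assumes one panel at one
time point, standard HCO₃⁻ preferred (actual HCO₃⁻ accepted in its place),
and no clinical context — a deliberately narrow contract that keeps every
decision auditable from the printed evidence in the report.

## Screening

Interpretation refuses to start without pH, PaCO₂, HCO₃⁻ and a gap (given
or derivable from Na⁺/Cl⁻). Values outside generous survivable-extreme
windows (pH 6.5–8.0, PaCO₂ 10–150 mm Hg, HCO₃⁻ 1–60 mmol/L, SBE ±35
mmol/L, AG −5–60 mEq/L, albumin 5–70 g/L) draw warnings only: the windows
flag probable typos, and rejecting on them would punish genuine extreme
physiology. The only hard gate is Henderson–Hasselbalch consistency,
|pH − (6.1 + log₁₀(HCO₃⁻/(0.03·PaCO₂)))|: ≤ 0.02 silent, ≤ 0.1 warning,
beyond that the panel is rejected as incorrect data. pK 6.1 and CO₂
solubility 0.03 (mmol/L)/mm Hg are the conventional constants and
reproduce the packaged survey panels to within ~0.001 pH unit. A supplied
SBE that disagrees with the van Slyke estimate is reported as information
only — analyzers legitimately use different base-excess formulas — and the
supplied value always wins.

## Classification

Reference intervals (pH 7.34–7.44, PaCO₂ 36–44, HCO₃⁻ 22–26, SBE −2–2,
AG 3–11, albumin 35–50) are treated as closed: a boundary value is normal.
The AG interval is the modern ion-selective-electrode range; older,
higher AG ranges can be restored through the config file.

The pH decides the branch. When it is abnormal and explained by exactly
one axis, that axis is primary and the other axis' *secondary response* is
graded against an expectation:

| primary | physiological rule | chemical rule |
|---|---|---|
| metabolic acidosis | PaCO₂ = 1.5·HCO₃⁻ + 8 ± 2 | PaCO₂ = 40 + 1.0·SBE (point) |
| metabolic alkalosis | PaCO₂ = 0.7·(HCO₃⁻−24) + 40 ± 2 | PaCO₂ = 40 + 0.6·SBE (point) |
| respiratory, acute | HCO₃⁻ = 24 + 0.1·ΔPaCO₂ (acidosis) / 24 − 0.2·\|ΔPaCO₂\| (alkalosis) | SBE = 0 ± 2 |
| respiratory, chronic | HCO₃⁻ = 24 ± 0.4·\|ΔPaCO₂\| | SBE = 0.4·ΔPaCO₂ ± 2 |

ΔPaCO₂ is measured from the 40 mm Hg baseline. A partner value beyond the
expected band by at most 5% of the edge yields a *probable* additional
disorder; beyond 5%, a *definite* one. The margin is computed relative to
the band edge (not the center) and is configurable; for point estimates
the two coincide. For respiratory primaries the marker position grades
chronicity: near the acute expectation (±5%) → acute, near the chronic
one → chronic, beyond chronic in the compensation direction → chronic plus
a definite metabolic disorder in that direction, short of the acute
expectation toward baseline → an opposing metabolic disorder with
chronicity left ungraded, and in the gap between the two expectations the
chronicity is reported indeterminate. The chronic respiratory-acidosis
slope is 0.4 by default and exposed in the config, since published
variants use 0.35.

When the pH is abnormal and both axes explain it, both disorders are
reported without compensation grading (a concordant double derangement
admits no unique expectation). When the pH is normal but a component is
abnormal, the panel cannot be a fully compensated simple disorder —
no disturbance compensates completely — so every component-supported
disorder is reported as part of a mixed picture, without chronicity.

## Anion-gap logic

Metabolic acidosis is typed high-gap (HAGMA) or normal-gap (NAGMA) by the
gap in use (AG or AGc; AGc = AG + 0.25·(40 − albumin)). An elevated gap
with *no* metabolic disorder on the list reveals an occult HAGMA. With
metabolic alkalosis present, moderate gap elevation is an expected
fluctuation and is not escalated; only AG ≥ 25 mEq/L draws a
consider-additional-disorder note and AG ≥ 30 asserts HAGMA outright.
Whenever HAGMA is present the delta ratio (AG − 7)/(24 − HCO₃⁻) — always
computed from HCO₃⁻, also in the chemical approaches, since it is a
bicarbonate-consumption ratio — screens for a third disorder: < 0.8
suggests coexisting NAGMA (probable); 0.8–1.2 is proportionate; 1.2–2
suggests metabolic alkalosis (probable); > 2 asserts it. Edges 0.8, 1.2
belong to the middle band and 2.0 to the 1.2–2 band. When bicarbonate has
not fallen (denominator ≤ 0) but the gap is up, the ratio is taken as
infinite (metabolic alkalosis definite); with a baseline gap it is not
applicable. The 1.2–2 band maps to *probable* metabolic alkalosis: the
reference case collection consistently labels ratios of 1.385, 1.8 and
exactly 2.0 as "possible additional metabolic alkalosis", so the probable
grade is the behavior the packaged expectations encode. A ratio
suggestion never downgrades a disorder already established as definite.

## Aggregation and output

Compliance is the largest fraction of approaches whose diagnosis sets —
compared as sets of (kind, chronicity, certainty), never as prose — are
identical: 25/50/75/100% over four approaches, 50/100% over two. Rendering
is a pure function of the label set with a fixed order (definite before
probable, respiratory before metabolic-typed labels), so equal sets are
byte-identical in text and JSON output. Probable respiratory labels read
"probably with …" (borderline compensation); probable metabolic labels
read "possible additional …" (delta-ratio suggestions).

## Synthetic generator

`fixtures.generate` inverts the physiological rule table: it samples a
severity for the requested primary disorder (metabolic acidosis HCO₃⁻ 4–20
mmol/L, alkalosis 30–50; respiratory severities chosen so the derived pH
stays on the acid or alkaline side of normal), places the partner value in
the requested adequacy zone (in-band, probable, definite) relative to the
expected compensation, chooses the gap to realize the requested anion-gap
scenario (normal, occult HAGMA, ≥ 25, ≥ 30, low-albumin masking), and
derives the pH exactly from PaCO₂ and HCO₃⁻, optionally offsetting it to
inject an inconsistency. Sampling windows are deliberately restricted so
the construction labels are provable from the rule set itself (e.g.
fully compensated chronic respiratory disorders would land at normal pH
and be reported as mixed, so chronic in-band severities are drawn where
the pH stays abnormal). The generator emulates rule-consistent panels
only: it adds no measurement noise, no analyzer-specific SBE formulas and
no biological covariance between albumin and the gap, so a passing
recovery suite demonstrates internal consistency of the classifier, not
performance on real analyzer output. Randomness comes from a named
`random.Random(seed)`; every generated case records its seed and truth
specification.

## Numerical choices and problem sizes

All comparisons run at full float precision; no rounding precedes a
threshold. The delta-ratio property test scans AG ∈ [3, 50] × HCO₃⁻ ∈
[2, 26] at 0.25 steps against an independent edge-rule oracle; the
recovery suite draws 1000 seeded cases across ten truth specifications
(and a further ~5000 across all combinations during development), sizes
chosen to cover every branch of the rule table while keeping the default
test run in seconds.

## Known limitations

- A ketoacidosis presenting with alkalemia and AG < 25 reports only the
  metabolic alkalosis; the coexisting high-gap acidosis needs the clinical
  context the engine does not see.
- The chemical approaches use point compensation estimates, so a panel
  sitting a fraction of a mm Hg from the expectation can pick up a
  probable label that the banded physiological rule ignores; one packaged
  discordant case is shipped with its chemical expectations deliberately
  unasserted for this reason.
- The delta ratio is a known source of false positives/negatives; its
  suggestions therefore enter as probable wherever the evidence is
  borderline.
- Oxygenation, temperature correction, lactate/ketone/urine chemistry and
  strong-ion calculations are out of scope.
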