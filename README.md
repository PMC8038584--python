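# abgkit

Rule-based interpretation of arterial blood-gas (ABG) panels.

Acid–base disturbances are read from three measurements — pH, the partial
pressure of CO₂ (PaCO₂) and bicarbonate (HCO₃⁻) — yet the same panel can be
interpreted by competing schools: the *physiological* (Boston) approach grades
compensation against HCO₃⁻-based rules, while the *chemical* (Copenhagen)
approach uses the standard base excess (SBE). On top of that, the anion gap
(AG) may or may not be corrected for albumin, and the correction can flip a
diagnosis (a hypoalbuminemic patient's "normal-gap" acidosis may really be a
high-gap one). `abgkit` runs **all four variants concurrently** —
physiological and chemical, each with the plain and the albumin-corrected
gap (AGc) — and reports how much the four diagnoses agree, so discordant
panels get flagged instead of silently resolved. It is aimed at laboratory
scientists, clinicians and educators who need a transparent, configurable
second reader for blood-gas panels.

## The rule set

For a panel (pH, PaCO₂, HCO₃⁻ [, SBE, AG or Na⁺/Cl⁻, albumin]):

**Derived quantities**

- Henderson–Hasselbalch pH (consistency screen):
  `pH = 6.1 + log₁₀(HCO₃⁻ / (0.03 · PaCO₂))`.
  |ΔpH| > 0.02 warns; |ΔpH| > 0.1 rejects the panel as incorrect data.
- van Slyke SBE (when not supplied):
  `SBE = 0.9287 · (HCO₃⁻ − 24.4 + 14.83 · (pH − 7.4))`.
- Anion gap: `AG = Na⁺ − (Cl⁻ + HCO₃⁻)`; albumin-corrected gap:
  `AGc = AG + 0.25 · (Alb_normal − Alb)` with Alb_normal = 40 g/L.

**Classification** (reference intervals: pH 7.34–7.44, PaCO₂ 36–44 mm Hg,
HCO₃⁻ 22–26 mmol/L, SBE −2–2 mmol/L, AG 3–11 mEq/L). An abnormal pH
explained by one axis makes that axis the primary disorder and the expected
secondary response of the other axis is graded (e.g. Winter-type
`PaCO₂ = 1.5 · HCO₃⁻ + 8 ± 2` for metabolic acidosis; `PaCO₂ = 0.7 ·
(HCO₃⁻ − 24) + 40 ± 2` for metabolic alkalosis; SBE-based point rules in the
chemical approaches). A measured value beyond the expected band by at most
5% yields a *probable* additional disorder, beyond that a *definite* one;
for respiratory primaries the marker position grades chronicity
(acute/chronic). Since no disturbance compensates completely, any abnormal
component at normal pH is reported as part of a mixed disorder. Finally the
delta ratio `ΔAG/ΔHCO₃⁻ = (AG − 7)/(24 − HCO₃⁻)` screens every high-gap
acidosis for a third disorder (< 0.8 suggests coexisting normal-gap
acidosis; 1.2–2 suggests, and > 2 asserts, metabolic alkalosis), with
escalations at AG ≥ 25 and ≥ 30 mEq/L.

**Compliance** = 100 × (largest group of approaches returning an identical
diagnosis set) / (approaches run).

Every constant above lives in a config file (`--config ranges/rules
overrides`), because reference ranges and compensation coefficients vary
between laboratories.

## Worked example

A severe metabolic acidosis with hypoalbuminemia:

```sh
abg analyze --ph 7.06 --paco2 28 --hco3 8 --ag 10 --alb 23
```

prints

```
Comparing four approaches. The compliance of the results is 50%.

physiological approach: respiratory acidosis and normal anion gap metabolic acidosis
physiological approach with AGc: respiratory acidosis and high anion gap metabolic acidosis, possible additional normal anion gap metabolic acidosis
chemical approach: respiratory acidosis and normal anion gap metabolic acidosis
chemical approach with AGc: respiratory acidosis and high anion gap metabolic acidosis, possible additional normal anion gap metabolic acidosis

validation:
  [info] SBE absent - estimated from pH and HCO3- (van Slyke)
```

Reading the numbers: the expected compensation for HCO₃⁻ 8 is PaCO₂ 18–22
mm Hg, and the measured 28 exceeds the band by more than 5%, so an
additional respiratory acidosis is definite. The plain gap (10) is normal,
but the albumin correction gives AGc = 10 + 0.25 · (40 − 23) = **14.25
mEq/L** — a high-gap acidosis. Its delta ratio (14.25 − 7)/(24 − 8) =
**0.45** falls below 0.8, so a coexisting normal-gap acidosis is also
suspected. The two plain-gap approaches disagree with the two corrected
ones, hence **50%** compliance: a grey-zone panel worth a second look.

Batch mode (`abg batch cases.csv --out reports.json`) interprets a CSV/JSON
table of panels and writes schema-checked JSON reports; rejected panels are
results, not crashes.

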