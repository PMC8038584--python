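"""Classifier behavior: branch logic, anion-gap screen, aggregation."""

import itertools

import pytest

from abgkit import (
    Approach,
    ApproachResult,
    BloodGasPanel,
    Certainty,
    Chronicity,
    DisorderKind,
    DisorderLabel,
    build_contexts,
    classify,
    compliance,
    resolve_panel,
    run_all,
)

D = DisorderKind
C = Chronicity


def _labels(report, approach):
    result = next(r for r in report.results if r.approach is approach)
    return {(l.kind, l.chronicity, l.certainty) for l in result.labels}


def _lab(kind, chronicity=C.NONE, certainty=Certainty.DEFINITE):
    return (kind, chronicity, certainty)


class TestClassifyBranches:
    def test_fully_normal_panel_is_correct_results(self, normal_panel):
        report = run_all(normal_panel)
        assert len(report.results) == 4
        assert all(not r.labels for r in report.results)

    def test_single_primary_with_failed_compensation(self):
        # alkalemia, PaCO2 far below the expected compensation band
        report = run_all(BloodGasPanel(ph=7.6, paco2=45, hco3=51, ag=14))
        assert _labels(report, Approach.PHYSIOLOGICAL) == {
            _lab(D.METABOLIC_ALKALOSIS),
            _lab(D.RESPIRATORY_ALKALOSIS),
        }

    def test_concordant_double_derangement(self):
        # acidemia explained by both axes at once
        report = run_all(BloodGasPanel(ph=7.068, paco2=61, hco3=17, sbe=-11.44, ag=8))
        assert _lab(D.RESPIRATORY_ACIDOSIS) in _labels(report, Approach.PHYSIOLOGICAL)
        assert _lab(D.NAGMA) in _labels(report, Approach.PHYSIOLOGICAL)

    def test_normal_ph_with_abnormal_components_is_mixed(self):
        # opposing derangements cancel in the pH: both are reported
        report = run_all(BloodGasPanel(ph=7.42, paco2=59, hco3=36, ag=7))
        assert _labels(report, Approach.PHYSIOLOGICAL) == {
            _lab(D.RESPIRATORY_ACIDOSIS),
            _lab(D.METABOLIC_ALKALOSIS),
        }


class TestSecondaryResponse:
    def test_metabolic_primary_definite_beyond_margin(self):
        # expected PaCO2 18-22; measured 28 exceeds the 5% margin
        report = run_all(BloodGasPanel(ph=7.06, paco2=28, hco3=8, ag=10))
        assert _lab(D.RESPIRATORY_ACIDOSIS) in _labels(report, Approach.PHYSIOLOGICAL)

    def test_metabolic_primary_probable_within_margin(self):
        # expected PaCO2 20 +/- 2; measured just above 22 but below 23.1
        report = run_all(BloodGasPanel(ph=7.083, paco2=22.8, hco3=8, ag=10))
        assert _lab(
            D.RESPIRATORY_ACIDOSIS, certainty=Certainty.PROBABLE
        ) in _labels(report, Approach.PHYSIOLOGICAL)

    def test_respiratory_primary_acute_chronicity(self):
        # HCO3- exactly at the acute expectation 24 - 0.2 x 13 = 21.4
        report = run_all(BloodGasPanel(ph=7.522, paco2=27, hco3=21.4, sbe=-1.11, ag=11))
        assert _labels(report, Approach.PHYSIOLOGICAL) == {
            _lab(D.RESPIRATORY_ALKALOSIS, chronicity=C.ACUTE)
        }

    def test_respiratory_primary_chronic_chronicity(self):
        # HCO3- 16 within 5% of the chronic expectation 17.2
        report = run_all(BloodGasPanel(ph=7.47, paco2=23, hco3=16, ag=9))
        labels = _labels(report, Approach.PHYSIOLOGICAL)
        assert _lab(D.RESPIRATORY_ALKALOSIS, chronicity=C.CHRONIC) in labels

    def test_respiratory_primary_marker_short_of_acute(self):
        # HCO3- 21 well below the acute expectation 28.2: an opposing
        # metabolic acidosis coexists and chronicity cannot be graded
        report = run_all(BloodGasPanel(ph=7.042, paco2=82, hco3=21, sbe=-8.09, ag=8))
        assert _labels(report, Approach.PHYSIOLOGICAL) == {
            _lab(D.RESPIRATORY_ACIDOSIS),
            _lab(D.NAGMA),
        }

    def test_respiratory_marker_between_acute_and_chronic(self):
        # PaCO2 70: acute expectation 27, chronic 36; HCO3- 31.5 sits in
        # the gap -> chronicity indeterminate, no extra metabolic label
        report = run_all(BloodGasPanel(ph=7.272, paco2=70, hco3=31.5, ag=9))
        result = next(
            r for r in report.results if r.approach is Approach.PHYSIOLOGICAL
        )
        assert {(l.kind, l.chronicity) for l in result.labels} == {
            (D.RESPIRATORY_ACIDOSIS, C.NONE)
        }
        assert any("indeterminate" in note for note in result.notes)


class TestAnionGapLogic:
    def test_occult_hagma_behind_a_normal_panel(self):
        # all values in range, gap 19: occult high-gap acidosis plus the
        # metabolic alkalosis implied by an unconsumed bicarbonate
        report = run_all(BloodGasPanel(ph=7.39, paco2=39, hco3=22, ag=19))
        assert _labels(report, Approach.PHYSIOLOGICAL) == {
            _lab(D.HAGMA),
            _lab(D.METABOLIC_ALKALOSIS),
        }

    def test_elevated_gap_tolerated_during_metabolic_alkalosis(self):
        # gap 14 with metabolic alkalosis: expected fluctuation, no HAGMA
        report = run_all(BloodGasPanel(ph=7.6, paco2=45, hco3=51, ag=14))
        kinds = {k for k, _, _ in _labels(report, Approach.PHYSIOLOGICAL)}
        assert D.HAGMA not in kinds

    def test_gap_at_consider_threshold_notes_additional_disorder(self):
        report = run_all(BloodGasPanel(ph=7.36, paco2=22, hco3=11, ag=25))
        result = next(r for r in report.results if r.approach is Approach.PHYSIOLOGICAL)
        assert any("consider" in note for note in result.notes)

    def test_ratio_exactly_two_stays_probable(self):
        # (43-7)/(24-6) = 2.0 belongs to the 1.2-2 band
        report = run_all(BloodGasPanel(ph=7.01, paco2=26, hco3=6, ag=43))
        assert _lab(
            D.METABOLIC_ALKALOSIS, certainty=Certainty.PROBABLE
        ) in _labels(report, Approach.PHYSIOLOGICAL)

    def test_ratio_below_0p8_suggests_coexisting_nagma(self):
        report = run_all(BloodGasPanel(ph=7.06, paco2=28, hco3=8, ag=10, albumin=23))
        assert _labels(report, Approach.PHYSIOLOGICAL_AGC) == {
            _lab(D.HAGMA),
            _lab(D.RESPIRATORY_ACIDOSIS),
            _lab(D.NAGMA, certainty=Certainty.PROBABLE),
        }

    @pytest.mark.parametrize(
        "ph, paco2, hco3",
        [(7.06, 28, 8), (7.39, 39, 22), (7.6, 45, 51)],
    )
    def test_gap_monotonicity_never_removes_hagma(self, ph, paco2, hco3, ranges):
        """With everything else fixed, raising the gap can only add HAGMA."""
        from abgkit import CompensationRules

        rules = CompensationRules()
        seen_hagma = False
        for ag in [6 + 0.5 * i for i in range(60)]:
            resolved = resolve_panel(BloodGasPanel(ph=ph, paco2=paco2, hco3=hco3, ag=ag))
            contexts, _ = build_contexts(resolved, ranges, rules)
            phys = next(c for c in contexts if c.approach is Approach.PHYSIOLOGICAL)
            kinds = {l.kind for l in classify(resolved, phys).labels}
            if seen_hagma:
                assert D.HAGMA in kinds, ag
            seen_hagma = seen_hagma or D.HAGMA in kinds
        assert seen_hagma


class TestRunAllAggregation:
    def test_four_approaches_with_albumin_two_without(self):
        with_alb = run_all(BloodGasPanel(ph=7.4, paco2=40, hco3=24, ag=11, albumin=40))
        without = run_all(BloodGasPanel(ph=7.4, paco2=40, hco3=24, ag=11))
        assert len(with_alb.results) == 4 and not with_alb.skipped
        assert len(without.results) == 2
        assert set(without.skipped) == {Approach.PHYSIOLOGICAL_AGC, Approach.CHEMICAL_AGC}

    def test_reject_suppresses_all_results(self):
        report = run_all(BloodGasPanel(ph=7.438, paco2=38, hco3=18, ag=17))
        assert report.rejected
        assert report.results == []
        assert report.compliance_pct is None

    def test_supplied_sbe_takes_precedence_over_van_slyke(self):
        # a deliberately shifted SBE changes the chemical result only
        panel = BloodGasPanel(ph=7.331, paco2=31.3, hco3=16, sbe=-14.0, ag=10.5)
        report = run_all(panel)
        chem = next(r for r in report.results if r.approach is Approach.CHEMICAL)
        assert chem.evidence["expected_paco2_hi"] == pytest.approx(26.0)

    def test_compliance_permutation_invariant(self):
        report = run_all(BloodGasPanel(ph=7.06, paco2=28, hco3=8, ag=10, albumin=23))
        assert report.compliance_pct == 50.0
        values = {
            compliance(list(perm)) for perm in itertools.permutations(report.results)
        }
        assert values == {50.0}

    def test_three_against_one_split_is_75(self):
        labels = frozenset({DisorderLabel(D.HAGMA)})
        results = [
            ApproachResult(approach=Approach.PHYSIOLOGICAL, labels=labels),
            ApproachResult(approach=Approach.PHYSIOLOGICAL_AGC, labels=labels),
            ApproachResult(approach=Approach.CHEMICAL, labels=labels),
            ApproachResult(approach=Approach.CHEMICAL_AGC, labels=frozenset()),
        ]
        assert compliance(results) == 75.0

    def test_determinism(self):
        panel = BloodGasPanel(ph=7.47, paco2=23, hco3=16, ag=44)
        first = run_all(panel)
        second = run_all(panel)
        assert [r.labels for r in first.results] == [r.labels for r in second.results]
        assert first.compliance_pct == second.compliance_pct
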