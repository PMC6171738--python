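"""SDI, weighted SDI and percent-improvement arithmetic and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexsim import (
    ModelSpec,
    ObservedCoexpression,
    Rule,
    compute_sdi_report,
    interpret_sdi,
    percent_improvement,
    rank_models,
    run_model,
    sdi,
    weighted_sdi,
)


class TestSdi:
    def test_perfect_consensus_is_zero(self):
        assert sdi(0.42, 0.42, 0.05, 0.03) == 0.0

    def test_uses_the_greatest_sd(self):
        assert sdi(0.50, 0.40, 0.05, 0.10) == pytest.approx(1.0)

    def test_symmetric_in_sign_of_difference(self):
        assert sdi(0.30, 0.40, 0.10, 0.05) == pytest.approx(1.0)
        assert sdi(0.50, 0.40, 0.10, 0.05) == pytest.approx(
            sdi(0.30, 0.40, 0.10, 0.05)
        )

    def test_both_sds_zero(self):
        assert sdi(0.4, 0.4, 0.0, 0.0) == 0.0
        with pytest.raises(ValueError, match="undefined"):
            sdi(0.5, 0.4, 0.0, 0.0)

    @given(
        mm=st.floats(0, 1), mo=st.floats(0, 1),
        sm=st.floats(0.001, 1), so=st.floats(0.001, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_and_sign_symmetric(self, mm, mo, sm, so):
        value = sdi(mm, mo, sm, so)
        assert value >= 0
        assert value == sdi(mo, mm, sm, so)

    def test_interpretation_scale(self):
        assert "perfect" in interpret_sdi(0.0)
        assert "reasonably well" in interpret_sdi(0.8)
        assert "does not replicate" in interpret_sdi(2.3)


class TestWeightedSdi:
    def test_single_pair(self):
        assert weighted_sdi([1.0], [180], 360) == pytest.approx(0.5)

    def test_all_zero_sdis(self):
        assert weighted_sdi([0.0, 0.0, 0.0], [10, 20, 30], 360) == 0.0

    def test_prevalence_weighting_arithmetic(self):
        # a prevalent pair (overlap 144) outweighs a rare one (overlap 12)
        value = weighted_sdi([1.0, 0.5], [12, 144], 360)
        assert value == pytest.approx(1.0 * 12 / 360 + 0.5 * 144 / 360)
        assert value == pytest.approx(0.2333, abs=1e-4)

    def test_missing_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="missing observed overlap"):
            weighted_sdi([1.0, 0.5], [12, np.nan], 360)

    @given(
        sdis=st.lists(st.floats(0, 5), min_size=1, max_size=8),
        extra=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_and_zero_pair_invariant(self, sdis, extra):
        weights = [10.0] * len(sdis)
        base = weighted_sdi(sdis, weights, 360)
        # linearity in the per-pair SDIs with fixed weights
        doubled = weighted_sdi([2 * s for s in sdis], weights, 360)
        assert doubled == pytest.approx(2 * base, rel=1e-9, abs=1e-12)
        # removing a zero-SDI pair never changes the total
        with_zero = weighted_sdi(sdis + [0.0], weights + [99.0], 360)
        assert with_zero == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestPercentImprovement:
    def test_printed_weighted_sdis_give_75_8(self):
        # the two headline weighted SDIs: single-rule 0.36 vs independent 1.49
        assert percent_improvement(0.36, 1.49) == pytest.approx(75.84, abs=0.005)

    def test_no_improvement_is_zero(self):
        assert percent_improvement(0.7, 0.7) == 0.0

    def test_doubling_is_minus_100(self):
        assert percent_improvement(2.98, 1.49) == pytest.approx(-100.0)

    def test_zero_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            percent_improvement(0.5, 0.0)


def _observed_from_result(result, overlap_value=30.0, sd=0.02):
    k = len(result.transmitters)
    return ObservedCoexpression(
        transmitters=result.transmitters,
        ratio_mean=result.mean_ratio.copy(),
        ratio_sd=np.full((k, k), sd),
        overlap=np.full((k, k), overlap_value),
    )


class TestRankModels:
    def test_model_vs_itself_ranks_first_with_zero_sdi(self, peptide_panel):
        spec = ModelSpec(panel=peptide_panel, n_iterations=300, seed=11)
        result = run_model(spec)
        observed = _observed_from_result(result)
        reports = rank_models([(spec, result)], observed)
        assert reports[0].weighted_sdi == pytest.approx(0.0)
        assert reports[0].percent_improvement is None  # reference SDI is 0

    def test_clamped_model_scores_better_on_the_clamped_pair(self, peptide_panel):
        # observed MIP->Mas-AT at 0.42; the clamping model must have lower SDI
        indep = ModelSpec(panel=peptide_panel, n_iterations=600, seed=13, label="independent")
        ruled = ModelSpec(
            panel=peptide_panel, rules=(Rule("MIP", "Mas-AT", 0.42),),
            n_iterations=600, seed=13,
        )
        ri, rr = run_model(indep), run_model(ruled)
        observed = _observed_from_result(ri)
        i, j = peptide_panel.index("MIP"), peptide_panel.index("Mas-AT")
        observed.ratio_mean[i, j] = 0.42
        pairs = [("MIP", "Mas-AT")]
        rep_i = compute_sdi_report(ri, observed, pairs=pairs)
        rep_r = compute_sdi_report(rr, observed, pairs=pairs, n_rules=1)
        assert rep_r.pairs["sdi"].iloc[0] < rep_i.pairs["sdi"].iloc[0]

    def test_sorted_ascending_with_rule_count_tiebreak(self, peptide_panel):
        spec_a = ModelSpec(panel=peptide_panel, n_iterations=200, seed=17, label="independent")
        spec_b = ModelSpec(
            panel=peptide_panel, rules=(Rule("TK", "MIP", 1.0),), n_iterations=200, seed=17
        )
        items = [(spec_b, run_model(spec_b)), (spec_a, run_model(spec_a))]
        observed = _observed_from_result(items[1][1])
        reports = rank_models(items, observed)
        assert [r.weighted_sdi for r in reports] == sorted(r.weighted_sdi for r in reports)
        assert reports[0].label == "independent"  # exact match on its own output

    def test_pairs_without_observed_sd_are_excluded_and_listed(self, peptide_panel):
        spec = ModelSpec(panel=peptide_panel, n_iterations=100, seed=19)
        result = run_model(spec)
        observed = _observed_from_result(result)
        i, j = peptide_panel.index("TK"), peptide_panel.index("MIP")
        observed.ratio_sd[i, j] = np.nan
        pairs = [("TK", "MIP"), ("TK", "FMRF"), ("MIP", "Mas-AT")]
        report = compute_sdi_report(result, observed, pairs=pairs)
        assert ("TK", "MIP") in report.excluded_pairs
        assert ("TK", "MIP") not in report.pairs_used()
        assert ("TK", "FMRF") in report.pairs_used()
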