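"""Dose-band assignment, the rule-based marker predictor and trans-inhibition."""

import itertools

import pytest

from laserddr import TreatmentCondition, dose_band, predict, trans_inhibition
from laserddr.errors import InvalidArgumentError, OutOfRangeError


def cond(*tokens):
    return TreatmentCondition.from_tokens(tokens)


class TestDoseBand:
    @pytest.mark.parametrize(
        "setting,band",
        [(20, "sub_threshold"), (25, "low"), (60, "low"), (84.9, "low"),
         (85, "high"), (100, "high"), (155, "high")],
    )
    def test_mira_bands(self, mira, setting, band):
        assert dose_band(mira, setting) == band

    @pytest.mark.parametrize("setting,band", [(15, "low"), (20, "low"), (25, "high")])
    def test_meta_bands(self, meta, setting, band):
        assert dose_band(meta, setting) == band

    def test_out_of_domain(self, meta):
        with pytest.raises(OutOfRangeError):
            dose_band(meta, 40)


class TestBaselinePredictions:
    def test_low_band_profile(self, mira):
        levels = predict(mira, 60).marker_levels
        assert levels["53BP1_early"] == "robust"
        assert levels["53BP1_late"] == "robust"
        assert levels["TRF2"] == "none"
        assert levels["PAR"] == "weak"
        assert levels["gammaH2AX_pattern"] == "local"
        assert levels["MDC1_at_site"] == "at_site"
        assert levels["Ub"] == "robust"
        assert levels["CPD"] == "none"
        assert levels["base_damage_NTH1"] == "none"

    def test_high_band_profile(self, mira):
        levels = predict(mira, 100).marker_levels
        assert levels["53BP1_early"] == "none"
        assert levels["53BP1_late"] == "weak"
        assert levels["TRF2"] == "robust"
        assert levels["PAR"] == "robust"
        assert levels["gammaH2AX_pattern"] == "pan_nuclear"
        assert levels["MDC1_at_site"] == "dispersed"
        assert levels["CPD"] == "robust"
        assert levels["base_damage_NTH1"] == "robust"
        assert levels["XPA"] == "occasional"
        assert levels["pChk2_pattern"] == "pan_nuclear"

    def test_trf2_timing_note_at_high_band(self, mira):
        notes = predict(mira, 100).timing_notes
        assert "within 1 min" in notes["TRF2"]

    def test_baseline_constant_within_band(self, mira):
        ref = predict(mira, 60).marker_levels
        for s in (25, 40, 84.9):
            assert predict(mira, s).marker_levels == ref

    def test_prediction_flips_exactly_at_band_edges(self, mira):
        assert predict(mira, 24.9).marker_levels != predict(mira, 25).marker_levels
        assert predict(mira, 84.9).marker_levels != predict(mira, 85).marker_levels


class TestModifiers:
    def test_parp_inhibition_abolishes_trf2_and_par(self, mira):
        levels = predict(mira, 100, cond("Pi")).marker_levels
        assert levels["TRF2"] == "none"
        assert levels["PAR"] == "none"

    def test_parp_inhibition_partially_restores_53bp1_at_high(self, mira):
        assert predict(mira, 100, cond("Pi")).marker_levels["53BP1_early"] == "weak"

    def test_parp_inhibition_enhances_53bp1_at_low(self, mira):
        assert predict(mira, 60, cond("Pi")).marker_levels["53BP1_early"] == "enhanced"

    def test_kinase_inhibition_relocalizes_patterns(self, mira):
        levels = predict(mira, 100, cond("Ai", "Di")).marker_levels
        assert levels["gammaH2AX_pattern"] == "local"
        assert levels["MDC1_at_site"] == "at_site"
        assert levels["pChk2_pattern"] == "suppressed"
        assert levels["TRF2"] == "robust"  # Ai+Di has no significant TRF2 effect
        assert levels["53BP1_early"] == "weak"  # partial restore

    def test_triple_inhibition_fully_restores_53bp1(self, mira, meta):
        assert predict(mira, 100, cond("Ai", "Di", "Pi")).marker_levels["53BP1_early"] == "robust"
        assert predict(meta, 25, cond("Ai", "Di", "Pi")).marker_levels["53BP1_early"] == "robust"
        assert predict(meta, 15, cond("Ai", "Di", "Pi")).marker_levels["53BP1_early"] == "robust"

    def test_kinase_inhibition_minimal_at_low_dose(self, mira):
        base = predict(mira, 60).marker_levels["53BP1_early"]
        assert predict(mira, 60, cond("Ai", "Di")).marker_levels["53BP1_early"] == base

    def test_parg_inhibition_suppresses_53bp1_at_low_dose(self, mira):
        levels = predict(mira, 60, cond("PARGi")).marker_levels
        assert levels["53BP1_early"] == "weak"
        assert levels["PAR"] == "robust"  # stabilized PAR, up from weak

    def test_parp1_knockdown_abolishes_trf2(self, mira):
        c = TreatmentCondition(knockdowns=frozenset({"PARP1_siRNA"}))
        assert predict(mira, 100, c).marker_levels["TRF2"] == "none"

    def test_trf2_knockdown_changes_nothing(self, mira):
        c = TreatmentCondition(knockdowns=frozenset({"TRF2_siRNA"}))
        assert predict(mira, 100, c).marker_levels == predict(mira, 100).marker_levels

    def test_hoechst_photosensitization(self, mira):
        p = predict(mira, 60, cond("hoechst"))
        assert p.endogenous_trf2_detectable
        assert p.marker_levels["gammaH2AX_pattern"] == "pan_nuclear"  # upgraded from local

    def test_unknown_token_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cond("ATRi")


class TestPurityAndOrderIndependence:
    def test_pure_function(self, mira):
        a = predict(mira, 100, cond("Pi", "Ai"))
        b = predict(mira, 100, cond("Pi", "Ai"))
        assert a == b

    @pytest.mark.parametrize("band_setting", [60, 100])
    def test_modifier_order_independence(self, mira, band_setting):
        for subset in itertools.chain.from_iterable(
            itertools.combinations(("Pi", "Ai", "Di", "PARGi"), r) for r in range(5)
        ):
            results = {
                tuple(sorted(predict(mira, band_setting, cond(*perm)).marker_levels.items()))
                for perm in itertools.permutations(subset)
            }
            assert len(results) == 1


class TestTransInhibition:
    def test_single_low_site_unaffected(self, meta):
        [p] = trans_inhibition([predict(meta, 15)])
        assert p.marker_levels["53BP1_early"] == "robust"

    def test_high_site_suppresses_low_site_in_trans(self, meta):
        low, high = predict(meta, 15), predict(meta, 25)
        adj_low, adj_high = trans_inhibition([low, high])
        assert adj_low.marker_levels["53BP1_early"] == "none"
        assert adj_high.marker_levels["53BP1_early"] == "none"

    def test_triple_inhibition_restores_both_sites(self, meta):
        c = cond("Ai", "Di", "Pi")
        preds = [predict(meta, 15, c), predict(meta, 25, c)]
        for p in trans_inhibition(preds):
            assert p.marker_levels["53BP1_early"] == "robust"

    def test_only_53bp1_early_is_touched(self, meta):
        low, high = predict(meta, 15), predict(meta, 25)
        adj_low, _ = trans_inhibition([low, high])
        for marker, level in low.marker_levels.items():
            if marker != "53BP1_early":
                assert adj_low.marker_levels[marker] == level

    def test_empty_site_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            trans_inhibition([])

    def test_mixed_conditions_rejected(self, meta):
        with pytest.raises(InvalidArgumentError):
            trans_inhibition([predict(meta, 15), predict(meta, 25, cond("Pi"))])
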