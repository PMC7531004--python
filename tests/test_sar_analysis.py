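"""Composition tables, percent-active, Hill fits, MIC and fold changes."""

import numpy as np
import pytest

from obocscreen.library_design import PeptideSequence
from obocscreen.sar_analysis import (
    ActivityProfile,
    CensoredValue,
    effect_concentration,
    fit_hill,
    fold_change,
    group_composition,
    hc10_from_curve,
    hill_response,
    mic_from_dilutions,
    percent_active,
    profile_table,
)
from obocscreen.screening_classify import CompoundRecord, GroupLabel


def _seq_with_counts(scheme, n_l, n_v, n_t=0, n_z=0):
    assert n_l + n_v + n_t + n_z == 6
    residues = list(scheme.parent)
    fill = ["L"] * n_l + ["V"] * n_v + ["T"] * n_t + ["Z"] * n_z
    for pos, c in zip(scheme.variable_positions, fill):
        residues[pos] = c
    return PeptideSequence(residues="".join(residues), scheme=scheme)


class TestGroupComposition:
    def test_parent_alone_is_67_33(self, parent):
        df = group_composition({"parent": [parent]})
        row = df.loc["parent"]
        assert (row["L"], row["V"], row["T"], row["Z"]) == (67, 33, 0, 0)

    def test_all_thr_sequence(self, scheme):
        df = group_composition({"g": [_seq_with_counts(scheme, 0, 0, 6, 0)]})
        assert df.loc["g", "T"] == 100

    def test_planted_group_a_row(self, scheme):
        """41 sequences with 140 L and 106 V over 246 variable slots give
        the 57% / 43% aliphatic split."""
        seqs = [_seq_with_counts(scheme, 4, 2) for _ in range(23)] + [
            _seq_with_counts(scheme, 3, 3) for _ in range(15)
        ] + [_seq_with_counts(scheme, 1, 5) for _ in range(3)]
        total_l = 23 * 4 + 15 * 3 + 3 * 1
        assert total_l == 140 and len(seqs) == 41
        df = group_composition({"A": seqs})
        assert df.loc["A", "L"] == 57
        assert df.loc["A", "V"] == 43

    def test_empty_group_reports_zero_row(self, parent):
        df = group_composition({"A": [parent], "B": []})
        assert df.loc["B", "n_compounds"] == 0
        assert df.loc["B", ["L", "V", "T", "Z"]].sum() == 0

    def test_rounded_percentages_sum_close_to_100(self, scheme, library):
        rng = np.random.default_rng(1)
        for _ in range(10):
            members = [library[i] for i in rng.integers(0, 4096, size=17)]
            row = group_composition({"g": members}).loc["g"]
            assert abs(row[["L", "V", "T", "Z"]].sum() - 100) <= 2


class TestPercentActive:
    @staticmethod
    def _rec(active_wells):
        return CompoundRecord(
            sequence="x", appearance_frequency=1, group=GroupLabel.B,
            n_abx_active_wells=active_wells,
        )

    def test_30_of_31_is_97(self):
        records = [self._rec(1)] * 30 + [self._rec(0)]
        assert percent_active(records) == 97

    def test_all_inactive_and_empty(self):
        assert percent_active([self._rec(0)] * 5) == 0
        assert percent_active([]) is None


class TestFitHill:
    def test_noiseless_recovery_is_exact(self):
        c = np.logspace(-1, 3, 9)
        r = hill_response(c, ec50=4.5, hill_slope=2.0)
        fit = fit_hill(c, r)
        assert fit.converged
        assert fit.ec50 == pytest.approx(4.5, rel=1e-6)
        assert fit.hill_slope == pytest.approx(2.0, rel=1e-6)

    def test_midpoint_identity(self):
        fit = fit_hill([1, 3, 10, 30, 100], hill_response([1, 3, 10, 30, 100], 10.0, 1.5))
        assert hill_response(fit.ec50, fit.ec50, fit.hill_slope) == pytest.approx(50.0)

    def test_concentration_scale_equivariance(self):
        c = np.logspace(0, 4, 8)
        r = hill_response(c, ec50=40.0, hill_slope=1.2)
        fit1 = fit_hill(c, r)
        fit10 = fit_hill(10 * c, r)
        assert fit10.ec50 == pytest.approx(10 * fit1.ec50, rel=1e-6)

    def test_constant_response_does_not_converge(self):
        fit = fit_hill([1, 10, 100, 1000], [50.0, 50.0, 50.0, 50.0])
        assert not fit.converged

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(7)
        c = 4.5 * np.logspace(-1.5, 1.5, 8)
        errors = []
        for _ in range(25):
            r = hill_response(c, 4.5, 2.0) + rng.normal(0, 2.0, c.size)
            fit = fit_hill(c, r)
            errors.append(abs(fit.ec50 / 4.5 - 1))
        assert np.median(errors) < 0.15

    def test_free_top_variant(self):
        c = np.logspace(-1, 3, 9)
        r = hill_response(c, ec50=20.0, hill_slope=1.0, top=80.0)
        fit = fit_hill(c, r, free_top=True)
        assert fit.top == pytest.approx(80.0, rel=1e-4)
        assert fit.ec50 == pytest.approx(20.0, rel=1e-4)


class TestEffectConcentration:
    @staticmethod
    def _fit(ec50, slope):
        c = ec50 * np.logspace(-2, 2, 9)
        return fit_hill(c, hill_response(c, ec50, slope))

    def test_50_percent_is_ec50(self):
        fit = self._fit(4.5, 2.0)
        assert effect_concentration(fit, 50.0) == pytest.approx(fit.ec50)

    def test_ec75_with_unit_slope(self):
        fit = self._fit(10.0, 1.0)
        assert effect_concentration(fit, 75.0) == pytest.approx(30.0, rel=1e-6)

    def test_inverse_identity_across_curve(self):
        fit = self._fit(4.5, 1.7)
        for c in [0.5, 2.0, 4.5, 20.0, 100.0]:
            resp = float(hill_response(c, fit.ec50, fit.hill_slope))
            assert effect_concentration(fit, resp) == pytest.approx(c, rel=1e-9)

    def test_out_of_range_percent_errors(self):
        fit = self._fit(10.0, 1.0)
        with pytest.raises(ValueError):
            effect_concentration(fit, 0.0)
        with pytest.raises(ValueError):
            effect_concentration(fit, 100.0)

    def test_hc10(self):
        fit = self._fit(1440.0, 1.0)
        assert hc10_from_curve(fit) == pytest.approx(160.0, rel=1e-6)
        assert hc10_from_curve(fit) <= fit.ec50


class TestMic:
    def test_standard_series(self):
        series = [(64, False), (32, False), (16, False), (8, False), (4, True)]
        assert mic_from_dilutions(series) == CensoredValue(8)

    def test_growth_everywhere_is_right_censored(self):
        mic = mic_from_dilutions([(64, True), (32, True), (16, True)])
        assert mic == CensoredValue(64, "gt")
        assert str(mic) == ">64"

    def test_no_growth_anywhere_is_left_censored(self):
        mic = mic_from_dilutions([(64, False), (32, False)])
        assert mic == CensoredValue(32, "le")

    def test_true_mic_between_dilutions_reports_next_dilution_up(self):
        """Growth wherever the concentration is below the (hidden) true
        MIC: the reported MIC is the next dilution above it."""
        true_mic = 11.0  # between the 8 and 16 steps
        series = [(c, c < true_mic) for c in (64, 32, 16, 8, 4)]
        assert mic_from_dilutions(series) == CensoredValue(16)

    def test_non_monotone_pattern_warns(self):
        series = [(64, False), (32, True), (16, False), (8, True)]
        with pytest.warns(UserWarning, match="non-monotone"):
            mic = mic_from_dilutions(series)
        assert mic == CensoredValue(64)


class TestFoldChange:
    def test_printed_value_folds(self):
        assert fold_change(160, 5.8) == 28  # hemolysis vs P388 of the parent
        assert fold_change(8.3, 1.0) == 8  # S. pneumoniae MIC ratio
        assert fold_change(33, 8.0) == 4  # S. pyogenes MIC ratio
        assert fold_change(1.3, 4.5, rounding="2sig") == 0.29  # min EC50 ratio

    def test_identity_and_inverse_product(self):
        assert fold_change(7.7, 7.7) == 1
        a, b = 160.0, 5.8
        assert fold_change(a, b, rounding=None) * fold_change(b, a, rounding=None) == pytest.approx(1.0)

    def test_censored_numerator_propagates(self):
        fold = fold_change(CensoredValue(1000, "gt"), 5.8)
        assert fold.censor == "gt"
        assert fold.value == pytest.approx(1000 / 5.8)

    def test_censored_denominator_flips_direction(self):
        fold = fold_change(160.0, CensoredValue(3000, "gt"))
        assert fold.censor == "lt"

    def test_two_censored_operands_error(self):
        with pytest.raises(ValueError):
            fold_change(CensoredValue(10, "gt"), CensoredValue(5, "gt"))


class TestProfileTable:
    @staticmethod
    def _profile(cid, group, ic50):
        return ActivityProfile(
            compound_id=cid,
            group=group,
            ec50_transport=CensoredValue(4.5),
            ic50_p388=ic50,
            hc10=CensoredValue(160.0),
        )

    def test_sorted_by_cytotoxicity_within_group(self):
        df = profile_table(
            [
                self._profile("slow", "A", CensoredValue(17.0)),
                self._profile("fast", "A", CensoredValue(4.1)),
            ]
        )
        assert list(df["compound_id"]) == ["fast", "slow"]

    def test_censored_ic50_sorts_last(self):
        df = profile_table(
            [
                self._profile("cens", "B2", CensoredValue(1000.0, "gt")),
                self._profile("meas", "B2", CensoredValue(390.0)),
            ]
        )
        assert list(df["compound_id"]) == ["meas", "cens"]

    def test_groups_ordered_and_parent_renders_uncensored(self):
        parent_profile = ActivityProfile(
            compound_id="gramicidin A",
            group="parent",
            ec50_transport=CensoredValue(4.5),
            ic50_p388=CensoredValue(5.8),
            hc10=CensoredValue(160.0),
            mic={
                "S_pyogenes": CensoredValue(33.0),
                "E_faecalis": CensoredValue(270.0),
                "S_pneumoniae": CensoredValue(8.3),
                "S_agalactiae": CensoredValue(1100.0),
                "L_monocytogenes": CensoredValue(4300.0),
            },
        )
        df = profile_table(
            [self._profile("b", "B1", CensoredValue(67.0)), parent_profile]
        )
        assert list(df["group"]) == ["parent", "B1"]
        parent_row = df.iloc[0]
        assert not any(">" in str(v) for v in parent_row.values)
        assert df.attrs["heatmap_bounds"]["hc10"] == (160.0, 3000.0)
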