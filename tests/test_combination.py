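import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugcombo import (
    CombinationObservation,
    InvalidArgumentError,
    MedianEffectParams,
    OutOfDomainError,
    SchemaError,
    SimulationConfig,
    UnitMismatchError,
    classify_ci,
    combination_index,
    default_fa_grid,
    design_fixed_ratio,
    fa_ci_curve,
    fa_from_dose,
    fit_combination_as_single,
    fit_median_effect,
    simulate_combination,
    simulate_single_drug,
)
from drugcombo.combination import read_combination_csv, write_combination_csv

from .conftest import COMBO_DM, DM_TRIPLE


class TestDesignFixedRatio:
    def test_dm_proportional_weights(self, dm_triple_params):
        design = design_fixed_ratio(dm_triple_params)
        assert design.weights == pytest.approx((0.3278, 0.2772, 0.3950), abs=5e-5)
        assert sum(design.weights) == pytest.approx(1.0, abs=1e-12)

    def test_equal_dm_gives_equal_weights(self):
        params = [MedianEffectParams(dm=4.0, m=m) for m in (1.0, 2.0, 3.0)]
        design = design_fixed_ratio(params)
        assert design.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-12)

    def test_explicit_top_ladder(self, dm_triple_params):
        design = design_fixed_ratio(dm_triple_params, 1.5, 4, top_total_dose=36.0)
        assert design.total_doses() == pytest.approx([36.0, 24.0, 16.0, 10.0 + 2 / 3], rel=1e-12)

    def test_default_ladder_contains_dm_sum_interior(self, dm_triple_params):
        design = design_fixed_ratio(dm_triple_params, 1.5, 8)
        totals = design.total_doses()
        dm_sum = sum(DM_TRIPLE)
        interior = totals[1:-1]
        assert any(t == pytest.approx(dm_sum, rel=1e-9) for t in interior)
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_mixed_units_rejected(self):
        params = [
            MedianEffectParams(dm=1.0, m=1.0, unit="uM"),
            MedianEffectParams(dm=2.0, m=1.0, unit="ug/mL"),
        ]
        with pytest.raises(UnitMismatchError):
            design_fixed_ratio(params)

    def test_dilution_factor_must_exceed_one(self, dm_triple_params):
        with pytest.raises(InvalidArgumentError):
            design_fixed_ratio(dm_triple_params, dilution_factor=1.0)


class TestCombinationIndex:
    def test_closed_form_at_fa_half(self, dm_triple_params):
        # at fa = 0.5, Dx_j = Dm_j, so CI = total / sum(Dm) * n_terms... i.e.
        # with Dm-proportional split: CI = 3 * total / sum(Dm)
        total = COMBO_DM
        dm_sum = sum(DM_TRIPLE)
        doses = [dm / dm_sum * total for dm in DM_TRIPLE]
        ci = combination_index(dm_triple_params, doses, 0.5)
        assert ci == pytest.approx(3 * total / dm_sum, rel=1e-12)
        assert ci == pytest.approx(0.5594, abs=5e-5)

    @pytest.mark.parametrize("m_set", [(1.0, 1.0, 1.0), (0.7, 2.3, 3.1), (2.0, 2.0, 2.0)])
    def test_ci_at_fa_half_independent_of_m(self, m_set):
        params = [MedianEffectParams(dm=dm, m=m) for dm, m in zip(DM_TRIPLE, m_set)]
        doses = [dm / sum(DM_TRIPLE) * COMBO_DM for dm in DM_TRIPLE]
        ci = combination_index(params, doses, 0.5)
        assert ci == pytest.approx(3 * COMBO_DM / sum(DM_TRIPLE), rel=1e-12)

    def test_sham_self_combination_is_additive(self):
        p = MedianEffectParams(dm=6.0, m=1.7)
        for total in (1.0, 6.0, 20.0):
            fa = fa_from_dose(p, total)
            ci = combination_index([p, p], [0.4 * total, 0.6 * total], fa)
            assert ci == pytest.approx(1.0, rel=1e-12)

    def test_linearity_in_doses(self, dm_triple_params):
        doses = [1.0, 2.0, 3.0]
        fa = 0.37
        ci1 = combination_index(dm_triple_params, doses, fa)
        ci2 = combination_index(dm_triple_params, [2 * d for d in doses], fa)
        assert ci2 == pytest.approx(2 * ci1, rel=1e-12)

    def test_unit_invariance_under_common_rescale(self):
        scale = 123.456
        params = [MedianEffectParams(dm=dm, m=m) for dm, m in zip(DM_TRIPLE, (1.2, 2.1, 2.9))]
        scaled = [MedianEffectParams(dm=p.dm * scale, m=p.m) for p in params]
        doses = [0.8, 1.1, 2.2]
        for fa in (0.1, 0.5, 0.9):
            ci = combination_index(params, doses, fa)
            ci_scaled = combination_index(scaled, [d * scale for d in doses], fa)
            assert abs(ci - ci_scaled) <= 1e-12 * max(ci, 1.0)

    def test_length_mismatch(self, dm_triple_params):
        with pytest.raises(InvalidArgumentError):
            combination_index(dm_triple_params, [1.0, 2.0], 0.5)

    def test_boundary_fa(self, dm_triple_params):
        with pytest.raises(OutOfDomainError):
            combination_index(dm_triple_params, [1.0, 1.0, 1.0], 1.0)

    def test_nonpositive_dose(self, dm_triple_params):
        with pytest.raises(InvalidArgumentError):
            combination_index(dm_triple_params, [1.0, 0.0, 1.0], 0.5)


class TestFitCombinationAsSingle:
    def test_noiseless_mixture_recovered(self):
        truth = MedianEffectParams(dm=3.72, m=1.8)
        observations = [
            (d, fa_from_dose(truth, d)) for d in [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
        ]
        fit = fit_combination_as_single(observations)
        assert fit.dm == pytest.approx(3.72, rel=1e-9)
        assert fit.m == pytest.approx(1.8, rel=1e-9)

    def test_two_point_line(self):
        truth = MedianEffectParams(dm=5.0, m=1.0)
        fit = fit_combination_as_single([(2.0, fa_from_dose(truth, 2.0)), (10.0, fa_from_dose(truth, 10.0))])
        assert fit.dm == pytest.approx(5.0, rel=1e-9)

    def test_boundary_fa_rows_excluded(self):
        truth = MedianEffectParams(dm=3.72, m=1.8)
        observations = [(d, fa_from_dose(truth, d)) for d in [1.0, 2.0, 4.0, 8.0]]
        observations += [(0.0001, 0.0), (1e6, 1.0)]
        fit = fit_combination_as_single(observations)
        assert fit.n_used == 4
        assert fit.n_excluded == 2

    def test_accepts_observation_objects(self):
        truth = MedianEffectParams(dm=2.0, m=1.3)
        obs = [
            CombinationObservation(component_doses=(0.5 * d, 0.5 * d), fa=fa_from_dose(truth, d))
            for d in [0.5, 1.0, 2.0, 4.0]
        ]
        fit = fit_combination_as_single(obs)
        assert fit.dm == pytest.approx(2.0, rel=1e-9)


class TestFaCiCurve:
    def test_sham_design_gives_unit_ci(self):
        p = MedianEffectParams(dm=6.0, m=1.7)
        design = design_fixed_ratio([p, p], components=["X", "X'"])
        curve = fa_ci_curve([p, p], p, design, default_fa_grid())
        assert len(curve) == len(default_fa_grid())
        for _, ci in curve:
            assert ci == pytest.approx(1.0, rel=1e-9)

    def test_single_point_grid_closed_form(self, dm_triple_params):
        combo = MedianEffectParams(dm=COMBO_DM, m=1.8, unit="ug/mL")
        design = design_fixed_ratio(dm_triple_params)
        curve = fa_ci_curve(dm_triple_params, combo, design, [0.5])
        assert curve[0][0] == 0.5
        assert curve[0][1] == pytest.approx(0.5594, abs=5e-5)

    def test_generator_half_ci_recovered(self, drug_truths):
        cfg = SimulationConfig(drugs=drug_truths, true_ci=0.5, seed=3)
        singles = [fit_median_effect(simulate_single_drug(cfg, d.name)) for d in drug_truths]
        combo = fit_combination_as_single(simulate_combination(cfg))
        design = design_fixed_ratio(singles)
        mid = [fa for fa in default_fa_grid() if 0.2 <= fa <= 0.8]
        for fa, ci in fa_ci_curve(singles, combo, design, mid):
            assert abs(ci - 0.5) / 0.5 < 0.05

    def test_grid_boundary_rejected(self, dm_triple_params):
        combo = MedianEffectParams(dm=COMBO_DM, m=1.8, unit="ug/mL")
        design = design_fixed_ratio(dm_triple_params)
        with pytest.raises(OutOfDomainError):
            fa_ci_curve(dm_triple_params, combo, design, [0.5, 1.0])


class TestClassifyCi:
    @pytest.mark.parametrize(
        "ci,label",
        [
            (0.05, "very strong synergism"),
            (0.27, "strong synergism"),
            (0.52, "synergism"),
            (0.75, "moderate synergism"),
            (0.87, "slight synergism"),
            (1.0, "nearly additive"),
            (1.15, "slight antagonism"),
            (2.0, "antagonism"),
            (10.0, "strong antagonism"),
        ],
    )
    def test_band_examples(self, ci, label):
        assert classify_ci(ci).label == label

    def test_bands_tile_without_gaps_or_overlaps(self):
        edges = [0.10, 0.30, 0.70, 0.85, 0.90, 1.10, 1.20, 3.30]
        eps = 1e-12
        labels_seen = []
        prev_hi = None
        for edge in edges:
            below = classify_ci(edge - eps)
            at = classify_ci(edge)
            # lower-inclusive: the edge belongs to the upper band
            assert below.label != at.label
            assert below.ci_interval[1] == pytest.approx(edge)
            assert at.ci_interval[0] == pytest.approx(edge)
            if prev_hi is not None:
                assert below.ci_interval[0] == pytest.approx(prev_hi)
            prev_hi = edge
            labels_seen.extend([below.label, at.label])
        assert len(set(labels_seen)) == 9
        assert classify_ci(1e-9).ci_interval == (0.0, 0.10)
        assert classify_ci(1e9).ci_interval[1] == math.inf

    @given(ci=st.floats(1e-6, 100.0))
    @settings(max_examples=200)
    def test_every_positive_ci_classified(self, ci):
        verdict = classify_ci(ci)
        lo, hi = verdict.ci_interval
        assert lo <= ci < hi

    @pytest.mark.parametrize("ci", [0.0, -1.0, float("inf"), float("nan")])
    def test_invalid_ci_rejected(self, ci):
        with pytest.raises(InvalidArgumentError):
            classify_ci(ci)


class TestCombinationCsv:
    def test_roundtrip(self, tmp_path):
        obs = [
            CombinationObservation(component_doses=(1.0, 2.0, 3.0), fa=0.4),
            CombinationObservation(component_doses=(0.5, 1.0, 1.5), fa=0.2),
        ]
        path = tmp_path / "combo.csv"
        write_combination_csv(path, ["A", "B", "C"], obs)
        components, back = read_combination_csv(path)
        assert components == ["A", "B", "C"]
        assert back == obs

    def test_missing_fa_column(self, tmp_path):
        path = tmp_path / "combo.csv"
        path.write_text("A,B\n1.0,2.0\n")
        with pytest.raises(SchemaError, match="fa"):
            read_combination_csv(path)
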