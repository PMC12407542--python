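"""Dose-response curves, PA fold change, crossover dose and sweeps."""

import numpy as np
import pytest

from raf_paradox import (
    ModelVariant,
    ValidationError,
    dose_response,
    pa_crossover_dose,
    pa_fold_change,
    pa_metrics,
    solve_totals,
    sweep_grid,
)
from raf_paradox.metrics import DEFAULT_DOSE_GRID
from conftest import ALL_VARIANTS, random_parameters


class TestDoseResponse:
    def test_pa_shape_rise_then_fall(self, defaults):
        curve = dose_response(
            ModelVariant.CA, defaults, mode="free_drug", engine="analytic"
        )
        assert curve.active.max() > curve.baseline  # rises above baseline
        assert curve.active[-1] < curve.baseline  # ends below it
        peak = int(np.argmax(curve.active))
        assert 0 < peak < len(curve.doses) - 1

    def test_dose_zero_only_returns_baseline(self, defaults):
        curve = dose_response(
            ModelVariant.CAS, defaults, doses=[0.0], mode="free_drug", engine="analytic"
        )
        assert curve.active.tolist() == [curve.baseline]

    def test_zero_dose_prepended(self, defaults):
        curve = dose_response(
            ModelVariant.CA, defaults, doses=[0.1, 1.0], mode="free_drug", engine="analytic"
        )
        assert curve.doses[0] == 0.0 and len(curve.doses) == 3

    def test_analytic_requires_free_drug_mode(self, defaults):
        with pytest.raises(ValidationError):
            dose_response(ModelVariant.CA, defaults, mode="total_drug", engine="analytic")

    def test_clamp_rejected_in_total_mode(self, defaults):
        with pytest.raises(ValidationError):
            dose_response(
                ModelVariant.CA, defaults, mode="total_drug", engine="oracle", s_free=1.0
            )

    def test_unsorted_doses_rejected(self, defaults):
        with pytest.raises(ValidationError):
            dose_response(ModelVariant.CA, defaults, doses=[1.0, 0.5])

    def test_total_mode_reparameterized_by_solved_free_drug(self, defaults):
        # conservation re-clamping: evaluating the closed forms at the
        # oracle's solved free concentrations reproduces the totals curve
        from raf_paradox import active_fraction

        doses = np.logspace(-2, 1, 7)
        curve = dose_response(ModelVariant.CAS_DS, defaults, doses)
        for dose, active in zip(curve.doses[1:], curve.active[1:]):
            state = solve_totals(
                ModelVariant.CAS_DS, defaults.replace(D_total=dose)
            )
            closed = active_fraction(
                ModelVariant.CAS_DS, defaults, state.d_free, state.s_free
            )
            assert closed == pytest.approx(active, rel=1e-9)

    def test_engines_agree_under_free_clamp(self, rng):
        for _ in range(10):
            p = random_parameters(rng, with_totals=True)
            variant = ALL_VARIANTS[rng.integers(0, 4)]
            doses = np.logspace(-3, 2, 20)
            a = dose_response(variant, p, doses, mode="free_drug", engine="analytic")
            o = dose_response(variant, p, doses, mode="free_drug", engine="oracle")
            np.testing.assert_allclose(a.active, o.active, rtol=1e-8)


class TestFoldChange:
    def test_monotone_decreasing_curve_gives_unity(self, defaults):
        p = defaults.replace(K_A=0.0, S_total=0.0)
        curve = dose_response(ModelVariant.CA, p, mode="free_drug", engine="analytic")
        assert pa_fold_change(curve) == 1.0

    def test_grid_independent_refinement(self, defaults):
        coarse = dose_response(
            ModelVariant.CA, defaults, mode="free_drug", engine="analytic"
        )
        fine = dose_response(
            ModelVariant.CA,
            defaults,
            np.logspace(-4, 2, 100_000),
            mode="free_drug",
            engine="analytic",
        )
        refined = pa_fold_change(coarse)
        scanned = fine.active.max() / fine.baseline
        assert refined == pytest.approx(scanned, rel=1e-6)
        assert refined > 1.0

    def test_dimensionless_invariance(self, defaults):
        # doubling R_total and K_dim jointly fixes RAF_rel; with the free-
        # drug grid fixed in d_rel the fold change is unchanged
        scaled = defaults.replace(
            R_total=2 * defaults.R_total, K_dim=2 * defaults.K_dim
        )
        c1 = dose_response(ModelVariant.CA, defaults, mode="free_drug", engine="analytic")
        c2 = dose_response(ModelVariant.CA, scaled, mode="free_drug", engine="analytic")
        assert pa_fold_change(c1) == pytest.approx(pa_fold_change(c2), rel=1e-9)


class TestCrossover:
    def test_no_pa_at_unit_autoinhibition(self, defaults):
        p = defaults.replace(K_A=1.0, S_total=0.0)
        assert pa_crossover_dose(
            ModelVariant.CA, p, mode="free_drug", engine="analytic"
        ) is None

    def test_agrees_with_fine_grid_scan(self, defaults):
        cross = pa_crossover_dose(
            ModelVariant.CA, defaults, mode="free_drug", engine="analytic", s_free=0.0
        )
        grid = np.logspace(-4, 2, 1_000_000)
        curve = dose_response(
            ModelVariant.CA, defaults, mode="free_drug", engine="analytic", s_free=0.0
        )
        vals = np.array([curve.evaluate(d) for d in grid[:: 1000]])
        # locate the down-crossing on a 1000-point subsample, then refine on
        # the full million-point grid within that bracket
        above = vals > curve.baseline
        i = np.max(np.nonzero(above)[0])
        lo, hi = grid[i * 1000], grid[min((i + 2) * 1000, len(grid) - 1)]
        fine = grid[(grid >= lo) & (grid <= hi)]
        fvals = np.array([curve.evaluate(d) for d in fine])
        j = np.max(np.nonzero(fvals > curve.baseline)[0])
        assert fine[j] <= cross <= fine[min(j + 1, len(fine) - 1)]

    def test_variant_ordering_at_defaults(self, defaults):
        crossings = {
            v: pa_crossover_dose(v, defaults)
            for v in (ModelVariant.CAS, ModelVariant.CAS_DS, ModelVariant.DS)
        }
        assert (
            crossings[ModelVariant.CAS]
            >= crossings[ModelVariant.CAS_DS]
            >= crossings[ModelVariant.DS]
        )

    def test_metrics_bundle_consistency(self, defaults):
        curve = dose_response(ModelVariant.CA, defaults)
        m = pa_metrics(curve)
        assert m.pa_detected and m.fold_change > 1.0
        assert m.crossover_dose is not None and m.peak_dose is not None
        assert m.peak_dose < m.crossover_dose


class TestSweepGrid:
    def test_degenerate_grid_equals_scalar_metric(self, defaults):
        grid = sweep_grid(
            ModelVariant.CA,
            defaults,
            ("K_A", [10.0]),
            ("R_total", [0.04]),
            metric="fold_change",
        )
        curve = dose_response(ModelVariant.CA, defaults, mode="free_drug", engine="analytic")
        assert grid.values[0, 0] == pytest.approx(pa_fold_change(curve), rel=1e-9)

    def test_cas_crossover_widens_with_14_3_3(self, defaults):
        grid = sweep_grid(
            ModelVariant.CAS,
            defaults,
            ("K_A", [3.0, 10.0, 30.0]),
            ("S_total", np.logspace(-2, 1, 5)),
            metric="crossover_dose",
        )
        for row in grid.values:
            finite = row[np.isfinite(row)]
            assert np.all(np.diff(finite) >= -1e-9 * finite[:-1])

    def test_ds_crossover_narrows_with_14_3_3(self, defaults):
        grid = sweep_grid(
            ModelVariant.DS,
            defaults,
            ("K_A", [3.0, 10.0, 30.0]),
            ("S_total", np.logspace(-2, 1, 5)),
            metric="crossover_dose",
        )
        for row in grid.values:
            finite = row[np.isfinite(row)]
            assert np.all(np.diff(finite) <= 1e-9 * finite[:-1])

    def test_alpha_axis_and_tidy_output(self, defaults):
        grid = sweep_grid(
            ModelVariant.CAS_DS,
            defaults,
            ("S_total", [0.1, 1.0]),
            ("alpha", [0.1, 1.0, 10.0]),
            metric="baseline_pct",
        )
        frame = grid.to_dataframe()
        assert len(frame) == 6
        assert set(frame.columns) >= {"S_total", "alpha", "metric", "value", "variant"}

    def test_unknown_axis_rejected(self, defaults):
        with pytest.raises(ValidationError):
            sweep_grid(
                ModelVariant.CA,
                defaults,
                ("K_bogus", [1.0]),
                ("K_A", [1.0]),
                metric="fold_change",
            )

    def test_large_14_3_3_enhances_pa_in_full_model(self, defaults):
        # sufficiently large 14-3-3 increases PA relative to none at all
        lo = defaults.replace(S_total=0.0)
        hi = defaults.replace(S_total=1e3 * defaults.R_total)
        f_lo = pa_metrics(dose_response(ModelVariant.CAS_DS, lo)).fold_change
        f_hi = pa_metrics(dose_response(ModelVariant.CAS_DS, hi)).fold_change
        assert f_hi > f_lo
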