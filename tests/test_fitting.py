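"""Grid-search engine: RMSE objective, exhaustive search, envelopes."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from cortivasc.datasets import best_fit_params
from cortivasc.fitting import (
    VASO_FIT_GROUPS,
    BoldProfileFitter,
    GridSpec,
    VasoProfileFitter,
    envelope,
    fit_bold,
    fit_vaso,
    rmse,
)
from cortivasc.profiles import HemodynamicParams, simulate_profile
from cortivasc.vascular import COMPARTMENTS


def params_from_tuple(ac, ven, ica, icv):
    dcbv = dict.fromkeys(COMPARTMENTS, 0.0)
    dcbv.update(
        arterioles=float(ac), capillaries=float(ac),
        venules=float(ven), icas=float(ica), icvs=float(icv),
    )
    return HemodynamicParams(dcbv_mid=dcbv)


def brute_force_vaso(measured, unit, grid):
    """Independent oracle: nested loops over the grid, one forward
    simulation per point, no basis-profile shortcut."""
    names = list(VASO_FIT_GROUPS)
    best = None
    for values in itertools.product(*(grid.axis(n) for n in names)):
        prof = simulate_profile(
            unit, params_from_tuple(*values), "vaso"
        ).values
        err = rmse(prof, measured)
        if best is None or err < best[0]:
            best = (err, dict(zip(names, (int(v) for v in values))))
    return best


class TestRmse:
    def test_identical_profiles(self):
        assert rmse(np.ones(8), np.ones(8)) == 0.0

    def test_constant_offset(self):
        assert rmse(np.full(8, 1.7), np.full(8, 1.0)) == pytest.approx(0.7)

    def test_ramp_against_zero(self):
        # sqrt(mean(1^2..8^2)) = sqrt(204/8)
        assert rmse(np.arange(1, 9), np.zeros(8)) == pytest.approx(5.0498, abs=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.ones(8), np.ones(7))


class TestGridSpec:
    def test_default_shapes(self):
        g = GridSpec.default_vaso()
        assert g.n_points == 91**4
        assert GridSpec.default_bold().n_points == 16 * 16

    def test_validation(self):
        with pytest.raises(ValueError):
            GridSpec({})
        with pytest.raises(ValueError):
            GridSpec({"a": (10, 0, 1)})
        with pytest.raises(ValueError):
            GridSpec({"a": (0, 10, 0)})


class TestEnvelope:
    def test_threshold_membership(self):
        members, ranges = envelope([0.10, 0.11, 0.13], [(0,), (1,), (2,)])
        np.testing.assert_array_equal(members, [True, True, False])
        assert ranges[0] == (0.0, 1.0)

    def test_zero_minimum_keeps_exact_fits_only(self):
        members, _ = envelope([0.0, 0.0, 0.2], [(0,), (1,), (2,)])
        np.testing.assert_array_equal(members, [True, True, False])

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.1, 1.0, 50)
        pts = [(i,) for i in range(50)]
        members, _ = envelope(vals, pts, factor=1.3)
        expected = vals <= 1.3 * vals.min()
        np.testing.assert_array_equal(members, expected)

    def test_monotone_in_factor(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.1, 1.0, 50)
        pts = [(i,) for i in range(50)]
        m12, _ = envelope(vals, pts, factor=1.2)
        m15, _ = envelope(vals, pts, factor=1.5)
        assert np.all(m15[m12])  # 1.2-members subset of 1.5-members

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            envelope([0.1], [(0,)], factor=0.9)


class TestVasoFitter:
    def test_matches_brute_force_on_coarse_grid(self, unit_dd):
        """Basis-profile search equals naive enumeration, point by point."""
        grid = GridSpec({g: (0, 90, 30) for g in VASO_FIT_GROUPS})
        truth = params_from_tuple(60, 0, 30, 0)
        measured = simulate_profile(unit_dd, truth, "vaso").values
        est = VasoProfileFitter(unit=unit_dd, grid=grid).fit(measured)
        err_oracle, best_oracle = brute_force_vaso(measured, unit_dd, grid)
        assert est.best_params_ == best_oracle
        assert est.rmse_min_ == pytest.approx(err_oracle, abs=1e-10)

    def test_noiseless_on_grid_recovery_is_exact(self, unit_dd):
        """Refitting a noiseless self-generated profile returns the
        generating tuple for every randomly drawn on-grid truth."""
        rng = np.random.default_rng(2024)
        grid = GridSpec({g: (0, 90, 1) for g in VASO_FIT_GROUPS})
        for _ in range(20):
            ac, ven, ica, icv = rng.integers(0, 91, size=4)
            measured = simulate_profile(
                unit_dd, params_from_tuple(ac, ven, ica, icv), "vaso"
            ).values
            est = VasoProfileFitter(
                unit=unit_dd, grid=grid, compute_envelope=False
            ).fit(measured)
            assert est.best_params_ == {
                "arterioles_capillaries": ac, "venules": ven,
                "icas": ica, "icvs": icv,
            }
            assert est.rmse_min_ < 1e-7

    def test_single_depth_perturbation_bound(self, unit_dd):
        """One perturbed depth bounds the best RMSE by delta/sqrt(8)."""
        delta = 0.05
        measured = simulate_profile(
            unit_dd, params_from_tuple(56, 2, 21, 5), "vaso"
        ).values.copy()
        measured[3] += delta
        est = VasoProfileFitter(unit=unit_dd, compute_envelope=False).fit(measured)
        assert est.rmse_min_ <= delta / np.sqrt(8) + 1e-9

    def test_envelope_contains_best_and_band_contains_profile(self, unit_dd):
        rng = np.random.default_rng(5)
        measured = simulate_profile(
            unit_dd, params_from_tuple(56, 2, 21, 5), "vaso"
        ).values + rng.normal(0, 0.05, 8)
        est = VasoProfileFitter(unit=unit_dd).fit(measured)
        for name, (lo, hi) in est.envelope_.items():
            assert lo <= est.best_params_[name] <= hi
        assert np.all(est.band_[0] <= est.result_.profile + 1e-12)
        assert np.all(est.band_[1] >= est.result_.profile - 1e-12)

    def test_envelope_ranges_monotone_in_factor(self, unit_dd):
        rng = np.random.default_rng(9)
        measured = simulate_profile(
            unit_dd, params_from_tuple(40, 10, 15, 5), "vaso"
        ).values + rng.normal(0, 0.05, 8)
        grid = GridSpec({g: (0, 90, 5) for g in VASO_FIT_GROUPS})
        e12 = VasoProfileFitter(unit=unit_dd, grid=grid, envelope_factor=1.2).fit(measured)
        e15 = VasoProfileFitter(unit=unit_dd, grid=grid, envelope_factor=1.5).fit(measured)
        for name in e12.envelope_:
            assert e15.envelope_[name][0] <= e12.envelope_[name][0]
            assert e15.envelope_[name][1] >= e12.envelope_[name][1]

    def test_wrong_length_rejected(self, unit_dd):
        with pytest.raises(ValueError, match="points"):
            VasoProfileFitter(unit=unit_dd).fit(np.ones(5))

    def test_wrapper_returns_result(self, unit_dd):
        grid = GridSpec({g: (0, 90, 45) for g in VASO_FIT_GROUPS})
        measured = simulate_profile(
            unit_dd, params_from_tuple(45, 0, 45, 0), "vaso"
        ).values
        res = fit_vaso(measured, unit=unit_dd, grid=grid)
        assert res.best_params["arterioles_capillaries"] == 45
        assert res.n_evaluated == grid.n_points

    def test_sklearn_protocol(self, unit_dd):
        est = VasoProfileFitter(unit=unit_dd, envelope_factor=1.3)
        cloned = clone(est)
        assert cloned.get_params()["envelope_factor"] == 1.3
        cloned.set_params(envelope_factor=1.1)
        assert cloned.envelope_factor == 1.1


class TestBoldFitter:
    def test_matches_brute_force_double_loop(self, unit_dd, params_best):
        measured = simulate_profile(unit_dd, params_best, "bold").values
        grid = GridSpec({"y_base": (60, 75, 5), "y_act": (75, 90, 5)})
        est = BoldProfileFitter(
            unit=unit_dd, dcbv=params_best.dcbv_mid, grid=grid
        ).fit(measured)
        best = None
        for yb in grid.axis("y_base"):
            for ya in grid.axis("y_act"):
                prof = simulate_profile(
                    unit_dd,
                    params_best.with_venous_oxygenation(yb / 100, ya / 100),
                    "bold",
                ).values
                err = rmse(prof, measured)
                if best is None or err < best[0]:
                    best = (err, {"y_base": int(yb), "y_act": int(ya)})
        assert est.best_params_ == best[1]
        assert est.rmse_min_ == pytest.approx(best[0], abs=1e-12)

    def test_noiseless_recovery_of_oxygenation_pair(self, unit_dd, params_best):
        measured = simulate_profile(unit_dd, params_best, "bold").values
        est = BoldProfileFitter(unit=unit_dd, dcbv=params_best.dcbv_mid).fit(measured)
        assert est.best_params_ == {"y_base": 70, "y_act": 90}
        assert est.rmse_min_ == 0.0

    def test_single_point_grid_returns_that_point(self, unit_dd, params_best):
        measured = simulate_profile(unit_dd, params_best, "bold").values
        grid = GridSpec({"y_base": (65, 65, 1), "y_act": (80, 80, 1)})
        res = fit_bold(measured, unit=unit_dd, dcbv=params_best.dcbv_mid, grid=grid)
        assert res.best_params == {"y_base": 65, "y_act": 80}
        assert res.rmse_min > 0.0

    def test_landscape_shape(self, unit_dd, params_best):
        measured = simulate_profile(unit_dd, params_best, "bold").values
        est = BoldProfileFitter(unit=unit_dd, dcbv=params_best.dcbv_mid).fit(measured)
        assert est.landscape_.shape == (16, 16)
        assert est.landscape_.min() == est.rmse_min_


def test_best_fit_lookup_rejects_unknown_scenario():
    with pytest.raises(ValueError):
        best_fit_params("zero_gravity")
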