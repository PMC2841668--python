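"""Grid-search recovery of creation attributes and goodness of fit."""

import numpy as np
import pytest

from shgquant.fitting import (
    chi_squared_gof,
    chi_squared_test,
    fit_forward_fraction,
    fit_relative_efficiency,
)
from shgquant.montecarlo import (
    DepthProfile,
    SHGSource,
    simulate_depth_response,
    simulate_lobe_tallies,
)
from shgquant.optics import OpticalParameters, TissueSlab


def _clear_slab():
    return TissueSlab(
        100.0,
        OpticalParameters(890, 0.0, 0.0, 0.0, 1.33),
        OpticalParameters(457, 0.0, 0.0, 0.0, 1.33),
    )


class TestForwardFractionFit:
    def test_scatter_free_closed_form(self):
        """Noiseless constant ratio r in a clear slab fits f = r/(1+r)."""
        slab = _clear_slab()
        r = 4.0  # -> f = 0.8
        measured = DepthProfile([0.0, 30.0, 60.0], [r, r, r])
        res = fit_forward_fraction(measured, slab, SHGSource(), n_photons=5000, seed=1)
        assert res.status == "ok"
        assert res.best == pytest.approx(r / (1 + r), abs=0.005)

    @pytest.mark.parametrize("tissue,f_true", [("normal_slab", 0.93), ("cancer_slab", 0.77)])
    def test_self_consistency_recovery(self, tissue, f_true, depths, request):
        """Simulated truth is recovered within the stated +/-3% uncertainty."""
        slab = request.getfixturevalue(tissue)
        fb, _ = simulate_depth_response(slab, SHGSource(f_shg=f_true), depths, 50_000, seed=21)
        res = fit_forward_fraction(fb, slab, SHGSource(), n_photons=50_000, seed=22)
        assert res.status == "ok"
        assert abs(res.best - f_true) <= 0.03
        assert res.uncertainty >= 0.01

    def test_residual_curve_reproducible(self, normal_slab, depths):
        fb, _ = simulate_depth_response(normal_slab, SHGSource(f_shg=0.9), depths, 10_000, seed=23)
        a = fit_forward_fraction(fb, normal_slab, SHGSource(), n_photons=10_000, seed=24)
        b = fit_forward_fraction(fb, normal_slab, SHGSource(), n_photons=10_000, seed=24)
        assert np.array_equal(a.residual_curve, b.residual_curve)
        assert a.best == b.best

    def test_argmin_invariant(self, normal_slab, depths):
        fb, _ = simulate_depth_response(normal_slab, SHGSource(f_shg=0.85), depths, 10_000, seed=25)
        res = fit_forward_fraction(fb, normal_slab, SHGSource(), n_photons=10_000, seed=26)
        grid, r2 = res.residual_curve[:, 0], res.residual_curve[:, 1]
        assert res.best == grid[np.argmin(r2)]

    def test_too_few_depths_rejected(self, normal_slab):
        measured = DepthProfile([0.0, 10.0], [3.0, 3.5])
        with pytest.raises(ValueError):
            fit_forward_fraction(measured, normal_slab, SHGSource())


class TestRelativeEfficiencyFit:
    def _synthetic_attenuation(self, slab, eta_true, depths, seed):
        lt = simulate_lobe_tallies(slab, depths, 0.8, 50_000, seed=seed)
        f = 0.77
        shape = lt["t_exc"] ** 2 * (f * lt["ff"] + (1 - f) * lt["bf"])
        return DepthProfile(depths, eta_true * shape / shape.max())

    def test_recovers_brightness_ratio(self, cancer_slab, depths):
        measured = self._synthetic_attenuation(cancer_slab, 3.9, depths, seed=31)
        res = fit_relative_efficiency(
            measured, cancer_slab, SHGSource(f_shg=0.77), n_photons=50_000, seed=32
        )
        assert res.status == "ok"
        assert res.best == pytest.approx(3.9, abs=0.1)

    def test_identity_efficiency(self, cancer_slab, depths):
        measured = self._synthetic_attenuation(cancer_slab, 1.0, depths, seed=33)
        res = fit_relative_efficiency(
            measured, cancer_slab, SHGSource(f_shg=0.77), n_photons=50_000, seed=34
        )
        assert res.best == pytest.approx(1.0, abs=0.1)

    def test_self_normalization_is_degenerate(self, cancer_slab, depths):
        """A per-curve normalized profile carries no efficiency information."""
        measured = self._synthetic_attenuation(cancer_slab, 1.0, depths, seed=35)
        res = fit_relative_efficiency(
            measured,
            cancer_slab,
            SHGSource(f_shg=0.77),
            n_photons=20_000,
            seed=36,
            self_normalize=True,
        )
        assert res.status == "unidentifiable"


class TestChiSquared:
    def test_identical_profiles(self):
        p = DepthProfile([0, 10, 20.0], [1.0, 2.0, 3.0])
        assert chi_squared_gof(p, p) == 0.0

    def test_arithmetic_example(self):
        sim = DepthProfile([0, 10.0], [9.0, 10.0])
        meas = DepthProfile([0, 10.0], [10.0, 12.0])
        assert chi_squared_gof(sim, meas) == pytest.approx(1 / 9 + 4 / 10, rel=1e-12)

    def test_nonnegative_and_zero_iff_identical(self):
        sim = DepthProfile([0, 10.0], [2.0, 3.0])
        meas = DepthProfile([0, 10.0], [2.0, 3.1])
        assert chi_squared_gof(sim, meas) > 0

    def test_gross_mismatch_rejected_at_alpha(self):
        depths = np.arange(0, 60.0, 10.0)
        sim = DepthProfile(depths, np.full(6, 2.0))
        meas = DepthProfile(depths, np.full(6, 20.0))
        stat, dof, crit, reject = chi_squared_test(sim, meas)
        assert dof == 5
        assert reject

    def test_close_profiles_not_rejected(self):
        depths = np.arange(0, 60.0, 10.0)
        sim = DepthProfile(depths, np.linspace(2, 5, 6))
        meas = DepthProfile(depths, np.linspace(2, 5, 6) * 1.02)
        _, _, _, reject = chi_squared_test(sim, meas)
        assert not reject

    def test_nonpositive_sim_rejected(self):
        sim = DepthProfile([0, 10.0], [0.0, 1.0])
        meas = DepthProfile([0, 10.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            chi_squared_gof(sim, meas)

    def test_mismatched_grids_rejected(self):
        sim = DepthProfile([0, 10.0], [1.0, 1.0])
        meas = DepthProfile([0, 20.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            chi_squared_gof(sim, meas)
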