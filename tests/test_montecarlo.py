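"""Monte Carlo transport: analytic limits, conservation, sampler calibration."""

import numpy as np
import pytest

from shgquant.montecarlo import (
    DepthProfile,
    PhotonSet,
    SHGSource,
    excitation_transmission,
    generate_emission,
    propagate_emission,
    sample_hg_cosine,
    simulate_depth_response,
)
from shgquant.optics import OpticalParameters, TissueSlab


def _slab(mu_s_em, mu_a_em, g_em, thickness=100.0, n=1.33):
    return TissueSlab(
        thickness=thickness,
        excitation=OpticalParameters(890, 0.0, 0.0, 0.0, n),
        emission=OpticalParameters(457, mu_s_em, mu_a_em, g_em, n),
    )


class TestExcitationTransmission:
    def test_transparent_medium(self, clear_slab):
        assert excitation_transmission(clear_slab, 50.0, 0.8) == 1.0

    def test_surface(self, cancer_slab):
        assert excitation_transmission(cancer_slab, 0.0, 0.8) == 1.0

    def test_pencil_beam_limit(self, cancer_slab):
        """na -> 0 reduces to the on-axis Beer-Lambert factor."""
        mu_t = cancer_slab.excitation.mu_t_per_um
        got = excitation_transmission(cancer_slab, 50.0, 1e-9)
        assert got == pytest.approx(np.exp(-mu_t * 50.0), rel=1e-9)

    def test_cone_quadrature_oracle(self, cancer_slab):
        """Solid-angle cone average vs an independent fine-grid quadrature."""
        mu_t = cancer_slab.excitation.mu_t_per_um  # 0.02016 um^-1
        z, na, n = 50.0, 0.8, cancer_slab.excitation.n
        cos_max = np.cos(np.arcsin(na / n))
        mu = np.linspace(cos_max, 1.0, 200_001)
        oracle = np.trapezoid(np.exp(-mu_t * z / mu), mu) / (1.0 - cos_max)
        got = excitation_transmission(cancer_slab, z, na)
        assert got == pytest.approx(oracle, abs=1e-4)
        assert got < np.exp(-mu_t * z)  # oblique rays travel farther

    def test_na_above_index_rejected(self, cancer_slab):
        with pytest.raises(ValueError):
            excitation_transmission(cancer_slab, 10.0, 1.4)


class TestEmissionGeneration:
    def test_all_forward(self):
        ph = generate_emission(1000, 1.0, 0.8, rng=1)
        assert np.all(ph.uz > 0)
        assert len(ph) == 1000

    def test_binomial_split(self):
        ph = generate_emission(100_000, 0.5, 0.8, rng=2)
        n_fwd = int((ph.uz > 0).sum())
        assert abs(n_fwd - 50_000) <= 3 * np.sqrt(25_000)

    def test_cone_confinement(self):
        ph = generate_emission(10_000, 0.7, 0.8, rng=3, n_medium=1.33)
        cos_max = np.cos(np.arcsin(0.8 / 1.33))
        assert np.all(np.abs(ph.uz) >= cos_max - 1e-12)
        norms = ph.ux**2 + ph.uy**2 + ph.uz**2
        assert np.allclose(norms, 1.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_emission(100, 1.2, 0.8, rng=0)


class TestPropagation:
    def test_ballistic_clear_medium(self, clear_slab):
        ph = generate_emission(5000, 0.7, 0.8, rng=4, focal_depth=30.0)
        tally = propagate_emission(clear_slab, ph, rng=5)
        n_fwd = float(ph.weight[ph.uz > 0].sum())
        assert tally.forward_weight == n_fwd
        assert tally.backward_weight == 5000 - n_fwd
        assert tally.absorbed_weight == 0.0

    def test_absorption_only_beer_lambert(self):
        """mu_s = 0 with on-axis photons: forward weight is exp(-mu_a * path)."""
        mu_a, z0, thick = 50.0, 20.0, 100.0  # cm^-1, um, um
        slab = _slab(0.0, mu_a, 0.0, thickness=thick)
        n = 200_000
        ph = PhotonSet(
            z=np.full(n, z0),
            ux=np.zeros(n),
            uy=np.zeros(n),
            uz=np.ones(n),
            weight=np.ones(n),
        )
        tally = propagate_emission(slab, ph, rng=6)
        expected = n * np.exp(-mu_a / 1e4 * (thick - z0))
        se = np.sqrt(n * np.exp(-mu_a / 1e4 * (thick - z0)) * (1 - np.exp(-mu_a / 1e4 * (thick - z0))))
        assert abs(tally.forward_weight - expected) <= 3 * se

    @pytest.mark.parametrize("tissue", ["normal_slab", "cancer_slab"])
    def test_weight_conservation(self, tissue, request):
        slab = request.getfixturevalue(tissue)
        ph = generate_emission(50_000, 0.8, 0.8, rng=7, focal_depth=40.0)
        tally = propagate_emission(slab, ph, rng=8)
        assert tally.conservation_error <= 0.005

    def test_empty_set_rejected(self, normal_slab):
        ph = PhotonSet(*[np.empty(0)] * 5)
        with pytest.raises(ValueError):
            propagate_emission(normal_slab, ph, rng=0)

    def test_bit_identical_under_seed(self, normal_slab):
        def run():
            ph = generate_emission(20_000, 0.9, 0.8, rng=11, focal_depth=30.0)
            return propagate_emission(normal_slab, ph, rng=12)

        a, b = run(), run()
        assert (a.forward_weight, a.backward_weight, a.absorbed_weight) == (
            b.forward_weight,
            b.backward_weight,
            b.absorbed_weight,
        )


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.86, 0.94])
    def test_mean_cosine_matches_g(self, g):
        rng = np.random.default_rng(13)
        n = 200_000
        cost = sample_hg_cosine(g, rng, n)
        se = np.std(cost, ddof=1) / np.sqrt(n)
        assert abs(cost.mean() - g) <= 3 * se
        assert np.all(np.abs(cost) <= 1.0)


class TestDepthResponse:
    def test_scatter_free_fb_equals_emission_ratio(self):
        """Without scattering the detected F/B is the creation ratio f/(1-f)."""
        slab = _slab(0.0, 0.0, 0.0)
        n, p = 50_000, 0.93
        fb, _ = simulate_depth_response(slab, SHGSource(f_shg=p), [0.0, 40.0, 80.0], n, seed=14)
        # delta method on r = p/(1-p): var(r_hat) ~ p / (n (1-p)^3)
        se_ratio = np.sqrt(p / (n * (1 - p) ** 3))
        assert np.all(np.abs(fb.values - p / (1 - p)) <= 3 * se_ratio)

    def test_fb_increases_with_depth(self, normal_slab, depths):
        fb, _ = simulate_depth_response(normal_slab, SHGSource(f_shg=0.93), depths, 50_000, seed=15)
        assert np.all(np.diff(fb.values) > 0)

    def test_normal_exceeds_cancer(self, normal_slab, cancer_slab, depths):
        fb_n, _ = simulate_depth_response(normal_slab, SHGSource(f_shg=0.93), depths, 50_000, seed=16)
        fb_c, _ = simulate_depth_response(cancer_slab, SHGSource(f_shg=0.77), depths, 50_000, seed=17)
        assert np.all(fb_n.values > fb_c.values)

    def test_attenuation_normalized(self, cancer_slab, depths):
        _, atten = simulate_depth_response(cancer_slab, SHGSource(), depths, 10_000, seed=18)
        assert atten.values.max() == 1.0
        assert np.all(atten.values > 0)

    def test_raising_mu_s_does_not_raise_fb(self):
        """More emission-wavelength scattering randomizes direction: mean F/B drops."""
        lo = _slab(150.0, 5.0, 0.85)
        hi = _slab(300.0, 5.0, 0.85)
        means = []
        for slab in (lo, hi):
            vals = [
                simulate_depth_response(slab, SHGSource(f_shg=0.9), [20.0, 50.0], 10_000, seed=100 + r)[0].values.mean()
                for r in range(10)
            ]
            means.append(np.mean(vals))
        assert means[1] <= means[0]

    def test_depth_profile_validation(self):
        with pytest.raises(ValueError):
            DepthProfile([0, 10, 5], [1, 2, 3])
        with pytest.raises(ValueError):
            DepthProfile([0, 10], [1, -2])
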