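"""Synthetic-data generators: determinism, manifests, round-trip recovery."""

import numpy as np
import pytest

from shgquant.fitting import fit_forward_fraction
from shgquant.imaging import anisotropy_beta, fb_profile, normalized_attenuation
from shgquant.montecarlo import SHGSource
from shgquant.synthetic import (
    SyntheticTruth,
    default_truth,
    make_fb_dataset,
    make_paired_stacks,
    make_polarization_pair,
    make_tissue_fixture,
)


class TestTissueFixture:
    def test_cancer_emission_scattering(self):
        slab = make_tissue_fixture("cancer")
        assert slab.emission.mu_s == 267
        assert slab.thickness == 100.0

    def test_normal_parameters(self):
        slab = make_tissue_fixture("normal")
        assert slab.excitation.g == 0.94
        assert slab.emission.mu_s == 172

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            make_tissue_fixture("benign")


class TestFBDataset:
    def test_zero_noise_matches_simulator(self, depths):
        truth = default_truth("cancer", seed=61)
        truth.noise_model = "none"
        profiles, manifest = make_fb_dataset(truth, depths, n_subjects=1, n_photons=5000)
        assert len(profiles) == 1
        assert manifest["f_shg"] == 0.77
        # rerun is bit-identical
        profiles2, _ = make_fb_dataset(truth, depths, n_subjects=1, n_photons=5000)
        assert np.array_equal(profiles[0].values, profiles2[0].values)

    def test_subjects_distinct_with_common_truth(self, depths):
        truth = default_truth("normal", seed=62)
        profiles, manifest = make_fb_dataset(truth, depths, n_subjects=5, n_photons=5000)
        assert len(profiles) == 5
        assert manifest["n_subjects"] == 5
        vals = np.array([p.values for p in profiles])
        assert np.unique(vals, axis=0).shape[0] == 5

    def test_recovery_loop(self, depths, normal_slab):
        """Fit on a generated cohort mean recovers the programmed truth +/- 0.03."""
        truth = default_truth("normal", seed=63)
        profiles, _ = make_fb_dataset(truth, depths, n_subjects=5, n_photons=50_000)
        from shgquant.montecarlo import DepthProfile

        mean = DepthProfile(depths, np.mean([p.values for p in profiles], axis=0))
        res = fit_forward_fraction(mean, normal_slab, SHGSource(), n_photons=50_000, seed=64)
        assert abs(res.best - 0.93) <= 0.03


class TestPairedStacks:
    def test_round_trip_fb_and_attenuation(self, depths):
        truth = default_truth("cancer", seed=65)
        truth.noise_model = "poisson"
        fwd, bwd, manifest = make_paired_stacks(
            truth, depths, frames_per_section=5, shape=(32, 32), n_photons=10_000
        )
        prof = fb_profile(fwd, bwd)
        true_fb = np.asarray(manifest["true_fb"])
        se = np.where(np.isfinite(prof.errors) & (prof.errors > 0), prof.errors, 0.05 * true_fb)
        assert np.all(np.abs(prof.values - true_fb) <= np.maximum(3 * se, 0.05 * true_fb))
        atten = normalized_attenuation(fwd)
        assert atten.values.max() == 1.0

    def test_exposure_invariance(self, depths):
        truth = default_truth("normal", seed=66)
        truth.noise_model = "none"
        fwd, bwd, _ = make_paired_stacks(truth, depths, shape=(16, 16), n_photons=5000)
        base = fb_profile(fwd, bwd).values
        from shgquant.imaging import ImageStack

        doubled = fb_profile(
            ImageStack(fwd.data * 2, fwd.depth_step), ImageStack(bwd.data * 2, bwd.depth_step)
        ).values
        assert np.allclose(base, doubled)

    def test_bad_geometry_rejected(self, depths):
        truth = default_truth("normal", seed=67)
        with pytest.raises(ValueError):
            make_paired_stacks(truth, depths, shape=(0, 16))


class TestPolarizationPair:
    @pytest.mark.parametrize("beta_true", [0.88, 0.76])
    def test_round_trip_recovery(self, beta_true):
        pair, _ = make_polarization_pair(beta_true, seed=68)
        got = anisotropy_beta(pair).overall
        assert got == pytest.approx(beta_true, abs=0.02)

    def test_zero_anisotropy_equal_sums(self):
        pair, _ = make_polarization_pair(0.0, seed=69, poisson=False)
        assert pair.i_par.sum() == pytest.approx(pair.i_perp.sum(), rel=1e-9)

    def test_full_order_no_perpendicular(self):
        pair, _ = make_polarization_pair(1.0, seed=70, poisson=False)
        assert pair.i_perp.sum() == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_polarization_pair(1.2, seed=0)

    def test_truth_validation(self):
        truth = default_truth("normal")
        with pytest.raises(ValueError):
            SyntheticTruth(truth.slab, truth.source, noise_model="speckle")
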