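"""Synthetic inputs with known ground truth for every pipeline stage.

Stands in for the ex vivo biopsy measurements: tissue slabs built from the
packaged bulk-optics fixture, per-subject noisy F/B depth profiles, paired
forward/backward detector stacks whose per-section integrals follow
simulated profiles, and polarization frame pairs with a programmed
anisotropy.  Every generator is deterministic under a fixed seed and
returns a manifest embedding the ground truth alongside the data.

Default study conditions mirror the measured cohort: normal (n = 5) versus
malignant (n = 3) ovarian stroma, 100 um sections, 50,000 photons per focal
depth, depths 0-80 um in 10 um steps, forward fractions 0.93 (normal) and
0.77 (cancer), anisotropies 0.76 and 0.88.  Profile noise is Gaussian with
sigma = 5% of the local value (subject-to-subject variability); pixel
counts are Poisson (photon-counting detectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ImageStack, PolarizationPair
from .montecarlo import DepthProfile, SHGSource, simulate_depth_response
from .optics import TissueSlab, optical_parameters

__all__ = [
    "SyntheticTruth",
    "TISSUE_F_SHG",
    "TISSUE_BETA",
    "make_tissue_fixture",
    "make_fb_dataset",
    "make_paired_stacks",
    "make_polarization_pair",
    "fiber_texture",
]

# measured creation attributes per tissue class: initial forward fraction and
# polarization anisotropy (malignant stroma is more backward-emitting and
# more ordered than normal)
TISSUE_F_SHG = {"normal": 0.93, "cancer": 0.77}
TISSUE_BETA = {"normal": 0.76, "cancer": 0.88}
DEFAULT_DEPTHS = np.arange(0.0, 81.0, 10.0)


@dataclass
class SyntheticTruth:
    """Ground-truth bundle for one synthetic tissue."""

    slab: TissueSlab
    source: SHGSource
    beta_true: float = 0.8
    noise_model: str = "gaussian"  # "gaussian" (fractional sigma) or "poisson"
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not -0.5 <= self.beta_true <= 1.0:
            raise ValueError("beta_true must lie in [-0.5, 1]")

    def manifest(self) -> dict:
        return {
            "tissue": self.slab.label,
            "thickness_um": self.slab.thickness,
            "f_shg": self.source.f_shg,
            "eta_rel": self.source.eta_rel,
            "na": self.source.na,
            "beta_true": self.beta_true,
            "noise_model": self.noise_model,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


def make_tissue_fixture(tissue_class: str, thickness: float = 100.0) -> TissueSlab:
    """Tissue slab from the packaged measured bulk-optics means.

    ``tissue_class`` is ``"normal"`` or ``"cancer"``; excitation parameters
    are the 890 nm set, emission the 457 nm set, thickness 100 um.
    """
    if tissue_class not in ("normal", "cancer"):
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    return TissueSlab(
        thickness=thickness,
        excitation=optical_parameters(tissue_class, 890),
        emission=optical_parameters(tissue_class, 457),
        label=tissue_class,
    )


def default_truth(tissue_class: str, seed: int = 0) -> SyntheticTruth:
    """Study-condition truth for one tissue class."""
    return SyntheticTruth(
        slab=make_tissue_fixture(tissue_class),
        source=SHGSource(f_shg=TISSUE_F_SHG[tissue_class]),
        beta_true=TISSUE_BETA[tissue_class],
        seed=seed,
    )


def make_fb_dataset(
    truth: SyntheticTruth,
    depths: Sequence[float] = DEFAULT_DEPTHS,
    n_subjects: int = 5,
    n_photons: int = 50_000,
) -> tuple[list[DepthProfile], dict]:
    """Per-subject noisy F/B depth profiles plus a ground-truth manifest.

    Each subject gets an independent simulator seed (spawned from the truth
    seed) and, under the Gaussian noise model, multiplicative noise with
    sigma equal to ``noise_sigma`` times the local value — the
    subject-to-subject variability of the cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    depths = np.asarray(depths, dtype=float)
    ss = np.random.SeedSequence(truth.seed)
    children = ss.spawn(n_subjects)
    profiles = []
    for child in children:
        rng = np.random.default_rng(child)
        fb, _ = simulate_depth_response(truth.slab, truth.source, depths, n_photons, seed=rng)
        vals = fb.values.copy()
        if truth.noise_model == "gaussian" and truth.noise_sigma > 0:
            vals = vals * (1.0 + truth.noise_sigma * rng.standard_normal(vals.size))
            vals = np.maximum(vals, 0.0)
        profiles.append(DepthProfile(depths, vals, errors=fb.errors, undefined=fb.undefined))
    manifest = truth.manifest() | {
        "n_subjects": n_subjects,
        "n_photons": n_photons,
        "depths_um": depths.tolist(),
    }
    return profiles, manifest


def fiber_texture(
    shape: tuple[int, int], rng: np.random.Generator, orientation_sigma: tuple[float, float] = (1.0, 8.0)
) -> np.ndarray:
    """Oriented filament field, normalized to unit mean.

    Anisotropically smoothed positive noise — purely cosmetic; only
    integrated sums carry signal in the generated stacks.
    """
    noise = rng.random(shape)
    tex = gaussian_filter(noise, sigma=orientation_sigma, mode="wrap")
    tex = tex - tex.min() + 0.05
    return tex / tex.mean()


def make_paired_stacks(
    truth: SyntheticTruth,
    depths: Sequence[float] = DEFAULT_DEPTHS,
    frames_per_section: int = 5,
    shape: tuple[int, int] = (64, 64),
    n_photons: int = 50_000,
    peak_counts: float = 2.0e5,
) -> tuple[ImageStack, ImageStack, dict]:
    """Paired forward/backward detector stacks following simulated profiles.

    Per-section integrated forward intensity follows the simulated
    normalized attenuation (peak section totals ``peak_counts`` per frame);
    the backward integral is the forward integral divided by the simulated
    F/B.  Pixel counts are Poisson around an oriented fiber texture.
    """
    if shape[0] < 1 or shape[1] < 1 or frames_per_section < 1:
        raise ValueError("non-positive stack geometry")
    depths = np.asarray(depths, dtype=float)
    rng = np.random.default_rng(truth.seed)
    fb, atten = simulate_depth_response(truth.slab, truth.source, depths, n_photons, seed=rng)
    if depths.size > 1:
        step = float(depths[1] - depths[0])
    else:
        step = 1.0

    tex = fiber_texture(shape, rng)
    npix = shape[0] * shape[1]
    fwd = np.empty((depths.size, frames_per_section, *shape))
    bwd = np.empty_like(fwd)
    for i in range(depths.size):
        f_total = peak_counts * atten.values[i]
        b_total = f_total / fb.values[i]
        lam_f = tex * (f_total / npix)
        lam_b = tex * (b_total / npix)
        for j in range(frames_per_section):
            if truth.noise_model == "poisson":
                fwd[i, j] = rng.poisson(lam_f)
                bwd[i, j] = rng.poisson(lam_b)
            else:
                fwd[i, j] = lam_f
                bwd[i, j] = lam_b
    manifest = truth.manifest() | {
        "depths_um": depths.tolist(),
        "frames_per_section": frames_per_section,
        "shape": list(shape),
        "true_fb": fb.values.tolist(),
        "true_attenuation": atten.values.tolist(),
        "n_photons": n_photons,
    }
    return (
        ImageStack(fwd, depth_step=step),
        ImageStack(bwd, depth_step=step),
        manifest,
    )


def make_polarization_pair(
    beta_true: float,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    total_counts: float = 2.0e6,
    poisson: bool = True,
) -> tuple[PolarizationPair, dict]:
    """Analyzer-parallel/perpendicular frame pair with programmed anisotropy.

    Frame sums satisfy ``beta = (P - Q)/(P + 2 Q)`` exactly before noise:
    ``P/Q = (1 + 2 beta)/(1 - beta)``.  Poisson pixel noise optional.
    """
    if not -0.5 <= beta_true <= 1.0:
        raise ValueError("beta_true must lie in [-0.5, 1]")
    rng = np.random.default_rng(seed)
    tex = fiber_texture(shape, rng)
    npix = shape[0] * shape[1]
    if beta_true == 1.0:
        p_total, q_total = total_counts, 0.0
    else:
        ratio = (1.0 + 2.0 * beta_true) / (1.0 - beta_true)  # P/Q
        q_total = total_counts / (1.0 + ratio)
        p_total = total_counts - q_total
    lam_p = tex * (p_total / npix)
    lam_q = tex * (q_total / npix)
    if poisson:
        i_par = rng.poisson(lam_p).astype(float)
        i_perp = rng.poisson(lam_q).astype(float)
    else:
        i_par, i_perp = lam_p, lam_q
    manifest = {
        "beta_true": beta_true,
        "shape": list(shape),
        "total_counts": total_counts,
        "poisson": poisson,
        "seed": seed,
    }
    return PolarizationPair(i_par=i_par, i_perp=i_perp), manifest
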