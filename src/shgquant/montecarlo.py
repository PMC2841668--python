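"""Monte Carlo model of second-harmonic creation and propagation in a slab.

The model decouples the measured depth-resolved forward/backward (F/B)
second-harmonic response into *creation attributes* — a relative conversion
efficiency ``eta_rel`` (proportional to the chi2-derived intensity) and an
initial forward-emitted fraction ``f_shg`` — and subsequent *propagation*
through the turbid slab governed by the bulk optical parameters at the
emission wavelength.

Excitation delivery is ballistic: the focused laser cone attenuates by
Beer-Lambert along each ray of the NA-defined cone (the primary filter
effect), and second-harmonic creation scales with the transmitted intensity
squared (two excitation photons per emitted photon).  Emitted photons are
launched at the focal depth into forward (+z) or backward (-z) cones and
walked with the standard multilayer Monte Carlo scheme: exponential steps in
the total interaction coefficient, weight deposition by the single-scattering
albedo, Henyey-Greenstein deflection, Russian roulette termination.
Boundaries are refractive-index matched (no Fresnel reflection) and the slab
is laterally infinite; all weight crossing a face is tallied regardless of
exit angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from .optics import CM_TO_UM, TissueSlab

__all__ = [
    "SHGSource",
    "PhotonSet",
    "DirectionalTally",
    "DepthProfile",
    "excitation_transmission",
    "sample_hg_cosine",
    "generate_emission",
    "propagate_emission",
    "simulate_depth_response",
    "simulate_lobe_tallies",
]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_GAUSS_NODES = 64


@dataclass(frozen=True)
class SHGSource:
    """Creation attributes of the second-harmonic signal at the focus.

    ``eta_rel`` is the conversion efficiency relative to a reference tissue
    (dimensionless); ``f_shg`` the initially forward-emitted fraction;
    ``na`` the objective numerical aperture defining both the excitation
    cone and the emission cones; ``focal_depth`` the focus position in um
    below the entry face.
    """

    eta_rel: float = 1.0
    f_shg: float = 0.93
    na: float = 0.8
    focal_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.eta_rel <= 0:
            raise ValueError(f"eta_rel must be positive, got {self.eta_rel}")
        if not 0.0 <= self.f_shg <= 1.0:
            raise ValueError(f"f_shg must lie in [0, 1], got {self.f_shg}")
        if self.na <= 0:
            raise ValueError(f"na must be positive, got {self.na}")
        if self.focal_depth < 0:
            raise ValueError(f"focal_depth must be >= 0, got {self.focal_depth}")


@dataclass
class PhotonSet:
    """Photon ensemble: axial position, direction cosines and weights."""

    z: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    weight: np.ndarray

    def __len__(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class DirectionalTally:
    """Weight budget of one propagation run.

    forward_weight exits through the deep face, backward_weight through the
    entry face, absorbed_weight is deposited in the slab; conservation versus
    launched_weight holds to within the Russian-roulette tolerance.
    """

    forward_weight: float
    backward_weight: float
    absorbed_weight: float
    launched_weight: float

    def __post_init__(self) -> None:
        for name in ("forward_weight", "backward_weight", "absorbed_weight", "launched_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def conservation_error(self) -> float:
        """Relative weight-conservation defect (unbiased roulette residual)."""
        total = self.forward_weight + self.backward_weight + self.absorbed_weight
        return abs(total - self.launched_weight) / self.launched_weight


@dataclass
class DepthProfile:
    """Ordered (depth, value[, error]) series: F/B ratio or normalized intensity.

    ``undefined`` marks depths where the quantity could not be formed (e.g. a
    zero backward integral); values there are NaN, never silently dropped.
    """

    depths: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.size != self.depths.size:
                raise ValueError("errors must match depths in length")
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)
        else:
            self.undefined = np.asarray(self.undefined, dtype=bool)
        if self.values.size != self.depths.size:
            raise ValueError("values must match depths in length")
        if self.depths.size > 1 and not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")
        ok = ~self.undefined
        if np.any(self.values[ok] < 0):
            raise ValueError("values must be non-negative")

    def __len__(self) -> int:
        return self.depths.size


def excitation_transmission(slab: TissueSlab, focal_depth: float, na: float) -> float:
    """Ballistic transmission of the focused laser cone to ``focal_depth``.

    Solid-angle-weighted average, over the aperture cone of half-angle
    ``asin(na / n)``, of ``exp(-mu_t * focal_depth / cos(theta))`` with
    ``mu_t`` at the excitation wavelength.  Equals the Beer-Lambert on-axis
    factor in the pencil-beam (na -> 0) limit and 1 at the surface.
    """
    if not 0.0 <= focal_depth <= slab.thickness:
        raise ValueError("focal_depth must lie within the slab")
    n_med = slab.excitation.n
    if na >= n_med:
        raise ValueError(f"na ({na}) must be below the medium index ({n_med})")
    mu_t = slab.excitation.mu_t_per_um
    if mu_t == 0.0 or focal_depth == 0.0:
        return 1.0
    cos_max = np.cos(np.arcsin(na / n_med))
    if cos_max >= 1.0 - 1e-12:
        return float(np.exp(-mu_t * focal_depth))
    # uniform in solid angle <=> uniform in mu = cos(theta) on [cos_max, 1];
    # Gauss-Legendre nodes mapped to that interval, mean = weighted sum / 2
    x, w = leggauss(_GAUSS_NODES)
    mu = 0.5 * (1.0 - cos_max) * x + 0.5 * (1.0 + cos_max)
    vals = np.exp(-mu_t * focal_depth / mu)
    return float(np.sum(w * vals) / 2.0)


def sample_hg_cosine(g: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw deflection cosines from the Henyey-Greenstein phase function."""
    xi = rng.random(size)
    if g == 0.0:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(cost, -1.0, 1.0)


def _cone_directions(
    n_photons: int, cos_max: float, sign: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directions uniform in solid angle within a cone about +/-z."""
    cost = rng.uniform(cos_max, 1.0, n_photons)
    sint = np.sqrt(1.0 - cost * cost)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_photons)
    return sint * np.cos(phi), sint * np.sin(phi), sign * cost


def generate_emission(
    n_photons: int,
    f_shg: float,
    na: float,
    rng: np.random.Generator | int,
    *,
    n_medium: float = 1.33,
    focal_depth: float = 0.0,
) -> PhotonSet:
    """Launch ``n_photons`` second-harmonic photons at the focal point.

    Each photon is emitted forward (+z) with probability ``f_shg`` and
    backward otherwise, into a cone of half-angle ``asin(na / n_medium)``
    about its lobe axis, uniform in solid angle within the cone.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not 0.0 <= f_shg <= 1.0:
        raise ValueError(f"f_shg must lie in [0, 1], got {f_shg}")
    if na >= n_medium:
        raise ValueError(f"na ({na}) must be below the medium index ({n_medium})")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    forward = rng.random(n_photons) < f_shg
    sign = np.where(forward, 1.0, -1.0)
    cos_max = float(np.cos(np.arcsin(na / n_medium)))
    ux, uy, uz = _cone_directions(n_photons, cos_max, sign, rng)
    return PhotonSet(
        z=np.full(n_photons, float(focal_depth)),
        ux=ux,
        uy=uy,
        uz=uz,
        weight=np.ones(n_photons),
    )


def _spin(
    ux: np.ndarray, uy: np.ndarray, uz: np.ndarray, cost: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate direction cosines by (theta, phi) — standard multilayer-MC update."""
    sint = np.sqrt(np.maximum(0.0, 1.0 - cost * cost))
    cosp, sinp = np.cos(phi), np.sin(phi)
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1e-30, 1.0 - uz * uz))
    nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
    nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
    nuz = -sint * cosp * denom + uz * cost
    pux = sint * cosp
    puy = sint * sinp
    puz = np.sign(uz) * cost
    ux_out = np.where(near_pole, pux, nux)
    uy_out = np.where(near_pole, puy, nuy)
    uz_out = np.where(near_pole, puz, nuz)
    norm = np.sqrt(ux_out**2 + uy_out**2 + uz_out**2)
    return ux_out / norm, uy_out / norm, uz_out / norm


def _walk(
    photons: PhotonSet,
    mu_s: float,
    mu_a: float,
    g: float,
    thickness: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random-walk all photons to termination.

    Returns per-photon (forward-exit, backward-exit, absorbed) weights, in
    the launch order.  Weight dropped by losing the Russian roulette is not
    tallied anywhere; the scheme is unbiased and the residual is bounded by
    the roulette threshold.
    """
    n = len(photons)
    fwd = np.zeros(n)
    bwd = np.zeros(n)
    absorbed = np.zeros(n)

    mu_t = (mu_s + mu_a) / CM_TO_UM  # um^-1
    if mu_t == 0.0:
        going_up = photons.uz > 0
        fwd[going_up] = photons.weight[going_up]
        bwd[~going_up] = photons.weight[~going_up]
        return fwd, bwd, absorbed
    albedo = mu_s / (mu_s + mu_a)

    idx = np.arange(n)
    z = photons.z.copy()
    ux, uy, uz = photons.ux.copy(), photons.uy.copy(), photons.uz.copy()
    w = photons.weight.copy()

    while idx.size:
        m = idx.size
        step = -np.log(rng.random(m)) / mu_t
        z = z + step * uz

        exit_fwd = z >= thickness
        exit_bwd = (z <= 0.0) & ~exit_fwd
        alive = ~(exit_fwd | exit_bwd)
        np.add.at(fwd, idx[exit_fwd], w[exit_fwd])
        np.add.at(bwd, idx[exit_bwd], w[exit_bwd])

        idx, z, ux, uy, uz, w = (
            idx[alive],
            z[alive],
            ux[alive],
            uy[alive],
            uz[alive],
            w[alive],
        )
        if not idx.size:
            break

        # interaction: deposit, scatter, roulette
        deposit = w * (1.0 - albedo)
        np.add.at(absorbed, idx, deposit)
        w = w * albedo

        cost = sample_hg_cosine(g, rng, idx.size)
        phi = rng.uniform(0.0, 2.0 * np.pi, idx.size)
        ux, uy, uz = _spin(ux, uy, uz, cost, phi)

        low = w < ROULETTE_THRESHOLD
        if np.any(low):
            survive = rng.random(idx.size) < ROULETTE_SURVIVAL
            keep = ~low | survive
            w = np.where(low & survive, w / ROULETTE_SURVIVAL, w)
            idx, z, ux, uy, uz, w = (
                idx[keep],
                z[keep],
                ux[keep],
                uy[keep],
                uz[keep],
                w[keep],
            )

    return fwd, bwd, absorbed


def propagate_emission(
    slab: TissueSlab, photons: PhotonSet, rng: np.random.Generator | int
) -> DirectionalTally:
    """Walk an emitted photon set through the slab at the emission wavelength."""
    if len(photons) == 0:
        raise ValueError("empty photon set")
    if np.any(photons.z < 0) or np.any(photons.z > slab.thickness):
        raise ValueError("photons must start inside the slab")
    for arr in (photons.z, photons.ux, photons.uy, photons.uz, photons.weight):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite photon state")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    em = slab.emission
    fwd, bwd, absorbed = _walk(photons, em.mu_s, em.mu_a, em.g, slab.thickness, rng)
    return DirectionalTally(
        forward_weight=float(fwd.sum()),
        backward_weight=float(bwd.sum()),
        absorbed_weight=float(absorbed.sum()),
        launched_weight=float(photons.weight.sum()),
    )


def _batch_ratio_se(fwd: np.ndarray, bwd: np.ndarray, n_batches: int = 10) -> float:
    """Standard error of the F/B ratio from batch means of per-photon fates."""
    n = fwd.size
    k = n // n_batches
    if k == 0:
        return np.nan
    f = fwd[: k * n_batches].reshape(n_batches, k).sum(axis=1)
    b = bwd[: k * n_batches].reshape(n_batches, k).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = f / b
    r = r[np.isfinite(r)]
    if r.size < 2:
        return np.nan
    return float(np.std(r, ddof=1) / np.sqrt(r.size))


def simulate_depth_response(
    slab: TissueSlab,
    source: SHGSource,
    depths: Sequence[float],
    n_photons: int = 50_000,
    seed: int | np.random.Generator = 0,
) -> tuple[DepthProfile, DepthProfile]:
    """Simulate detected F/B and normalized forward attenuation versus depth.

    At each focal depth ``z`` the creation weight is
    ``eta_rel * T_exc(z)**2`` (ballistic excitation transmission squared);
    the emitted ensemble is generated with ``f_shg`` and propagated at the
    emission wavelength.  The F/B value is the ratio of exiting forward to
    backward weight; the attenuation value is the creation weight times the
    forward-transmitted fraction, and the attenuation series is
    self-normalized to its maximum.

    Returns ``(fb_profile, attenuation_profile)``; depths with zero backward
    weight are flagged undefined in the F/B profile, never dropped.  A single
    seeded generator drives the whole call, so results are reproducible
    bit-for-bit given the seed.
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0) or np.any(depths > slab.thickness):
        raise ValueError("depths must lie within [0, thickness]")
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed

    em = slab.emission
    fb_vals = np.empty(depths.size)
    fb_se = np.empty(depths.size)
    atten = np.empty(depths.size)
    undefined = np.zeros(depths.size, dtype=bool)

    for i, z in enumerate(depths):
        t_exc = excitation_transmission(slab, float(z), source.na)
        creation = source.eta_rel * t_exc * t_exc
        photons = generate_emission(
            n_photons, source.f_shg, source.na, rng, n_medium=em.n, focal_depth=float(z)
        )
        fwd, bwd, _ = _walk(photons, em.mu_s, em.mu_a, em.g, slab.thickness, rng)
        f_tot, b_tot = fwd.sum(), bwd.sum()
        if b_tot == 0.0:
            fb_vals[i] = np.nan
            fb_se[i] = np.nan
            undefined[i] = True
        else:
            fb_vals[i] = f_tot / b_tot
            fb_se[i] = _batch_ratio_se(fwd, bwd)
        atten[i] = creation * f_tot / photons.weight.sum()

    peak = atten.max()
    if peak <= 0:
        raise ValueError("attenuation profile is identically zero")
    fb_profile = DepthProfile(depths, fb_vals, errors=fb_se, undefined=undefined)
    attenuation = DepthProfile(depths, atten / peak)
    return fb_profile, attenuation


def simulate_lobe_tallies(
    slab: TissueSlab,
    depths: Sequence[float],
    na: float,
    n_photons: int = 50_000,
    seed: int | np.random.Generator = 0,
    n_batches: int = 10,
) -> dict:
    """Propagate the forward and backward emission lobes separately per depth.

    Because propagation is independent of the emission split, the detected
    response for any forward fraction ``f`` is the mixture
    ``f * (forward-lobe tally) + (1 - f) * (backward-lobe tally)``.  Fitting
    routines exploit this: one pair of lobe simulations per depth serves the
    entire grid of candidate fractions with common random numbers.

    Returns a dict of arrays, each of shape (n_depths,): the per-launched-
    photon forward/backward exit fractions for each lobe (``ff``, ``fb`` for
    the forward lobe; ``bf``, ``bb`` for the backward lobe), their batch
    variances, and the excitation transmissions.
    """
    depths = np.asarray(depths, dtype=float)
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    em = slab.emission
    nd = depths.size
    out = {
        key: np.zeros(nd)
        for key in ("ff", "fb", "bf", "bb", "var_ff", "var_fb", "var_bf", "var_bb", "t_exc")
    }
    k = n_photons // n_batches

    for i, z in enumerate(depths):
        out["t_exc"][i] = excitation_transmission(slab, float(z), na)
        for lobe, (key_f, key_b) in (("forward", ("ff", "fb")), ("backward", ("bf", "bb"))):
            f_frac = 1.0 if lobe == "forward" else 0.0
            photons = generate_emission(
                n_photons, f_frac, na, rng, n_medium=em.n, focal_depth=float(z)
            )
            fwd, bwd, _ = _walk(photons, em.mu_s, em.mu_a, em.g, slab.thickness, rng)
            out[key_f][i] = fwd.sum() / n_photons
            out[key_b][i] = bwd.sum() / n_photons
            bf_ = fwd[: k * n_batches].reshape(n_batches, k).mean(axis=1)
            bb_ = bwd[: k * n_batches].reshape(n_batches, k).mean(axis=1)
            out["var_" + key_f][i] = np.var(bf_, ddof=1) / n_batches
            out["var_" + key_b][i] = np.var(bb_, ddof=1) / n_batches

    out["depths"] = depths
    out["n_photons"] = n_photons
    return out
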