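"""Bulk tissue optical parameters and derived scalar quantities.

Collagenous tissue is characterized, per wavelength, by a scattering
coefficient ``mu_s`` (cm^-1), an absorption coefficient ``mu_a`` (cm^-1),
a scattering anisotropy ``g`` (mean cosine of the single-scattering
deflection angle) and a refractive index ``n``.  Two derived scalars are
used throughout the pipeline: the reduced scattering coefficient
``mu_s' = mu_s * (1 - g)`` and the scattering mean free path
``MFP = 1/mu_s``.

Coefficients are stored in cm^-1 and geometry in micrometres; the
``x 1e-4`` unit conversion happens inside operations, never at call sites.
A read-only fixture of measured ovarian-stroma parameters (normal and
malignant classes at the laser and SHG wavelengths) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "OpticalParameters",
    "TissueSlab",
    "GroupSummary",
    "reduced_scattering",
    "spectral_slope_ratio",
    "mean_free_path",
    "load_bulk_optics",
    "optical_parameters",
    "group_summary",
]

CM_TO_UM = 1e4  # 1 cm = 1e4 um; coefficients in cm^-1, geometry in um


@dataclass(frozen=True)
class OpticalParameters:
    """Bulk optical parameters of one tissue at one wavelength.

    Attributes
    ----------
    wavelength : float
        Vacuum wavelength in nm.
    mu_s, mu_a : float
        Scattering / absorption coefficients in cm^-1.
    g : float
        Scattering anisotropy (mean cosine), in [0, 1].
    n : float
        Refractive index (>= 1).
    """

    wavelength: float
    mu_s: float
    mu_a: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be non-negative, got {self.mu_s}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [0, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_s + mu_a (cm^-1)."""
        return self.mu_s + self.mu_a

    @property
    def mu_t_per_um(self) -> float:
        """Total interaction coefficient in um^-1."""
        return self.mu_t / CM_TO_UM

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / (mu_s + mu_a); 0 for a clear medium."""
        return self.mu_s / self.mu_t if self.mu_t > 0 else 0.0


@dataclass(frozen=True)
class TissueSlab:
    """A laterally infinite tissue section of finite thickness.

    Holds the optical parameters at the excitation (laser) wavelength and at
    the emission (second-harmonic) wavelength.  Second-harmonic generation
    halves the wavelength, so the excitation wavelength must be twice the
    emission wavelength to within 5% (the bulk measurement wavelength of
    457 nm stands in for the exact second harmonic of 890 nm).
    """

    thickness: float  # um
    excitation: OpticalParameters
    emission: OpticalParameters
    label: str = ""

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        ratio = self.excitation.wavelength / (2.0 * self.emission.wavelength)
        if abs(ratio - 1.0) > 0.05:
            raise ValueError(
                "excitation wavelength must be ~2x the emission wavelength "
                f"(got {self.excitation.wavelength} vs {self.emission.wavelength})"
            )


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and sample count of one measured quantity."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = mu_s * (1 - g), in cm^-1.

    Equals mu_s for isotropic scattering (g = 0) and vanishes in the fully
    forward-scattering limit (g = 1).
    """
    if mu_s < 0:
        raise ValueError(f"mu_s must be non-negative, got {mu_s}")
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"g must lie in [0, 1], got {g}")
    return mu_s * (1.0 - g)


def spectral_slope_ratio(mu_s_prime_shg: float, mu_s_prime_laser: float) -> float:
    """Fold-increase of mu_s' from the laser to the (shorter) SHG wavelength.

    A steep spectral slope (large fold-increase) is characteristic of
    mass-fractal refractive-index organization; a flat slope of assemblies
    with a typical scatterer size.
    """
    if mu_s_prime_shg <= 0 or mu_s_prime_laser <= 0:
        raise ValueError("reduced scattering coefficients must be positive")
    return mu_s_prime_shg / mu_s_prime_laser


def mean_free_path(mu_s: float) -> float:
    """Scattering mean free path 1/mu_s, returned in micrometres.

    The distance a photon propagates, on average, before a scattering
    collision redirects it.
    """
    if mu_s <= 0:
        raise ValueError(f"mu_s must be positive, got {mu_s}")
    return CM_TO_UM / mu_s


def load_bulk_optics() -> pd.DataFrame:
    """Load the packaged measured bulk-optics fixture.

    One row per (tissue class, wavelength): scattering and absorption
    coefficients, anisotropy, the printed reduced-scattering summaries, the
    refractive index used for cone geometry, and the number of biopsies.
    """
    with resources.files("shgquant.data").joinpath(
        "bulk_optical_parameters.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _fixture_row(tissue: str, wavelength_nm: int) -> pd.Series:
    table = load_bulk_optics()
    sel = table[(table.tissue == tissue) & (table.wavelength_nm == wavelength_nm)]
    if len(sel) != 1:
        raise KeyError(f"no fixture entry for ({tissue!r}, {wavelength_nm} nm)")
    return sel.iloc[0]


def optical_parameters(tissue: str, wavelength_nm: int) -> OpticalParameters:
    """Fixture lookup -> :class:`OpticalParameters` (means of the measured group)."""
    row = _fixture_row(tissue, wavelength_nm)
    return OpticalParameters(
        wavelength=float(row.wavelength_nm),
        mu_s=float(row.mu_s),
        mu_a=float(row.mu_a),
        g=float(row.g),
        n=float(row.refractive_index),
    )


def group_summary(tissue: str, wavelength_nm: int, quantity: str) -> GroupSummary:
    """Fixture lookup -> :class:`GroupSummary` for one printed quantity.

    ``quantity`` is one of ``"mu_s"``, ``"mu_a"``, ``"g"``, ``"mu_s_prime"``.
    Note the printed ``mu_s_prime`` summaries are per-specimen averages and do
    not exactly equal ``mu_s * (1 - g)`` of the printed group means; use
    :func:`reduced_scattering` when recomputing from means is wanted.
    """
    row = _fixture_row(tissue, wavelength_nm)
    if quantity not in ("mu_s", "mu_a", "g", "mu_s_prime"):
        raise KeyError(f"unknown quantity {quantity!r}")
    return GroupSummary(
        mean=float(row[quantity]),
        sd=float(row[f"{quantity}_sd"]),
        n=int(row.n_samples),
    )
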