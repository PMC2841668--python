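"""Quantification of detector image stacks and polarization pairs.

Three measured quantities are extracted from image data:

* depth-resolved F/B — per optical section, the integrated intensity of the
  forward-detector frames divided by that of the backward-detector frames;
* normalized forward attenuation — per-section mean integrated intensity,
  self-normalized to the section with the maximum mean;
* polarization anisotropy ``beta = (I_par - I_perp) / (I_par + 2 I_perp)``,
  computed on intensity sums over a region of interest.  The denominator
  with the factor of 2 makes the range exactly [-0.5, 1]: 1 for perfectly
  ordered fibers (no perpendicular component), 0 for random organization,
  -0.5 when all intensity is perpendicular.

Integration is over whole fields of view by default (no thresholding or
background subtraction); stacks are multi-page TIFFs grouped into optical
sections by a fixed frames-per-section count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .montecarlo import DepthProfile

__all__ = [
    "ImageStack",
    "PolarizationPair",
    "BetaResult",
    "fb_profile",
    "normalized_attenuation",
    "anisotropy_beta",
]


@dataclass
class ImageStack:
    """Ordered detector frames grouped into optical sections.

    ``data`` has shape (n_sections, frames_per_section, height, width);
    ``depth_step`` is the axial spacing between sections in um.
    """

    data: np.ndarray
    depth_step: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (sections, frames, height, width)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one section")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.depth_step <= 0:
            raise ValueError("depth_step must be positive")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def frames_per_section(self) -> int:
        return self.data.shape[1]

    @property
    def depths(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.depth_step

    @classmethod
    def from_tiff(
        cls, path, frames_per_section: int = 5, depth_step: float = 10.0
    ) -> "ImageStack":
        """Read a multi-page TIFF, grouping pages into optical sections."""
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        n = (pages.shape[0] // frames_per_section) * frames_per_section
        if n == 0:
            raise ValueError("fewer pages than frames_per_section")
        data = pages[:n].reshape(-1, frames_per_section, *pages.shape[1:])
        return cls(data=data, depth_step=depth_step)

    def to_tiff(self, path) -> None:
        flat = self.data.reshape(-1, *self.data.shape[2:])
        tifffile.imwrite(path, flat.astype(np.float32))


@dataclass
class PolarizationPair:
    """Parallel/perpendicular analyzer frame pair, with optional ROI mask.

    ``roi_mask`` may be boolean (one region) or an integer label image
    (region k where mask == k, k >= 1); None means the whole field.
    """

    i_par: np.ndarray
    i_perp: np.ndarray
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.i_par = np.asarray(self.i_par, dtype=float)
        self.i_perp = np.asarray(self.i_perp, dtype=float)
        if self.i_par.shape != self.i_perp.shape:
            raise ValueError("i_par and i_perp must have matching shapes")
        if np.any(self.i_par < 0) or np.any(self.i_perp < 0):
            raise ValueError("intensities must be non-negative")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask)
            if self.roi_mask.shape != self.i_par.shape:
                raise ValueError("roi_mask must match frame shape")


@dataclass
class BetaResult:
    """Anisotropy per region of interest plus the whole-field value."""

    overall: float
    per_roi: dict[int, float]
    undefined_rois: list[int]


def fb_profile(forward: ImageStack, backward: ImageStack) -> DepthProfile:
    """Depth-resolved F/B ratio from paired, cross-calibrated detector stacks.

    Per section the value is the summed forward intensity over the summed
    backward intensity; the error is the standard error of the frame-wise
    ratios.  Sections with zero backward integral are flagged undefined.
    """
    if forward.n_sections != backward.n_sections:
        raise ValueError("stacks must have equal section counts")
    if forward.depth_step != backward.depth_step:
        raise ValueError("stacks must share a depth step")
    f_sum = forward.data.sum(axis=(1, 2, 3))
    b_sum = backward.data.sum(axis=(1, 2, 3))
    undefined = b_sum == 0
    values = np.full(forward.n_sections, np.nan)
    errors = np.full(forward.n_sections, np.nan)
    np.divide(f_sum, b_sum, out=values, where=~undefined)
    f_frames = forward.data.sum(axis=(2, 3))
    b_frames = backward.data.sum(axis=(2, 3))
    k = forward.frames_per_section
    for i in np.flatnonzero(~undefined):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = f_frames[i] / b_frames[i]
        r = r[np.isfinite(r)]
        if r.size >= 2:
            errors[i] = np.std(r, ddof=1) / np.sqrt(r.size)
    return DepthProfile(forward.depths, values, errors=errors, undefined=undefined)


def normalized_attenuation(forward: ImageStack) -> DepthProfile:
    """Per-section mean integrated intensity, self-normalized to its maximum."""
    means = forward.data.sum(axis=(2, 3)).mean(axis=1)
    peak = means.max()
    if peak <= 0:
        raise ValueError("all-zero stack")
    return DepthProfile(forward.depths, means / peak)


def _beta_from_sums(p: float, q: float, simple_contrast: bool) -> float:
    denom = (p + q) if simple_contrast else (p + 2.0 * q)
    if denom == 0:
        return np.nan
    return (p - q) / denom


def anisotropy_beta(
    pair: PolarizationPair, simple_contrast: bool = False
) -> BetaResult:
    """Polarization anisotropy beta over each ROI and the whole field.

    Uses intensity sums over the region (robust to dark pixels), not
    per-pixel averages.  ``simple_contrast=True`` switches to the plain
    (P - Q)/(P + Q) contrast whose range is [-1, 1].
    """
    p_all = float(pair.i_par.sum())
    q_all = float(pair.i_perp.sum())
    overall = _beta_from_sums(p_all, q_all, simple_contrast)

    per_roi: dict[int, float] = {}
    undefined: list[int] = []
    if pair.roi_mask is not None:
        mask = pair.roi_mask
        labels = [1] if mask.dtype == bool else sorted(int(k) for k in np.unique(mask) if k > 0)
        for k in labels:
            sel = mask if mask.dtype == bool else (mask == k)
            if not np.any(sel):
                undefined.append(k)
                continue
            b = _beta_from_sums(float(pair.i_par[sel].sum()), float(pair.i_perp[sel].sum()), simple_contrast)
            if np.isnan(b):
                undefined.append(k)
            else:
                per_roi[k] = b
    return BetaResult(overall=overall, per_roi=per_roi, undefined_rois=undefined)
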