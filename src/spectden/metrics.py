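"""Quantitative evaluation: VOI error indices, polar maps, agreement analysis.

All voxel-based indices are computed inside a cubic volume-of-interest
(default 18x18x18, N = 5832 voxels) anchored on the heart, against the
filtered full-time reconstruction as reference:

    NMSE = sum (I_D - I_FT)^2 / sum I_FT^2
    SSIM = (2 mu_D mu_FT + C1)(2 sigma_DFT + C2)
           / ((mu_D^2 + mu_FT^2 + C1)(sigma_D^2 + sigma_FT^2 + C2))
    PSNR = 10 log10( MAX_FT / MSE )

SSIM is a single global index over the VOI (not sliding-window) with
C1 = 0.01 and C2 = 0.02 taken at face value.  The PSNR numerator is MAX_FT
(not MAX_FT^2) by default, matching the printed formula of the protocol this
package emulates; the conventional squared-maximum definition is available
via ``convention='standard'``.

The perfusion-defect-size surrogate is a documented threshold rule on the
polar map (percent of wall pixels below a fraction of the normal-region
mean).  It is NOT the proprietary WLCQ algorithm used clinically; it plays
the same role as an extent index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "voi_slices", "nmse", "ssim", "psnr",
    "PolarMapROIs", "polar_map", "default_rois", "intensity_ratio",
    "defect_extent_surrogate", "bland_altman", "BlandAltmanResult",
    "joint_regression", "RegressionResult", "paired_test",
]

#: SSIM stabilisation constants, as printed in the emulated protocol
SSIM_C1 = 0.01
SSIM_C2 = 0.02
#: default VOI edge length (voxels); N = 18^3 = 5832
DEFAULT_VOI = 18


# ---------------------------------------------------------------------------
# VOI handling

def voi_slices(center, size: int, shape) -> tuple[slice, slice, slice]:
    """Cubic VOI of edge ``size`` centered on ``center``, clamped inside ``shape``.

    Raises if the VOI cannot fit in the volume.
    """
    out = []
    for c, n in zip(center, shape):
        if size > n:
            raise ValueError(f"VOI size {size} exceeds volume extent {n}")
        lo = int(round(c)) - size // 2
        lo = min(max(lo, 0), n - size)
        out.append(slice(lo, lo + size))
    return tuple(out)


def _extract(i_d, i_ft, voi):
    a = np.asarray(i_d, dtype=np.float64)
    b = np.asarray(i_ft, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    if voi is not None:
        a, b = a[voi], b[voi]
    return a.ravel(), b.ravel()


def nmse(i_d, i_ft, voi=None) -> float:
    """Normalized mean square error over the VOI."""
    a, b = _extract(i_d, i_ft, voi)
    denom = float((b ** 2).sum())
    if denom <= 0:
        raise ValueError("reference has zero energy in the VOI")
    return float(((a - b) ** 2).sum()) / denom


def ssim(i_d, i_ft, voi=None, c1: float = SSIM_C1, c2: float = SSIM_C2) -> float:
    """Global (whole-VOI) structural similarity index."""
    a, b = _extract(i_d, i_ft, voi)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                 / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


def psnr(i_d, i_ft, voi=None, convention: str = "printed") -> float:
    """Peak signal-to-noise ratio in dB.

    convention 'printed': 10 log10(MAX_FT / MSE), the form the emulated
    protocol prints (maximum, not maximum squared); 'standard':
    10 log10(MAX_FT^2 / MSE).  Identical images give +inf.
    """
    a, b = _extract(i_d, i_ft, voi)
    mse = float(((a - b) ** 2).mean())
    peak = float(b.max())
    if convention == "standard":
        peak = peak ** 2
    elif convention != "printed":
        raise ValueError(f"unknown PSNR convention {convention!r}")
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak / mse))


# ---------------------------------------------------------------------------
# polar map and regional indices

@dataclass
class PolarMapROIs:
    """Circumferential-profile map plus defect / normal region masks.

    ``polar_map`` is a (n_axial, n_angles) array: each row is one short-axis
    slice, each column one azimuth; values are the maximum counts along the
    radial ray from the LV long axis (radial maximum-count sampling).
    """

    polar_map: np.ndarray
    roi_defect: np.ndarray | None = None   # ROI_1
    roi_normal: np.ndarray | None = None   # ROI_2
    angles_rad: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate(self):
        for roi in (self.roi_defect, self.roi_normal):
            if roi is not None and roi.shape != self.polar_map.shape:
                raise ValueError("ROI mask shape must match the polar map")
        if (self.roi_defect is not None and self.roi_normal is not None
                and (self.roi_defect & self.roi_normal).any()):
            raise ValueError("defect and normal ROIs must be disjoint")


def polar_map(image: np.ndarray, center, z_range=None, n_angles: int = 36,
              r_max: float | None = None, n_r: int = 24) -> np.ndarray:
    """Sample the LV wall into a (n_axial, n_angles) circumferential map.

    ``center`` is the LV long-axis position (x, y, z) in voxel coordinates;
    the long axis is assumed along z (phantom convention).  For every
    short-axis slice in ``z_range`` and azimuth, the maximum interpolated
    count along the radial ray from the axis is recorded — the standard
    maximum-count circumferential profile that clinical bull's-eye maps are
    built from.  Deterministic for fixed inputs.
    """
    img = np.asarray(image, dtype=np.float64)
    nx, ny, nz = img.shape
    cx, cy, cz = center
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError(f"LV axis {center} outside volume {img.shape}")
    if z_range is None:
        half = nz // 4
        z_range = (max(int(round(cz)) - half, 0), min(int(round(cz)) + half + 1, nz))
    z_lo, z_hi = int(z_range[0]), int(z_range[1])
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(f"invalid z_range {z_range}")
    if r_max is None:
        r_max = min(cx, cy, nx - 1 - cx, ny - 1 - cy)
    angles = 2 * np.pi * np.arange(n_angles) / n_angles
    radii = np.linspace(0.0, r_max, n_r)
    # sample grid: (z, angle, radius)
    xs = cx + radii[None, :] * np.cos(angles)[:, None]
    ys = cy + radii[None, :] * np.sin(angles)[:, None]
    out = np.empty((z_hi - z_lo, n_angles))
    for i, z in enumerate(range(z_lo, z_hi)):
        coords = np.stack([
            np.broadcast_to(xs, (n_angles, n_r)).ravel(),
            np.broadcast_to(ys, (n_angles, n_r)).ravel(),
            np.full(n_angles * n_r, float(z)),
        ])
        vals = ndimage.map_coordinates(img, coords, order=1, mode="constant")
        out[i] = vals.reshape(n_angles, n_r).max(axis=1)
    return out


def default_rois(pmap: np.ndarray, defect_phi0: float | None = None,
                 defect_extent_frac: float = 0.15,
                 n_angles: int | None = None) -> PolarMapROIs:
    """Construct defect / normal ROI masks on a circumferential map.

    ROI_1 covers the azimuth sector starting at ``defect_phi0`` with the
    given fractional width (ground-truth placement for synthetic subjects;
    an arbitrary fixed sector when no defect exists); ROI_2 is the
    diametrically opposite sector of the same width.
    """
    nz, na = pmap.shape
    angles = 2 * np.pi * np.arange(na) / na
    phi0 = 0.0 if defect_phi0 is None else float(defect_phi0)
    width = max(defect_extent_frac, 1.0 / na) * 2 * np.pi
    d_ang = (angles - phi0) % (2 * np.pi)
    sector1 = d_ang <= width
    sector2 = ((angles - phi0 - np.pi) % (2 * np.pi)) <= width
    sector2 &= ~sector1
    roi1 = np.zeros_like(pmap, dtype=bool)
    roi2 = np.zeros_like(pmap, dtype=bool)
    roi1[:, sector1] = True
    roi2[:, sector2] = True
    rois = PolarMapROIs(polar_map=pmap, roi_defect=roi1, roi_normal=roi2,
                        angles_rad=angles)
    rois.validate()
    return rois


def intensity_ratio(rois: PolarMapROIs) -> float:
    """Mean of the defect ROI divided by mean of the uniform normal ROI."""
    if rois.roi_defect is None or rois.roi_normal is None:
        raise ValueError("both ROIs are required")
    if not rois.roi_defect.any() or not rois.roi_normal.any():
        raise ValueError("empty ROI")
    normal = float(rois.polar_map[rois.roi_normal].mean())
    if normal <= 0:
        raise ValueError("normal ROI mean must be positive")
    return float(rois.polar_map[rois.roi_defect].mean()) / normal


def defect_extent_surrogate(pmap_or_rois, threshold_fraction: float = 0.6) -> float:
    """Percent of polar-map pixels below threshold x normal-region mean.

    A documented threshold-based stand-in for clinical perfusion-defect-size
    software (which is proprietary): when ROI information is available the
    normal reference is the ROI_2 mean, otherwise the mean of the
    above-median half of the map.  Returns percent of wall (%LV-like).
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    if isinstance(pmap_or_rois, PolarMapROIs):
        pmap = pmap_or_rois.polar_map
        if pmap_or_rois.roi_normal is not None and pmap_or_rois.roi_normal.any():
            normal = float(pmap[pmap_or_rois.roi_normal].mean())
        else:
            normal = float(pmap[pmap >= np.median(pmap)].mean())
    else:
        pmap = np.asarray(pmap_or_rois, dtype=np.float64)
        normal = float(pmap[pmap >= np.median(pmap)].mean())
    if normal <= 0:
        raise ValueError("normal reference must be positive")
    below = pmap < threshold_fraction * normal
    return 100.0 * float(below.mean())


# ---------------------------------------------------------------------------
# agreement / regression / testing

@dataclass
class BlandAltmanResult:
    mean_diff: float
    lower95: float
    upper95: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Limits of agreement: mean difference +/- 1.96 SD.

    Sign convention: differences are a - b (method minus reference when the
    reference is passed second).
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("equal-length 1D series required")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    diffs = a - b
    means = (a + b) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(md, md - 1.96 * sd, md + 1.96 * sd, means, diffs)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    hist2d: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def joint_regression(i_ft_voxels, i_d_voxels, bins: int = 64) -> RegressionResult:
    """OLS of method voxels on reference voxels plus their joint histogram.

    The reference goes on the x axis; R^2 is the squared Pearson
    correlation.
    """
    x = np.asarray(i_ft_voxels, dtype=np.float64).ravel()
    y = np.asarray(i_d_voxels, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("voxel series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined regression")
    res = stats.linregress(x, y)
    h, xe, ye = np.histogram2d(x, y, bins=bins)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), h, xe, ye)


def paired_test(metric_a, metric_b, n_comparisons: int = 1) -> float:
    """Two-tailed paired t-test with Bonferroni correction.

    Returns min(1, p * n_comparisons).  Zero-variance differences are
    degenerate: p = 1 when the series are identical, else 0 (reported with a
    warning).
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired equal-length samples required")
    d = a - b
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        warnings.warn("zero-variance paired differences; degenerate t-test",
                      RuntimeWarning)
        return 1.0 if np.allclose(d, 0.0) else 0.0
    p = float(stats.ttest_rel(a, b).pvalue)
    return min(1.0, p * n_comparisons)
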