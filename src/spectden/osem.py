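"""Ordered-subset expectation-maximization reconstruction.

OS-EM accelerates MLEM by cycling multiplicative EM updates over subsets of
the projection views:

    x <- x * A_s^T( y_s / (A_s x + eps) ) / (A_s^T 1 + eps)

with A the forward projector and A^T its exact adjoint.  The multiplicative
form preserves non-negativity at every sub-iteration, and with a single
subset the algorithm is plain MLEM.  Defaults follow the clinical protocol
this package emulates: 5 iterations with 4 subsets, and a 3D Gaussian
post-reconstruction filter of 0.6 voxel applied only to the full-time
reference images (denoised/fast reconstructions are left unfiltered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .projector import ParallelProjector, ProjectionStack

__all__ = ["ReconSettings", "ReconVolume", "osem_reconstruct", "gaussian_postfilter"]


@dataclass(frozen=True)
class ReconSettings:
    n_iterations: int = 5
    n_subsets: int = 4
    attenuation_on: bool = True
    postfilter_sigma_voxels: float = 0.0
    epsilon: float = 1e-12
    subset_order: tuple[int, ...] | None = None  # default 0..n_subsets-1

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be positive")
        if self.postfilter_sigma_voxels < 0:
            raise ValueError("postfilter sigma must be non-negative")


@dataclass
class ReconVolume:
    image: np.ndarray
    settings: ReconSettings
    voxel_size_cm: float
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self):
        return tuple(self.image.shape)


def _subsets(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """View i belongs to subset (i mod n_subsets)."""
    if n_views % n_subsets:
        raise ValueError(f"{n_views} views not divisible into {n_subsets} subsets")
    return [np.arange(n_views)[s::n_subsets] for s in range(n_subsets)]


def osem_reconstruct(
    stack: ProjectionStack,
    settings: ReconSettings,
    grid_shape: tuple[int, int, int] | None = None,
    voxel_size_cm: float = 0.6096,
    attenuation: np.ndarray | None = None,
    projector: ParallelProjector | None = None,
    iteration_callback=None,
) -> ReconVolume:
    """Reconstruct a projection stack.

    The reconstruction grid defaults to (n_u, n_u, n_v) — square in-plane
    matrix matching the detector.  ``iteration_callback(it, image)`` is
    invoked after every full iteration (used e.g. to track convergence).
    """
    y = np.asarray(stack.counts, dtype=np.float64)
    n_views, nu, nv = y.shape
    if projector is None:
        if grid_shape is None:
            grid_shape = (nu, nu, nv)
        mu = attenuation if settings.attenuation_on else None
        if attenuation is not None and not settings.attenuation_on:
            mu = None
        projector = ParallelProjector(grid_shape, voxel_size_cm,
                                      stack.angles_deg, attenuation=mu)
    grid_shape = projector.grid_shape
    eps = settings.epsilon

    subsets = _subsets(n_views, settings.n_subsets)
    order = settings.subset_order or tuple(range(settings.n_subsets))
    if sorted(order) != list(range(settings.n_subsets)):
        raise ValueError("subset_order must be a permutation of the subsets")
    sens = [projector.adjoint(np.ones((len(s), nu, nv)), view_idx=s) for s in subsets]

    x = np.ones(grid_shape)
    warned = False
    for it in range(settings.n_iterations):
        for s_id in order:
            s = subsets[s_id]
            fp = projector.forward(x, view_idx=s)
            if not warned and (fp <= 0).any() and (y[s] > 0).any():
                warnings.warn("zero bins in the forward projection denominator; "
                              f"stabilized with epsilon={eps:g}", RuntimeWarning)
                warned = True
            ratio = y[s] / (fp + eps)
            x = x * projector.adjoint(ratio, view_idx=s) / (sens[s_id] + eps)
        if iteration_callback is not None:
            iteration_callback(it, x.copy())

    vol = ReconVolume(
        image=x,
        settings=settings,
        voxel_size_cm=projector.voxel_size_cm,
        provenance=str(stack.meta.get("subject_index", "")),
        meta={"time_per_view_s": stack.time_per_view_s, **stack.meta},
    )
    if settings.postfilter_sigma_voxels > 0:
        vol = gaussian_postfilter(vol, settings.postfilter_sigma_voxels)
    return vol


def gaussian_postfilter(v: ReconVolume, sigma_voxels: float) -> ReconVolume:
    """Isotropic 3D Gaussian smoothing (reflect boundaries, count-preserving)."""
    if sigma_voxels < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_voxels == 0:
        return v
    img = ndimage.gaussian_filter(v.image, sigma=sigma_voxels, mode="reflect")
    return replace(v, image=img,
                   meta={**v.meta, "postfilter_sigma_voxels": float(sigma_voxels)})
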