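"""Parallel-beam projection, Poisson counting noise, and count thinning.

The forward model is rotation-based: for a view at angle theta the volume is
rotated in the transaxial (x, y) plane by bilinear interpolation and summed
along the +y axis toward an ideal planar detector; optional attenuation
weights exp(-integral mu dl) are applied per voxel before summation.  The
rotation and summation are realized as explicit ``scipy.sparse`` matrices, so
the backprojector used by OS-EM is the exact matrix transpose of the forward
projector and the pair passes an adjointness test to machine precision.

Acquisition-time reduction ("fast" scans) is modelled as binomial thinning of
the measured counts with p = t_target / t_full, which has the same marginal
statistics as truncating a list-mode acquisition after the corresponding
fraction of events: a thinned Poisson process is again Poisson with the
scaled mean.

Volume axes are (x, y, z); projection stacks are (n_views, n_u, n_v) with
u along the rotated x axis and v along z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import sparse

from .phantom import PhantomVolume

__all__ = [
    "AcquisitionSpec",
    "ProjectionStack",
    "ParallelProjector",
    "forward_project",
    "add_poisson",
    "thin_to_time",
    "rebin_projections",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner-side description of one acquisition protocol."""

    n_views: int = 60
    arc_deg: float = 180.0
    full_time_s: float = 10.0
    mean_counts_per_view_at_full_time: float = 2.0e4
    attenuation_on: bool = True
    detector_rebin: int = 1   # sum detector bins in blocks of this factor
    rng_seed: int = 0

    def __post_init__(self):
        if self.full_time_s <= 0:
            raise ValueError("full_time_s must be positive")
        if self.mean_counts_per_view_at_full_time <= 0:
            raise ValueError("mean counts per view must be positive")
        if self.n_views < 1:
            raise ValueError("need at least one view")

    @property
    def angles_deg(self) -> np.ndarray:
        return self.arc_deg * np.arange(self.n_views) / self.n_views


@dataclass
class ProjectionStack:
    """A stack of 2D projection views with acquisition metadata."""

    counts: np.ndarray           # (n_views, n_u, n_v)
    angles_deg: np.ndarray
    time_per_view_s: float
    is_noisy: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_views(self) -> int:
        return self.counts.shape[0]

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def validate(self) -> None:
        if self.counts.shape[0] != len(self.angles_deg):
            raise ValueError("one angle per view required")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.is_noisy and not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("noisy stacks must hold integer counts")


def _rotation_matrix_2d(n: int, theta_rad: float) -> sparse.csr_matrix:
    """Sparse bilinear in-plane rotation operator on flattened n x n slices.

    Inverse-mapping formulation: output pixel (xt, yt) samples the input at
    the back-rotated location.  Out-of-grid samples contribute zero.
    """
    c = (n - 1) / 2.0
    xt, yt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    xs = c + ct * (xt - c) - st * (yt - c)
    ys = c + st * (xt - c) + ct * (yt - c)
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    rows, cols, vals = [], [], []
    ridx = (xt * n + yt).ravel()
    for ddx, ddy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + ddx
        yi = y0 + ddy
        ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n) & (w.ravel().reshape(n, n) > 0)
        rows.append(ridx[ok.ravel()])
        cols.append((xi * n + yi)[ok].ravel())
        vals.append(w[ok].ravel())
    m = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    m.sum_duplicates()
    return m


class ParallelProjector:
    """Linear forward/backprojection operator for a fixed geometry.

    Supports view subsets (for ordered-subset reconstruction) and an exact
    adjoint.  Attenuation, when enabled, is folded into fixed per-view voxel
    weights computed once from the attenuation map, so the operator remains
    linear in the activity.
    """

    def __init__(self, grid_shape: tuple[int, int, int], voxel_size_cm: float,
                 angles_deg: np.ndarray, attenuation: np.ndarray | None = None):
        nx, ny, nz = grid_shape
        if nx != ny:
            raise ValueError("in-plane grid must be square")
        if attenuation is not None and tuple(attenuation.shape) != tuple(grid_shape):
            raise ValueError(
                f"attenuation shape {attenuation.shape} does not match grid {grid_shape}")
        self.grid_shape = tuple(grid_shape)
        self.voxel_size_cm = voxel_size_cm
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self._rot = [_rotation_matrix_2d(nx, np.deg2rad(a)) for a in self.angles_deg]
        self._weights: list[np.ndarray | None] = [None] * len(self._rot)
        if attenuation is not None:
            for i, R in enumerate(self._rot):
                mu_rot = self._apply_rot(R, attenuation)
                # path length of attenuating material between each voxel and
                # the detector at +y, with a half-voxel self-contribution
                path = (np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
                        - 0.5 * mu_rot) * voxel_size_cm
                self._weights[i] = np.exp(-path)

    def _apply_rot(self, R: sparse.csr_matrix, vol: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        return (R @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def _apply_rot_t(self, R: sparse.csr_matrix, vol: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        return (R.T @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    @property
    def n_views(self) -> int:
        return len(self._rot)

    def forward(self, vol: np.ndarray, view_idx=None) -> np.ndarray:
        """Project ``vol`` into (len(view_idx), n_u, n_v) line sums."""
        if tuple(vol.shape) != self.grid_shape:
            raise ValueError(f"volume shape {vol.shape} does not match grid {self.grid_shape}")
        idx = list(range(self.n_views)) if view_idx is None else list(view_idx)
        nx, ny, nz = self.grid_shape
        out = np.empty((len(idx), nx, nz))
        for j, i in enumerate(idx):
            r = self._apply_rot(self._rot[i], vol)
            if self._weights[i] is not None:
                r = r * self._weights[i]
            out[j] = r.sum(axis=1)
        return out

    def adjoint(self, proj: np.ndarray, view_idx=None) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        idx = list(range(self.n_views)) if view_idx is None else list(view_idx)
        if proj.shape[0] != len(idx):
            raise ValueError("projection stack does not match the view subset")
        nx, ny, nz = self.grid_shape
        out = np.zeros(self.grid_shape)
        for j, i in enumerate(idx):
            back = np.broadcast_to(proj[j][:, None, :], (nx, ny, nz)).copy()
            if self._weights[i] is not None:
                back *= self._weights[i]
            out += self._apply_rot_t(self._rot[i], back)
        return out


def forward_project(p: PhantomVolume, spec: AcquisitionSpec) -> ProjectionStack:
    """Noiseless full-time projection stack of a phantom.

    The stack is scaled so that the mean counts per view equals
    ``spec.mean_counts_per_view_at_full_time`` (a detector-sensitivity /
    injected-dose calibration), then optionally rebinned to a coarser
    detector.
    """
    proj = ParallelProjector(
        p.grid_shape, p.voxel_size_cm, spec.angles_deg,
        attenuation=p.attenuation if spec.attenuation_on else None,
    )
    raw = proj.forward(p.activity)
    total = raw.sum()
    if total <= 0:
        scale = 0.0
    else:
        scale = spec.mean_counts_per_view_at_full_time * spec.n_views / total
    stack = ProjectionStack(
        counts=raw * scale,
        angles_deg=spec.angles_deg,
        time_per_view_s=spec.full_time_s,
        is_noisy=False,
        meta={"subject_index": p.subject_index, "count_scale": float(scale),
              "attenuation_on": spec.attenuation_on},
    )
    if spec.detector_rebin > 1:
        stack = rebin_projections(stack, spec.detector_rebin)
    return stack


def rebin_projections(stack: ProjectionStack, factor: int) -> ProjectionStack:
    """Sum detector bins in ``factor`` x ``factor`` blocks (coarser detector).

    Summing preserves total counts and, applied to Poisson data, yields
    Poisson data again.
    """
    v, nu, nv = stack.counts.shape
    if nu % factor or nv % factor:
        raise ValueError(f"detector {nu}x{nv} not divisible by rebin factor {factor}")
    c = stack.counts.reshape(v, nu // factor, factor, nv // factor, factor).sum(axis=(2, 4))
    return replace(stack, counts=c, meta={**stack.meta, "detector_rebin": factor})


def add_poisson(stack: ProjectionStack, seed: int) -> ProjectionStack:
    """Independent Poisson draw per bin with the noiseless bin value as mean."""
    if stack.is_noisy:
        raise ValueError("stack is already noisy")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(stack.counts).astype(np.int64)
    return replace(stack, counts=counts, is_noisy=True,
                   meta={**stack.meta, "poisson_seed": np.asarray(seed).tolist()})


def thin_to_time(stack: ProjectionStack, target_time_s: float, seed: int) -> ProjectionStack:
    """Binomial thinning to a shorter acquisition time per view.

    Each bin count n is replaced by Binomial(n, p) with
    p = target_time / time_per_view; statistically an exact sub-acquisition
    of the underlying Poisson process.
    """
    if not stack.is_noisy:
        raise ValueError("thinning requires a noisy (integer-count) stack")
    if not np.allclose(stack.counts, np.round(stack.counts)):
        raise ValueError("thinning requires integer counts")
    p = target_time_s / stack.time_per_view_s
    if not (0.0 < p <= 1.0):
        raise ValueError(f"target time {target_time_s}s outside (0, {stack.time_per_view_s}]s")
    if p == 1.0:
        return replace(stack, meta={**stack.meta, "thin_p": 1.0})
    rng = np.random.default_rng(seed)
    counts = rng.binomial(stack.counts.astype(np.int64), p)
    return replace(stack, counts=counts, time_per_view_s=target_time_s,
                   meta={**stack.meta, "thin_p": float(p),
                         "thin_seed": np.asarray(seed).tolist()})


# ---------------------------------------------------------------------------
# I/O: npz archive + JSON sidecar

def save_stack(stack: ProjectionStack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, counts=stack.counts, angles_deg=stack.angles_deg)
    sidecar = {
        "time_per_view_s": stack.time_per_view_s,
        "is_noisy": stack.is_noisy,
        "meta": stack.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_stack(path: str | Path) -> ProjectionStack:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    info = json.loads(path.with_suffix(".json").read_text())
    stack = ProjectionStack(
        counts=arrays["counts"],
        angles_deg=arrays["angles_deg"],
        time_per_view_s=float(info["time_per_view_s"]),
        is_noisy=bool(info["is_noisy"]),
        meta=info.get("meta", {}),
    )
    stack.validate()
    return stack
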