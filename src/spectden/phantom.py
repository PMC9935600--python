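"""Synthetic cardiac phantom cohort.

Generates paired activity / attenuation volumes that stand in for a clinical
myocardial-perfusion SPECT cohort: a truncated ellipsoidal left-ventricular
shell with uniform tracer uptake, an optional hypo-perfused sector (the
"defect"), a low uniform soft-tissue background, and a body/lung attenuation
map.  Every subject is a pure function of ``(spec, rng_seed, subject_index)``
so cohorts are bitwise reproducible.

Axis convention: volumes are indexed ``(x, y, z)`` with the LV long axis along
``z``.  Geometry parameters are in centimetres so the same cohort description
scales to any grid/voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CohortSpec",
    "PhantomVolume",
    "make_phantom",
    "defect_extent",
    "save_phantom",
    "load_phantom",
]

#: linear attenuation coefficients at 140 keV, cm^-1
MU_SOFT_TISSUE = 0.15
MU_LUNG = 0.04


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic cohort.

    All intervals are sampled uniformly per subject.  Defaults give a cohort
    whose defect prevalence matches the 36% of the emulated clinical
    population, with defect sizes spanning a few percent to roughly a third
    of the LV wall.
    """

    n_subjects: int = 50
    defect_fraction: float = 0.36
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size_cm: float = 0.6096
    # LV geometry (cm): outer short-axis radius, long semi-axis factor, wall
    lv_outer_radius_cm: tuple[float, float] = (2.8, 3.4)
    lv_long_axis_factor: tuple[float, float] = (1.3, 1.5)
    wall_thickness_cm: tuple[float, float] = (0.9, 1.3)
    center_jitter_cm: float = 0.9
    # defect model
    defect_extent_frac: tuple[float, float] = (0.05, 0.30)
    defect_severity: tuple[float, float] = (0.3, 0.8)
    # uptake
    background_ratio: float = 0.15
    myocardium_uptake: float = 1.0
    liver_insert: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.defect_fraction <= 1.0):
            raise ValueError("defect_fraction must lie in [0, 1]")
        if min(self.grid_shape) < 16:
            raise ValueError(f"grid {self.grid_shape} too small; need >= 16 per axis")
        for lo, hi in (self.defect_extent_frac, self.defect_severity,
                       self.lv_outer_radius_cm, self.wall_thickness_cm,
                       self.lv_long_axis_factor):
            if not (lo <= hi):
                raise ValueError(f"empty interval ({lo}, {hi})")
        if not (0.0 <= self.defect_severity[0] and self.defect_severity[1] <= 1.0):
            raise ValueError("defect severity must lie in [0, 1]")
        if self.voxel_size_cm <= 0:
            raise ValueError("voxel_size_cm must be positive")


@dataclass
class PhantomVolume:
    """One synthetic subject: activity, attenuation and ground truth.

    ``defect_label`` is the binary flag later embedded into the network input
    (0 = without defect, 1 = with defect); it is 1 exactly when
    ``defect_mask`` is non-empty.
    """

    activity: np.ndarray          # relative counts/voxel, >= 0
    attenuation: np.ndarray       # cm^-1, >= 0
    defect_mask: np.ndarray       # bool, subset of the myocardium
    myocardium_mask: np.ndarray   # bool
    defect_label: int
    voxel_size_cm: float
    subject_index: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.activity.shape)

    @property
    def lv_center(self) -> tuple[float, float, float]:
        """Centroid of the myocardium support, in voxel coordinates."""
        idx = np.argwhere(self.myocardium_mask)
        return tuple(idx.mean(axis=0))

    def validate(self) -> None:
        if self.activity.shape != self.attenuation.shape != self.defect_mask.shape:
            raise ValueError("activity/attenuation/defect_mask shapes differ")
        if (self.activity < 0).any() or (self.attenuation < 0).any():
            raise ValueError("activity and attenuation must be non-negative")
        if self.defect_label != int(self.defect_mask.any()):
            raise ValueError("defect_label inconsistent with defect_mask")
        if (self.defect_mask & ~self.myocardium_mask).any():
            raise ValueError("defect_mask extends outside the myocardium")


def _ellipsoid(coords, center, semi):
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_phantom(spec: CohortSpec, subject_index: int) -> PhantomVolume:
    """Realize subject ``subject_index`` of the cohort described by ``spec``.

    Deterministic: the per-subject RNG is seeded with
    ``(spec.rng_seed, subject_index)``, so regenerating any subject gives a
    bitwise identical volume regardless of generation order.
    """
    if not (0 <= subject_index < spec.n_subjects):
        raise ValueError(f"subject_index {subject_index} outside cohort of {spec.n_subjects}")
    rng = np.random.default_rng([spec.rng_seed, subject_index])
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_cm
    x, y, z = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) * vs,
        (np.arange(ny) - (ny - 1) / 2) * vs,
        (np.arange(nz) - (nz - 1) / 2) * vs,
        indexing="ij",
    )

    # --- LV shell geometry -------------------------------------------------
    a = rng.uniform(*spec.lv_outer_radius_cm)
    b = a * rng.uniform(*spec.lv_long_axis_factor)
    t = rng.uniform(*spec.wall_thickness_cm)
    t = min(t, 0.8 * a)  # keep a cavity
    jit = spec.center_jitter_cm
    center = rng.uniform(-jit, jit, size=3)
    # keep the heart inside the axial FOV
    center[2] = np.clip(center[2], -(nz * vs / 2 - b) , (nz * vs / 2 - b))

    outer = _ellipsoid((x, y, z), center, (a, a, b))
    inner = _ellipsoid((x, y, z), center, (a - t, a - t, b - t))
    # basal truncation: open the shell above half the long semi-axis
    wall = outer & ~inner & ((z - center[2]) < 0.55 * b)
    if not wall.any():
        raise RuntimeError("degenerate geometry produced an empty myocardium")

    # --- defect ------------------------------------------------------------
    has_defect = rng.random() < spec.defect_fraction
    severity = rng.uniform(*spec.defect_severity)
    extent = rng.uniform(*spec.defect_extent_frac)
    phi0 = rng.uniform(0.0, 2 * np.pi)
    defect = np.zeros_like(wall)
    if has_defect:
        phi = np.arctan2(y - center[1], x - center[0])
        dphi = (phi - phi0) % (2 * np.pi)
        defect = wall & (dphi <= extent * 2 * np.pi)

    # --- activity ----------------------------------------------------------
    body = _ellipsoid((x, y, z), (0.0, 0.0, 0.0),
                      (0.45 * nx * vs, 0.38 * ny * vs, nz * vs))
    activity = np.where(body, spec.background_ratio * spec.myocardium_uptake, 0.0)
    activity[wall] = spec.myocardium_uptake
    activity[defect] = spec.myocardium_uptake * (1.0 - severity)
    if spec.liver_insert:
        liver = _ellipsoid((x, y, z), (0.30 * nx * vs, 0.12 * ny * vs, -0.15 * nz * vs),
                           (0.18 * nx * vs, 0.15 * ny * vs, 0.35 * nz * vs)) & body
        activity[liver & ~wall] = 0.6 * spec.myocardium_uptake

    # --- attenuation -------------------------------------------------------
    mu = np.where(body, MU_SOFT_TISSUE, 0.0)
    for side in (-1.0, 1.0):
        lung = _ellipsoid((x, y, z), (side * 0.24 * nx * vs, -0.10 * ny * vs, 0.0),
                          (0.13 * nx * vs, 0.20 * ny * vs, 0.45 * nz * vs)) & body & ~outer
        mu[lung] = MU_LUNG

    label = int(defect.any())
    vol = PhantomVolume(
        activity=activity,
        attenuation=mu,
        defect_mask=defect,
        myocardium_mask=wall,
        defect_label=label,
        voxel_size_cm=vs,
        subject_index=subject_index,
        meta={
            "seed": spec.rng_seed,
            "lv_outer_radius_cm": float(a),
            "lv_long_semi_axis_cm": float(b),
            "wall_thickness_cm": float(t),
            "center_cm": [float(c) for c in center],
            "severity": float(severity) if label else 0.0,
            "defect_phi0": float(phi0),
        },
    )
    vol.validate()
    return vol


def defect_extent(p: PhantomVolume) -> float:
    """Ground-truth defect extent, percent of the LV wall (%LV)."""
    n_wall = int(p.myocardium_mask.sum())
    if n_wall == 0:
        raise ValueError("phantom has an empty myocardium")
    return 100.0 * float(p.defect_mask.sum()) / n_wall


# ---------------------------------------------------------------------------
# I/O: NIfTI pair + JSON sidecar

def save_phantom(p: PhantomVolume, out_dir: str | Path, stem: str | None = None) -> Path:
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"subject{p.subject_index:03d}"
    affine = np.diag([p.voxel_size_cm * 10, p.voxel_size_cm * 10, p.voxel_size_cm * 10, 1.0])
    nib.save(nib.Nifti1Image(p.activity.astype(np.float32), affine), out_dir / f"{stem}_act.nii")
    nib.save(nib.Nifti1Image(p.attenuation.astype(np.float32), affine), out_dir / f"{stem}_mu.nii")
    nib.save(nib.Nifti1Image(p.defect_mask.astype(np.uint8), affine), out_dir / f"{stem}_defect.nii")
    nib.save(nib.Nifti1Image(p.myocardium_mask.astype(np.uint8), affine), out_dir / f"{stem}_myo.nii")
    sidecar = {
        "defect_label": p.defect_label,
        "defect_extent_pct": defect_extent(p),
        "voxel_size_cm": p.voxel_size_cm,
        "subject_index": p.subject_index,
        "meta": p.meta,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / f"{stem}.json"


def load_phantom(sidecar_path: str | Path) -> PhantomVolume:
    import nibabel as nib

    sidecar_path = Path(sidecar_path)
    info = json.loads(sidecar_path.read_text())
    stem = sidecar_path.stem
    d = sidecar_path.parent

    def _load(suffix):
        return np.asarray(nib.load(d / f"{stem}_{suffix}.nii").dataobj)

    vol = PhantomVolume(
        activity=_load("act").astype(np.float64),
        attenuation=_load("mu").astype(np.float64),
        defect_mask=_load("defect").astype(bool),
        myocardium_mask=_load("myo").astype(bool),
        defect_label=int(info["defect_label"]),
        voxel_size_cm=float(info["voxel_size_cm"]),
        subject_index=int(info["subject_index"]),
        meta=info.get("meta", {}),
    )
    vol.validate()
    return vol


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
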