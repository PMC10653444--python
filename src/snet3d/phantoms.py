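"""Synthetic 3D phantoms for thin-structure segmentation.

Two geometries are produced, each mimicking a class of cardiovascular
targets that conventional encoder–decoder networks under-segment:

* **shells** — closed ellipsoidal bands of controllable wall thickness
  (1–4 voxels), the analog of a thin cardiac wall;
* **tube trees** — branching capsule trees whose radii decay towards a
  single voxel, optionally carrying a spherical sac, the analog of
  intracranial vasculature with an aneurysm.

Every phantom is a pure function of ``(spec, shape, model, seed)``: the same
inputs always produce bitwise-identical volumes, which is what makes the
end-to-end pipeline reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ShellSpec", "TubeTreeSpec", "IntensityModel", "PhantomCase",
    "GeometryError", "make_shell_phantom", "make_tube_phantom",
    "make_dataset", "load_manifest",
]


class GeometryError(ValueError):
    """A requested structure does not fit in the volume."""


@dataclass(frozen=True)
class ShellSpec:
    """Ellipsoidal band: voxels whose normalized ellipsoidal radius
    rho(x) lies within t/(2*rbar) of 1, rbar the geometric-mean semi-axis."""
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    wall_thickness: float
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (min(self.semi_axes) > self.wall_thickness > 0):
            raise ValueError("need semi_axes > wall_thickness > 0")


@dataclass(frozen=True)
class TubeTreeSpec:
    """Branching capsule tree; radius at generation g is
    root_radius * radius_decay**g, and branching stops below 0.5 voxel."""
    root: tuple[float, float, float]
    root_radius: float
    branch_factor: int = 2
    depth: int = 3
    radius_decay: float = 0.7
    segment_length: float = 14.0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    branch_angle: float = 0.6  # radians, mean deviation of children from parent
    aneurysm: tuple[int, float] | None = None  # (node index, sac radius)

    def __post_init__(self):
        if self.root_radius < 0.5:
            raise ValueError("root_radius below the 0.5-voxel resolvable limit")
        if not (0.0 < self.radius_decay < 1.0):
            raise ValueError("radius_decay must lie in (0, 1)")


@dataclass(frozen=True)
class IntensityModel:
    fg_mean: float = 1.0
    bg_mean: float = 0.0
    noise_sd: float = 0.1
    bias_amplitude: float = 0.2
    bias_scale: float = 32.0  # voxels, characteristic wavelength of the bias

    def __post_init__(self):
        if self.fg_mean == self.bg_mean:
            raise ValueError("foreground and background means must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomCase:
    volume: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    seed: int
    spec: ShellSpec | TubeTreeSpec

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _grid(shape):
    return np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                       indexing="ij")


def _bias_field(shape, model: IntensityModel, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative-style inhomogeneity: mean of 3 seeded
    low-frequency cosine products, scaled by ``bias_amplitude``."""
    if model.bias_amplitude == 0:
        return np.zeros(shape, dtype=np.float64)
    zz, yy, xx = _grid(shape)
    out = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        freqs = rng.uniform(0.3, 1.2, size=3) / model.bias_scale
        phases = rng.uniform(0, 2 * np.pi, size=3)
        out += (np.cos(2 * np.pi * freqs[0] * zz + phases[0])
                * np.cos(2 * np.pi * freqs[1] * yy + phases[1])
                * np.cos(2 * np.pi * freqs[2] * xx + phases[2]))
    return model.bias_amplitude * out / 3.0


def _render(mask: np.ndarray, model: IntensityModel,
            rng: np.random.Generator) -> np.ndarray:
    vol = model.bg_mean + (model.fg_mean - model.bg_mean) * mask.astype(np.float64)
    vol += _bias_field(mask.shape, model, rng)
    if model.noise_sd > 0:
        vol += rng.normal(0.0, model.noise_sd, size=mask.shape)
    return vol.astype(np.float32)


def shell_band_indicator(spec: ShellSpec, points: np.ndarray) -> np.ndarray:
    """Band membership for an (..., 3) array of voxel coordinates."""
    rot = Rotation.from_euler("zyx", spec.orientation).as_matrix()
    local = (points - np.asarray(spec.center)) @ rot  # world -> ellipsoid frame
    rho = np.sqrt(((local / np.asarray(spec.semi_axes)) ** 2).sum(axis=-1))
    rbar = float(np.prod(spec.semi_axes)) ** (1.0 / 3.0)
    half_band = spec.wall_thickness / (2.0 * rbar)
    return np.abs(rho - 1.0) <= half_band


def make_shell_phantom(spec: ShellSpec, shape: tuple[int, int, int],
                       model: IntensityModel, seed: int,
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                       ) -> PhantomCase:
    """Render an ellipsoidal-shell phantom with bias field and noise."""
    shape = tuple(int(n) for n in shape)
    rbar = float(np.prod(spec.semi_axes)) ** (1.0 / 3.0)
    outer = max(spec.semi_axes) * (1.0 + spec.wall_thickness / (2.0 * rbar))
    lo = np.asarray(spec.center) - outer
    hi = np.asarray(spec.center) + outer
    if (lo < 2).any() or (hi > np.asarray(shape) - 3).any():
        raise GeometryError(
            f"shell of outer radius {outer:.1f} at {spec.center} exceeds "
            f"shape {shape} minus the 2-voxel margin")
    zz, yy, xx = _grid(shape)
    pts = np.stack([zz, yy, xx], axis=-1)
    mask = shell_band_indicator(spec, pts).astype(np.uint8)
    rng = np.random.default_rng(seed)
    return PhantomCase(_render(mask, model, rng), mask, tuple(spacing), seed, spec)


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _tree_segments(spec: TubeTreeSpec, rng: np.random.Generator):
    """Grow the capsule tree; returns (segments, nodes) where each segment is
    (start, end, radius) and nodes are the branch points (node 0 = root)."""
    d0 = np.asarray(spec.direction, dtype=np.float64)
    d0 /= np.linalg.norm(d0)
    segments, nodes = [], [np.asarray(spec.root, dtype=np.float64)]
    tips = [(nodes[0], d0)]
    for g in range(spec.depth + 1):
        radius = spec.root_radius * spec.radius_decay ** g
        if radius < 0.5:
            break  # sub-resolution: stop branching, not an error
        new_tips = []
        for start, d in tips:
            end = start + d * spec.segment_length
            segments.append((start, end, radius))
            nodes.append(end)
            if g < spec.depth:
                u, v = _orthonormal_frame(d)
                for _ in range(spec.branch_factor):
                    theta = rng.normal(spec.branch_angle, 0.15 * spec.branch_angle)
                    phi = rng.uniform(0, 2 * np.pi)
                    child = (np.cos(theta) * d
                             + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v))
                    new_tips.append((end, child / np.linalg.norm(child)))
        tips = new_tips
    return segments, nodes


def _paint_capsule(mask: np.ndarray, start, end, radius) -> bool:
    """Set voxels within ``radius`` of the segment; returns True if clipped.

    Voxels traced along the centerline are always included so that
    sub-voxel radii still yield a 26-connected tube.
    """
    shape = np.asarray(mask.shape)
    lo = np.floor(np.minimum(start, end) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(start, end) + radius + 2).astype(int)
    clipped = bool((lo < 0).any() or (hi > shape).any())
    lo = np.clip(lo, 0, shape)
    hi = np.clip(hi, 0, shape)
    if (hi <= lo).any():
        return clipped
    sub = np.meshgrid(*[np.arange(a, b, dtype=np.float64)
                        for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack(sub, axis=-1)
    ab = np.asarray(end) - np.asarray(start)
    denom = float(ab @ ab)
    t = np.clip(((pts - start) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = np.asarray(start) + np.multiply.outer(t, ab)
    dist = np.linalg.norm(pts - closest, axis=-1)
    region = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region |= (dist <= radius)
    # centerline trace (guarantees connectivity for thin tubes)
    n_steps = max(2, int(np.ceil(np.linalg.norm(ab) * 2)))
    line = np.asarray(start) + np.linspace(0, 1, n_steps)[:, None] * ab
    idx = np.round(line).astype(int)
    keep = ((idx >= 0) & (idx < shape)).all(axis=1)
    idx = idx[keep]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return clipped or not keep.all()


def make_tube_phantom(spec: TubeTreeSpec, shape: tuple[int, int, int],
                      model: IntensityModel, seed: int,
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                      ) -> PhantomCase:
    """Render a branching-tube phantom (optionally with an aneurysm sac)."""
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    segments, nodes = _tree_segments(spec, rng)
    mask = np.zeros(shape, dtype=bool)
    clipped = False
    for start, end, radius in segments:
        clipped |= _paint_capsule(mask, start, end, radius)
    if spec.aneurysm is not None:
        node_idx, sac_radius = spec.aneurysm
        if not 0 <= node_idx < len(nodes):
            raise GeometryError(f"aneurysm node index {node_idx} out of range "
                                f"(tree has {len(nodes)} nodes)")
        center = nodes[node_idx]
        clipped |= _paint_capsule(mask, center, center, sac_radius)
    if clipped:
        warnings.warn("tube tree exceeded the volume bounds and was clipped",
                      stacklevel=2)
    mask = mask.astype(np.uint8)
    return PhantomCase(_render(mask, model, rng), mask, tuple(spacing), seed, spec)


# -- datasets on disk --------------------------------------------------------

_GEOMETRIES = {"shell", "tube"}

#: parameter intervals sampled per case (values drawn uniformly)
DEFAULT_SHELL_RANGES = {
    "semi_axes": (10.0, 20.0),
    "wall_thickness": (2.0, 2.0),
    "center_jitter": 4.0,
}
DEFAULT_TUBE_RANGES = {
    "root_radius": (2.5, 4.0),
    "radius_decay": (0.6, 0.75),
    "segment_length": (10.0, 16.0),
    "depth": 3,
    "branch_factor": 2,
    "aneurysm_prob": 0.5,
    "sac_radius": (4.0, 6.0),
}


def _case_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sample_shell_spec(ranges: dict, shape, rng: np.random.Generator) -> ShellSpec:
    r = {**DEFAULT_SHELL_RANGES, **ranges}
    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(
        -r["center_jitter"], r["center_jitter"], size=3)
    t = rng.uniform(*np.atleast_1d(r["wall_thickness"])[[0, -1]])
    # cap the semi-axes so the shell plus margin always fits the volume
    sa_lo, sa_hi = r["semi_axes"]
    sa_cap = (min(shape) - 1) / 2.0 - r["center_jitter"] - t - 4.0
    sa_hi = min(sa_hi, sa_cap)
    sa_lo = min(sa_lo, sa_hi - 1e-6)
    axes = tuple(rng.uniform(sa_lo, sa_hi, size=3))
    orient = tuple(rng.uniform(0, np.pi, size=3))
    return ShellSpec(tuple(center), axes, float(t), orient)


def _sample_tube_spec(ranges: dict, shape, rng: np.random.Generator) -> TubeTreeSpec:
    r = {**DEFAULT_TUBE_RANGES, **ranges}
    root = (float(shape[0] * 0.12),
            shape[1] / 2.0 + rng.uniform(-4, 4),
            shape[2] / 2.0 + rng.uniform(-4, 4))
    direction = np.array([1.0, rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)])
    aneurysm = None
    if rng.random() < r["aneurysm_prob"]:
        aneurysm = (1, float(rng.uniform(*r["sac_radius"])))
    return TubeTreeSpec(
        root=root,
        root_radius=float(rng.uniform(*r["root_radius"])),
        branch_factor=int(r["branch_factor"]),
        depth=int(r["depth"]),
        radius_decay=float(rng.uniform(*r["radius_decay"])),
        segment_length=float(rng.uniform(*r["segment_length"])),
        direction=tuple(direction / np.linalg.norm(direction)),
        aneurysm=aneurysm,
    )


def _spec_to_json(spec) -> dict:
    d = dataclasses.asdict(spec)
    d["kind"] = type(spec).__name__
    return d


def _spec_from_json(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    cls = {"ShellSpec": ShellSpec, "TubeTreeSpec": TubeTreeSpec}[kind]
    for key, val in d.items():
        if isinstance(val, list):
            d[key] = tuple(val)
    return cls(**d)


def save_nifti(path: Path, array: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def make_dataset(n_cases: int, geometry: str, spec_ranges: dict | None,
                 shape: tuple[int, int, int], seed: int, out_dir,
                 model: IntensityModel | None = None,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> dict:
    """Write ``n_cases`` image/mask NIfTI pairs plus a JSON manifest.

    Per-case seeds are derived deterministically from the master seed, so a
    re-run with the same arguments overwrites the files with identical
    content.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if geometry not in _GEOMETRIES:
        raise ValueError(f"geometry must be one of {sorted(_GEOMETRIES)}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    model = model or IntensityModel()
    spec_ranges = spec_ranges or {}
    cases = []
    for i in range(n_cases):
        case_seed = _case_seed(seed, i)
        spec_rng = np.random.default_rng(case_seed)
        if geometry == "shell":
            spec = _sample_shell_spec(spec_ranges, shape, spec_rng)
            case = make_shell_phantom(spec, shape, model, case_seed, spacing)
        else:
            spec = _sample_tube_spec(spec_ranges, shape, spec_rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clipping is acceptable here
                case = make_tube_phantom(spec, shape, model, case_seed, spacing)
        img_path = out_dir / f"case_{i:03d}_image.nii.gz"
        mask_path = out_dir / f"case_{i:03d}_mask.nii.gz"
        save_nifti(img_path, case.volume, spacing)
        save_nifti(mask_path, case.mask, spacing)
        cases.append({
            "case": f"case_{i:03d}",
            "image": img_path.name,
            "mask": mask_path.name,
            "seed": case_seed,
            "spacing": list(spacing),
            "spec": _spec_to_json(spec),
        })
    manifest = {
        "geometry": geometry,
        "shape": list(shape),
        "master_seed": int(seed),
        "intensity_model": dataclasses.asdict(model),
        "cases": cases,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(path) -> dict:
    """Load a dataset manifest; ``spec`` entries come back as dataclasses."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        manifest = json.load(fh)
    for case in manifest["cases"]:
        case["spec"] = _spec_from_json(case["spec"])
    manifest["root"] = str(path.parent)
    return manifest
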