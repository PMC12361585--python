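"""Synthetic thoracic CT phantoms with ground-truth lesion instances.

The generator emulates the heterogeneity of a multicenter lung-cancer CT
cohort at desk scale: anisotropic voxel spacing, variable fields of view,
a median of two lesions per scan with diameters in the 10-26 mm regime,
and lesions in three anatomical situations (fully intrapulmonary,
wall-attached straddling the pleural boundary, and extrapulmonary).

Geometry is piecewise-constant HU on simple shapes:

* air background        -1000 HU
* body ellipsoid            0 HU
* two lung ellipsoids    -800 HU
* lesions                 +20 HU (ellipsoids, optionally lobulated unions)

Two kinds of *distractor* structures are planted to give downstream
false-positive sources with a ground-truth excuse: vessel-like tubes
inside the lungs (same HU as lesions, but thin and elongated) and
nodule-in-fat pockets outside the lungs (a +20 HU core inside a -100 HU
fat ellipsoid).  Distractors are never part of the ground-truth lesion
mask.

Everything is deterministic under the spec's seed, bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CtVolume, InstanceMask

__all__ = [
    "PhantomSpec",
    "LesionMeta",
    "DistractorMeta",
    "PhantomCase",
    "PlacementError",
    "generate_phantom",
    "generate_cohort",
    "reference_lung_masker",
]

HU_AIR = -1000.0
HU_BODY = 0.0
HU_LUNG = -800.0
HU_LESION = 20.0
HU_FAT = -100.0

#: per-case lesion-count distribution used by generate_cohort (median 2,
#: matching the cohort regime of ~2 lesions per CT scan)
LESION_COUNT_VALUES = (1, 2, 3, 4, 5)
LESION_COUNT_PROBS = (0.30, 0.35, 0.20, 0.10, 0.05)

_MAX_PLACEMENT_TRIES = 300


def sample_lesion_count(rng: np.random.Generator) -> int:
    """Draw a per-case lesion count (median 2 across a cohort)."""
    return int(rng.choice(LESION_COUNT_VALUES, p=LESION_COUNT_PROBS))


class PlacementError(RuntimeError):
    """A lesion or distractor could not be placed after bounded retries."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic thoracic CT case."""

    shape: tuple[int, int, int] = (80, 80, 56)
    spacing: tuple[float, float, float] = (2.8, 2.0, 2.3)
    n_lesions: int = 2
    lesion_diameter_range: tuple[float, float] = (10.0, 26.0)
    #: fraction of *fully* extrapulmonary true lesions.  Default 0: lung
    #: lesions are intrapulmonary or wall-attached; fully extrapulmonary
    #: structures appear as distractors, not ground truth.  Non-zero values
    #: exist to exercise the extrapulmonary code paths in isolation.
    p_extrapulmonary: float = 0.0
    p_wall_attached: float = 0.2
    noise_sd: float = 10.0
    seed: int = 0
    #: vessel-like intrapulmonary tubes (candidate false positives)
    n_tube_distractors: int = 2
    #: nodule-in-fat extrapulmonary pockets (candidate false positives)
    n_extra_distractors: int = 1
    p_lobulated: float = 0.3

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.lesion_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_diameter_range must satisfy 0 < min <= max")
        if lo < 2.0 * max(self.spacing):
            raise ValueError(
                "minimum lesion diameter must be >= 2 x max(spacing) so every "
                f"lesion spans >= 2 voxels per axis; got {lo} < {2.0 * max(self.spacing)}"
            )
        for p in (self.p_extrapulmonary, self.p_wall_attached):
            if not 0.0 <= p <= 1.0:
                raise ValueError("location probabilities must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class LesionMeta:
    label: int
    center_mm: tuple[float, float, float]
    diameter_mm: float
    location: str  # intrapulmonary | wall | extrapulmonary


@dataclasses.dataclass(frozen=True)
class DistractorMeta:
    kind: str  # tube | extrapulmonary_nodule
    center_mm: tuple[float, float, float]


@dataclasses.dataclass
class PhantomCase:
    ct: CtVolume
    gt_lesions: InstanceMask
    lung_mask: BinaryMask
    lesions: list[LesionMeta]
    distractors: list[DistractorMeta]
    spec: PhantomSpec

    def to_manifest_entry(self) -> dict:
        return {
            "seed": self.spec.seed,
            "shape": list(self.spec.shape),
            "spacing": list(self.spec.spacing),
            "lesions": [dataclasses.asdict(m) for m in self.lesions],
            "distractors": [dataclasses.asdict(d) for d in self.distractors],
        }


class _Canvas:
    """Scratch grids for one phantom under construction."""

    def __init__(self, spec: PhantomSpec):
        nx, ny, nz = spec.shape
        sx, sy, sz = spec.spacing
        self.spec = spec
        # voxel-center physical coordinates
        self.xs = (np.arange(nx) * sx).astype(np.float64)
        self.ys = (np.arange(ny) * sy).astype(np.float64)
        self.zs = (np.arange(nz) * sz).astype(np.float64)
        self.fov = (nx * sx, ny * sy, nz * sz)
        self.hu = np.full(spec.shape, HU_AIR, dtype=np.float32)
        self.lesion_labels = np.zeros(spec.shape, dtype=np.uint16)

    def ellipsoid(self, center, semi) -> np.ndarray:
        cx, cy, cz = center
        a, b, c = semi
        dx = ((self.xs - cx) / a) ** 2
        dy = ((self.ys - cy) / b) ** 2
        dz = ((self.zs - cz) / c) ** 2
        return dx[:, None, None] + dy[None, :, None] + dz[None, None, :] <= 1.0

    def capsule(self, p0, p1, radius) -> np.ndarray:
        """Voxels within *radius* mm of the segment p0-p1 (vessel-like tube)."""
        X, Y, Z = np.meshgrid(self.xs, self.ys, self.zs, indexing="ij")
        p = np.stack([X, Y, Z], axis=-1)
        p0 = np.asarray(p0, dtype=np.float64)
        d = np.asarray(p1, dtype=np.float64) - p0
        denom = float(d @ d)
        t = ((p - p0) @ d) / denom if denom > 0 else np.zeros(p.shape[:-1])
        t = np.clip(t, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist2 = ((p - closest) ** 2).sum(axis=-1)
        return dist2 <= radius * radius


def _lesion_support(canvas: _Canvas, rng: np.random.Generator, center, diameter: float,
                    lobulated: bool) -> np.ndarray:
    """Rasterize one lesion: an ellipsoid, or a union of overlapping lobes.

    The largest in-plane semi-axis equals diameter/2 so the recorded diameter
    tracks the axial Feret diameter of the voxelized support.
    """
    a = diameter / 2.0
    b = a * rng.uniform(0.75, 1.0)
    c = a * rng.uniform(0.65, 1.0)
    support = canvas.ellipsoid(center, (a, b, c))
    if lobulated:
        for _ in range(rng.integers(1, 4)):
            # lobes stay inside the primary envelope so diameter is preserved
            frac = rng.uniform(0.35, 0.55)
            off = rng.uniform(-0.4, 0.4, size=3) * np.array([a, b, c])
            lobe_semi = (frac * a, frac * b, frac * c)
            support |= canvas.ellipsoid(np.asarray(center) + off, lobe_semi)
    return support


def _is_single_component(mask: np.ndarray) -> bool:
    if not mask.any():
        return False
    _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return n == 1


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one phantom case; identical spec (incl. seed) gives bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    canvas = _Canvas(spec)
    FX, FY, FZ = canvas.fov
    center = np.array([FX / 2.0, FY / 2.0, FZ / 2.0])

    body_semi = np.array([0.46 * FX, 0.43 * FY, 0.58 * FZ])
    body = canvas.ellipsoid(center, body_semi)
    canvas.hu[body] = HU_BODY

    lung_semi = np.array([0.15 * FX, 0.26 * FY, 0.36 * FZ])
    lung_offsets = ((-0.21 * FX, -0.03 * FY, 0.0), (0.21 * FX, -0.03 * FY, 0.0))
    lungs = np.zeros(spec.shape, dtype=bool)
    lung_params = []
    for off in lung_offsets:
        c = center + np.asarray(off)
        lungs |= canvas.ellipsoid(c, lung_semi)
        lung_params.append((c, lung_semi))
    canvas.hu[lungs] = HU_LUNG

    lesions: list[LesionMeta] = []
    occupied = np.zeros(spec.shape, dtype=bool)  # lesions dilated by 1 voxel
    struct26 = np.ones((3, 3, 3), dtype=bool)

    def _place(tag: str, diameter: float, label: int) -> np.ndarray:
        for _ in range(_MAX_PLACEMENT_TRIES):
            if tag == "intrapulmonary":
                c, semi = lung_params[int(rng.integers(0, 2))]
                u = rng.uniform(-0.75, 0.75, size=3)
                pos = c + u * semi
            elif tag == "wall":
                c, semi = lung_params[int(rng.integers(0, 2))]
                phi = rng.uniform(0, 2 * np.pi)
                costh = rng.uniform(-0.7, 0.7)
                sinth = np.sqrt(1 - costh**2)
                n = np.array([sinth * np.cos(phi), sinth * np.sin(phi), costh])
                pos = c + n * semi  # on the lung surface -> straddles the boundary
            else:  # extrapulmonary
                pos = center + rng.uniform(-0.95, 0.95, size=3) * body_semi
            support = _lesion_support(canvas, rng, pos, diameter,
                                      lobulated=rng.random() < spec.p_lobulated)
            if not support.any() or not _is_single_component(support):
                continue
            if (support & occupied).any():
                continue
            if tag == "intrapulmonary":
                if not (support <= lungs).all():
                    continue
            elif tag == "extrapulmonary":
                if (support & lungs).any() or not (support <= body).all():
                    continue
            else:  # wall: must genuinely straddle, and stay inside the body
                if not (support & lungs).any() or not (support & body & ~lungs).any():
                    continue
                if not (support <= body).all():
                    continue
            canvas.hu[support] = HU_LESION
            canvas.lesion_labels[support] = label
            occupied[:] |= ndimage.binary_dilation(support, structure=struct26)
            lesions.append(LesionMeta(label, tuple(np.round(pos, 3)), float(diameter), tag))
            return support
        raise PlacementError(
            f"could not place lesion {label} ({tag}, {diameter:.1f} mm) "
            f"after {_MAX_PLACEMENT_TRIES} attempts"
        )

    lo_d, hi_d = spec.lesion_diameter_range
    for k in range(spec.n_lesions):
        u = rng.random()
        if u < spec.p_extrapulmonary:
            tag = "extrapulmonary"
        elif u < spec.p_extrapulmonary + spec.p_wall_attached:
            tag = "wall"
        else:
            tag = "intrapulmonary"
        _place(tag, float(rng.uniform(lo_d, hi_d)), k + 1)

    distractors: list[DistractorMeta] = []
    for _ in range(spec.n_tube_distractors):
        for _try in range(_MAX_PLACEMENT_TRIES):
            c, semi = lung_params[int(rng.integers(0, 2))]
            p0 = c + rng.uniform(-0.6, 0.6, size=3) * semi
            direction = rng.normal(size=3)
            direction[2] *= 2.0  # vessels run preferentially along z
            direction /= np.linalg.norm(direction)
            length = rng.uniform(22.0, 40.0)
            p1 = p0 + direction * length
            radius = rng.uniform(2.0, 3.2)
            support = canvas.capsule(p0, p1, radius) & lungs
            if not support.any() or (support & occupied).any():
                continue
            if not _is_single_component(support):
                continue
            canvas.hu[support] = HU_LESION
            occupied |= ndimage.binary_dilation(support, structure=struct26)
            distractors.append(DistractorMeta("tube", tuple(np.round((p0 + p1) / 2, 3))))
            break
    for _ in range(spec.n_extra_distractors):
        for _try in range(_MAX_PLACEMENT_TRIES):
            pos = center + rng.uniform(-0.95, 0.95, size=3) * body_semi
            core_d = rng.uniform(9.0, 14.0)
            fat_semi = np.array([core_d, core_d, core_d]) * rng.uniform(1.0, 1.4)
            fat = canvas.ellipsoid(pos, fat_semi)
            a = core_d / 2.0
            core = canvas.ellipsoid(pos, (a, a * rng.uniform(0.75, 1.0), a * rng.uniform(0.7, 1.0)))
            pocket = fat | core
            if not core.any() or (pocket & (lungs | occupied)).any() or not (pocket <= body).all():
                continue
            if not _is_single_component(core):
                continue
            canvas.hu[fat & ~core] = HU_FAT
            canvas.hu[core] = HU_LESION
            occupied |= ndimage.binary_dilation(pocket, structure=struct26)
            distractors.append(DistractorMeta("extrapulmonary_nodule", tuple(np.round(pos, 3))))
            break

    if spec.noise_sd > 0:
        canvas.hu += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    ct = CtVolume(canvas.hu, spec.spacing)
    gt = InstanceMask(canvas.lesion_labels, spec.spacing)
    lung_mask = BinaryMask(lungs.astype(np.uint8), spec.spacing)
    return PhantomCase(ct, gt, lung_mask, lesions, distractors, spec)


def generate_cohort(
    n_cases: int,
    base_spec: PhantomSpec = PhantomSpec(),
    spacing_jitter: Optional[dict] = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate *n_cases* phantoms with per-case jittered spacing and lesion counts.

    ``spacing_jitter`` maps axis names to (lo, hi) mm ranges; defaults jitter
    the in-plane spacing over 2.0-3.0 mm and the z spacing over 1.2-5.0 mm,
    emulating the multicenter spread of slice thicknesses and fields of view.
    Lesion counts are drawn from a distribution with median 2 per case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    jitter = {"xy": (2.0, 3.0), "z": (1.2, 5.0)}
    if spacing_jitter:
        jitter.update(spacing_jitter)
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        sxy = float(rng.uniform(*jitter["xy"]))
        sz = float(rng.uniform(*jitter["z"]))
        n_lesions = sample_lesion_count(rng)
        lo_d, hi_d = base_spec.lesion_diameter_range
        lo_d = max(lo_d, 2.0 * max(sxy, sxy, sz))
        spec = dataclasses.replace(
            base_spec,
            spacing=(sxy, sxy, sz),
            n_lesions=n_lesions,
            lesion_diameter_range=(lo_d, max(hi_d, lo_d)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # an infeasible draw (crowded lungs at an extreme spacing) is redrawn
        # with a fresh per-case seed; still fully deterministic under `seed`
        for _attempt in range(10):
            try:
                cases.append(generate_phantom(spec))
                break
            except PlacementError:
                spec = dataclasses.replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        else:
            raise PlacementError(
                f"could not generate case {len(cases)} after 10 seed redraws"
            )
    return cases


def reference_lung_masker(ct: CtVolume) -> BinaryMask:
    """Threshold-based lung segmentation used by the bounding-box stage.

    Voxels below -400 HU are low-density; connected components touching the
    x/y image border (ambient air) are discarded, small components are
    dropped, and a morphological closing smooths the boundary.  An empty
    output is legal (the bbox stage falls back to the whole image).

    Like any density-based lung masker, dense lesions attached to the chest
    wall are excluded from the mask, which is exactly the failure mode the
    bounding-box minimum-size fallback protects against.
    """
    low = ct.data < -400.0
    labels, n = ndimage.label(low, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return BinaryMask(np.zeros(ct.shape, dtype=np.uint8), ct.spacing, ct.origin)
    border = np.zeros(ct.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border_labels = np.unique(labels[border])
    voxel_vol = float(np.prod(ct.spacing))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    min_voxels = int(10_000.0 / voxel_vol)  # 10 cm^3
    for lab in range(1, n + 1):
        keep[lab] = counts[lab] >= min_voxels and lab not in border_labels
    mask = keep[labels]
    if mask.any():
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return BinaryMask(mask.astype(np.uint8), ct.spacing, ct.origin)


def write_cohort_manifest(cases: list[PhantomCase], path) -> None:
    entries = [c.to_manifest_entry() for c in cases]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)
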