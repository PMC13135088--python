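"""Image-derived physical-trait measurement from hip-containing CT volumes.

Measures the six image traits used by the hip-fracture risk score:
trabecular/cortical BMD ratio, posterior subcutaneous fat thickness,
gluteus maximus cross-sectional area, intramuscular fat fraction of the
gluteus medius/minimus, femoral neck volume, and hip width.

Coordinate convention (one place, used everywhere): axis 0 runs left to
right (x), axis 1 posterior to anterior (y), axis 2 inferior to superior
(z); the "frontal plane" is the x-z plane.  World coordinates (mm) are
``origin + index * spacing`` with values sampled at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "Volume",
    "SectionGeometry",
    "MixtureModel",
    "TraitExtractionConfig",
    "RoiSpec",
    "TraitMeasurements",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "locate_femoral_heads",
    "hip_width",
    "section_through_heads",
    "medius_minimus_section",
    "gluteus_maximus_area",
    "posterior_fat_thickness",
    "intramuscular_fat_fraction",
    "trab_cort_ratio",
    "femoral_neck_volume",
    "cylinder_mask",
    "measure_all_traits",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3-D scalar grid with physical spacing.

    ``unit`` is ``"HU"`` for attenuation or ``"g/cm3"`` for calibrated
    apparent density.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    unit: str = "HU"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[i] + np.arange(self.data.shape[i]) * self.spacing[i]
            for i in range(3)
        )  # type: ignore[return-value]

    def world_to_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = [
            int(round((point[i] - self.origin[i]) / self.spacing[i]))
            for i in range(3)
        ]
        for i in range(3):
            idx[i] = min(max(idx[i], 0), self.data.shape[i] - 1)
        return tuple(idx)  # type: ignore[return-value]

    def index_to_world(self, idx: Sequence[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)


@dataclass
class SectionGeometry:
    """A thick planar slab: mid-plane through ``center`` with unit ``normal``."""

    center: np.ndarray
    normal: np.ndarray
    thickness: float = 10.0
    rotation_angle: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("section normal is degenerate")
        self.normal = self.normal / n
        if self.thickness <= 0:
            raise ValueError("section thickness must be positive")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.center) @ self.normal

    def slab_mask(self, volume: Volume) -> np.ndarray:
        """Boolean mask of voxels whose centers lie within the slab.

        Membership is half-open, ``-t/2 <= d < t/2``, so a slab of
        thickness t samples exactly t/spacing voxel layers on an aligned
        grid (a closed interval would double-count both boundary layers).
        """
        xs, ys, zs = volume.world_axes()
        d = (
            (xs - self.center[0])[:, None, None] * self.normal[0]
            + (ys - self.center[1])[None, :, None] * self.normal[1]
            + (zs - self.center[2])[None, None, :] * self.normal[2]
        )
        return (d >= -self.thickness / 2.0) & (d < self.thickness / 2.0)


@dataclass
class MixtureModel:
    """Biphasic muscle-fat attenuation mixture at a fixed effective energy.

    A voxel's HU is modelled as a linear mixture of pure muscle and pure
    fat at a generic 50 keV effective energy; the per-voxel fat volume
    fraction is the affine inversion of that mixture, clamped to [0, 1].
    The exact pure-tissue constants are configurable; defaults are
    +60 HU (muscle) and -120 HU (fat).
    """

    hu_muscle: float = 60.0
    hu_fat: float = -120.0
    contrast_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.hu_muscle <= self.hu_fat:
            raise ValueError("hu_muscle must exceed hu_fat")

    def fat_fraction(self, hu: np.ndarray, contrast_present: bool = False) -> np.ndarray:
        hu_eff = np.asarray(hu, dtype=float)
        if contrast_present:
            hu_eff = hu_eff - self.contrast_offset
        f = (self.hu_muscle - hu_eff) / (self.hu_muscle - self.hu_fat)
        return np.clip(f, 0.0, 1.0)


@dataclass
class RoiSpec:
    """Measurement regions a caller supplies explicitly.

    Phantoms (and, in clinical use, an operator) parameterize the femoral
    neck cylinder per side and the axial bounds of the trabecular/cortical
    region of interest; both are world-coordinate parameters, not masks.
    ``neck_cylinders`` maps side -> dict(start, axis, length, radius).
    """

    neck_cylinders: Optional[dict] = None
    trabcort_z_bounds: Optional[tuple[float, float]] = None


@dataclass
class TraitExtractionConfig:
    """All tunable constants of the trait-extraction stage."""

    mixture: MixtureModel = field(default_factory=MixtureModel)
    # HU window used to segment muscle tissue, the field-standard skeletal
    # muscle attenuation range (excludes fat planes, viscera and bone);
    # voxels with fat fraction above ~0.5 fall below it, so the threshold
    # stand-in presumes moderately infiltrated muscle
    muscle_hu_window: tuple[float, float] = (-30.0, 100.0)
    # classification thresholds along the posterior fat ray
    fat_hu_window: tuple[float, float] = (-250.0, -60.0)
    air_hu_threshold: float = -400.0
    # bone segmentation (kept several noise-SDs above soft-tissue HU)
    bone_hu_threshold: float = 200.0
    bone_density_threshold: float = 0.2  # g/cm3
    cortical_density_threshold: float = 1.0  # g/cm3
    cortical_shell_mm: float = 2.0
    # density <-> HU affine map (scanner calibration stand-in)
    hu_slope: float = 1000.0  # HU per g/cm3
    hu_intercept: float = 0.0
    # atlas-prior seed offsets (mm) from each femoral head center; the
    # lateral component is signed away from the mid-sagittal plane
    maximus_seed_offset: tuple[float, float, float] = (5.0, -50.0, 0.0)
    medius_seed_offset: tuple[float, float, float] = (10.0, 0.0, 0.0)
    minimus_seed_offset: tuple[float, float, float] = (8.0, 36.0, 0.0)
    # section geometry
    section_thickness: float = 10.0
    medius_offset_diameters: float = 1.5
    contrast_present: bool = False
    seed_search_radius_mm: float = 8.0
    # odd median-filter size (voxels) applied before HU-window muscle
    # segmentation; 1 (default) disables.  Available for noise levels at
    # which tissue HU distributions overlap the window edges; note the
    # filter slightly dilates muscle into adjacent fat planes.  The
    # mixture fat fraction always uses the raw HU.
    segmentation_median_size: int = 1


@dataclass
class TraitMeasurements:
    """The six image traits for one patient, with per-side intermediates."""

    trab_cort_ratio: float = np.nan
    fat_thickness: float = np.nan
    muscle_area: float = np.nan
    intramuscular_fat: float = np.nan
    fn_volume: float = np.nan
    hip_width: float = np.nan
    per_side: dict = field(default_factory=dict)
    missing: dict = field(default_factory=dict)

    TRAITS = (
        "trab_cort_ratio",
        "fat_thickness",
        "muscle_area",
        "intramuscular_fat",
        "fn_volume",
        "hip_width",
    )

    def to_row(self) -> dict:
        row = {t: getattr(self, t) for t in self.TRAITS}
        row.update({f"missing_{t}": bool(self.missing.get(t, False)) for t in self.TRAITS})
        return row


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def read_volume(path: str, unit: str = "HU") -> Volume:
    """Read a NIfTI volume; spacing comes from the affine zooms."""
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(np.asanyarray(img.dataobj), spacing, unit=unit, origin=origin)


def write_volume(volume: Volume, path: str) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.data, affine), path)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(v: Volume, target: float = 1.0) -> Volume:
    """Linearly resample to isotropic ``target`` mm voxels.

    The output grid spans the same world extent, with shape
    ``round(extent / target)`` per axis.  If the grid already matches the
    target exactly the input data are returned unchanged (bitwise).
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if all(abs(s - target) < 1e-12 for s in v.spacing):
        return Volume(v.data.copy(), (target,) * 3, unit=v.unit, origin=v.origin)
    new_shape = tuple(
        max(1, int(round(v.data.shape[i] * v.spacing[i] / target))) for i in range(3)
    )
    coords = np.meshgrid(
        *[np.arange(new_shape[i]) * target / v.spacing[i] for i in range(3)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        v.data.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )
    return Volume(out.astype(np.float32), (target,) * 3, unit=v.unit, origin=v.origin)


# ---------------------------------------------------------------------------
# Femoral head localization and sections
# ---------------------------------------------------------------------------

def _bone_mask(v: Volume, config: TraitExtractionConfig) -> np.ndarray:
    thr = (
        config.bone_hu_threshold if v.unit == "HU" else config.bone_density_threshold
    )
    return v.data >= thr


def locate_femoral_heads(
    v: Volume,
    hint: Optional[Sequence[Sequence[float]]] = None,
    config: Optional[TraitExtractionConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the two femoral head centers (mm) in a bone-containing volume.

    The heads are the two deepest quasi-spherical bodies of the bone mask:
    centers are taken at the two dominant maxima of the Euclidean distance
    transform, refined to the centroid of the surrounding thresholded
    ball.  With ``hint`` given, each hint is refined to the local bone
    centroid, deterministically.  Returns ``(centers, radii)`` with
    centers ordered left (smaller x) first.
    """
    config = config or TraitExtractionConfig()
    mask = _bone_mask(v, config)
    if hint is not None:
        centers, radii = [], []
        edt = ndimage.distance_transform_edt(mask, sampling=v.spacing)
        for h in hint:
            c = _refine_center(v, mask, np.asarray(h, float), config.seed_search_radius_mm * 4)
            centers.append(c)
            radii.append(float(edt[v.world_to_index(c)]))
        order = np.argsort([c[0] for c in centers])
        return np.asarray(centers)[order], np.asarray(radii)[order]

    if not mask.any():
        raise ValueError("no bone voxels found; provide head-center hints")
    edt = ndimage.distance_transform_edt(mask, sampling=v.spacing)
    centers, radii = [], []
    work = edt.copy()
    xs, ys, zs = v.world_axes()
    for _ in range(2):
        idx = np.unravel_index(int(np.argmax(work)), work.shape)
        r = float(work[idx])
        if r <= 0:
            raise ValueError(
                "fewer than two candidate spherical bodies found; provide hints"
            )
        peak = v.index_to_world(idx)
        centers.append(_refine_center(v, mask, peak, 0.9 * r))
        radii.append(r)
        # suppress this head before searching for the second
        d2 = (
            (xs - peak[0])[:, None, None] ** 2
            + (ys - peak[1])[None, :, None] ** 2
            + (zs - peak[2])[None, None, :] ** 2
        )
        work[d2 <= (2.2 * r) ** 2] = 0.0
    order = np.argsort([c[0] for c in centers])
    return np.asarray(centers)[order], np.asarray(radii)[order]


def _refine_center(v: Volume, mask: np.ndarray, point: np.ndarray, radius: float) -> np.ndarray:
    """Centroid of mask voxels within ``radius`` mm of ``point``."""
    xs, ys, zs = v.world_axes()
    d2 = (
        (xs - point[0])[:, None, None] ** 2
        + (ys - point[1])[None, :, None] ** 2
        + (zs - point[2])[None, None, :] ** 2
    )
    ball = mask & (d2 <= radius**2)
    if not ball.any():
        return np.asarray(point, dtype=float)
    ii = np.nonzero(ball)
    return np.array(
        [
            xs[ii[0]].mean(),
            ys[ii[1]].mean(),
            zs[ii[2]].mean(),
        ]
    )


def hip_width(centers: np.ndarray) -> float:
    """Three-dimensional distance (mm) between the femoral head centers."""
    c = np.asarray(centers, dtype=float)
    d = float(np.linalg.norm(c[1] - c[0]))
    if d == 0:
        raise ValueError("head centers coincide")
    return d


def section_through_heads(centers: np.ndarray, thickness: float = 10.0) -> SectionGeometry:
    """Transverse slab rotated about the anterior-posterior axis so its
    mid-plane contains both femoral head centers.

    The rotation angle equals atan(superior-inferior offset over
    left-right offset of the centers).
    """
    c = np.asarray(centers, dtype=float)
    dx = c[1, 0] - c[0, 0]
    dz = c[1, 2] - c[0, 2]
    if dx == 0 and dz == 0:
        raise ValueError(
            "head centers are separated only along the section normal; "
            "a head-containing transverse slab is undefined"
        )
    normal = np.array([-dz, 0.0, dx])
    if normal[2] < 0:
        normal = -normal
    angle = float(np.arctan2(dz, dx)) if dx != 0 else np.pi / 2
    return SectionGeometry(
        center=(c[0] + c[1]) / 2.0,
        normal=normal,
        thickness=thickness,
        rotation_angle=angle,
    )


def medius_minimus_section(
    centers: np.ndarray,
    head_diameter: float,
    offset_in_diameters: float = 1.5,
    thickness: float = 10.0,
) -> SectionGeometry:
    """Slab parallel to the through-heads section, displaced superiorly by
    ``offset_in_diameters`` femoral head diameters (default 1.5)."""
    if head_diameter <= 0:
        raise ValueError("head diameter must be positive")
    base = section_through_heads(np.asarray(centers, float), thickness=thickness)
    shift = offset_in_diameters * head_diameter
    return SectionGeometry(
        center=base.center + shift * base.normal,
        normal=base.normal,
        thickness=thickness,
        rotation_angle=base.rotation_angle,
    )


# ---------------------------------------------------------------------------
# Muscle segmentation and muscle-derived traits
# ---------------------------------------------------------------------------

def _seed_point(
    center: np.ndarray,
    midline_x: float,
    offset: tuple[float, float, float],
) -> np.ndarray:
    """Anatomical seed: offset from a head center; lateral component is
    signed away from the mid-sagittal plane."""
    lateral_sign = -1.0 if center[0] < midline_x else 1.0
    return np.array(
        [center[0] + lateral_sign * offset[0], center[1] + offset[1], center[2] + offset[2]]
    )


def _segment_component(
    v: Volume,
    region_mask: np.ndarray,
    seed_world: np.ndarray,
    search_radius_mm: float,
) -> np.ndarray:
    """Connected component of ``region_mask`` containing (or nearest to)
    the seed point, within ``search_radius_mm``."""
    labels, nlab = ndimage.label(region_mask)
    if nlab == 0:
        return np.zeros_like(region_mask)
    idx = v.world_to_index(seed_world)
    lab = labels[idx]
    if lab == 0:
        # deterministic nearest in-mask voxel within the search radius
        r = max(1, int(round(search_radius_mm / min(v.spacing))))
        sl = tuple(
            slice(max(0, idx[i] - r), min(v.data.shape[i], idx[i] + r + 1)) for i in range(3)
        )
        sub = labels[sl]
        if not (sub > 0).any():
            return np.zeros_like(region_mask)
        ii = np.argwhere(sub > 0)
        local = np.array([idx[i] - sl[i].start for i in range(3)])
        d2 = ((ii - local) * np.asarray(v.spacing)) ** 2
        best = ii[int(np.argmin(d2.sum(axis=1)))]
        lab = sub[tuple(best)]
    return labels == lab


def _muscle_mask_for_side(
    v: Volume,
    section: SectionGeometry,
    seed_world: np.ndarray,
    config: TraitExtractionConfig,
) -> np.ndarray:
    lo, hi = config.muscle_hu_window
    slab = section.slab_mask(v)
    if not slab.any():
        return slab
    # work on the slab bounding box; median-denoise before windowing so
    # noise cannot punch holes through thin fat planes between muscles
    ii = np.nonzero(slab)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in ii)
    sub = v.data[sl]
    if config.segmentation_median_size > 1:
        sub = ndimage.median_filter(sub, size=config.segmentation_median_size)
    region = np.zeros_like(slab)
    region[sl] = (sub >= lo) & (sub <= hi) & slab[sl]
    return _segment_component(v, region, seed_world, config.seed_search_radius_mm)


def gluteus_maximus_area(
    v: Volume,
    section: SectionGeometry,
    side: str,
    centers: np.ndarray,
    config: Optional[TraitExtractionConfig] = None,
) -> float:
    """Cross-sectional area (cm^2) of the gluteus maximus on one side in
    the 10-mm through-heads slab: segmented slab volume / thickness.

    Segmentation is an HU-window plus seeded connected component (a
    geometric stand-in for a learned muscle segmenter, adequate on
    phantoms with known compartments).
    """
    config = config or TraitExtractionConfig()
    c = np.asarray(centers, float)
    midline = c[:, 0].mean()
    head = c[0] if side == "left" else c[1]
    seed = _seed_point(head, midline, config.maximus_seed_offset)
    mask = _muscle_mask_for_side(v, section, seed, config)
    if not mask.any():
        raise ValueError(f"empty gluteus maximus segmentation on {side} side")
    voxel_vol = float(np.prod(v.spacing))
    return mask.sum() * voxel_vol / section.thickness / 100.0


def posterior_fat_thickness(
    v: Volume,
    section: SectionGeometry,
    centers: np.ndarray,
    config: Optional[TraitExtractionConfig] = None,
) -> tuple[float, dict]:
    """Subcutaneous fat thickness (mm) directly posterior to the femoral
    head centers, within the through-heads slab.

    For each side, the posterior ray from the head center is walked to
    the skin boundary (air); the thickness is the contiguous fat run
    immediately inside the boundary, i.e. between the muscle-fat and
    fat-skin interfaces.  The trait is the lower of the two sides.
    """
    config = config or TraitExtractionConfig()
    c = np.asarray(centers, float)
    sides = {}
    for side, head in zip(("left", "right"), c):
        xi, yi, zi = v.world_to_index(head)
        column = v.data[xi, : yi + 1, zi][::-1]  # marching posteriorly
        lo, hi = config.fat_hu_window
        air = column < config.air_hu_threshold
        if not air.any():
            raise ValueError(
                f"posterior ray on {side} side exits the grid before reaching skin"
            )
        j_air = int(np.argmax(air))
        run = 0
        for j in range(j_air - 1, -1, -1):
            if lo <= column[j] <= hi:
                run += 1
            else:
                break
        sides[side] = run * v.spacing[1]
    return min(sides.values()), sides


def intramuscular_fat_fraction(
    v: Volume,
    muscle_mask: np.ndarray,
    m: MixtureModel,
    contrast_present: bool = False,
) -> float:
    """Percent fat tissue by volume within a muscle mask, via the biphasic
    mixture model (per-voxel fraction clamped to [0, 1])."""
    if not np.asarray(muscle_mask).any():
        raise ValueError("empty muscle mask")
    f = m.fat_fraction(v.data[muscle_mask], contrast_present=contrast_present)
    return 100.0 * float(f.mean())


# ---------------------------------------------------------------------------
# Bone-compartment traits
# ---------------------------------------------------------------------------

def trab_cort_ratio(
    density_volume: Volume,
    femur_mask: np.ndarray,
    roi: np.ndarray,
    config: Optional[TraitExtractionConfig] = None,
) -> float:
    """Mean trabecular / mean cortical apparent density within a proximal
    femur region of interest.

    Cortical voxels are those with density >= 1.0 g/cm^3 *or* within 2 mm
    of the periosteal surface (Euclidean distance transform of the femur
    mask; ties at exactly 2 mm count as cortical).  Trabecular voxels are
    the ROI remainder.
    """
    config = config or TraitExtractionConfig()
    if density_volume.unit != "g/cm3":
        raise ValueError("trab/cort ratio requires a density volume in g/cm3")
    roi = roi & femur_mask
    if not roi.any():
        raise ValueError("empty femur region of interest")
    depth = ndimage.distance_transform_edt(femur_mask, sampling=density_volume.spacing)
    cortical = roi & (
        (density_volume.data >= config.cortical_density_threshold)
        | (depth <= config.cortical_shell_mm)
    )
    trabecular = roi & ~cortical
    if not cortical.any():
        raise ValueError("empty cortical compartment")
    if not trabecular.any():
        raise ValueError("empty trabecular compartment")
    return float(density_volume.data[trabecular].mean() / density_volume.data[cortical].mean())


def cylinder_mask(
    v: Volume,
    start: Sequence[float],
    axis: Sequence[float],
    length: float,
    radius: float,
) -> np.ndarray:
    """Boolean mask of a finite cylinder given in world coordinates."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    s = np.asarray(start, float)
    xs, ys, zs = v.world_axes()
    px = (xs - s[0])[:, None, None]
    py = (ys - s[1])[None, :, None]
    pz = (zs - s[2])[None, None, :]
    t = px * a[0] + py * a[1] + pz * a[2]
    d2 = (px - t * a[0]) ** 2 + (py - t * a[1]) ** 2 + (pz - t * a[2]) ** 2
    # half-open along the axis so a length-L cylinder samples L/spacing
    # aligned voxel layers (and lengths add exactly)
    return (t >= 0) & (t < length) & (d2 <= radius**2)


def femoral_neck_volume(femur_mask: np.ndarray, neck_roi: np.ndarray, spacing) -> float:
    """Bone volume (cm^3) within the femoral neck region of interest."""
    if not np.asarray(neck_roi).any():
        raise ValueError("empty femoral neck region of interest")
    count = int((femur_mask & neck_roi).sum())
    return count * float(np.prod(spacing)) / 1000.0


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def measure_all_traits(
    hu_volume: Volume,
    config: Optional[TraitExtractionConfig] = None,
    rois: Optional[RoiSpec] = None,
    density_volume: Optional[Volume] = None,
    head_hint: Optional[Sequence[Sequence[float]]] = None,
) -> TraitMeasurements:
    """Measure all six image traits from one volume.

    Left/right combination rules: minimum of sides for muscle area and
    fat thickness, average of sides for intramuscular fat; femoral neck
    volume is taken on the left side, nominally; hip width and the
    trabecular/cortical ratio are single whole-pelvis measurements.
    A trait whose anatomy is unavailable (e.g. truncated by the grid) is
    flagged missing rather than aborting the measurement.
    """
    config = config or TraitExtractionConfig()
    rois = rois or RoiSpec()
    out = TraitMeasurements()

    if density_volume is None:
        dens = (hu_volume.data - config.hu_intercept) / config.hu_slope
        density_volume = Volume(
            np.clip(dens, 0.0, None),
            hu_volume.spacing,
            unit="g/cm3",
            origin=hu_volume.origin,
        )

    centers, radii = locate_femoral_heads(density_volume, hint=head_hint, config=config)
    midline = centers[:, 0].mean()

    try:
        out.hip_width = hip_width(centers)
    except ValueError:
        out.missing["hip_width"] = True

    try:
        section = section_through_heads(centers, thickness=config.section_thickness)
    except ValueError:
        section = None
        for t in ("muscle_area", "fat_thickness", "intramuscular_fat"):
            out.missing[t] = True

    if section is not None:
        areas = {}
        for side in ("left", "right"):
            try:
                areas[side] = gluteus_maximus_area(
                    hu_volume, section, side, centers, config
                )
            except ValueError:
                pass
        if len(areas) == 2:
            out.muscle_area = min(areas.values())
            out.per_side["muscle_area"] = areas
        else:
            out.missing["muscle_area"] = True

        try:
            out.fat_thickness, sides = posterior_fat_thickness(
                hu_volume, section, centers, config
            )
            out.per_side["fat_thickness"] = sides
        except ValueError:
            out.missing["fat_thickness"] = True

        try:
            diameter = 2.0 * float(np.mean(radii))
            upper = medius_minimus_section(
                centers, diameter, config.medius_offset_diameters, config.section_thickness
            )
            fats = {}
            for side, head in zip(("left", "right"), centers):
                m_seed = _seed_point(
                    head + (upper.center - section.center), midline, config.medius_seed_offset
                )
                n_seed = _seed_point(
                    head + (upper.center - section.center), midline, config.minimus_seed_offset
                )
                mask = _muscle_mask_for_side(hu_volume, upper, m_seed, config)
                mask |= _muscle_mask_for_side(hu_volume, upper, n_seed, config)
                fats[side] = intramuscular_fat_fraction(
                    hu_volume, mask, config.mixture, config.contrast_present
                )
            out.intramuscular_fat = float(np.mean(list(fats.values())))
            out.per_side["intramuscular_fat"] = fats
        except ValueError:
            out.missing["intramuscular_fat"] = True

    femur = _bone_mask(density_volume, config)
    if rois.trabcort_z_bounds is not None:
        zlo, zhi = rois.trabcort_z_bounds
        zs = density_volume.world_axes()[2]
        zmask = (zs >= zlo) & (zs <= zhi)
        roi = femur & zmask[None, None, :]
        try:
            out.trab_cort_ratio = trab_cort_ratio(density_volume, femur, roi, config)
        except ValueError:
            out.missing["trab_cort_ratio"] = True
    else:
        out.missing["trab_cort_ratio"] = True

    if rois.neck_cylinders:
        try:
            vols = {}
            for side, cyl in rois.neck_cylinders.items():
                neck = cylinder_mask(
                    density_volume, cyl["start"], cyl["axis"], cyl["length"], cyl["radius"]
                )
                vols[side] = femoral_neck_volume(femur, neck, density_volume.spacing)
            out.per_side["fn_volume"] = vols
            out.fn_volume = vols.get("left", next(iter(vols.values())))
        except ValueError:
            out.missing["fn_volume"] = True
    else:
        out.missing["fn_volume"] = True

    return out
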