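"""Synthetic hip phantoms and synthetic case-cohort tables.

Two generators make every downstream stage testable without any data
download:

* :func:`generate_phantom` voxelizes a parametric hip-region phantom
  (femoral heads with cortical shell and trabecular core, neck cylinders,
  three gluteal muscles per side as ellipsoids with a fascial fat sheath,
  a posterior subcutaneous fat slab, and air behind the skin) and returns
  closed-form ground-truth values for all six image traits.

* :func:`generate_cohort` draws a per-sex source population with a
  Gaussian-copula trait structure (trait-age and trait-strength R^2
  targets), simulates 5-yr fracture outcomes from a logistic model with
  configurable per-SD coefficients whose signs are fixed by the known
  risk directions, and samples a case-cohort table: all fracture cases
  plus an age-matched random subcohort sized to give an approximate 1:1
  fracture:control ratio per sex.  Ages above 90 are coded as 90.

Ground truth is returned alongside every generated object and is never
consumed by the model-fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit as logit_fn
from scipy.optimize import brentq

from .trait_extraction import Volume, RoiSpec

__all__ = [
    "MuscleSpec",
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "phantom_rois",
    "CohortSpec",
    "CohortGroundTruth",
    "generate_cohort",
    "split_development_validation",
    "TRAIT_NAMES",
    "MODEL_COVARIATES",
    "RISK_DIRECTIONS",
    "DEFAULT_SITE_SPLIT",
]

# The eight model covariates (sex enters only through calibration offsets).
TRAIT_NAMES = (
    "trab_cort_ratio",
    "fat_thickness",
    "muscle_area",
    "intramuscular_fat",
    "fn_volume",
    "hip_width",
)
MODEL_COVARIATES = ("age", "femoral_strength") + TRAIT_NAMES

# +1: larger value increases fracture risk; -1: decreases it.
RISK_DIRECTIONS = {
    "age": +1,
    "femoral_strength": -1,
    "trab_cort_ratio": -1,
    "fat_thickness": -1,
    "muscle_area": -1,
    "intramuscular_fat": +1,
    "fn_volume": +1,
    "hip_width": +1,
}

# development sites 0-11, validation sites 12-27
DEFAULT_SITE_SPLIT = (tuple(range(12)), tuple(range(12, 28)))


# ===========================================================================
# Phantoms
# ===========================================================================

def _per_side(value):
    """Resolve a scalar-or-(left, right) parameter to a pair."""
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return tuple(value)
    return (value, value)


@dataclass
class MuscleSpec:
    """One gluteal muscle as an ellipsoid offset from the femoral head.

    ``lateral_offset`` is signed away from the mid-sagittal plane;
    ``fat_fraction`` is the intramuscular fat volume fraction in [0, 1].
    Each field accepts a scalar (both sides) or a (left, right) pair.
    """

    lateral_offset: float = 0.0
    y_offset: float = 0.0
    z_offset: float = 0.0
    semi_axes: tuple = (30.0, 20.0, 30.0)
    fat_fraction: float | tuple = 0.2


@dataclass
class PhantomSpec:
    """Parametric hip phantom with analytically known trait values."""

    grid_shape: tuple[int, int, int] = (200, 150, 190)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_centers: tuple = ((50.0, 100.0, 70.0), (150.0, 100.0, 70.0))
    head_radius: float = 24.0
    neck_axis: tuple = ((-0.6, 0.0, -0.8), (0.6, 0.0, -0.8))
    neck_length: float = 35.0
    neck_radius: float = 13.0
    cortical_shell_thickness: float = 3.0
    cortical_density: float = 1.2  # g/cm3
    trabecular_density: float = 0.3  # g/cm3
    muscle_regions: dict = field(default_factory=lambda: {
        "maximus": MuscleSpec(5.0, -50.0, 0.0, (38.0, 24.0, 55.0), 0.15),
        "medius": MuscleSpec(10.0, 0.0, 72.0, (30.0, 20.0, 26.0), 0.25),
        "minimus": MuscleSpec(8.0, 36.0, 72.0, (18.0, 12.0, 20.0), 0.25),
    })
    subcut_fat_thickness_posterior: float | tuple = 20.0
    fascia_thickness: float = 2.0
    # non-muscle viscera/parenchyma compartment; deliberately outside the
    # muscle HU window so that window-plus-seeded-component segmentation
    # is identifiable on the phantom (the phantom's stand-in for the
    # semantic discrimination a learned muscle segmenter provides)
    soft_tissue_hu: float = 120.0
    air_hu: float = -1000.0
    hu_muscle: float = 60.0
    hu_fat: float = -120.0
    hu_slope: float = 1000.0  # HU per g/cm3 for bone
    hu_intercept: float = 0.0
    noise_sd: float = 0.0  # HU
    contrast_offset: float = 0.0  # HU added to muscle when contrast present
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        for name, val in (
            ("head_radius", self.head_radius),
            ("neck_length", self.neck_length),
            ("neck_radius", self.neck_radius),
            ("cortical_shell_thickness", self.cortical_shell_thickness),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cortical_density < 0 or self.trabecular_density < 0:
            raise ValueError("densities must be non-negative")
        extent = np.array(self.grid_shape) * np.array(self.voxel_size)
        for si, c in enumerate(self.head_centers):
            lo = np.array(c) - self.head_radius
            hi = np.array(c) + self.head_radius
            if (lo < 0).any() or (hi > extent).any():
                raise ValueError(f"femoral head [{'left' if si == 0 else 'right'}] exceeds the grid")
        for name, m in self.muscle_regions.items():
            for si, side in enumerate(("left", "right")):
                c = self._muscle_center(name, si)
                ax = np.array(self._muscle_axes(name, si))
                if ((c - ax) < 0).any() or ((c + ax) > extent).any():
                    raise ValueError(f"muscle {name}[{side}] exceeds the grid")
            ffs = _per_side(m.fat_fraction)
            if any(not (0.0 <= f <= 1.0) for f in ffs):
                raise ValueError(f"muscle {name}: fat fraction must be in [0, 1]")
        for t in _per_side(self.subcut_fat_thickness_posterior):
            if t < 0:
                raise ValueError("subcutaneous fat thickness must be >= 0")

    # -- derived geometry -------------------------------------------------
    def _lateral_sign(self, side_idx: int) -> float:
        mid = (self.head_centers[0][0] + self.head_centers[1][0]) / 2.0
        return -1.0 if self.head_centers[side_idx][0] < mid else 1.0

    def _muscle_axes(self, name: str, side_idx: int) -> tuple:
        m = self.muscle_regions[name]
        sa = m.semi_axes
        if isinstance(sa[0], (tuple, list)):
            return tuple(sa[side_idx])
        return tuple(sa)

    def _muscle_center(self, name: str, side_idx: int) -> np.ndarray:
        m = self.muscle_regions[name]
        head = np.asarray(self.head_centers[side_idx], float)
        lat = _per_side(m.lateral_offset)[side_idx]
        return head + np.array(
            [self._lateral_sign(side_idx) * lat, _per_side(m.y_offset)[side_idx],
             _per_side(m.z_offset)[side_idx]]
        )


@dataclass
class PhantomResult:
    hu: Volume
    density: Volume
    ground_truth: dict
    rois: RoiSpec


def _slab_ellipse_mean_area(a: float, b: float, c: float, u1: float, u2: float) -> float:
    """Mean cross-sectional area (mm^2) of an ellipsoid over the axial
    window [u1, u2] (offsets from the ellipsoid center along its c axis).

    Area(u) = pi*a*b*(1 - u^2/c^2) inside [-c, c]; zero outside.
    """
    u1c, u2c = max(u1, -c), min(u2, c)
    if u2c <= u1c:
        return 0.0
    integral = np.pi * a * b * (
        (u2c - u1c) - (u2c**3 - u1c**3) / (3.0 * c**2)
    )
    return integral / (u2 - u1)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Voxelize a phantom and compute closed-form ground truth.

    Returns HU and paired density (g/cm^3) volumes plus a ground-truth
    dict with analytically computed hip width, per-side fat thickness,
    maximus slab-average areas, medius/minimus fat fractions, neck
    volumes, and the trabecular/cortical density ratio.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    sp = np.asarray(spec.voxel_size, float)
    xs = np.arange(shape[0]) * sp[0]
    ys = np.arange(shape[1]) * sp[1]
    zs = np.arange(shape[2]) * sp[2]
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    density = np.zeros(shape, dtype=np.float32)
    hu = np.full(shape, spec.soft_tissue_hu, dtype=np.float32)

    gt: dict = {"head_centers": np.asarray(spec.head_centers, float),
                "head_radius": spec.head_radius}
    gt["hip_width"] = float(
        np.linalg.norm(np.asarray(spec.head_centers[1]) - np.asarray(spec.head_centers[0]))
    )

    # --- bone: heads (shelled spheres) and necks (shelled cylinders) -----
    bone_trab = np.zeros(shape, dtype=bool)
    bone_cort = np.zeros(shape, dtype=bool)
    neck_cyls = {}
    for si, side in enumerate(("left", "right")):
        c = np.asarray(spec.head_centers[si], float)
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        inside = d2 <= spec.head_radius**2
        core = d2 <= (spec.head_radius - spec.cortical_shell_thickness) ** 2
        bone_cort |= inside & ~core
        bone_trab |= core

        ax = np.asarray(spec.neck_axis[si], float)
        ax = ax / np.linalg.norm(ax)
        start = c + spec.head_radius * ax
        end = start + spec.neck_length * ax
        extent = np.array(shape) * sp
        for p, tag in ((start, "start"), (end, "end")):
            if ((p - spec.neck_radius) < 0).any() or ((p + spec.neck_radius) > extent).any():
                raise ValueError(f"femoral neck [{side}] exceeds the grid")
        t = (X - start[0]) * ax[0] + (Y - start[1]) * ax[1] + (Z - start[2]) * ax[2]
        r2 = ((X - start[0]) - t * ax[0]) ** 2 + ((Y - start[1]) - t * ax[1]) ** 2 + (
            (Z - start[2]) - t * ax[2]
        ) ** 2
        in_cyl = (t >= 0) & (t <= spec.neck_length) & (r2 <= spec.neck_radius**2)
        # cortical shell covers the radial surface and both end caps
        core_cyl = (
            in_cyl
            & (r2 <= (spec.neck_radius - spec.cortical_shell_thickness) ** 2)
            & (t >= spec.cortical_shell_thickness)
            & (t <= spec.neck_length - spec.cortical_shell_thickness)
        )
        bone_cort |= in_cyl & ~core_cyl
        bone_trab |= core_cyl
        neck_cyls[side] = {
            "start": tuple(start),
            "axis": tuple(ax),
            "length": spec.neck_length,
            "radius": spec.neck_radius,
        }
    bone_cort &= ~bone_trab  # trabecular core wins where shells of two bodies overlap a core
    density[bone_cort] = spec.cortical_density
    density[bone_trab] = spec.trabecular_density
    bone = bone_cort | bone_trab

    # --- muscles with fascial fat sheath ---------------------------------
    muscle_masks: dict = {}
    fascia = np.zeros(shape, dtype=bool)
    for name in spec.muscle_regions:
        for si, side in enumerate(("left", "right")):
            cen = spec._muscle_center(name, si)
            a, b, cc = spec._muscle_axes(name, si)
            q = ((X - cen[0]) / a) ** 2 + ((Y - cen[1]) / b) ** 2 + ((Z - cen[2]) / cc) ** 2
            inner = q <= 1.0
            f = spec.fascia_thickness
            qo = (
                ((X - cen[0]) / (a + f)) ** 2
                + ((Y - cen[1]) / (b + f)) ** 2
                + ((Z - cen[2]) / (cc + f)) ** 2
            )
            fascia |= (qo <= 1.0) & ~inner
            muscle_masks[(name, side)] = inner

    fat_hu = spec.hu_fat
    for (name, side), mask in muscle_masks.items():
        si = 0 if side == "left" else 1
        ff = _per_side(spec.muscle_regions[name].fat_fraction)[si]
        mhu = (1.0 - ff) * spec.hu_muscle + ff * spec.hu_fat + spec.contrast_offset
        hu[mask & ~bone] = mhu
    any_muscle = np.zeros(shape, dtype=bool)
    for mask in muscle_masks.values():
        any_muscle |= mask
    hu[fascia & ~bone & ~any_muscle] = fat_hu

    # --- posterior subcutaneous fat slab and air -------------------------
    thicknesses = _per_side(spec.subcut_fat_thickness_posterior)
    mid_x = (spec.head_centers[0][0] + spec.head_centers[1][0]) / 2.0
    gt_fat = {}
    for si, side in enumerate(("left", "right")):
        head = np.asarray(spec.head_centers[si], float)
        mcen = spec._muscle_center("maximus", si)
        a, b, cc = spec._muscle_axes("maximus", si)
        arg = 1.0 - ((head[0] - mcen[0]) / a) ** 2 - ((head[2] - mcen[2]) / cc) ** 2
        if arg <= 0:
            raise ValueError("posterior ray misses the gluteus maximus; adjust muscle offsets")
        y_surf = mcen[1] - b * np.sqrt(arg)
        t = thicknesses[si]
        x_half = (X < mid_x) if side == "left" else (X >= mid_x)
        body = ~bone & ~any_muscle & ~fascia
        fat_slab = x_half & body & (Y >= y_surf - t) & (Y < y_surf)
        hu[fat_slab] = fat_hu
        air = x_half & (Y < y_surf - t)
        hu[air & ~bone & ~any_muscle & ~fascia] = spec.air_hu
        gt_fat[side] = float(t)
    gt["fat_thickness_per_side"] = gt_fat
    gt["fat_thickness"] = min(gt_fat.values())

    # --- noise and paired density volume ---------------------------------
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    density_from_hu = np.clip((hu - spec.hu_intercept) / spec.hu_slope, 0.0, None)
    # keep exact densities where bone is noise-free
    if spec.noise_sd == 0:
        density_from_hu[bone] = density[bone]
    hu[bone] = (density[bone] * spec.hu_slope + spec.hu_intercept) + (
        rng.normal(0.0, spec.noise_sd, size=int(bone.sum())).astype(np.float32)
        if spec.noise_sd > 0
        else 0.0
    )
    if spec.noise_sd > 0:
        density_from_hu = np.clip((hu - spec.hu_intercept) / spec.hu_slope, 0.0, None)

    hu_vol = Volume(hu, tuple(sp), unit="HU")
    dens_vol = Volume(density_from_hu.astype(np.float32), tuple(sp), unit="g/cm3")

    # --- analytic ground truth -------------------------------------------
    half = 5.0  # half-thickness of the standard 10-mm section
    areas = {}
    for si, side in enumerate(("left", "right")):
        cen = spec._muscle_center("maximus", si)
        a, b, cc = spec._muscle_axes("maximus", si)
        u0 = spec.head_centers[si][2] - cen[2]
        areas[side] = _slab_ellipse_mean_area(a, b, cc, u0 - half, u0 + half) / 100.0
    gt["muscle_area_per_side"] = areas
    gt["muscle_area"] = min(areas.values())

    imf = {}
    z_section = spec.head_centers[0][2] + 1.5 * 2.0 * spec.head_radius
    for si, side in enumerate(("left", "right")):
        num = den = 0.0
        for name in ("medius", "minimus"):
            cen = spec._muscle_center(name, si)
            a, b, cc = spec._muscle_axes(name, si)
            u0 = z_section - cen[2]
            vol = _slab_ellipse_mean_area(a, b, cc, u0 - half, u0 + half) * 2 * half
            ff = _per_side(spec.muscle_regions[name].fat_fraction)[si]
            num += vol * ff
            den += vol
        imf[side] = 100.0 * num / den if den > 0 else np.nan
    gt["intramuscular_fat_per_side"] = imf
    gt["intramuscular_fat"] = float(np.mean(list(imf.values())))

    gt["fn_volume_per_side"] = {
        s: np.pi * spec.neck_radius**2 * spec.neck_length / 1000.0 for s in ("left", "right")
    }
    gt["fn_volume"] = gt["fn_volume_per_side"]["left"]
    gt["trab_cort_ratio"] = spec.trabecular_density / spec.cortical_density

    rois = phantom_rois(spec, neck_cyls)
    return PhantomResult(hu_vol, dens_vol, gt, rois)


def phantom_rois(spec: PhantomSpec, neck_cyls: Optional[dict] = None) -> RoiSpec:
    """Measurement ROIs implied by a phantom spec: the neck cylinder
    primitives and axial bounds just below the head centers."""
    if neck_cyls is None:
        neck_cyls = {}
        for si, side in enumerate(("left", "right")):
            c = np.asarray(spec.head_centers[si], float)
            ax = np.asarray(spec.neck_axis[si], float)
            ax = ax / np.linalg.norm(ax)
            neck_cyls[side] = {
                "start": tuple(c + spec.head_radius * ax),
                "axis": tuple(ax),
                "length": spec.neck_length,
                "radius": spec.neck_radius,
            }
    z_head = spec.head_centers[0][2]
    return RoiSpec(
        neck_cylinders=neck_cyls,
        trabcort_z_bounds=(z_head - 45.0, z_head - 5.0),
    )


# ===========================================================================
# Cohorts
# ===========================================================================

def _default_trait_params() -> dict:
    """Per-sex marginal means/SDs and R^2 targets for each covariate.

    R^2 targets against age and strength follow the published per-sex
    univariate values for a random population sample; marginal means/SDs
    for the image traits are realistic defaults (the strength and T-score
    marginals follow published population characteristics).
    """
    return {
        "femoral_strength": {
            "mean": {"F": 3460.0, "M": 4570.0}, "sd": {"F": 860.0, "M": 1120.0},
            "r2_age": {"F": 0.091, "M": 0.044}, "sign_age": -1,
            "r2_strength": {"F": None, "M": None}, "sign_strength": +1,
            "lo": 500.0, "hi": 9000.0,
        },
        "trab_cort_ratio": {
            "mean": {"F": 0.50, "M": 0.46}, "sd": {"F": 0.10, "M": 0.10},
            "r2_age": {"F": 0.045, "M": 0.021}, "sign_age": -1,
            "r2_strength": {"F": 0.161, "M": 0.133}, "sign_strength": +1,
            "lo": 0.05, "hi": 0.95,
        },
        "fat_thickness": {
            "mean": {"F": 25.0, "M": 15.0}, "sd": {"F": 9.0, "M": 7.0},
            "r2_age": {"F": 0.030, "M": 0.008}, "sign_age": -1,
            "r2_strength": {"F": 0.019, "M": 0.004}, "sign_strength": +1,
            "lo": 0.0, "hi": 80.0,
        },
        "muscle_area": {
            "mean": {"F": 27.0, "M": 34.0}, "sd": {"F": 6.0, "M": 7.0},
            "r2_age": {"F": 0.100, "M": 0.115}, "sign_age": -1,
            "r2_strength": {"F": 0.131, "M": 0.137}, "sign_strength": +1,
            "lo": 5.0, "hi": 70.0,
        },
        "intramuscular_fat": {
            "mean": {"F": 26.0, "M": 26.0}, "sd": {"F": 9.0, "M": 9.0},
            "r2_age": {"F": 0.124, "M": 0.105}, "sign_age": +1,
            "r2_strength": {"F": 0.073, "M": 0.053}, "sign_strength": -1,
            "lo": 2.0, "hi": 75.0,
        },
        "fn_volume": {
            "mean": {"F": 9.5, "M": 13.0}, "sd": {"F": 1.4, "M": 1.9},
            "r2_age": {"F": 0.010, "M": 0.014}, "sign_age": +1,
            "r2_strength": {"F": 0.010, "M": 0.005}, "sign_strength": +1,
            "lo": 4.0, "hi": 25.0,
        },
        # the male-female mean gap is kept small so the pooled hip-width /
        # strength correlation stays near its weak per-sex values (unlike
        # FN volume, whose large sex gap makes the pooled correlation with
        # strength much stronger than within either sex)
        "hip_width": {
            "mean": {"F": 175.0, "M": 179.0}, "sd": {"F": 9.0, "M": 10.0},
            "r2_age": {"F": 0.0, "M": 0.004}, "sign_age": +1,
            "r2_strength": {"F": 0.011, "M": 0.010}, "sign_strength": +1,
            "lo": 140.0, "hi": 230.0,
        },
    }


def _default_coefficients() -> dict:
    """Logit-scale coefficients per SD of each covariate (signs fixed by
    the risk directions; magnitudes are simulation choices)."""
    return {
        "age": 0.30,
        "femoral_strength": -0.80,
        "trab_cort_ratio": -0.35,
        "fat_thickness": -0.20,
        "muscle_area": -0.35,
        "intramuscular_fat": 0.40,
        "fn_volume": 0.45,
        "hip_width": 0.25,
    }


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic source population."""

    n_per_sex: dict = field(default_factory=lambda: {"F": 5000, "M": 2200})
    age_range: tuple[float, float] = (65.0, 95.0)  # ages > 90 coded as 90
    trait_params: dict = field(default_factory=_default_trait_params)
    outcome_coefficients: dict = field(default_factory=_default_coefficients)
    base_rate: dict = field(default_factory=lambda: {"F": 0.058, "M": 0.034})
    late_fracture_factor: float = 0.6  # P(fracture in (5,10] | no 5-yr fx) = factor * p5
    dropout_rate: float = 0.15
    treated_rate: float = 0.08
    frax_positive_rate: dict = field(default_factory=lambda: {"F": 0.346, "M": 0.200})
    frax_slope: float = 0.8
    frax_noise_sd: float = 0.5
    t_score_params: dict = field(default_factory=lambda: {
        "hip_t_score": {"mean": {"F": -1.5, "M": -0.7}, "sd": {"F": 1.1, "M": 1.2}},
        "fn_t_score": {"mean": {"F": -1.7, "M": -1.0}, "sd": {"F": 1.1, "M": 1.2}},
    })
    t_score_strength_corr: float = 0.75
    n_sites: tuple[int, int] = (12, 16)
    n_random_per_sex: Optional[dict] = None  # default: one per fracture case
    seed: int = 0

    def validate(self) -> None:
        for name, d in (
            ("base_rate", self.base_rate),
            ("frax_positive_rate", self.frax_positive_rate),
        ):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0 or not 0.0 <= self.treated_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        for cov, beta in self.outcome_coefficients.items():
            want = RISK_DIRECTIONS[cov]
            if beta != 0 and np.sign(beta) != want:
                raise ValueError(
                    f"coefficient sign for {cov} must be "
                    f"{'positive' if want > 0 else 'negative'}"
                )


@dataclass
class CohortGroundTruth:
    """True generating quantities; never consumed by model fitting."""

    coefficients: dict           # per-sex raw-unit logit coefficients per covariate
    intercepts: dict             # per-sex raw-unit intercept
    coefficients_per_sd: dict    # the per-SD coefficients shared by both sexes
    source_tables: dict          # per-sex full source-population DataFrame
    true_p5: dict                # per-sex true 5-yr fracture probabilities


def _sample_ages(rng: np.random.Generator, n: int, age_range) -> np.ndarray:
    lo, hi = age_range
    ages = lo + (hi - lo) * rng.beta(1.2, 2.5, size=n)
    return np.minimum(ages, 90.0)  # ages above 90 coded as 90


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Generate a per-sex source population and sample a case-cohort table.

    The returned table holds all fracture cases (within 10 yr) plus a
    random subcohort flagged ``random_sample``; sexes share one age
    distribution (age-matched) and the per-sex fracture:control ratio in
    the full table is approximately 1:1.
    """
    spec.validate()
    master = np.random.default_rng(spec.seed)
    sex_seeds = {"F": master.integers(2**31), "M": master.integers(2**31)}

    frames = []
    gt_coef: dict = {}
    gt_int: dict = {}
    gt_sources: dict = {}
    gt_p5: dict = {}
    for sex in ("F", "M"):
        rng = np.random.default_rng(sex_seeds[sex])
        n = int(spec.n_per_sex[sex])
        age = _sample_ages(rng, n, spec.age_range)
        z_age = (age - age.mean()) / age.std()

        params = spec.trait_params
        sp_str = params["femoral_strength"]
        r2_sa = sp_str["r2_age"][sex]
        rho = sp_str["sign_age"] * np.sqrt(r2_sa)  # corr(strength, age)
        z_str = rho * z_age + np.sqrt(1 - r2_sa) * rng.standard_normal(n)
        strength = np.clip(
            sp_str["mean"][sex] + sp_str["sd"][sex] * z_str, sp_str["lo"], sp_str["hi"]
        )

        cols = {"age": age, "femoral_strength": strength}
        z_cols = {"age": z_age, "femoral_strength": z_str}
        for trait in TRAIT_NAMES:
            p = params[trait]
            c_a = p["sign_age"] * np.sqrt(p["r2_age"][sex])
            c_s = p["sign_strength"] * np.sqrt(p["r2_strength"][sex])
            a = (c_a - rho * c_s) / (1 - rho**2)
            b = (c_s - rho * c_a) / (1 - rho**2)
            resid = 1.0 - (a**2 + b**2 + 2 * a * b * rho)
            if resid <= 1e-9:
                raise ValueError(
                    f"infeasible R^2 targets for {trait}: implied residual "
                    "variance is not positive"
                )
            z_t = a * z_age + b * z_str + np.sqrt(resid) * rng.standard_normal(n)
            cols[trait] = np.clip(
                p["mean"][sex] + p["sd"][sex] * z_t, p["lo"], p["hi"]
            )
            z_cols[trait] = z_t

        # outcome model: logistic in the eight covariates (per-SD scale),
        # intercept solved so the population 5-yr rate matches base_rate
        eta = np.zeros(n)
        for cov, beta_sd in spec.outcome_coefficients.items():
            eta += beta_sd * z_cols[cov]
        target = spec.base_rate[sex]
        alpha = brentq(lambda a0: expit(a0 + eta).mean() - target, -30.0, 30.0)
        p5 = expit(alpha + eta)

        # raw-unit generating coefficients (for parameter-recovery tests)
        coef_raw = {}
        alpha_raw = alpha
        for cov, beta_sd in spec.outcome_coefficients.items():
            x = cols[cov]
            coef_raw[cov] = beta_sd / x.std()
            alpha_raw -= coef_raw[cov] * x.mean()
        gt_coef[sex] = coef_raw
        gt_int[sex] = alpha_raw

        u = rng.uniform(size=n)
        frac5 = u < p5
        p_late = np.clip(spec.late_fracture_factor * p5, 0.0, 0.5)
        late = (~frac5) & (rng.uniform(size=n) < p_late)
        fracture_time = np.full(n, np.nan)
        fracture_time[frac5] = rng.uniform(0.1, 4.99, size=int(frac5.sum()))
        fracture_time[late] = rng.uniform(5.01, 9.99, size=int(late.sum()))

        followup = np.full(n, 10.0)
        never = ~frac5 & ~late
        drop = never & (rng.uniform(size=n) < spec.dropout_rate)
        followup[drop] = rng.uniform(0.5, 4.9, size=int(drop.sum()))
        followup[late] = fracture_time[late]

        treated = rng.uniform(size=n) < spec.treated_rate
        treated_days = np.where(treated, rng.integers(180, 720, size=n), 0)
        short_course = (~treated) & (rng.uniform(size=n) < 0.05)
        treated_days = np.where(
            short_course, rng.integers(1, 179, size=n), treated_days
        )

        # FRAX: monotone in the true logit plus clinical noise, with the
        # 3%-positive rate pinned to its per-sex target by construction
        frax_lin = spec.frax_slope * (alpha + eta) + rng.normal(
            0.0, spec.frax_noise_sd, size=n
        )
        target_pr = spec.frax_positive_rate[sex]
        c = logit_fn(0.03) - np.quantile(frax_lin, 1.0 - target_pr)
        frax = 100.0 * expit(frax_lin + c)

        tsp = spec.t_score_params
        r = spec.t_score_strength_corr
        tcols = {}
        for tname, tp in tsp.items():
            z = r * z_str + np.sqrt(1 - r**2) * rng.standard_normal(n)
            tcols[tname] = tp["mean"][sex] + tp["sd"][sex] * z

        n_sites_total = sum(spec.n_sites)
        site = rng.integers(0, n_sites_total, size=n)

        df = pd.DataFrame(
            {
                "id": [f"{sex}{i:06d}" for i in range(n)],
                "sex": sex,
                **{k: cols[k] for k in MODEL_COVARIATES},
                **tcols,
                "frax_hip_risk": frax,
                "fracture_time": fracture_time,
                "followup_time": followup,
                "treated_days": treated_days,
                "site": site,
            }
        )
        gt_sources[sex] = df.copy()
        gt_p5[sex] = p5

        is_case = ~np.isnan(fracture_time)
        n_cases = int(is_case.sum())
        n_random = (
            int(spec.n_random_per_sex[sex])
            if spec.n_random_per_sex
            else n_cases
        )
        n_random = min(n_random, n)
        random_idx = rng.choice(n, size=n_random, replace=False)
        in_random = np.zeros(n, dtype=bool)
        in_random[random_idx] = True
        keep = is_case | in_random
        sub = df.loc[keep].copy()
        sub["random_sample"] = in_random[keep]
        frames.append(sub)

    table = pd.concat(frames, ignore_index=True)
    gt = CohortGroundTruth(
        coefficients=gt_coef,
        intercepts=gt_int,
        coefficients_per_sd=dict(spec.outcome_coefficients),
        source_tables=gt_sources,
        true_p5=gt_p5,
    )
    return table, gt


def split_development_validation(
    cohort: pd.DataFrame,
    dev_sites=None,
    val_sites=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint split of a cohort by site label (geographic partition).

    Membership is a pure function of ``site``.  Raises if either side of
    the partition is empty.
    """
    if dev_sites is None or val_sites is None:
        dev_sites, val_sites = DEFAULT_SITE_SPLIT
    dev_sites, val_sites = set(dev_sites), set(val_sites)
    if dev_sites & val_sites:
        raise ValueError("site partition sides overlap")
    present = set(cohort["site"].unique())
    uncovered = present - dev_sites - val_sites
    if uncovered:
        raise ValueError(f"sites {sorted(uncovered)} are in neither partition side")
    dev = cohort[cohort["site"].isin(dev_sites)].copy()
    val = cohort[cohort["site"].isin(val_sites)].copy()
    if len(dev) == 0 or len(val) == 0:
        raise ValueError("site partition leaves one side empty")
    return dev, val
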