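"""Synthetic ground-truth generators.

No raw micrographs accompany the measurements this package reproduces, so
every pipeline stage is exercised against constructed inputs whose true
volumes are known:

* :func:`gen_revolved_silhouette` — rasterized half-silhouettes of
  rotationally symmetric bodies (rotational ellipsoid, cylinder shell, and
  a champagne-flute lorica profile) with ground-truth volumes from closed
  forms or high-resolution trapezoid integration of the parametric profile;
* :func:`gen_granule_stack` — fields of non-overlapping spherical granules
  inside a bounding cell ellipsoid, voxelized into a binary Z-stack whose
  per-granule voxel counts are the exact raster truth;
* :func:`gen_divider_population` — cohorts of staged specimens whose
  lorica-forming-material volumes follow per-stage zero-inflated lognormal
  distributions calibrated to the published stage means and spreads.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PackingError, ValidationError
from .geometry import Silhouette, ellipsoid_volume
from .staging import (
    DEFAULT_CATEGORY_THRESHOLDS,
    DivisionStage,
    classify_lfm_category,
)
from .cohort import SpecimenRecord
from .stacks import PortionBoundaries, ZStack

__all__ = [
    "LoricaProfileSpec",
    "GranuleFieldSpec",
    "PopulationSpec",
    "SilhouetteFixture",
    "GranuleStackFixture",
    "gen_revolved_silhouette",
    "gen_granule_stack",
    "gen_divider_population",
    "gen_wall_volumes",
    "STAGE_LFM_MEANS",
    "STAGE_LFM_SIGMAS",
    "STAGE_ZERO_FRACTIONS",
    "STAGE_CELL_DIMS",
]

# ---------------------------------------------------------------------------
# published per-stage study conditions used as generator defaults

#: Mean total LFM volume (µm³) of the volumetrically analysed specimens per
#: divider stage; production starts at the early-divider stage, whose mean
#: is taken as 0.
STAGE_LFM_MEANS: dict[DivisionStage, float] = {
    DivisionStage.ED: 0.0,
    DivisionStage.EMD: 982.0,
    DivisionStage.LMD: 3_212.0,
    DivisionStage.ELD: 8_624.0,
    DivisionStage.VLD: 12_679.0,
}

#: Log-scale dispersion of the positive LFM component per stage.  EMD and
#: LMD are fitted to the reported within-stage maxima (1,037 and 4,474 µm³
#: at n = 3), VLD to the reported 5.3-fold spread at n = 5; the ELD value
#: is set slightly below the 2.4-fold-implied 0.42 so that the modal
#: category of early late dividers stays "high", matching the observed
#: category composition (see docs/methods.md).
STAGE_LFM_SIGMAS: dict[DivisionStage, float] = {
    DivisionStage.ED: 0.0,
    DivisionStage.EMD: 0.065,
    DivisionStage.LMD: 0.39,
    DivisionStage.ELD: 0.30,
    DivisionStage.VLD: 0.717,
}

#: Fraction of specimens per stage without any detectable LFM (category 0):
#: about half of the early middle dividers carry material, all later
#: dividers do.  Early dividers are effectively all-zero (their stage mean
#: is 0, taken as the onset of production; the occasional trace-LFM early
#: divider has no published volume and is not emulated).
STAGE_ZERO_FRACTIONS: dict[DivisionStage, float] = {
    DivisionStage.ED: 1.0,
    DivisionStage.EMD: 0.49,
    DivisionStage.LMD: 0.0,
    DivisionStage.ELD: 0.0,
    DivisionStage.VLD: 0.0,
}

#: Mean contracted cell length × width (µm) per stage.
STAGE_CELL_DIMS: dict[DivisionStage, tuple[float, float]] = {
    DivisionStage.MORPHOSTATIC: (72.0, 61.0),
    DivisionStage.ED: (81.0, 66.0),
    DivisionStage.EMD: (97.0, 71.0),
    DivisionStage.LMD: (97.0, 71.0),
    DivisionStage.ELD: (104.0, 73.0),
    DivisionStage.VLD: (104.0, 73.0),
    DivisionStage.POSTDIVIDER: (72.0, 61.0),
}

#: Typical anterior/middle/posterior split of the LFM per stage, encoding
#: the translocation of material into the proter: scattered in early middle
#: dividers, ringed around the primordium in late middle dividers, and
#: almost entirely anterior just before fission.
STAGE_PORTION_FRACTIONS: dict[DivisionStage, tuple[float, float, float]] = {
    DivisionStage.ED: (0.34, 0.33, 0.33),
    DivisionStage.EMD: (0.30, 0.40, 0.30),
    DivisionStage.LMD: (0.25, 0.55, 0.20),
    DivisionStage.ELD: (0.45, 0.45, 0.10),
    DivisionStage.VLD: (0.90, 0.10, 0.00),
}

#: Default per-stage specimen counts for a generated cohort.  The divider
#: frequencies follow the field-cohort counts (210 early, 70 middle, 43
#: late dividers), with middle and late counts split evenly between their
#: substages.
DEFAULT_STAGE_COUNTS: dict[DivisionStage, int] = {
    DivisionStage.ED: 210,
    DivisionStage.EMD: 35,
    DivisionStage.LMD: 35,
    DivisionStage.ELD: 22,
    DivisionStage.VLD: 21,
}


# ---------------------------------------------------------------------------
# revolved silhouettes

@dataclass
class LoricaProfileSpec:
    """Parametric champagne-flute lorica profile.

    The outer radius is a rounded aboral end (spherical cap of radius
    ``aboral_radius_um``) continued by a flaring bowl following a power law
    up to ``opening_radius_um`` at the oral opening; the wall has constant
    radial thickness.  A deliberately simple two-piece smooth test profile,
    not a morphometric model of any species.
    """

    total_length_um: float = 175.0
    opening_radius_um: float = 30.0
    aboral_radius_um: float = 8.0
    flare_exponent: float = 2.0
    wall_thickness_um: float = 1.5
    resolution_px_per_um: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "total_length_um", "opening_radius_um", "aboral_radius_um",
            "wall_thickness_um", "resolution_px_per_um",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.aboral_radius_um >= self.total_length_um:
            raise ValidationError("aboral radius must be shorter than the lorica")
        if self.wall_thickness_um >= min(
            self.aboral_radius_um, self.opening_radius_um
        ):
            raise ValidationError(
                "wall thickness must be smaller than every outer radius"
            )

    def outer_radius(self, z: np.ndarray) -> np.ndarray:
        """Outer radius (µm) at axial position ``z`` (µm from aboral tip)."""
        z = np.asarray(z, dtype=float)
        a = self.aboral_radius_um
        cap = np.sqrt(np.clip(z * (2 * a - z), 0.0, None))
        t = np.clip((z - a) / (self.total_length_um - a), 0.0, 1.0)
        bowl = a + (self.opening_radius_um - a) * t**self.flare_exponent
        return np.where(z < a, cap, bowl) * (z >= 0) * (z <= self.total_length_um)

    def inner_radius(self, z: np.ndarray) -> np.ndarray:
        """Inner radius (µm): outer minus the wall thickness, with a closed
        aboral floor of one wall thickness."""
        z = np.asarray(z, dtype=float)
        r = np.clip(self.outer_radius(z) - self.wall_thickness_um, 0.0, None)
        return np.where(z >= self.wall_thickness_um, r, 0.0)


@dataclass
class SilhouetteFixture:
    """A rasterized silhouette pair with its ground-truth volumes (µm³)."""

    outer: Silhouette
    inner: Silhouette | None
    truth: dict


def _rasterize_half(radius_um, length_um: float, px_per_um: float) -> np.ndarray:
    """Half-silhouette raster: row i is axial, column j foreground iff the
    pixel centre lies inside the radius (pixel-edge axis at column 0)."""
    n_rows = int(round(length_um * px_per_um))
    z = (np.arange(n_rows) + 0.5) / px_per_um
    r_px = np.asarray(radius_um(z), dtype=float) * px_per_um
    n_cols = max(int(np.ceil(r_px.max())), 1)
    cols = np.arange(n_cols) + 0.5
    return cols[None, :] < r_px[:, None]


def _revolved_truth_trapezoid(radius_um, length_um: float,
                              px_per_um: float, oversample: int = 10) -> float:
    """Reference volume by trapezoid integration of pi*r(z)**2 at
    ``oversample`` times the raster resolution."""
    n = int(round(length_um * px_per_um * oversample)) + 1
    z = np.linspace(0.0, length_um, n)
    integrand = math.pi * np.asarray(radius_um(z), dtype=float) ** 2
    return float(np.trapezoid(integrand, z))


def gen_revolved_silhouette(spec) -> SilhouetteFixture:
    """Rasterize a rotationally symmetric body as half-silhouette(s).

    ``spec`` is either a :class:`LoricaProfileSpec` (yields outer and inner
    wall silhouettes plus outer/inner/wall ground truths) or a tuple
    ``(length_um, width_um[, px_per_um])`` for a rotational ellipsoid
    (outer silhouette only, closed-form ground truth).

    Ground truths for parametric profiles come from trapezoid integration
    of the profile at 10× the raster resolution; closed forms are included
    where available.
    """
    if isinstance(spec, LoricaProfileSpec):
        scale = 1.0 / spec.resolution_px_per_um
        outer_mask = _rasterize_half(
            spec.outer_radius, spec.total_length_um, spec.resolution_px_per_um
        )
        inner_mask = _rasterize_half(
            spec.inner_radius, spec.total_length_um, spec.resolution_px_per_um
        )
        outer_truth = _revolved_truth_trapezoid(
            spec.outer_radius, spec.total_length_um, spec.resolution_px_per_um
        )
        inner_truth = _revolved_truth_trapezoid(
            spec.inner_radius, spec.total_length_um, spec.resolution_px_per_um
        )
        return SilhouetteFixture(
            outer=Silhouette(outer_mask, scale=scale),
            inner=Silhouette(inner_mask, scale=scale),
            truth={
                "outer_um3": outer_truth,
                "inner_um3": inner_truth,
                "wall_um3": outer_truth - inner_truth,
            },
        )
    # rotational ellipsoid given as (length, width[, px_per_um])
    length, width, *rest = spec
    px_per_um = rest[0] if rest else 10.0
    if length <= 0 or width <= 0 or px_per_um <= 0:
        raise ValidationError("ellipsoid spec values must be > 0")

    def radius(z):
        z = np.asarray(z, dtype=float)
        half = length / 2.0
        return (width / 2.0) * np.sqrt(
            np.clip(1.0 - ((z - half) / half) ** 2, 0.0, None)
        )

    mask = _rasterize_half(radius, length, px_per_um)
    return SilhouetteFixture(
        outer=Silhouette(mask, scale=1.0 / px_per_um),
        inner=None,
        truth={
            "outer_um3": ellipsoid_volume(length, width),
            "outer_um3_trapezoid": _revolved_truth_trapezoid(
                radius, length, px_per_um
            ),
        },
    )


# ---------------------------------------------------------------------------
# granule stacks

@dataclass
class GranuleFieldSpec:
    """Field of spherical LFM granules in a bounding cell ellipsoid.

    The cell's longitudinal axis runs along the in-plane ``y`` axis of the
    stack (the cell is imaged in ventral view); the bounding ellipsoid has
    semi-axes length/2 along y and width/2 along x and z.  Granule radii
    follow a two-component mixture of small and large granules.  The
    ``bias`` mode shifts granule placement: ``"uniform"`` anywhere in the
    cell, ``"ring-around-primordium"`` peripherally at the level between
    the two portion cuts, ``"anterior-cluster"`` entirely anterior to the
    first cut (the distribution just before fission).
    """

    cell_length_um: float = 40.0
    cell_width_um: float = 25.0
    n_granules: int = 60
    radius_small_um: float = 1.0
    radius_large_um: float = 2.5
    fraction_large: float = 0.4
    bias: str = "uniform"
    voxel_xy: float = 0.25
    voxel_z: float = 0.5
    anterior_cut_um: float | None = None   # default: 40% of cell length
    posterior_cut_um: float | None = None  # default: 70% of cell length
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_length_um <= 0 or self.cell_width_um <= 0:
            raise ValidationError("cell dimensions must be > 0")
        if min(self.radius_small_um, self.radius_large_um) <= 0:
            raise ValidationError("granule radii must be > 0")
        if not 0 <= self.fraction_large <= 1:
            raise ValidationError("fraction_large must be within [0, 1]")
        if self.bias not in ("uniform", "ring-around-primordium",
                             "anterior-cluster"):
            raise ValidationError(f"unknown bias mode {self.bias!r}")
        if self.n_granules < 1:
            raise ValidationError("need at least one granule")
        if max(self.radius_small_um, self.radius_large_um) >= self.cell_width_um / 2:
            raise ValidationError("granules do not fit inside the cell")
        if self.anterior_cut_um is None:
            self.anterior_cut_um = 0.4 * self.cell_length_um
        if self.posterior_cut_um is None:
            self.posterior_cut_um = 0.7 * self.cell_length_um
        if not 0 < self.anterior_cut_um < self.posterior_cut_um < self.cell_length_um:
            raise ValidationError("cuts must satisfy 0 < anterior < posterior < length")


@dataclass
class GranuleStackFixture:
    """Voxelized granule field with raster and analytic ground truths."""

    stack: ZStack
    bounds: PortionBoundaries
    centers_um: np.ndarray
    radii_um: np.ndarray
    truth: dict


_MAX_PLACEMENT_ATTEMPTS = 10_000


def _place_granules(spec: GranuleFieldSpec, rng: np.random.Generator):
    """Rejection-sample granule centres and radii inside the cell."""
    semi = np.array([
        spec.cell_width_um / 2.0,   # z
        spec.cell_length_um / 2.0,  # y (longitudinal)
        spec.cell_width_um / 2.0,   # x
    ])
    centre = semi.copy()
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < spec.n_granules:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise PackingError(
                f"packing failure: placed {len(centers)} of "
                f"{spec.n_granules} granules in {attempts} attempts; "
                "request fewer or smaller granules"
            )
        attempts += 1
        r = (
            spec.radius_large_um
            if rng.random() < spec.fraction_large
            else spec.radius_small_um
        )
        pos = rng.uniform(0.0, 2 * semi)
        # whole granule inside the bounding ellipsoid
        margin = semi - r
        if np.any(margin <= 0):
            raise PackingError("granule radius exceeds a cell semi-axis")
        if np.sum(((pos - centre) / margin) ** 2) > 1.0:
            continue
        y = pos[1]
        if spec.bias == "anterior-cluster":
            if y + r > spec.anterior_cut_um:
                continue
        elif spec.bias == "ring-around-primordium":
            if not (spec.anterior_cut_um <= y <= spec.posterior_cut_um):
                continue
            radial = math.hypot(pos[0] - centre[0], pos[2] - centre[2])
            if radial < 0.45 * (spec.cell_width_um / 2.0):
                continue
        if not spec.allow_overlap and centers:
            d = np.linalg.norm(np.asarray(centers) - pos, axis=1)
            if np.any(d < np.asarray(radii) + r):
                continue
        centers.append(pos)
        radii.append(r)
    return np.asarray(centers), np.asarray(radii)


def gen_granule_stack(spec: GranuleFieldSpec) -> GranuleStackFixture:
    """Generate a binary granule Z-stack with known ground-truth volumes.

    The raster truth is the voxel count of every granule rasterized on the
    stack grid (granules are non-overlapping by default, so the total is
    their sum; with ``allow_overlap`` the union count is used); the
    analytic sphere volumes are included for reference.  Per-portion truths
    apply the same voxel-centre assignment rule as
    :func:`loricavol.stacks.partition_volumes`.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_granules(spec, rng)

    shape = (
        int(round(spec.cell_width_um / spec.voxel_z)),    # z
        int(round(spec.cell_length_um / spec.voxel_xy)),  # y
        int(round(spec.cell_width_um / spec.voxel_xy)),   # x
    )
    pitch = np.array([spec.voxel_z, spec.voxel_xy, spec.voxel_xy])
    mask = np.zeros(shape, dtype=bool)
    voxel_um3 = spec.voxel_xy**2 * spec.voxel_z

    per_granule_voxels = []
    portion_voxels = np.zeros(3, dtype=np.int64)
    cuts = (spec.anterior_cut_um, spec.posterior_cut_um)
    for pos, r in zip(centers, radii):
        lo = np.maximum(np.floor((pos - r) / pitch - 1), 0).astype(int)
        hi = np.minimum(np.ceil((pos + r) / pitch + 1), shape).astype(int)
        grids = np.meshgrid(
            *[(np.arange(lo[d], hi[d]) + 0.5) * pitch[d] for d in range(3)],
            indexing="ij",
        )
        inside = (
            sum((g - p) ** 2 for g, p in zip(grids, pos)) <= r**2
        )
        per_granule_voxels.append(int(np.count_nonzero(inside)))
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub | inside
        # portion assignment by voxel-centre y coordinate (anterior on ties)
        y_inside = grids[1][inside]
        portion_voxels[0] += np.count_nonzero(y_inside <= cuts[0])
        portion_voxels[1] += np.count_nonzero(
            (y_inside > cuts[0]) & (y_inside <= cuts[1])
        )
        portion_voxels[2] += np.count_nonzero(y_inside > cuts[1])

    total_voxels = (
        int(np.count_nonzero(mask)) if spec.allow_overlap
        else int(sum(per_granule_voxels))
    )
    truth = {
        "total_um3_voxel": total_voxels * voxel_um3,
        "total_um3_analytic": float(np.sum(4.0 / 3.0 * math.pi * radii**3)),
        "per_granule_um3_voxel": [v * voxel_um3 for v in per_granule_voxels],
        "portions_um3_voxel": tuple(portion_voxels * voxel_um3),
    }
    stack = ZStack(mask, voxel_xy=spec.voxel_xy, voxel_z=spec.voxel_z)
    bounds = PortionBoundaries(
        anterior_cut=spec.anterior_cut_um,
        posterior_cut=spec.posterior_cut_um,
        axis="y",
    )
    return GranuleStackFixture(
        stack=stack, bounds=bounds, centers_um=centers, radii_um=radii,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# divider populations

@dataclass
class PopulationSpec:
    """Cohort of staged specimens with zero-inflated lognormal LFM volumes.

    ``stage_means`` are the target arithmetic means of the positive LFM
    component; ``stage_sigmas`` the log-scale dispersions; ``zero_fractions``
    the per-stage probability of carrying no detectable material.  Cell
    dimensions are drawn around the per-stage mean length × width with a
    5% coefficient of variation; cell volumes use the rotational-ellipsoid
    model (the generated cells are exact rotational ellipsoids).
    """

    stage_counts: dict[DivisionStage, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_COUNTS)
    )
    stage_means: dict[DivisionStage, float] = field(
        default_factory=lambda: dict(STAGE_LFM_MEANS)
    )
    stage_sigmas: dict[DivisionStage, float] = field(
        default_factory=lambda: dict(STAGE_LFM_SIGMAS)
    )
    zero_fractions: dict[DivisionStage, float] = field(
        default_factory=lambda: dict(STAGE_ZERO_FRACTIONS)
    )
    category_thresholds: tuple[float, float] = DEFAULT_CATEGORY_THRESHOLDS
    dimension_cv: float = 0.05
    population: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.stage_counts.values()):
            raise ValidationError("stage counts must be >= 0")
        if any(s < 0 for s in self.stage_sigmas.values()):
            raise ValidationError("dispersions must be >= 0")
        if any(m < 0 for m in self.stage_means.values()):
            raise ValidationError("stage means must be >= 0")
        if any(not 0 <= p <= 1 for p in self.zero_fractions.values()):
            raise ValidationError("zero fractions must be within [0, 1]")


def _draw_lfm(stage: DivisionStage, spec: PopulationSpec,
              rng: np.random.Generator) -> float:
    mean = spec.stage_means.get(stage, 0.0)
    if mean == 0.0:
        return 0.0
    if rng.random() < spec.zero_fractions.get(stage, 0.0):
        return 0.0
    sigma = spec.stage_sigmas.get(stage, 0.0)
    if sigma == 0.0:
        return mean
    mu = math.log(mean) - sigma**2 / 2.0  # mean-matched lognormal
    return float(rng.lognormal(mu, sigma))


def gen_divider_population(spec: PopulationSpec) -> list[SpecimenRecord]:
    """Generate a cohort of :class:`~loricavol.cohort.SpecimenRecord`.

    Per stage, each specimen's total LFM is zero with the stage's zero
    fraction and otherwise a mean-matched lognormal draw; the category
    follows from the configured thresholds, the portion split from the
    stage-typical translocation fractions, and the cell volume from drawn
    ellipsoid dimensions.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpecimenRecord] = []
    for stage in sorted(spec.stage_counts):
        n = spec.stage_counts[stage]
        dims = STAGE_CELL_DIMS.get(stage, STAGE_CELL_DIMS[DivisionStage.ED])
        fractions = STAGE_PORTION_FRACTIONS.get(stage, (1 / 3, 1 / 3, 1 / 3))
        for k in range(n):
            total = _draw_lfm(stage, spec, rng)
            length = max(rng.normal(dims[0], spec.dimension_cv * dims[0]), 1.0)
            width = max(rng.normal(dims[1], spec.dimension_cv * dims[1]), 1.0)
            vol = ellipsoid_volume(length, width)
            ant, mid, post = (f * total for f in fractions)
            records.append(
                SpecimenRecord(
                    id=f"{spec.population}-{stage.code}-{k:04d}",
                    stage=stage,
                    population=spec.population,
                    lfm_total_um3=total,
                    lfm_anterior_um3=ant,
                    lfm_middle_um3=mid,
                    lfm_posterior_um3=post,
                    category=classify_lfm_category(
                        total, spec.category_thresholds
                    ),
                    cell_length_um=length,
                    cell_width_um=width,
                    cell_vol_ellipsoid_um3=vol,
                    cell_vol_shape_um3=vol,
                )
            )
    return records


def gen_wall_volumes(
    n: int = 9,
    vmin: float = 98_655.0,
    vmax: float = 136_609.0,
    seed: int = 0,
) -> list[float]:
    """Draw ``n`` lorica-wall volumes (µm³) spanning exactly [vmin, vmax].

    The extremes are pinned to the requested bounds (they are the published
    anchors); interior values are uniform draws.  Stand-in for per-lorica
    measurements that are not individually published.
    """
    if n < 2:
        raise ValidationError("need at least two wall volumes")
    if not 0 < vmin < vmax:
        raise ValidationError("require 0 < vmin < vmax")
    rng = np.random.default_rng(seed)
    interior = sorted(rng.uniform(vmin, vmax, size=n - 2))
    return [vmin, *interior, vmax]
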