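"""Solid-of-revolution volumes from binary silhouettes.

Tintinnid cells and their loricae are, to a good approximation, rotationally
symmetric about the longitudinal axis.  A binary half-silhouette (one half of
the longitudinal optical section) therefore determines the body volume: each
axial pixel column of radius ``y`` (pixels) contributes a cylinder of volume
``pi * y**2 * dx`` with ``dx`` fixed at one pixel, and the sum is converted to
µm³ with the cube of the µm/pixel scale.  This "shape function" generalises
the classical geometric-model formulas (rotational ellipsoid, cylinder) to
arbitrary profiles, and lorica *wall* volumes follow as the difference of the
outer and inner revolved volumes.

Conventions
-----------
* The rotation axis of a half-silhouette lies on the pixel-edge boundary of
  radial index 0, so the radius of a column is ``(outermost foreground index)
  + 1`` pixel widths.  This makes axis-aligned rectangles and cylinders exact.
* For a full silhouette the midline is estimated per axial position as the
  mean of the two foreground extents (a user-supplied axis overrides), and
  the volume is the mean of the two half-revolutions.
* An optional axial truncation window is applied before profile extraction,
  e.g. to cut the anterior end at the level of the peristomial rim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

from .errors import NoObjectError, ValidationError, WallGeometryError

__all__ = [
    "Silhouette",
    "RadiusProfile",
    "GeometricModel",
    "extract_radius_profile",
    "revolve_volume",
    "ellipsoid_volume",
    "cylinder_volume",
    "spherical_cap_volume",
    "wall_volume",
    "silhouette_volume",
]


@dataclass
class Silhouette:
    """A binary 2-D silhouette with physical scale.

    Parameters
    ----------
    mask:
        2-D boolean raster; foreground (True) is the object.
    scale:
        µm per pixel, > 0.
    long_axis:
        Array axis along which the cell's longitudinal (rotation) axis runs
        (0 = rows are axial positions, 1 = columns are axial positions).
    profile_kind:
        ``"half"`` if the mask is one half of the silhouette with the
        rotation axis on the low-index radial border; ``"full"`` for a
        complete silhouette whose midline must be estimated or supplied.
    truncation:
        Optional ``(start, stop)`` half-open axial pixel range applied
        before extraction (e.g. peristomial-rim crop).
    axis:
        For full silhouettes only: radial pixel coordinate of the rotation
        axis (manual bipartition).  When None the midline is estimated per
        axial position.
    """

    mask: np.ndarray
    scale: float
    long_axis: int = 0
    profile_kind: str = "half"
    truncation: tuple[int, int] | None = None
    axis: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValidationError("silhouette mask must be 2-D")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0 µm/px, got {self.scale}")
        if self.long_axis not in (0, 1):
            raise ValidationError("long_axis must be 0 or 1")
        if self.profile_kind not in ("half", "full"):
            raise ValidationError("profile_kind must be 'half' or 'full'")

    def axial_mask(self) -> np.ndarray:
        """Mask with axis 0 axial and axis 1 radial, truncation applied."""
        m = self.mask if self.long_axis == 0 else self.mask.T
        if self.truncation is not None:
            start, stop = self.truncation
            if not (0 <= start < stop <= m.shape[0]):
                raise ValidationError(
                    f"truncation {self.truncation} outside axial range "
                    f"[0, {m.shape[0]}]"
                )
            m = m[start:stop]
        return m


@dataclass
class RadiusProfile:
    """Per-axial-position radii (pixels) of a solid of revolution."""

    positions: np.ndarray
    radii: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.positions.shape != self.radii.shape:
            raise ValidationError("positions and radii must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.radii < 0):
            raise ValidationError("radii must be non-negative")
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0 µm/px, got {self.scale}")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class GeometricModel:
    """Closed-form geometric body used for whole-cell estimates.

    ``kind`` is one of ``"rotational-ellipsoid"`` (params: length, width),
    ``"cylinder"`` (params: height, diameter) or ``"spherical-cap"``
    (params: cap height, sphere radius); all parameters in µm.
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def volume(self) -> float:
        if self.kind == "rotational-ellipsoid":
            return ellipsoid_volume(self.params["length"], self.params["width"])
        if self.kind == "cylinder":
            return cylinder_volume(self.params["height"], self.params["diameter"])
        if self.kind == "spherical-cap":
            return spherical_cap_volume(self.params["height"], self.params["radius"])
        raise ValidationError(f"unknown geometric model {self.kind!r}")


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValidationError(f"{name} must be >= 0 µm, got {value}")


def ellipsoid_volume(length: float, width: float) -> float:
    """Volume of a rotational ellipsoid, ``(pi/6) * L * W**2`` in µm³.

    ``length`` is the longitudinal axis, ``width`` the (circular) transverse
    diameter.  This is the standard geometric model for contracted tintinnid
    cells measured by maximum length and width.
    """
    _check_nonnegative(length=length, width=width)
    return math.pi / 6.0 * length * width**2


def cylinder_volume(height: float, diameter: float) -> float:
    """Volume of a circular cylinder in µm³."""
    _check_nonnegative(height=height, diameter=diameter)
    return math.pi / 4.0 * diameter**2 * height


def spherical_cap_volume(height: float, radius: float) -> float:
    """Volume of a spherical cap of height ``height`` cut from a sphere of
    radius ``radius``, ``pi * h**2 * (3R - h) / 3`` in µm³."""
    _check_nonnegative(height=height, radius=radius)
    if height > 2 * radius:
        raise ValidationError("cap height cannot exceed the sphere diameter")
    return math.pi * height**2 * (3 * radius - height) / 3.0


def extract_radius_profile(silhouette: Silhouette) -> RadiusProfile:
    """Extract the per-axial-position radius profile of a silhouette.

    For a half-silhouette the radius of each axial column is the distance in
    pixel widths from the rotation axis (the low-index radial border) to the
    outer edge of the outermost foreground pixel.  For a full silhouette the
    midline is estimated per column as the mean of the two foreground
    extents and the returned radius is the root-mean-square of the two half
    radii, so that revolving it yields exactly the mean of the two
    half-revolutions.

    Axial positions without foreground are excluded.  Interior holes are
    ignored (the profile is outline-based).  A disconnected foreground
    raises a warning because the column maxima may then bridge separate
    objects.
    """
    m = silhouette.axial_mask()
    if not m.any():
        raise NoObjectError("no object: silhouette mask has no foreground")
    if label(m, connectivity=2).max() > 1:
        warnings.warn(
            "silhouette foreground is disconnected; radii are still "
            "per-column maxima",
            stacklevel=2,
        )
    has_fg = m.any(axis=1)
    positions = np.flatnonzero(has_fg)
    rows = m[positions]
    ncols = m.shape[1]
    if silhouette.profile_kind == "half":
        # outermost foreground index + 1 => pixel-edge radius
        outer = ncols - 1 - np.argmax(rows[:, ::-1], axis=1)
        radii = (outer + 1).astype(float)
    else:
        outer = ncols - 1 - np.argmax(rows[:, ::-1], axis=1)
        inner = np.argmax(rows, axis=1)
        if silhouette.axis is not None:
            axis_pos = np.full(len(rows), float(silhouette.axis))
        else:
            axis_pos = (inner + outer + 1) / 2.0  # per-column midline (px)
        r_up = (outer + 1) - axis_pos
        r_down = axis_pos - inner
        radii = np.sqrt((r_up**2 + r_down**2) / 2.0)
    return RadiusProfile(positions=positions, radii=radii, scale=silhouette.scale)


def revolve_volume(profile: RadiusProfile) -> float:
    """Revolve a radius profile about its axis: ``sum(pi * y**2) * scale**3``.

    Each axial position contributes a cylinder of unit-pixel height; the
    pixel-unit volume is converted to µm³ by the cube of the scale.
    """
    if len(profile) == 0:
        return 0.0
    return float(np.pi * np.sum(profile.radii**2) * profile.scale**3)


def silhouette_volume(silhouette: Silhouette) -> float:
    """Convenience: extract the profile and revolve it, in µm³."""
    return revolve_volume(extract_radius_profile(silhouette))


def wall_volume(outer: RadiusProfile, inner: RadiusProfile) -> float:
    """Lorica wall volume: revolved outer minus revolved inner profile, µm³.

    Both profiles must share the µm/pixel scale and a common axial
    coordinate system (the inner profile may cover a shorter axial range).
    Axial positions where the inner radius exceeds the outer one are
    physically impossible for a wall and are reported as defects; a
    non-positive net volume raises :class:`WallGeometryError`.
    """
    if outer.scale != inner.scale:
        raise ValidationError(
            f"outer and inner profiles have mismatched scales "
            f"({outer.scale} vs {inner.scale} µm/px)"
        )
    common, o_idx, i_idx = np.intersect1d(
        outer.positions, inner.positions, return_indices=True
    )
    defects = common[inner.radii[i_idx] > outer.radii[o_idx]]
    if defects.size:
        warnings.warn(
            f"inner radius exceeds outer radius at {defects.size} axial "
            f"position(s); wall is non-physical there",
            stacklevel=2,
        )
    volume = revolve_volume(outer) - revolve_volume(inner)
    if volume < 0:
        raise WallGeometryError(
            f"inner exceeds outer: wall volume would be {volume:.1f} µm³"
        )
    if volume == 0:
        warnings.warn("wall volume is 0: inner profile equals outer (non-physical)",
                      stacklevel=2)
    return float(volume)
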