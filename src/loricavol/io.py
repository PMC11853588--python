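"""File I/O and configuration.

Silhouettes are single-channel PNG/TIFF images; granule stacks are
multi-page TIFFs or lexicographically ordered PNG slice series.  Grayscale
inputs are reduced to binary masks by a single global cutoff (Otsu's
threshold on the histogram by default); no segmentation beyond that is
attempted.  Configuration is a plain-text ``key: value`` file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ValidationError
from .geometry import Silhouette
from .stacks import SurfaceMesh, ZStack

__all__ = [
    "AnalysisConfig",
    "binarize",
    "load_silhouette",
    "load_stack",
    "save_stack_tiff",
    "save_mask_png",
    "export_mesh",
    "sha256_of",
]


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings with physical scales in µm."""

    scale_um_per_px: float = 1.0
    voxel_xy: float = 0.25
    voxel_z: float = 0.5
    iso_level: float = 0.5
    category_thresholds: tuple[float, float] = (2_000.0, 8_000.0)
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale_um_per_px", "voxel_xy", "voxel_z"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        t1, t2 = self.category_thresholds
        if not 0 < t1 < t2:
            raise ValidationError("category thresholds must be ascending")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Read a plain-text ``key: value`` configuration file."""
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "category_thresholds":
                parts = [float(v) for v in value.replace(",", " ").split()]
                if len(parts) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: category_thresholds needs two values"
                    )
                kwargs[key] = tuple(parts)
            elif key == "output_dir":
                kwargs[key] = value
            elif key == "seed":
                kwargs[key] = int(value)
            elif key in ("scale_um_per_px", "voxel_xy", "voxel_z", "iso_level"):
                kwargs[key] = float(value)
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_thresholds"] = list(self.category_thresholds)
        return d


def binarize(
    image: np.ndarray,
    threshold: float | None = None,
    invert: bool = False,
) -> tuple[np.ndarray, float | None]:
    """Reduce an array to a boolean mask by a single global cutoff.

    Boolean input is passed through (optionally inverted); otherwise pixels
    strictly above the cutoff are foreground.  Without an explicit cutoff,
    Otsu's threshold on the full histogram is used.  Returns the mask and
    the cutoff applied (None for already-boolean input).
    """
    image = np.asarray(image)
    if image.dtype == bool:
        mask, used = image, None
    else:
        uniq = np.unique(image)
        if np.isin(uniq, (0, 1)).all():
            mask, used = image.astype(bool), None
        else:
            if threshold is None:
                from skimage.filters import threshold_otsu

                threshold = float(threshold_otsu(image))
            mask, used = image > threshold, float(threshold)
    if invert:
        mask = ~mask
    return mask, used


def _as_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:  # drop an alpha/colour axis, keep the first channel
        return image[..., 0]
    return image


def load_silhouette(
    path,
    scale: float,
    invert: bool = False,
    threshold: float | None = None,
    **kwargs,
) -> Silhouette:
    """Read a single-channel PNG/TIFF silhouette; foreground = nonzero
    (inverted with ``invert``).  Extra keyword arguments are forwarded to
    :class:`~loricavol.geometry.Silhouette`."""
    image = _as_gray(iio.imread(path))
    mask, _ = binarize(image, threshold=threshold, invert=invert)
    return Silhouette(mask=mask, scale=scale, **kwargs)


def load_stack(
    path,
    voxel_xy: float,
    voxel_z: float = 0.5,
    threshold: float | None = None,
    invert: bool = False,
    return_provenance: bool = False,
):
    """Read a granule stack from a multi-page TIFF or a PNG slice directory.

    Directory slices are ordered lexicographically by filename.  Grayscale
    data are binarized with a single global cutoff on the whole-stack
    histogram (Otsu by default); the cutoff used is returned in the
    provenance dict when ``return_provenance`` is set.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValidationError(f"no image slices found in {path}")
        slices = [_as_gray(iio.imread(f)) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            first = slices[0].shape
            bad = next(
                f for f, s in zip(files, slices) if s.shape != first
            )
            raise ValidationError(
                f"inconsistent slice shapes: {bad.name} is "
                f"{slices[files.index(bad)].shape}, expected {first}"
            )
        data = np.stack(slices)
        source = [f.name for f in files]
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValidationError(
                f"{path}: expected a 2-D or 3-D TIFF, got shape {data.shape}"
            )
        source = str(path)
    if data.shape[0] == 0:
        raise ValidationError(f"{path}: stack has zero slices")
    mask, used = binarize(data, threshold=threshold, invert=invert)
    stack = ZStack(mask=mask, voxel_xy=voxel_xy, voxel_z=voxel_z)
    if return_provenance:
        return stack, {"source": source, "threshold": used,
                       "binarized": used is not None}
    return stack


def save_stack_tiff(stack: ZStack, path) -> None:
    """Write the binary mask as an 8-bit multi-page TIFF (0/255)."""
    tifffile.imwrite(path, (stack.mask.astype(np.uint8) * 255))


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a 2-D boolean mask as an 8-bit PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))


def export_mesh(mesh: SurfaceMesh, path) -> None:
    """Export a surface mesh as OBJ/PLY/STL (chosen by file extension)."""
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix not in ("obj", "ply", "stl"):
        raise ValidationError(f"unsupported mesh format {suffix!r}")
    mesh.as_trimesh().export(path)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
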