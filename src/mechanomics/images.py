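"""Voxel-image data model, smoothing, bone segmentation and VOI bookkeeping.

The pipeline operates on time-lapsed, pre-registered micro-CT density volumes
(mg HA/cm^3) with isotropic voxels (10.5 um by default). Axis conventions used
throughout the package:

* arrays are indexed ``values[i, j, k]`` with 0-based indices;
* the third axis (``k``) is the femur long axis, i.e. the axial/loading
  direction;
* the physical coordinate of the *center* of voxel ``(i, j, k)`` is
  ``origin + (index + 0.5) * spacing`` (um).

Bone is segmented by Gaussian smoothing followed by a global density
threshold (395 mg HA/cm^3 by default, inclusive). Morphometric analyses are
restricted to four non-overlapping volumes of interest (VOIs): the defect
center (DC), defect periphery (DP), fracture cortex + medullary cavity (FC)
and cortex periphery (FP). VOI geometry is an *input* (produced upstream or
by :mod:`mechanomics.synth`); this module only validates and counts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, FormatError, GeometryError, ParameterError

#: Integer codes used in VOI label volumes.
VOI_CODES = {"DC": 1, "DP": 2, "FC": 3, "FP": 4}
VOI_NAMES = {v: k for k, v in VOI_CODES.items()}

DEFAULT_SPACING_UM = 10.5
DEFAULT_BONE_THRESHOLD = 395.0  # mg HA/cm^3


@dataclass
class DensityImage:
    """A 3D mineral-density volume (mg HA/cm^3) on an isotropic voxel grid.

    Parameters
    ----------
    values
        3D array of densities, indexed ``[i, j, k]`` with ``k`` the axial
        (loading) direction.
    spacing
        Isotropic voxel edge length in micrometres.
    origin
        Physical coordinate (um) of the corner of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: float = DEFAULT_SPACING_UM
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.isfinite(self.values).all():
            raise FormatError("density values must be finite")
        if not (self.spacing > 0):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if self.origin.shape != (3,):
            raise GeometryError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates (um) along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        )


@dataclass
class BoneMask:
    """Boolean bone segmentation with the threshold that produced it."""

    values: np.ndarray
    threshold_used: float
    spacing: float = DEFAULT_SPACING_UM
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("bone mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def bone_voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class VOISet:
    """Label volume for the four analysis VOIs.

    ``labels`` uses the codes 0=outside, 1=DC, 2=DP, 3=FC, 4=FP; a
    single-label grid makes the VOIs disjoint by construction. ``volumes``
    (voxel counts per VOI) is filled by :func:`validate_vois`.
    """

    labels: np.ndarray
    volumes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("VOI label volume must be 3D")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one VOI by name ('DC', 'DP', 'FC', 'FP')."""
        try:
            code = VOI_CODES[name]
        except KeyError:
            raise FormatError(f"unknown VOI name {name!r}") from None
        return self.labels == code


def gaussian_filter(
    image: DensityImage, sigma: float = 1.2, support: int = 1
) -> DensityImage:
    """Truncated Gaussian smoothing with edge renormalisation.

    The kernel is a Gaussian of width ``sigma`` (voxels) truncated to a
    ``(2*support+1)^3`` window and renormalised to sum to one. At image
    borders the kernel is renormalised over the in-image voxels (normalised
    convolution), so constant inputs are reproduced exactly everywhere and
    no padding value leaks in.

    Parameters
    ----------
    sigma
        Gaussian width in voxel units; must be positive.
    support
        Kernel half-width in voxels; must be >= 1.
    """
    if not (sigma > 0):
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if not (int(support) == support and support >= 1):
        raise ParameterError(f"support must be an integer >= 1, got {support}")
    support = int(support)

    # Normalised convolution: filter(f)/filter(1) with zero padding renormalises
    # the truncated kernel over in-image voxels only.
    num = ndimage.gaussian_filter(
        image.values, sigma=sigma, mode="constant", cval=0.0, radius=support
    )
    den = ndimage.gaussian_filter(
        np.ones_like(image.values), sigma=sigma, mode="constant", cval=0.0, radius=support
    )
    return DensityImage(num / den, spacing=image.spacing, origin=image.origin.copy())


def threshold_bone(
    image: DensityImage, threshold: float = DEFAULT_BONE_THRESHOLD
) -> BoneMask:
    """Segment bone as voxels with density >= ``threshold`` (inclusive).

    The comparison is inclusive: a voxel at exactly the threshold density
    counts as bone.
    """
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    if image.values.size == 0:
        raise EmptyInputError("cannot threshold an empty image")
    return BoneMask(
        image.values >= threshold,
        threshold_used=float(threshold),
        spacing=image.spacing,
        origin=image.origin.copy(),
    )


def validate_vois(vois: VOISet, image: DensityImage | BoneMask) -> VOISet:
    """Check a VOI label volume against an image and fill per-VOI counts.

    Raises
    ------
    GeometryError
        If the label grid shape differs from the image shape.
    FormatError
        If the grid contains codes outside {0, 1, 2, 3, 4}.
    """
    if vois.labels.shape != image.shape:
        raise GeometryError(
            f"VOI shape {vois.labels.shape} != image shape {image.shape}"
        )
    codes = np.unique(vois.labels)
    bad = set(codes.tolist()) - {0, 1, 2, 3, 4}
    if bad:
        raise FormatError(f"unknown VOI label codes: {sorted(bad)}")
    counts = np.bincount(vois.labels.ravel().astype(np.int64), minlength=5)
    vois.volumes = {name: int(counts[code]) for name, code in VOI_CODES.items()}
    return vois
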