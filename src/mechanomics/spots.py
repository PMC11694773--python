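"""Embedding of a 2D spot grid into the 3D strain field, per-spot strain
summaries, strain-region classification and spot-level QC.

Spot tables are plain :class:`pandas.DataFrame` objects with one row per
spot; the columns this module reads/writes are

========== =====================================================
barcode     unique spot identifier (string)
x, y        spot center on the section plane (um)
x3, y3, z3  spot center in volume coordinates (um, after embedding)
n_umis      total UMI count of the spot
n_genes     number of detected genes
mean_eff    mean effective strain over the spot footprint (microstrain;
            NaN when no bone element falls inside the footprint)
region      'high' / 'low' / 'reference' / 'unassigned'
========== =====================================================

The section pose is a user-supplied rigid transform (the original platform
aligns sections visually); a spot's footprint is the 55-um-diameter capture
disk around its center, extruded symmetrically to the section thickness, and
its strain summary is the arithmetic mean of ``eff_actual`` over bone
elements whose centers fall inside that footprint. Spots over pure soft
tissue stay unassigned rather than being given zero strain.

Strain regions follow the 500/1000 microstrain convention: low < 500,
high > 1000, reference in between; values exactly on a boundary fold into
the reference region so that the three labels partition all assigned spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    ConsistencyError,
    DomainError,
    EmptyGroupError,
    GeometryError,
    ParameterError,
    PoseError,
)
from .images import BoneMask
from .microfe import StrainField

SPOT_DIAMETER_UM = 55.0
DEFAULT_SECTION_THICKNESS_UM = 5.0
LOW_STRAIN_UE = 500.0
HIGH_STRAIN_UE = 1000.0

REGIONS = ("high", "low", "reference")


@dataclass
class SectionPose:
    """Rigid transform from section-plane 2D coordinates into the volume.

    ``rotation`` (3x3, proper orthonormal) and ``translation`` (um) map a
    section point ``(x, y)`` to volume coordinates ``R @ (x, y, 0) + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    section_thickness: float = DEFAULT_SECTION_THICKNESS_UM

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise PoseError("pose needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise PoseError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise PoseError("rotation determinant must be +1 (no reflection)")
        if not (self.section_thickness > 0):
            raise ParameterError("section thickness must be positive")

    @classmethod
    def identity(cls, section_thickness: float = DEFAULT_SECTION_THICKNESS_UM):
        return cls(np.eye(3), np.zeros(3), section_thickness)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, section_thickness: float = DEFAULT_SECTION_THICKNESS_UM):
        """Build from a 4x4 homogeneous matrix."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise PoseError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3], section_thickness)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_volume(self, points_2d: np.ndarray) -> np.ndarray:
        """Map (N, 2) section coordinates to (N, 3) volume coordinates."""
        p = np.atleast_2d(np.asarray(points_2d, dtype=float))
        p3 = np.column_stack([p[:, 0], p[:, 1], np.zeros(len(p))])
        return p3 @ self.rotation.T + self.translation

    def to_section(self, points_3d: np.ndarray) -> np.ndarray:
        """Inverse map: (N, 3) volume coordinates to the section frame."""
        p = np.atleast_2d(np.asarray(points_3d, dtype=float))
        return (p - self.translation) @ self.rotation


def embed_section(spots: pd.DataFrame, pose: SectionPose) -> pd.DataFrame:
    """Fill volume coordinates (x3, y3, z3) from section coordinates (x, y)."""
    if not np.isfinite(spots[["x", "y"]].to_numpy()).all():
        raise DomainError("spot 2D centers must be finite")
    out = spots.copy()
    p3 = pose.to_volume(out[["x", "y"]].to_numpy())
    out["x3"], out["y3"], out["z3"] = p3[:, 0], p3[:, 1], p3[:, 2]
    return out


def classify_strain_region(
    mean_eff,
    low: float = LOW_STRAIN_UE,
    high: float = HIGH_STRAIN_UE,
):
    """Classify strain values into 'low' / 'reference' / 'high'.

    Values exactly at a boundary go to 'reference' (closed middle interval),
    NaN maps to 'unassigned'. Accepts scalars or arrays.
    """
    arr = np.asarray(mean_eff, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise DomainError("effective strain cannot be negative")
    out = np.full(arr.shape, "unassigned", dtype=object)
    out[arr < low] = "low"
    out[arr > high] = "high"
    out[(arr >= low) & (arr <= high)] = "reference"
    out[~np.isfinite(arr)] = "unassigned"
    if np.isscalar(mean_eff) or arr.ndim == 0:
        return out.item()
    return out


def spot_strain(
    spots: pd.DataFrame,
    strain: StrainField,
    bone_mask: BoneMask,
    pose: SectionPose,
    *,
    radius: float = SPOT_DIAMETER_UM / 2.0,
    low: float = LOW_STRAIN_UE,
    high: float = HIGH_STRAIN_UE,
) -> pd.DataFrame:
    """Summarise the strain field over each spot footprint and classify it.

    The footprint is a disk of ``radius`` um around the spot center in the
    section plane, extruded symmetrically over the section thickness;
    ``mean_eff`` is the arithmetic mean of ``eff_actual`` over bone-mask
    elements whose centers fall inside it (element centers, no
    partial-volume weighting — elements are ~10.5 um against a 55 um spot).
    Spots with no qualifying element get NaN and region 'unassigned'.
    """
    if strain.eff_actual is None:
        raise ParameterError("strain field has no eff_actual; call scale_strains first")
    if bone_mask.shape != strain.shape:
        raise GeometryError("bone mask and strain field shapes differ")
    if not np.isclose(bone_mask.spacing, strain.spacing):
        raise GeometryError(
            f"spacing mismatch: mask {bone_mask.spacing} vs field {strain.spacing}"
        )
    out = embed_section(spots, pose) if "x3" not in spots.columns else spots.copy()

    bone_idx = np.argwhere(bone_mask.values)
    mean_eff = np.full(len(out), np.nan)
    if bone_idx.size:
        centers = strain.origin + (bone_idx + 0.5) * strain.spacing
        local = pose.to_section(centers)
        in_slab = np.abs(local[:, 2]) <= pose.section_thickness / 2.0 + 1e-9
        slab_local = local[in_slab]
        slab_eff = strain.eff_actual[tuple(bone_idx[in_slab].T)]
        if len(slab_local):
            tree = cKDTree(slab_local[:, :2])
            hits = tree.query_ball_point(out[["x", "y"]].to_numpy(), r=radius + 1e-9)
            for s, idx in enumerate(hits):
                if idx:
                    mean_eff[s] = float(slab_eff[idx].mean())
    out["mean_eff"] = mean_eff
    out["region"] = classify_strain_region(mean_eff, low=low, high=high)
    return out


def qc_filter_spots(
    spots: pd.DataFrame,
    counts,
    min_umis: int = 500,
    min_genes: int = 250,
) -> tuple[pd.DataFrame, list[str]]:
    """Retain spots with >= min_umis UMIs and >= min_genes detected genes.

    Both thresholds are inclusive. UMI and gene counts are taken from the
    count matrix; a spot barcode missing from the matrix raises.

    Returns the retained table (with ``n_umis``/``n_genes`` columns filled)
    and the list of removed barcodes.
    """
    from .expression import CountMatrix  # local import to avoid cycle

    if isinstance(counts, CountMatrix):
        col = {b: i for i, b in enumerate(counts.barcodes)}
        missing = [b for b in spots["barcode"] if b not in col]
        if missing:
            raise ConsistencyError(
                f"{len(missing)} spot barcode(s) absent from the count matrix, "
                f"e.g. {missing[:3]}"
            )
        mat = counts.dense()
        idx = np.array([col[b] for b in spots["barcode"]])
        n_umis = mat[:, idx].sum(axis=0)
        n_genes = (mat[:, idx] > 0).sum(axis=0)
    else:
        raise TypeError("counts must be a CountMatrix")
    out = spots.copy()
    out["n_umis"] = np.asarray(n_umis).astype(int)
    out["n_genes"] = np.asarray(n_genes).astype(int)
    keep = (out["n_umis"] >= min_umis) & (out["n_genes"] >= min_genes)
    removed = out.loc[~keep, "barcode"].tolist()
    return out[keep].reset_index(drop=True), removed


def region_qc_stats(
    spots: pd.DataFrame, regions: list[str] | None = None
) -> pd.DataFrame:
    """Per-region medians of UMI and gene counts.

    Medians use the standard even-count convention (mean of the middle two).
    Raises if a requested region has no spots.
    """
    wanted = list(regions) if regions is not None else sorted(spots["region"].unique())
    rows = []
    for region in wanted:
        sub = spots[spots["region"] == region]
        if sub.empty:
            raise EmptyGroupError(f"no spots in region {region!r}")
        rows.append(
            {
                "region": region,
                "n_spots": len(sub),
                "median_umis": float(sub["n_umis"].median()),
                "median_genes": float(sub["n_genes"].median()),
            }
        )
    return pd.DataFrame(rows)
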