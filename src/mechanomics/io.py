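"""Readers and writers for the pipeline's file dialects.

Volumes travel as NIfTI (via nibabel; spacing stored in the affine, mm) or
MetaImage (via SimpleITK, optional extra); 2D section rasters as TIFF.
Strain fields export as ASCII VTK ImageData (.vti) with cell-data arrays in
microstrain, loadable in ParaView. Counts use the 10x convention
(Matrix-Market .mtx + features.tsv + barcodes.tsv), spot positions the
Visium tissue_positions CSV plus a pixel-size scale, poses a small YAML
file holding a 4x4 matrix, and gene sets the GMT format.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nibabel as nib
import scipy.io as sio
import scipy.sparse as sp

from .errors import FormatError
from .expression import CountMatrix
from .images import DensityImage, VOISet
from .microfe import StrainField
from .spots import SectionPose

# ---------------------------------------------------------------------------
# Volumes


def write_nifti(path, volume: np.ndarray, spacing_um: float) -> None:
    """Write a 3D array as NIfTI with isotropic spacing (stored in mm)."""
    affine = np.diag([spacing_um / 1000.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, isotropic spacing in um)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise FormatError(f"anisotropic spacing {zooms} not supported")
    return np.asanyarray(img.dataobj), float(zooms[0]) * 1000.0


def write_density_image(path, image: DensityImage) -> None:
    write_nifti(path, image.values, image.spacing)


def read_density_image(path) -> DensityImage:
    values, spacing = read_nifti(path)
    return DensityImage(np.asarray(values, dtype=float), spacing=spacing)


def write_labels(path, labels: np.ndarray, spacing_um: float) -> None:
    """Write an integer label volume (VOIs or remodeling classes)."""
    write_nifti(path, np.asarray(labels, dtype=np.int16), spacing_um)


def read_vois(path) -> VOISet:
    values, _ = read_nifti(path)
    return VOISet(labels=np.asarray(values, dtype=np.int16))


def write_metaimage(path, volume: np.ndarray, spacing_um: float) -> None:
    """Write a volume as MetaImage (.mha); requires SimpleITK."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.moveaxis(volume, (0, 1, 2), (2, 1, 0))))
    img.SetSpacing([spacing_um] * 3)
    sitk.WriteImage(img, str(path))


def read_metaimage(path) -> tuple[np.ndarray, float]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0]):
        raise FormatError(f"anisotropic spacing {spacing} not supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return np.moveaxis(arr, (0, 1, 2), (2, 1, 0)), float(spacing[0])


def write_section_tiff(path, raster: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(raster))


def read_section_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# VTK ImageData export (ASCII .vti, cell data)


def write_vti(path, arrays: dict[str, np.ndarray], spacing_um: float,
              origin_um=(0.0, 0.0, 0.0)) -> None:
    """Write per-element (cell) scalar arrays as ASCII VTK ImageData.

    All arrays must share one 3D shape; the written extent has one more
    point than cells per axis. Readable in ParaView.
    """
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise FormatError("all cell arrays must share one shape")
    (nx, ny, nz), = shapes
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {nx} 0 {ny} 0 {nz}" '
        f'Origin="{origin_um[0]} {origin_um[1]} {origin_um[2]}" '
        f'Spacing="{spacing_um} {spacing_um} {spacing_um}">',
        f'    <Piece Extent="0 {nx} 0 {ny} 0 {nz}">',
        "      <CellData>",
    ]
    for name, arr in arrays.items():
        # VTK cell order is x-fastest; our arrays are [i, j, k] C-ordered.
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
        body = " ".join(f"{v:.9g}" for v in flat)
        lines.append(
            f'        <DataArray type="Float64" Name="{name}" format="ascii">'
        )
        lines.append(f"          {body}")
        lines.append("        </DataArray>")
    lines += ["      </CellData>", "    </Piece>", "  </ImageData>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


def write_strain_field(path, field: StrainField) -> None:
    """Export a strain field (eff_sim and, if present, eff_actual) as .vti."""
    arrays = {"eff_sim_ue": field.eff_sim}
    if field.eff_actual is not None:
        arrays["eff_actual_ue"] = field.eff_actual
    write_vti(path, arrays, field.spacing, tuple(field.origin))


# ---------------------------------------------------------------------------
# Spots


def read_tissue_positions(path, pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Read a Visium-style tissue_positions CSV into a spot table.

    Expects columns (barcode, in_tissue, array_row, array_col, pixel_row,
    pixel_col), header optional; pixel coordinates are converted to um with
    ``pixel_size_um``. Only in-tissue spots are returned.
    """
    names = ["barcode", "in_tissue", "array_row", "array_col", "pixel_row", "pixel_col"]
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 1], str)
    df = pd.read_csv(path, header=0 if has_header else None, names=names)
    df = df[df["in_tissue"].astype(int) == 1].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "x": df["pixel_col"].astype(float) * pixel_size_um,
            "y": df["pixel_row"].astype(float) * pixel_size_um,
            "array_row": df["array_row"].astype(int),
            "array_col": df["array_col"].astype(int),
        }
    )
    return out


def write_spot_table(path, spots: pd.DataFrame) -> None:
    cols = [c for c in ["barcode", "x", "y", "x3", "y3", "z3", "n_umis",
                        "n_genes", "mean_eff", "region"] if c in spots.columns]
    spots[cols].to_csv(path, index=False)


def write_region_barcodes(path, spots: pd.DataFrame, region: str) -> None:
    """Loupe-compatible barcode CSV for one strain region."""
    sub = spots[spots["region"] == region]
    sub[["barcode"]].assign(region=region).to_csv(path, index=False)


def read_pose(path) -> SectionPose:
    """Read a section pose from YAML: 4x4 ``matrix`` + ``section_thickness``."""
    data = yaml.safe_load(Path(path).read_text())
    matrix = np.asarray(data["matrix"], dtype=float)
    thickness = float(data.get("section_thickness_um", 5.0))
    return SectionPose.from_matrix(matrix, section_thickness=thickness)


def write_pose(path, pose: SectionPose) -> None:
    data = {
        "matrix": pose.to_matrix().tolist(),
        "section_thickness_um": float(pose.section_thickness),
    }
    Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------------------
# Counts (10x convention) and gene sets


def read_10x_counts(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read Matrix-Market counts plus feature/barcode TSVs (genes x spots)."""
    mat = sio.mmread(str(mtx_path)).tocsr()
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    return CountMatrix(
        counts=mat,
        gene_ids=features.iloc[:, 0].astype(str).tolist(),
        barcodes=barcodes.iloc[:, 0].astype(str).tolist(),
    )


def write_10x_counts(out_dir, cm: CountMatrix) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = cm.counts if sp.issparse(cm.counts) else sp.csr_matrix(cm.counts)
    sio.mmwrite(str(out / "matrix.mtx"), mat.astype(int))
    pd.Series(cm.gene_ids).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path, sets: dict[str, list[str]]) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
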