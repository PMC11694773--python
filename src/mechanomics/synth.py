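"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators emulate the three data modalities the pipeline consumes:

* a femur-defect *phantom* — an idealised cortical tube with a
  mid-diaphyseal gap and a callus shell that grows (or resorbs) between
  time points on a prescribed schedule, so the set of formation/resorption
  voxels between any two frames is known exactly and the frames are
  pre-registered by construction;
* *striped strain fields* — piecewise-constant effective strain in axial
  bands with a known region label per element, the fixture for the
  500/1000 microstrain spot classification;
* *NB spot counts* — negative-binomial counts over a spot table with
  log-normal baseline means and size factors and planted strain-dependent
  log2 fold changes, the ground truth for the differential-expression and
  gene-set statistics.

The phantom is deliberately not anatomically realistic: ground truth must
be exact and cheap. Densities are piecewise constant with bone phases at or
above the 395 mg HA/cm^3 segmentation threshold and soft tissue below it.
A single seed fans out into per-stage substreams (`numpy` SeedSequence) so
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .images import DEFAULT_SPACING_UM, DensityImage, VOISet
from .microfe import StrainField

# ---------------------------------------------------------------------------
# Callus phantom


@dataclass
class PhantomSpec:
    """Geometry, schedule and densities of the tube-with-gap phantom.

    Lengths in micrometres. ``callus_radii`` gives the outer callus radius
    per time point (0 = no callus yet); radii may shrink to plant
    resorption. Bone-phase densities must sit at/above the segmentation
    threshold, soft tissue below it.
    """

    shape: tuple[int, int, int] = (40, 40, 48)
    spacing: float = DEFAULT_SPACING_UM
    cortex_outer_radius: float = 150.0
    cortex_inner_radius: float = 100.0
    gap_height: float = 120.0
    callus_radii: tuple[float, ...] = (0.0, 180.0, 210.0)
    cortex_density: float = 900.0
    callus_density: float = 650.0
    soft_density: float = 150.0

    def __post_init__(self):
        if not (0 < self.cortex_inner_radius < self.cortex_outer_radius):
            raise SpecError("need 0 < inner radius < outer radius")
        if self.gap_height <= 0:
            raise SpecError("gap height must be positive")
        if min(self.cortex_density, self.callus_density) < 395:
            raise SpecError("bone-phase densities must be >= 395 mg HA/cm^3")
        if self.soft_density >= 395:
            raise SpecError("soft-tissue density must be < 395 mg HA/cm^3")
        extent_xy = min(self.shape[0], self.shape[1]) * self.spacing / 2.0
        if max((*self.callus_radii, self.cortex_outer_radius)) >= extent_xy:
            raise SpecError("phantom radii exceed the grid extent")


def _phantom_coords(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    cx = nx * spec.spacing / 2.0
    cy = ny * spec.spacing / 2.0
    cz = nz * spec.spacing / 2.0
    x = (np.arange(nx) + 0.5) * spec.spacing - cx
    y = (np.arange(ny) + 0.5) * spec.spacing - cy
    z = (np.arange(nz) + 0.5) * spec.spacing - cz
    rho = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)[:, :, None]
    zz = z[None, None, :]
    return rho, zz


def phantom_masks(spec: PhantomSpec, callus_radius: float):
    """Boolean cortex and callus masks for one time point."""
    rho, zz = _phantom_coords(spec)
    in_gap = np.abs(zz) <= spec.gap_height / 2.0
    cortex = (
        (rho > spec.cortex_inner_radius)
        & (rho <= spec.cortex_outer_radius)
        & ~in_gap
    )
    callus = np.zeros(spec.shape, dtype=bool)
    if callus_radius > spec.cortex_outer_radius:
        shell = (rho > spec.cortex_outer_radius) & (rho <= callus_radius)
        # Callus spans the gap and bridges onto the adjacent cortex.
        callus = shell & (np.abs(zz) <= spec.gap_height * 1.5) | (
            (rho <= spec.cortex_outer_radius)
            & (rho > spec.cortex_inner_radius)
            & in_gap
            & (callus_radius >= spec.cortex_outer_radius)
        )
    return cortex, callus


def make_phantom_timeseries(spec: PhantomSpec):
    """Generate the phantom frames and exact remodeling ground truth.

    Returns ``(frames, bone_masks, truth)`` where ``frames`` is a list of
    :class:`DensityImage`, ``bone_masks`` the boolean bone masks each frame
    was built from, and ``truth`` a list (one per consecutive frame pair) of
    dicts with the exact boolean ``formation``/``resorption``/``quiescent``
    voxel sets.
    """
    if len(spec.callus_radii) < 1:
        raise SpecError("need at least one time point")
    frames: list[DensityImage] = []
    masks: list[np.ndarray] = []
    for radius in spec.callus_radii:
        cortex, callus = phantom_masks(spec, radius)
        values = np.full(spec.shape, spec.soft_density)
        values[callus] = spec.callus_density
        values[cortex] = spec.cortex_density
        frames.append(DensityImage(values, spacing=spec.spacing))
        masks.append(cortex | callus)
    truth = []
    for m1, m2 in zip(masks[:-1], masks[1:]):
        truth.append(
            {
                "formation": m2 & ~m1,
                "resorption": m1 & ~m2,
                "quiescent": m1 & m2,
            }
        )
    return frames, masks, truth


def make_phantom_vois(spec: PhantomSpec, periphery_radius: float | None = None) -> VOISet:
    """VOI labels for the phantom: DC/DP inside the gap, FC/FP outside.

    DC = within the outer cortical envelope at gap height, DP = annulus
    around it out to ``periphery_radius``; FC/FP are the same split outside
    the gap. The four labels are pairwise disjoint by construction.
    """
    if periphery_radius is None:
        periphery_radius = max(spec.callus_radii + (spec.cortex_outer_radius,)) + 2 * spec.spacing
    rho, zz = _phantom_coords(spec)
    in_gap = (np.abs(zz) <= spec.gap_height / 2.0) & np.ones(spec.shape, bool)
    central = (rho <= spec.cortex_outer_radius) & np.ones(spec.shape, bool)
    periph = (rho > spec.cortex_outer_radius) & (rho <= periphery_radius) & np.ones(
        spec.shape, bool
    )
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[central & in_gap] = 1  # DC
    labels[periph & in_gap] = 2  # DP
    labels[central & ~in_gap] = 3  # FC
    labels[periph & ~in_gap] = 4  # FP
    return VOISet(labels=labels)


# ---------------------------------------------------------------------------
# Striped strain fields


def make_strain_stripes(
    dims: tuple[int, int, int],
    band_values: list[float],
    spacing: float = DEFAULT_SPACING_UM,
    boundaries: list[int] | None = None,
) -> tuple[StrainField, np.ndarray]:
    """Piecewise-constant strain field in axial bands with known labels.

    ``band_values`` are effective strains (microstrain) of consecutive
    axial bands; ``boundaries`` (element indices, exclusive ends) defaults
    to equal thirds/halves etc. Returns the field (with ``eff_actual``
    filled so it can feed spot classification directly, ``f_resultant`` set
    to 1) and the per-element band index array.
    """
    nx, ny, nz = dims
    n_bands = len(band_values)
    if n_bands < 1:
        raise SpecError("need at least one band")
    if boundaries is None:
        edges = np.linspace(0, nz, n_bands + 1).round().astype(int)
    else:
        edges = np.asarray([0, *boundaries], dtype=int)
        if len(edges) != n_bands + 1 or edges[-1] != nz or (np.diff(edges) <= 0).any():
            raise SpecError("boundaries must partition the axial extent")
    eff = np.zeros(dims)
    band_index = np.zeros(dims, dtype=int)
    for b, value in enumerate(band_values):
        eff[:, :, edges[b] : edges[b + 1]] = value
        band_index[:, :, edges[b] : edges[b + 1]] = b
    field_out = StrainField(
        eff_sim=eff.copy(),
        f_resultant=1.0,
        eff_actual=eff,
        f_applied=1.0,
        spacing=spacing,
    )
    return field_out, band_index


def make_spot_grid(
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    pitch: float = 100.0,
    prefix: str = "SPOT",
) -> pd.DataFrame:
    """Square grid of spot centers over a section window (um), ~100 um pitch."""
    xs = np.arange(x_range[0], x_range[1] + 1e-9, pitch)
    ys = np.arange(y_range[0], y_range[1] + 1e-9, pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    n = gx.size
    return pd.DataFrame(
        {
            "barcode": [f"{prefix}-{i:05d}" for i in range(n)],
            "x": gx.ravel(),
            "y": gy.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# NB count simulation


@dataclass
class CountSimSpec:
    """Statistical structure of the simulated spot counts.

    Baseline gene means are log-normal (``exp(N(mean_log_mu,
    mean_log_sigma))``); set ``mean_log_sigma=0`` for a constant baseline.
    ``dispersion`` is the NB phi in Var = mu + phi mu^2 (scalar, applied to
    every gene). Per-spot size factors are log-normal with sigma
    ``size_factor_sigma`` (rescaled to geometric mean 1). ``effects`` is a
    table with columns ``gene`` (index into the simulated genes), ``group``
    (spot label that receives the effect) and ``log2fc``.
    """

    n_genes: int = 2000
    mean_log_mu: float = 1.0
    mean_log_sigma: float = 1.0
    dispersion: float = 0.1
    size_factor_sigma: float = 0.25
    effects: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise SpecError("need at least one gene")
        if not (self.dispersion > 0):
            raise SpecError("dispersion must be positive")
        if self.effects is not None:
            eff = self.effects
            required = {"gene", "group", "log2fc"}
            if not required.issubset(eff.columns):
                raise SpecError(f"effects table needs columns {sorted(required)}")
            if not np.isfinite(eff["log2fc"]).all():
                raise SpecError("planted log2fc must be finite")
            if (np.asarray(eff["gene"]) >= self.n_genes).any():
                raise SpecError("effect gene index out of range")


def simulate_counts(group_labels, spec: CountSimSpec):
    """Simulate an NB count matrix over labelled spots with planted effects.

    ``group_labels`` is one label per spot (e.g. a spot table's ``region``
    column). Counts are drawn as NB with mean
    ``sf_s * mu_g * 2**(log2fc_g * [label_s == group_g])`` and dispersion
    ``phi``. Returns ``(CountMatrix, truth)`` where truth records baseline
    means, dispersions, true size factors and the planted-effect table.
    Deterministic given ``spec.seed``.
    """
    from .expression import CountMatrix

    labels = np.asarray(group_labels)
    n_spots = len(labels)
    if n_spots < 1:
        raise SpecError("need at least one spot")
    ss = np.random.SeedSequence(spec.seed)
    rng_genes, rng_spots, rng_counts = [np.random.default_rng(s) for s in ss.spawn(3)]

    mu = np.exp(rng_genes.normal(spec.mean_log_mu, spec.mean_log_sigma, spec.n_genes))
    phi = np.full(spec.n_genes, spec.dispersion)
    sf = np.exp(rng_spots.normal(0.0, spec.size_factor_sigma, n_spots))
    sf /= np.exp(np.mean(np.log(sf)))

    log2_effect = np.zeros((spec.n_genes, n_spots))
    if spec.effects is not None:
        for _, row in spec.effects.iterrows():
            log2_effect[int(row["gene"]), labels == row["group"]] += row["log2fc"]

    mean = sf[None, :] * mu[:, None] * 2.0**log2_effect
    r = 1.0 / phi
    counts = rng_counts.negative_binomial(
        n=r[:, None], p=r[:, None] / (r[:, None] + mean)
    )
    gene_ids = [f"gene{i:05d}" for i in range(spec.n_genes)]
    barcodes = [f"SPOT-{i:05d}" for i in range(n_spots)]
    cm = CountMatrix(counts=counts, gene_ids=gene_ids, barcodes=barcodes)
    truth = {
        "mu": mu,
        "phi": phi,
        "size_factors": sf,
        "effects": spec.effects.copy() if spec.effects is not None else None,
        "labels": labels,
    }
    return cm, truth
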