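"""Voxel-hexahedral linear-elastic micro-FE.

Every voxel of a density image becomes one 8-node trilinear hexahedral
element; grayscale density is mapped to a Young's modulus (linear map by
default), soft tissue receives a small but strictly positive modulus
(0.003 GPa) and the marrow cavity on the top and bottom slices is capped
with 20 GPa plate material to suppress end artefacts. Uniaxial compression
is simulated by prescribing an axial displacement of 1% of the model height
on the top node layer while the bottom node layer is fully fixed; top-slice
in-plane displacements are left free.

Because all elements are congruent cubes, a single unit stiffness matrix
(E = 1, h = 1) is assembled per model and scaled per element by ``E_e * h``.
The solve is linear-elastic and static; the per-element *effective strain*

    EFF = sqrt(2 U / E)

with ``U`` the strain-energy density at the element centroid, is the scalar
strain measure carried downstream (reported in microstrain). Since
``U = 1/2 e^T D(E, nu) e`` and ``D`` is proportional to ``E``, EFF is
independent of a uniform rescaling of all moduli.

The unit simulation yields the field ``eff_sim`` and the resultant force
``F_resultant`` (sum of axial nodal reactions on the top surface). Linearity
then gives the strain state at any applied load:

    eff_actual = (F_applied / F_resultant) * eff_sim

and the adaptive loading rule scales the load to a median target strain,
clamps it to the prescribed 8-16 N window, and backs off in 1 N steps while
more than 100 bone voxels exceed the 10,000 microstrain overstrain limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ConvergenceError,
    GeometryError,
    MaterialError,
    OptimizationError,
    ParameterError,
    ScalingError,
)
from .images import BoneMask, DensityImage

# Node order of the hex8 element: natural coordinates (xi, eta, zeta) of the
# eight corners; node a sits at offset ((1+xi)/2, (1+eta)/2, (1+zeta)/2) of
# the voxel. DOFs are node-major (n0x, n0y, n0z, n1x, ...).
_HEX8_NAT = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)
_HEX8_OFFSETS = ((_HEX8_NAT + 1) // 2).astype(int)

DEFAULT_SOFT_MODULUS_GPA = 0.003
DEFAULT_PLATE_MODULUS_GPA = 20.0
DEFAULT_POISSON = 0.3
DEFAULT_COMPRESSION = 0.01
DEFAULT_MODULUS_SLOPE = 0.015  # GPa per (mg HA/cm^3); configurable calibration


def elastic_d_matrix(e_modulus: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix (6x6, engineering shear strains)."""
    if not (-1.0 < nu < 0.5):
        raise ParameterError(f"Poisson ratio must be in (-1, 0.5), got {nu}")
    c = e_modulus / ((1.0 + nu) * (1.0 - 2.0 * nu))
    d = np.zeros((6, 6))
    d[:3, :3] = c * nu
    np.fill_diagonal(d[:3, :3], c * (1.0 - nu))
    d[3:, 3:] = np.eye(3) * c * (1.0 - 2.0 * nu) / 2.0
    return d


def _shape_gradients(xi: float, eta: float, zeta: float) -> np.ndarray:
    """dN/d(xi,eta,zeta) for the 8 trilinear shape functions, (8, 3)."""
    g = np.empty((8, 3))
    for a, (xa, ya, za) in enumerate(_HEX8_NAT):
        g[a, 0] = 0.125 * xa * (1 + eta * ya) * (1 + zeta * za)
        g[a, 1] = 0.125 * ya * (1 + xi * xa) * (1 + zeta * za)
        g[a, 2] = 0.125 * za * (1 + xi * xa) * (1 + eta * ya)
    return g


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6x24) from shape gradients in x (8x3)."""
    b = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dndx[a]
        c = 3 * a
        b[0, c] = bx
        b[1, c + 1] = by
        b[2, c + 2] = bz
        b[3, c] = by      # gamma_xy
        b[3, c + 1] = bx
        b[4, c + 1] = bz  # gamma_yz
        b[4, c + 2] = by
        b[5, c] = bz      # gamma_zx
        b[5, c + 2] = bx
    return b


def hex8_stiffness(e_modulus: float, nu: float, h: float) -> np.ndarray:
    """Stiffness matrix (24x24) of a cube element, 2x2x2 Gauss quadrature.

    For congruent cubes the matrix scales as ``E * h``; callers exploit
    ``hex8_stiffness(E, nu, h) == E * h * hex8_stiffness(1, nu, 1)``.
    """
    d = elastic_d_matrix(e_modulus, nu)
    k = np.zeros((24, 24))
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    jac = h / 2.0  # isotropic cube: J = (h/2) I
    detj = jac**3
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                dndx = _shape_gradients(xi, eta, zeta) / jac
                b = _b_matrix(dndx)
                k += b.T @ d @ b * detj
    return 0.5 * (k + k.T)  # symmetrise roundoff


def centroid_b_matrix(h: float) -> np.ndarray:
    """B matrix at the element centroid (single-point strain evaluation)."""
    return _b_matrix(_shape_gradients(0.0, 0.0, 0.0) / (h / 2.0))


@dataclass
class FEModel:
    """Voxel FE model: per-element moduli plus boundary-condition spec."""

    element_moduli: np.ndarray  # (nx, ny, nz) Young's moduli in GPa, all > 0
    poisson_ratio: float = DEFAULT_POISSON
    spacing: float = 10.5  # um
    compression_fraction: float = DEFAULT_COMPRESSION
    plate_mask: np.ndarray | None = None  # voxels replaced by plate material

    def __post_init__(self):
        self.element_moduli = np.asarray(self.element_moduli, dtype=float)
        if self.element_moduli.ndim != 3:
            raise GeometryError("element_moduli must be 3D")
        if min(self.element_moduli.shape) < 1:
            raise GeometryError("model needs at least one element per axis")
        if not (self.element_moduli > 0).all():
            raise MaterialError("all element moduli must be strictly positive")
        if not (0.0 < self.compression_fraction <= 0.05):
            raise ParameterError(
                "compression_fraction must lie in (0, 0.05], got "
                f"{self.compression_fraction}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.element_moduli.shape


@dataclass
class StrainField:
    """Per-element effective strain plus the unit-simulation resultant force.

    ``eff_sim`` is the effective strain (microstrain) from the unit
    compression simulation, ``f_resultant`` the summed axial reaction force
    on the top-surface nodes (N), and ``eff_actual`` the field rescaled to an
    applied force (filled by :func:`scale_strains`).
    """

    eff_sim: np.ndarray  # (nx, ny, nz), microstrain
    f_resultant: float  # N
    eff_actual: np.ndarray | None = None
    f_applied: float | None = None
    spacing: float = 10.5  # um
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_top: float = np.nan
    f_bottom: float = np.nan
    equilibrium_imbalance: float = np.nan

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.eff_sim.shape

    def element_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical element-center coordinates (um) along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        )


@dataclass
class LoadPrescription:
    """Adaptive-loading parameters and the resulting applied force."""

    target_median_strain: float  # microstrain
    f_applied: float | None = None  # N
    f_min: float = 8.0
    f_max: float = 16.0
    overstrain_threshold: float = 10_000.0  # microstrain
    overstrain_voxel_limit: int = 100
    decrement: float = 1.0  # N
    single_step: bool = False
    overstrain_count: int | None = None

    def __post_init__(self):
        if not (self.decrement > 0):
            raise ParameterError("decrement must be positive")
        if not (self.f_min <= self.f_max):
            raise ParameterError("f_min must not exceed f_max")


def build_fe_model(
    image: DensityImage,
    mask: BoneMask,
    *,
    modulus_slope: float = DEFAULT_MODULUS_SLOPE,
    soft_modulus: float = DEFAULT_SOFT_MODULUS_GPA,
    plate_modulus: float = DEFAULT_PLATE_MODULUS_GPA,
    poisson_ratio: float = DEFAULT_POISSON,
    compression_fraction: float = DEFAULT_COMPRESSION,
) -> FEModel:
    """Turn a density image + bone mask into a voxel FE model.

    Bone voxels get ``E = modulus_slope * density`` (GPa); non-bone voxels
    get the soft-tissue modulus; non-bone voxels on the first and last axial
    slices are replaced by plate material so the soft marrow cavity does not
    create end artefacts under the prescribed-displacement boundary.
    """
    if image.shape != mask.shape:
        raise GeometryError("image and mask shapes differ")
    moduli = np.full(image.shape, float(soft_modulus))
    bone = mask.values
    e_bone = modulus_slope * image.values[bone]
    if bone.any() and not (e_bone > 0).all():
        raise MaterialError("density-to-modulus map produced non-positive moduli")
    moduli[bone] = e_bone
    plate = np.zeros(image.shape, dtype=bool)
    plate[:, :, 0] = ~bone[:, :, 0]
    plate[:, :, -1] = ~bone[:, :, -1]
    moduli[plate] = float(plate_modulus)
    return FEModel(
        element_moduli=moduli,
        poisson_ratio=poisson_ratio,
        spacing=image.spacing,
        compression_fraction=compression_fraction,
        plate_mask=plate,
    )


def _node_grid(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    return np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)


def element_dofs(shape: tuple[int, int, int]) -> np.ndarray:
    """Global DOF indices per element, (nelem, 24), C-ordered elements."""
    nx, ny, nz = shape
    nid = _node_grid(shape)
    en = np.stack(
        [
            nid[ox : ox + nx, oy : oy + ny, oz : oz + nz].ravel()
            for ox, oy, oz in _HEX8_OFFSETS
        ],
        axis=1,
    )  # (nelem, 8)
    return (3 * en[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)


def assemble_stiffness(model: FEModel) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the global stiffness matrix in SI units (N, m).

    Returns the CSR matrix and the (nelem, 24) element DOF map.
    """
    k_unit = hex8_stiffness(1.0, model.poisson_ratio, 1.0)
    h_m = model.spacing * 1e-6
    scale = model.element_moduli.ravel() * 1e9 * h_m  # E[Pa] * h[m]
    edofs = element_dofs(model.shape)
    nelem = edofs.shape[0]
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    vals = (scale[:, None] * k_unit.ravel()[None, :]).ravel()
    ndof = 3 * np.prod(np.asarray(model.shape) + 1)
    k = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return k, edofs


def _boundary_sets(shape: tuple[int, int, int]):
    nid = _node_grid(shape)
    bottom = nid[:, :, 0].ravel()
    top = nid[:, :, -1].ravel()
    fixed = np.concatenate([3 * bottom, 3 * bottom + 1, 3 * bottom + 2, 3 * top + 2])
    return bottom, top, np.unique(fixed)


def solve_uniaxial(
    model: FEModel,
    compression_fraction: float | None = None,
    *,
    solver: str = "auto",
    tol: float = 1e-8,
    maxiter: int = 20_000,
    direct_max_dofs: int = 150_000,
    return_displacements: bool = False,
):
    """Simulate uniaxial compression and return the effective-strain field.

    The bottom node layer is fixed in all directions; the top node layer is
    prescribed an axial displacement of ``compression_fraction`` of the model
    height (compression), with in-plane components free. The per-element
    strain tensor is evaluated at the centroid from trilinear shape-function
    gradients; effective strain is sqrt(2U/E) in microstrain. F_resultant is
    the magnitude of the summed axial reactions over top-surface nodes.

    Parameters
    ----------
    solver
        'auto' (sparse direct below ``direct_max_dofs`` free DOFs, conjugate
        gradients above), 'direct', or 'cg'.
    tol
        Relative residual target for the iterative solver.
    return_displacements
        Also return the full nodal displacement vector (m) for verification.
    """
    frac = model.compression_fraction if compression_fraction is None else compression_fraction
    if not (0.0 < frac <= 0.05):
        raise ParameterError(f"compression fraction must lie in (0, 0.05], got {frac}")
    nx, ny, nz = model.shape
    h_m = model.spacing * 1e-6
    k, edofs = assemble_stiffness(model)
    ndof = k.shape[0]
    bottom, top, fixed = _boundary_sets(model.shape)

    u = np.zeros(ndof)
    u[3 * top + 2] = -frac * nz * h_m  # compressive axial displacement
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)

    k_ff = k[free][:, free].tocsc()
    rhs = -k[free][:, fixed] @ u[fixed]

    use_direct = solver == "direct" or (solver == "auto" and free.size <= direct_max_dofs)
    if solver not in ("auto", "direct", "cg"):
        raise ParameterError(f"unknown solver {solver!r}")
    if use_direct:
        try:
            u[free] = spla.splu(k_ff).solve(rhs)
        except RuntimeError as exc:  # pragma: no cover - singular shouldn't occur
            raise ConvergenceError(f"direct solve failed: {exc}") from exc
    else:
        m_inv = 1.0 / k_ff.diagonal()
        precond = spla.LinearOperator(k_ff.shape, matvec=lambda x: m_inv * x)
        sol, info = spla.cg(k_ff, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=precond)
        if info != 0:
            res = float(np.linalg.norm(k_ff @ sol - rhs) / np.linalg.norm(rhs))
            raise ConvergenceError(
                f"CG did not converge within {maxiter} iterations "
                f"(relative residual {res:.3e})",
                residual=res,
            )
        u[free] = sol

    reactions = k @ u
    f_top = float(reactions[3 * top + 2].sum())
    f_bottom = float(reactions[3 * bottom + 2].sum())
    f_resultant = abs(f_top)
    imbalance = abs(f_top + f_bottom) / f_resultant if f_resultant > 0 else np.nan

    # Centroid strains and effective strain. D/E depends only on nu, so EFF
    # is invariant under uniform modulus rescaling.
    b0 = centroid_b_matrix(h_m)
    eps = u[edofs] @ b0.T  # (nelem, 6)
    dbar = elastic_d_matrix(1.0, model.poisson_ratio)
    q = np.einsum("ij,jk,ik->i", eps, dbar, eps)
    eff = np.sqrt(np.maximum(q, 0.0)).reshape(model.shape) * 1e6

    field_out = StrainField(
        eff_sim=eff,
        f_resultant=f_resultant,
        spacing=model.spacing,
        f_top=f_top,
        f_bottom=f_bottom,
        equilibrium_imbalance=imbalance,
    )
    if return_displacements:
        return field_out, u
    return field_out


def scale_strains(field: StrainField, f_applied: float) -> StrainField:
    """Rescale the unit-simulation strains to an applied force.

    ``eff_actual = (f_applied / f_resultant) * eff_sim`` elementwise;
    re-scaling always starts from ``eff_sim``, so repeated calls replace
    rather than compound.
    """
    if not (field.f_resultant > 0):
        raise ScalingError(
            f"f_resultant must be positive, got {field.f_resultant}"
        )
    ratio = f_applied / field.f_resultant
    return replace(field, eff_actual=ratio * field.eff_sim, f_applied=float(f_applied))


def optimize_load(
    field: StrainField,
    prescription: LoadPrescription,
    bone_mask: BoneMask | np.ndarray,
) -> LoadPrescription:
    """Scale the applied load to a median target strain with overstrain guard.

    The raw load ``F = F_resultant * target / median(eff_sim over bone)`` is
    clamped to ``[f_min, f_max]``; then, while more than
    ``overstrain_voxel_limit`` bone voxels exceed ``overstrain_threshold``
    at load F and a decrement stays within bounds, F is reduced by
    ``decrement`` (a single reduction only if ``single_step``). Overstrain
    counting is restricted to bone-mask elements.
    """
    bone = bone_mask.values if isinstance(bone_mask, BoneMask) else np.asarray(bone_mask, bool)
    if bone.shape != field.shape:
        raise GeometryError("bone mask and strain field shapes differ")
    eff_bone = field.eff_sim[bone]
    if eff_bone.size == 0:
        raise OptimizationError("no bone elements to optimise over")
    med = float(np.median(eff_bone))
    if not (med > 0):
        raise OptimizationError(f"median simulated strain must be positive, got {med}")

    f = field.f_resultant * prescription.target_median_strain / med
    f = min(max(f, prescription.f_min), prescription.f_max)

    def overstrain_count(load: float) -> int:
        eff_actual = (load / field.f_resultant) * eff_bone
        return int((eff_actual > prescription.overstrain_threshold).sum())

    count = overstrain_count(f)
    while (
        count > prescription.overstrain_voxel_limit
        and f - prescription.decrement >= prescription.f_min
    ):
        f -= prescription.decrement
        count = overstrain_count(f)
        if prescription.single_step:
            break
    return replace(prescription, f_applied=float(f), overstrain_count=count)
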