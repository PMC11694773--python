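# Methods

`mechanomics` implements a desk-scale, fully testable version of a spatial
"mechanomics" workflow for bone fracture healing: time-lapsed micro-CT
morphometrics, voxel micro-finite-element (micro-FE) strain mapping with
adaptive load optimisation, embedding of a 2D spatial-transcriptomics spot
grid into the 3D strain field, and strain-stratified expression statistics.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic inputs do and do not establish.

## Image model and morphometrics

Density volumes are 3D arrays of mineral density (mg HA/cm³) on isotropic
voxel grids (default 10.5 μm edge). The third array axis is the femur long
axis, i.e. the axial loading direction; the physical center of voxel
`(i, j, k)` is `origin + (index + 0.5) · spacing`. Inputs are assumed
pre-registered; time-lapse registration is out of scope.

Smoothing uses a Gaussian kernel of width σ = 1.2 voxels truncated to a
`(2·support+1)³` window (support = 1 by default) and renormalised to sum to
one. At image borders the kernel is renormalised over in-image voxels
(normalised convolution), so constants are reproduced exactly everywhere
and no padding value enters. Bone is segmented at 395 mg HA/cm³; the
comparison is **inclusive** (a voxel exactly at the threshold is bone) —
the convention had to be fixed one way and inclusive keeps the segmentation
monotone in the threshold with a closed bone set.

Between two registered bone masks, voxels are classified by set logic:
formation (bone at t₂ only), resorption (bone at t₁ only), quiescence
(both). The three counts sum to `|mask₁ ∪ mask₂|` exactly — an integer
identity the tests assert.

Analysis is restricted to four disjoint VOIs — defect center (DC), defect
periphery (DP), fracture cortex + medullary cavity (FC), cortex periphery
(FP) — supplied as a single-label volume (the cylinder construction around
a real defect is upstream of this package; the phantom generator provides a
synthetic equivalent). Bone volume fractions are normalised by the central
VOIs, which stand in for the total volume of intact bone: DC/DC, DP/DC,
FC/FC, FP/FC, reported in percent. Formation and resorption rates use the
same normalisers:

    BFR(VOI) = 100 · |formation ∩ VOI| / TV_ref / Δt   [%/day]
    BRR(VOI) = −100 · |resorption ∩ VOI| / TV_ref / Δt

with TV_ref = |DC| for DC/DP and |FC| for FC/FP (the denominators are not
fixed independently anywhere; adopting the BV/TV normalisers is the one
self-consistent choice). Rates are attributed to the later scan of each
interval. Defect size is `h = 2·V_DC / (CSA_P + CSA_D)` with the week-0
defect volume and the adjacent proximal/distal cortical cross-sections.
Percent scales are applied only at the reporting boundary; everything
internal is a fraction.

## Micro-FE

Every voxel becomes an 8-node trilinear hexahedral element with 2×2×2 Gauss
quadrature. Since all elements are congruent cubes, a single unit stiffness
matrix (E = 1, h = 1) is scaled per element by `E·h`; assembly is fully
vectorised into one sparse CSR matrix in SI units.

Material model:

* bone voxels: `E = k·ρ` with `k` configurable (default 0.015 GPa per
  mg HA/cm³, i.e. 15 GPa at 1000 mg HA/cm³ — a placeholder slope in the
  physiological range; the published density–modulus calibration for a
  specific scanner is an input, not a constant of this package);
* soft tissue: 0.003 GPa (never zero, so the system is never singular);
* non-bone voxels on the first and last axial slices: 20 GPa plate
  material, suppressing end artefacts from the compliant marrow;
* one global Poisson ratio, default ν = 0.3 (not fixed by the workflow this
  reimplements; analytic tests use ν = 0 where the closed form requires it).

Boundary conditions: the bottom node layer is fixed in all three
directions; the top node layer is prescribed an axial displacement of 1% of
the model height (compression), in-plane components free. The reduced
system is solved directly (sparse LU) up to 150k free DOFs and by Jacobi-
preconditioned conjugate gradients (relative residual 10⁻⁸ by default)
above; a non-converged iterative solve raises with the residual attached.

Per element, the strain tensor is evaluated once at the centroid from the
trilinear shape-function gradients, and the scalar carried downstream is
the **effective strain**

    EFF = sqrt(2U/E),  U = ½ εᵀ D(E, ν) ε,

which combines volumetric and deviatoric contributions and is invariant
under a uniform rescaling of all moduli (D ∝ E cancels). Reported in
microstrain. For a homogeneous bar at ν = 0 under 1% compression,
EFF = 10,000 με exactly — the analytic anchor test.

`F_resultant` is the magnitude of the summed axial nodal reactions on the
top surface; global equilibrium (top vs bottom) is checked to 10⁻⁶
relative on every solve. Strain under an applied load is the linear
rescaling `eff_actual = (F_applied/F_resultant)·eff_sim`; re-scaling always
restarts from `eff_sim` (replaces, never compounds).

Adaptive loading scales the load to a median target strain over bone
elements, clamps to `[f_min, f_max]` (defaults 8–16 N, the in vivo loading
hardware window), then decrements by 1 N while more than 100 bone voxels
exceed 10,000 με. Two documented choices: overstrain counting is restricted
to bone elements (soft tissue legitimately reaches large strains), and the
decrement iterates to a fixed point rather than firing once (a single-step
mode is available via `single_step=True`). The optimisation never steps
below `f_min`.

## Spot integration

The section pose is a user-supplied rigid transform (rotation + translation)
from section-plane coordinates into the volume; automatic 2D-to-3D
registration is out of scope. A spot's footprint is the 55-μm-diameter
capture disk around its center, extruded **symmetrically** over the section
thickness (default 5 μm; the slab had to sit on one side or be centred, and
the centred slab is the natural choice for a visually aligned pose). The
per-spot summary is the arithmetic mean of `eff_actual` over bone-mask
elements whose centers fall inside the footprint — element centers, no
partial-volume weighting, justified because elements (10.5 μm) are small
against the spot (55 μm). Spots with no qualifying bone element stay
unassigned rather than receiving zero strain.

Strain regions: low < 500 με, high > 1000 με, reference in between. The
defining inequalities are strict on both sides, which would leave the exact
boundary values unassigned; values exactly at 500 or 1000 με are folded
into the reference region so the three labels partition all assigned spots.

Spot QC keeps spots with ≥ 500 UMIs **and** ≥ 250 detected genes, both
inclusive; per-region medians use the standard even-count convention.

## Expression statistics

Counts are modelled as negative binomial with `Var = μ + φμ²`. Size factors
are median-of-ratios against the geometric-mean pseudo-reference over genes
detected in every spot, rescaled to geometric mean one; for sparse data a
pool-and-deconvolve variant forms ring pools of spots (ordered by library
size), normalises the pooled profiles against the average profile, and
solves the per-spot factors by least squares with low-weight per-spot
anchor rows (weight 0.1) that pin the components smooth pools determine
poorly.

Differential expression between two spot groups is a per-gene NB GLM with
log link and log-size-factor offsets; full model intercept + group, null
model intercept only; significance from the likelihood-ratio test against
χ²(1). Means are fitted by a vectorised Newton iteration on the log scale
(the score is monotone, convergence is certified per gene); dispersions by
per-gene maximum likelihood (Newton on log r with analytic di-/trigamma
derivatives, method-of-moments start, bounds φ ∈ [10⁻⁸, 100]), alternated
with the mean fits for three outer rounds, then shrunk toward a log-linear
mean–dispersion trend with 10 pseudo-observations (`prior_df`) — mild
moderation that stabilises small samples without biasing large ones. Log2
fold changes are ratios of fitted group means with **no** shrinkage. Genes
enter testing if total count ≥ 10 and detected in ≥ 5% of spots (both
inclusive, configurable — stand-ins for an upstream pipeline's unstated
independent filter). BH adjustment runs over eligible, converged genes; a
DEG requires FDR < 0.05 and |log2FC| > 0.5. Non-convergent genes are
flagged, given NaN p, and excluded from the FDR, never called.

The CV ranking computes `cv = sd/mean` (sample sd) on normalised counts
over a region's spots for genes detected in ≥ 50% of them and ranks
**ascending** — low CV marks consistently expressed, functionally
significant genes; the canonical top genes in such analyses are
high-abundance structural markers, which sit at low CV. Direction is
configurable. Ties break by higher mean, then gene id, for determinism.

Gene sets are scored competitively: per gene the log2 ratio of group mean
normalised expression (pseudo-count 0.5 guards zero means), per set the
Welch two-sample t statistic of member vs non-member ratios, two-sided p,
BH across sets. Sets with fewer than two present genes are skipped. Being
competitive, a large planted signal shifts the background and can push
unshifted sets mildly the other way — expected behaviour, demonstrated in
the examples.

## Synthetic data

The phantom is an idealised cortical tube (annulus `r_in < ρ ≤ r_out`) with
a mid-diaphyseal gap and a callus shell whose outer radius follows a
per-frame schedule; shrinking radii plant resorption. It is deliberately
not anatomical: ground truth (the exact formation/resorption voxel sets)
must be integer-exact and cheap. Densities are piecewise constant with
bone phases ≥ 395 and soft tissue < 395 mg HA/cm³, so thresholding the raw
phantom reproduces the generator's masks exactly; morphometric ground-truth
checks therefore threshold unfiltered frames (smoothing is validated by its
own convolution oracle, and would blur the planted boundary by design, not
by error). Striped strain fields are piecewise constant in axial bands with
known per-element labels. Counts are NB draws with log-normal baselines and
size factors and planted per-group log2 effects; a single seed fans out
into independent substreams (SeedSequence) for genes, spots and counts, and
all outputs are bit-reproducible from (seed, parameters).

What the synthetic conditions do not emulate: anatomical geometry, partial
volume and noise in the CT images, spatial correlation of expression
between neighbouring spots, gene–gene correlation, and zero inflation
beyond NB sampling. Passing tests therefore establish correctness of the
computations under the stated models, not performance on real sections.

## Problem sizes and configurations used in the checks

The self-checks run at desk scale by design: FE oracles on 8³ and ≤ 6³
element meshes (dense linear-algebra reference), the end-to-end run on a
20×20×24 phantom (~33k free DOFs, sparse direct solve), DE calibration on
2,000 genes × 80 spots. The end-to-end configuration opens the 8–16 N
clamp (`f_min=0, f_max=∞`) because the clamp window belongs to the in vivo
loading hardware while the desk-scale phantom is orders of magnitude more
compliant; the clamp logic itself is exercised by its own fixtures. The
phantom's section uses a 21 μm spot pitch (denser than the 100 μm
production pitch) so that a small phantom still yields enough spots per
strain region for group statistics; the 700 με median target places the
phantom's strain distribution across the 500/1000 με classification bands.
These are configurations of the synthetic study, chosen once and fixed.

## Known limitations

* Linear elasticity only; no geometric/material nonlinearity, no dynamics —
  the cyclic loading waveform (10 Hz, 3000 cycles) is metadata.
* The solver is a general sparse LU/CG, not a matrix-free multigrid; very
  large production volumes (300×300×186) would need the latter.
* The density→modulus slope and Poisson ratio are configurable defaults,
  not calibrated constants.
* Spot footprints use center-in-disk membership; sub-element partial
  volumes are ignored (bounded by the element/spot size ratio).
* The NB fitter assumes a two-group design; covariates and multi-factor
  designs are out of scope.
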