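# Methods

`trabdvc` measures full-field displacement and strain inside trabecular
bone imaged in two mechanical states, and quantifies the measurement
uncertainty of that chain. This note documents the models, the conventions
and the numerical choices, and what the synthetic test bed does and does
not establish about real data.

## Problem setting

Stepwise in situ compression of a bone specimen inside a microCT scanner
yields a reference image (preloaded state) and one deformed image per load
step. Digital volume correlation (DVC) registers each pair and
differentiates the displacement field into strain, giving a
three-dimensional map of where the tissue deforms — including around
osteoarthritis-specific features such as subchondral cysts and sclerotic
(locally denser, thicker) regions. Because such scan data are typically not
redistributable, the package ships a synthetic-volume generator with
exactly known ground truth, on which every stage of the chain is validated.

## Synthetic trabecular volumes (`synthgen`)

A Gaussian random field (white noise blurred to a correlation length ℓ,
periodic boundary) is thresholded at the quantile that yields a target
bone volume fraction BV/TV, giving strut/plate mixtures with exact control
of the bone fraction. Defaults emulate osteoarthritic femoral-head
trabecular bone:

| parameter | default | rationale |
|---|---|---|
| voxel size | 39 µm | typical in situ microCT resolution for a whole femoral head |
| target BV/TV | 0.20 | inside the 17.7–25.7% range of OA femoral-head specimens (presets for the five specimen values are provided) |
| correlation length ℓ | 190 µm | places the re-segmented mean trabecular thickness in the 200–300 µm band reported for OA subchondral bone |
| foreground / background grey | 180 / 60 GSV | straddle the 110 GSV segmentation threshold with realistic contrast |
| partial-volume blur | 0.5 voxel | mimics scanner blur; keeps the volume separable at 110 GSV |
| noise sigma | 0 (generator), 5 GSV in repeated-scan studies | repeated-scan noise level is a free parameter; 5 GSV (≈4% of the dynamic range) is a plausible scanner noise figure |

Cysts are spherical voids forced to background; a sclerotic region raises
the local bone fraction by relaxing the threshold inside a sphere.
Generation is bit-reproducible from a single integer seed; no global
random state is touched. Volumes whose extent resolves fewer than about
four struts per axis (extent < 8 ℓ) are rejected.

What the generator does **not** emulate: anatomically realistic
femoral-head geometry and the cortical shell, scanner physics (beam
hardening, ring artifacts, polychromatic spectra), spatially correlated
noise, and rigid misalignment between repeated scans (synthetic pairs are
generated pre-aligned, because rigid registration is out of scope). Tests
passing on synthetic volumes therefore validate the measurement chain —
segmentation arithmetic, registration accuracy, differentiation, error
bookkeeping — not robustness to scanner artifacts.

### Virtual deformation

`apply_virtual_deformation` warps a volume by an analytically known field:
uniform axial compression toward a stationary plane (z = 0 by default,
mirroring a specimen potted at its base), or a general linear field
u(x) = A·x. Grey values are resampled by trilinear interpolation under the
inverse map. Voxels revealed at the boundary take the background grey
level by default; the `black (0 GSV)` fill option reproduces the sharp
boundary gradients that concentrate registration error in the outermost
slices, which is useful when studying boundary-slice exclusion.
Deformations are restricted to the small-strain regime (|strain| < 0.2).

## Preprocessing (`imageproc`)

The standard chain: 8-bit conversion (linear window map, round half-up);
Gaussian filter with sigma 0.5 voxel truncated at a 1-voxel support;
global threshold 110 GSV; despeckle keeping the single largest
26-connected component. The threshold is exposed in every API but the
synthetic volumes are generated to be separable at the default.

Half-resolution resampling uses a 2×2×2 block mean — identical to
trilinear interpolation at half-sample offsets, isotropic and exactly
reproducible; a strict slice-wise bilinear dialect (`xy_only`) is kept for
comparison with 2D pipelines. Voxel size doubles (39 → 78 µm).

The external-contour mask is built by a Euclidean closing (distance
transforms give an exact ball element at any radius cheaply) followed by
filling of fully enclosed cavities. The closing radius must exceed the
largest pore half-width; with the default synthetic microstructure a
radius of 10 voxels at 39 µm closes most of the inter-trabecular space.
No fidelity claim attaches to the radius — it is a free parameter.

The best-fit sphere (used to delimit the trabecular analysis region of a
femoral head) is fitted to the mask boundary voxels: an algebraic linear
least-squares seed refined geometrically with a soft-L1 loss and residual
trimming, so that the flat neck-cut plane of a real specimen mask does not
drag the fit off the spherical part.

## Morphometry (`morphometry`)

* **Tb.BV/TV** — bone voxels per region voxel, in percent.
* **Tb.Th / Tb.Sp** — model-free local thickness: for every voxel of the
  phase, the diameter of the largest inscribed sphere containing it,
  computed from the Euclidean distance transform with redundant-sphere
  pruning and ridge-sphere painting. Diameter convention: 2·EDT − 0.5
  voxels (surface lies half a voxel beyond the last foreground center;
  lattice quantization of sphere centers costs up to half a voxel the
  other way). Residual bias on analytic plate/cylinder phantoms is within
  half a voxel, with the parity of the structure width deciding the sign.
* **Tb.N** — (BV/TV)/Tb.Th in mm⁻¹.
* **Conn.D** — (1 − χ)/TV in mm⁻³, with the Euler characteristic χ
  computed by 2×2×2 octant counting under 26-connected foreground /
  6-connected background (via `skimage.measure.euler_number`). The
  convention matters on thin structures and is therefore fixed and stated;
  solid ball χ = 1, torus χ = 0, two balls χ = 2.

## Registration (`dvc_core`)

A regular node grid with spacing NS voxels is laid over the image pair
(nodes at voxel coordinates {0, NS, 2NS, …}). Nodal displacements u
minimize

    E(u) = Σ_masked voxels [fixed(x) − moving(x + u(x))]²
         + λ_abs · Σ_nodes ‖(L u)_node‖²

with u(x) trilinearly interpolated inside each hexahedral cell and L the
6-neighbor graph Laplacian of the node grid. Sum-of-squared grey
differences is the natural metric for same-modality repeated scans.
Minimization is damped Gauss–Newton: per-cell assembly of the normal
matrix, sparse solve, backtracking line search on the full objective, with
a warm start from a grid of doubled spacing on images blurred with sigma
2 voxels. The warm start covers the few-voxel displacement magnitudes of
stepwise loading; displacements remain sub-cell by design.

Numerical details that matter:

* The moving image is padded by one background voxel so trilinear sampling
  blends smoothly into the fill value at the volume border (a hard switch
  to the fill value creates a spurious objective cliff at sub-voxel
  displacements).
* The regularization weight is dimensionless: λ_abs = λ · mean diagonal of
  the Gauss–Newton normal matrix, making behaviour invariant to grey-level
  scaling and voxel counts. The default λ = 0.1 was chosen on synthetic
  calibration pairs as the weight that keeps the virtual-deformation
  strain bias under ~5% while suppressing zero-strain noise error to tens
  of µε — on zero-strain pairs alone the error decreases monotonically in
  λ (the truth is zero, so infinite smoothing would "win"), so the
  deformed condition must anchor the upper end.
* Convergence: relative objective decrease < 1e-5 or 30 iterations;
  non-convergence is returned as a flag, never silently.
* Nodes whose ±NS/2 support cube contains < 5% masked voxels are flagged
  low-confidence; their values are carried by the smoothing term.

Registering a volume against itself returns |u| ≤ 0.01 voxel; a pure
translation of 2 voxels is recovered to ±0.1 voxel; small linear fields
(‖A‖ ≤ 0.02) are recovered with interior-node RMS error ≤ 0.1 voxel on
noise-free synthetic bone.

## Strain differentiation (`strainfield`)

The displacement gradient of each grid cell is evaluated from the
trilinear shape-function derivatives at the cell center (mean of the four
edge differences per axis over the spacing); the small-strain tensor is
ε = ½(∇u + ∇uᵀ); nodal tensors average the adjacent cells (interior nodes
8 cells, boundary nodes fewer — flagged, since boundary cells concentrate
registration error). Principal strains are the eigenvalues sorted
descending (εp3 most compressive); the von Mises equivalent strain is the
deviatoric invariant

    ε_eqv = (2/3)·√{[(εp1−εp2)² + (εp2−εp3)² + (εp3−εp1)²]/2}.

No formula convention is universal here; the deviatoric form (equal to
√(2/3 e:e)) is used because it is material-parameter-free, and stored
shears are tensor shears ε_ij = γ_ij/2 (engineering shears available).
Differentiating on the DVC node grid directly keeps the strain field and
the measurement grid congruent; no intermediate fine mesh is introduced.
Strains are reported in µε (10,000 µε = 1%).

Node masking removes nodes whose NS-cube neighborhood has masked-voxel
coverage below a cutoff (default 5%) from all downstream statistics —
e.g. nodes centered in cysts or outside the specimen contour.

## Uncertainty quantification (`uncertainty`)

Zero-strain design: register two repeated acquisitions; any measured
strain is error (reference identically zero). Virtual-deformation design:
register the original against an exactly warped copy; errors are taken
against the analytic field, and the recovered mean axial strain is
reported alongside.

Per component, systematic error = mean and random error = sample (n−1)
standard deviation over nodes. MAER is the mean over nodes of the per-node
average of the absolute six strain-component errors; SDER is the standard
deviation of that same per-node quantity. Displacement errors are emitted
in both µm and voxels.

Boundary exclusion is counted in node layers (at NS 25 on 78 µm images,
2 layers ≈ 3.9 mm): the replaced slices of a virtually deformed image
create grey-level cliffs whose error is confined to the outermost layers,
and excluding two layers restores the axial random error to the level of
the other components.

The NS trade-off: MAER decays roughly logarithmically with NS, so a fit
a + b·log NS is reported with R²; the recommendation itself is the
smallest NS whose **measured** MAER is at or below the threshold (default
1000 µε — one order of magnitude below the 10,000 µε yield strain of bone
tissue, so yielded regions stay discriminable from noise). The fitted
curve is deliberately not used for the decision: with only four NS values
a two-parameter fit can predict above-threshold error at an NS whose
measured error is already acceptable.

## Load-step statistics (`loadstep`)

Per load step: max/min/median of each strain component, εp1, εp3 and
ε_eqv over masked nodes (equal node weights; even-count medians use the
midpoint); median |εp3| (compressive strains are conventionally printed
positive, the sign is retained in storage); and the percentage of nodes
with |εp3| strictly above the yield threshold (default 10,000 µε).
Node-equal weighting is the default; each node represents the same tissue
volume on a regular grid, and a bone-coverage-weighted variant would
conflate morphometry with the strain summary.

Spearman rank correlations between strain outputs and morphometric
parameters are computed with midranks; two p-values are attached:

* the t-approximation, t = r_s·√((n−2)/(1−r_s²)) on n−2 df — the common
  reporting convention for small exploratory cohorts (at r_s = 0.9, n = 5
  it gives p = 0.037);
* the exact two-tailed permutation p for n ≤ 8 (at r_s = 1, n = 5:
  2/120 ≈ 0.017; at r_s = 0.9, n = 5: 0.083 — materially different from
  the t value at these n, which is why both are reported).

At |r_s| = 1 the t statistic diverges and its p underflows to zero; the
exact value is authoritative there. No multiple-testing correction is
applied to the significance flags (10 correlations per load step); a
Bonferroni-corrected flag is emitted alongside for reference.

## Problem sizes and reproducibility

The validation suite runs on 64³–128³ synthetic volumes: identity,
translation, affine and compression recovery at 64³ (NS 16); the
zero-strain NS sweep {13, 25, 35, 50} at 104³/78 µm; and the full-chain
virtual-deformation recovery at 128³ (NS 25, 1% and 5% compression, two
boundary layers excluded), which recovers the applied level within a few
percent. These sizes exercise every code path with realistic node counts.
All randomness flows through explicit integer seeds; repeated runs are
bit-identical.

## Known limitations

* The elastic-operator formulation of established global DVC packages is
  not reproduced exactly; plain Laplacian smoothing on the node graph is
  used, so absolute error magnitudes are not comparable
  implementation-to-implementation — only the designs (zero-strain,
  virtual deformation, NS sweeps) are.
* Small-strain theory only; no Green–Lagrange strain, no stresses.
* Local thickness carries the documented half-voxel convention bias.
* Rigid pre-registration of repeated scans is assumed done upstream.
* The closing radius of the contour mask and the repeated-scan noise sigma
  are free parameters with no claimed fidelity to any particular scanner.
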