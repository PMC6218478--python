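# Methods

## Model

The epithelium is a laterally periodic monolayer of prismatic cells. Each
cell has an apical polygon, a basal polygon with the same cyclic order
(columnar pairing: apical vertex *i* is permanently paired with basal
vertex *i*), and quadrilateral lateral faces shared with neighbours. The
topology is fixed for the whole simulation: no neighbour exchanges (T1
transitions), divisions, or extrusions — folds form purely by vertex
displacement, consistent with a quasistatic shape-change model. The domain
is periodic in x and y and free in z; z increases from basal to apical in
the flat reference state, so an apical indentation is a negative
z-displacement of apical fold vertices.

The work function is the sum of (i) apical and basal surface tensions per
cell times the face areas, (ii) lateral surface tension times lateral face
areas, (iii) apical and basal edge (junctional) tensions times edge
lengths, (iv) harmonic springs of stiffness k anchoring every basal vertex
to its reference position in the relaxed pre-fold state (the ECM
attachment; rest length zero, full 3D displacement penalized), and (v) a
quadratic volume penalty (K_V/2)(V_c − V_0)²/V_0 per cell. Lateral faces
and junctional edges shared by two cells carry the **mean** of the two
cells' tension parameters and are counted once; this makes "increased
lateral tension of a stripe" well defined at stripe boundaries.

Faces are triangulated by a fan about the face centroid (the mean of the
cycle vertices); cell volumes use the divergence theorem over the closed
cell surface with the **same** triangulation, so volume gradients are
consistent with area gradients. Forces are the exact analytic gradient of
every term (validated against central finite differences to < 1e-6
relative error in the test suite); the inner loops are numba-compiled.

### Nondimensionalization and parameters

The reference apical surface tension and the cell target volume are 1, so
lengths are in units of V_0^(1/3) and tensions in units of T_a. Defaults:

| parameter | default | meaning |
|---|---|---|
| T_b / T_a, Λ_b / Λ_a | 4 | basal:apical tension ratio (ablation-derived) |
| Λ̂ = Λ_a/(T_a V_0^(1/3)) | 1 | normalized edge tension (free parameter) |
| k̂ = k V_0^(1/3)/T_a | 1 | normalized ECM spring constant (free parameter) |
| aspect ratio h/(2√(A_a/π)) | 5 | columnar cell height/diameter before folding |
| K_V | 2·10⁴ | volume-penalty stiffness (implementation parameter) |
| stripe width | 2 rows | pre-fold stripe (4 rows available, matching the observed ECM-reduction stripe) |

The two normalized free parameters are set to 1 by default; a test sweep
varies each by a factor of two in both directions and confirms that
basal-decrease folding persists. K_V = 2·10⁴ keeps the maximum cell-volume
violation below 0.1% in every shipped scenario (asserted at every accepted
ramp step); stiffer penalties reduce the violation further but slow
relaxation.

### Initial packing and calibration

The builder tiles nx × ny regular hexagonal prisms (ny even, required by
the periodic tiling parity). Two calibrations fix the free geometry: the
box is sized so that cells of unit volume have the target aspect ratio,
and the lateral tension is set from the closed-form stationarity condition
of the per-cell energy of a regular hexagonal prism,
T_l = √3 s² [3√3 s (T_a+T_b) + 3(Λ_a+Λ_b)] / (2 V_0),
so the flat packing carries no in-plane tissue stress (it would be an
equilibrium even with a free box). The packing is then relaxed, ECM
anchors are set to the relaxed basal positions, and the achieved aspect
ratio is verified to within 2%. Replicate variation is modelled as a
small seeded vertex perturbation before re-relaxation; because the energy
landscape at the flat state has a single basin, replicates differ only
marginally — disordered packings are out of scope.

## Relaxation and ramps

Mechanical equilibrium is found by deterministic quasi-Newton descent
(L-BFGS on all vertex coordinates, analytic gradient) to a maximum vertex
force norm below 1e-6 (reduced units). Because the total energy is O(100)
while the force tolerance is 1e-6, plain descent can stall when energy
*differences* reach machine precision; the relaxer then polishes the
solution by solving the force balance F(x)=0 directly with a matrix-free
Newton–Krylov step (accepted only if it does not raise the energy). Runs
are bit-reproducible given the configuration.

Tension ramps rescale the stripe parameters by (1+δ) on a uniform grid
(default 40 steps, to δ_b = −0.8 for basal ramps — the scale of the
measured basal recoil reduction in pre-fold cells — and δ_l = +1.0 for
lateral ramps), re-relaxing warm-started from the previous equilibrium;
warm starting defines the quasistatic branch being followed. Box
dimensions are held fixed during ramps. Up-down ramps at small magnitude
return the initial energy to < 1e-6 (no hysteresis on the branch).

### Degenerate elements

With fixed topology, a contracting fold can drive a junctional edge to
zero length (the configuration a T1 transition would resolve) or collapse
a fan triangle; at such points |L| and the triangle area are non-smooth
and no interior force balance exists. Both are regularized by
√(x² + ε²) smoothing (ε = 2·10⁻³ length units for edges, 10⁻³ for
triangle-normal magnitudes). The energy offset is O(ε²/size) for healthy
elements and O(ε) at degeneracy — far below every analysis tolerance — and
the collapsed state becomes a genuine smooth minimum (a rosette-like
vertex) that the minimizer can certify. Geometry primitives
(`face_area`, `cell_volume`) remain exact; the smoothing exists only in
the energy.

Periodic minimum-image wrap offsets for every face and edge are computed
once from the reference configuration and frozen: topology never changes
and cells never migrate across the box, so this keeps the energy smooth in
the vertex positions no matter how deep the fold grows.

## In-silico ablation

Ablating an element sets its (shared-mean) tension to zero, everything
else unchanged. Recoil is integrated from the pre-ablation equilibrium
with explicit overdamped dynamics dx/dt = F/drag (drag 1, dt 2·10⁻⁵
reduced time; an energy-increase guard rejects unstable steps). The
estimator is the experimental one: separation increase of the two bounding
points from the frame before ablation to the first frame after, divided by
the frame interval. The frame interval maps to the experimental cadence
(0.25 s for junctional edges, 1 s for lateral interfaces) via the 1%-recoil
rule: one frame is the time for the separation to grow by 1% of the
element's pre-ablation length; paired comparisons always use one common
window, so only window-consistent ratios are reported and drag cancels.
For lateral faces the tracked points are the midpoints of the face's
apical and basal edges (the apico-basal extent of the released region).
The estimator implements the first-frame formula literally, with no
edge-length or geometry correction.

## Fold-shape quantification

Cross sections are y–z planes perpendicular to the stripe (taken between
lattice vertex columns of the reference configuration). Per cell, the
apical and basal polygon–plane intersections give 2D segments; fold-center
cells are the pre-fold-labelled ones. The readout follows the tracked-cell
scheme: d_a = apical plane of the neighbours minus the lowest apical
z of the fold cells; d_b = extremal signed deviation of fold-cell basal
vertices from the neighbours' basal plane, **positive = outward bulge**
(away from the apical side), negative = basal indentation — the sign
convention is ours and fixed; l_a, l_b = mean in-plane segment lengths of
fold cells; h_tissue = mean apico-basal (z) height of neighbour cells.
"Neighbours' plane" means a least-squares line through the section
vertices of neighbours at least 2 cell rows from the stripe (the exact
operational definition used in manual tracking is not published; this
choice is ours). All quantities are also reported normalized by h_tissue.

## Fluctuation analysis

Relative rates of change are central differences,
g_i = (x_{i+1} − x_{i−1}) / (2 Δt x_i), endpoints dropped. The
cross-correlation C(τ) = ⟨g_a(t) g_h(t+τ)⟩ is the plain product mean over
overlapping samples per cell, then the unweighted mean over cells (a
Pearson-normalized variant sits behind a flag); lags with fewer than 5
overlapping samples are reported missing. No detrending is applied by
default — the slow height decrease of fold cells is part of the signal — an
optional linear detrend exists for sensitivity analysis. The minimum of
the cell-averaged C is located on the lag grid with ties broken toward the
smallest |τ|. The null bound for independence uses a Bartlett-type
variance, Var C(τ) ≈ (1/n) Σ_k γ₁(k) γ₂(k), which accounts for the
autocorrelation of the rate series and reduces to var₁·var₂/n for white
noise. The derivative estimator and averaging order are not published;
the chosen conventions are recorded in the result metadata.

## Synthetic-data generators

Generators are pure functions of their arguments including the seed, and
target the analysis interfaces (tracked tables), not images.

* **Wedge cross sections** realize requested (d_a, d_b, l_a, l_b,
  h_tissue) exactly with V-shaped fold chains and flat neighbours;
  tracking noise jitters each shared chain vertex once. They emulate
  manually tracked cross sections, not real cell outlines (no curvature,
  no cell-to-cell variability).
* **Recoil tracks** separate two vertices at constant speed with
  per-coordinate Gaussian tracking noise; the first-frame estimator is
  exactly unbiased to first order because the noise bias in the two
  frames' separations cancels in the difference.
* **Coupled intensity/height series** use an Ornstein–Uhlenbeck
  log-intensity (stationary s.d. 0.2, correlation time 30 s — pulsatile
  fluctuations on the tens-of-seconds scale) and integrate the relative
  height rate as −coupling × (intensity rate delayed by 22 s) + noise +
  trend at 1 s resolution, sampled every 10 s (the experimental cadence
  for lateral imaging). Defaults: 12 cells, 600 s records. The weak
  (neighbour-like) regime uses small fluctuation s.d. and coupling.
* **Intensity tables** draw mean-one lognormal noise around a known
  fold/neighbour contrast (default 0.8, i.e. a 20% reduction).

Passing tests on these generators demonstrates estimator correctness and
statistical calibration on data with the *assumed* structure; they cannot
validate image segmentation, tracking quality, or biological variability,
which are outside the package's scope.

## Problem sizes and numerical choices

The shipped full-scale scenario is a 10×10-cell tissue with 40 ramp steps
(a few minutes per ramp on one core); unit tests use 4×4 and 6×6 tissues
with shorter ramps, which show the same phase behavior at smaller
amplitude. Relaxation tolerance 1e-6 (max force norm), volume violation
asserted < 1e-3, recoil dt 2·10⁻⁵ with a halving-convergence test.
Energies quoted in comparisons (hysteresis) cancel the constant smoothing
offset exactly.

## Known limitations

* No T1 transitions: deep folds pin collapsed edges into rosette-like
  vertices instead of remodelling; l_a at the fold bottom is therefore a
  lower bound on what a remodelling tissue would show.
* Equilibrium shapes only: the ramp magnitude is an analog of the time
  axis; no statement about folding dynamics or timescales is made.
* Regular monodisperse packing; curved global disc geometry, lumen
  pressure, and multilayer (peripodial) structure are not modelled.
* The ECM is vertex-wise springs to fixed anchors; continuum ECM
  mechanics (strain propagation, remodelling) is absent.
* Volume conservation is a stiff penalty, not an exact constraint.
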