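# Methods

`legtomo` is a numerical feasibility study of monitoring bone density in
the lower leg with 2D microwave tomography (MWT): changes in bone volume
fraction (BVF) shift the bone's complex relative permittivity, and the
question is whether those shifts survive the full chain of scattering,
ill-posed inversion, and image segmentation. This note documents the
models, the numerical choices, and what the synthetic experiments do and
do not establish.

## Scene model

A leg cross section is five nested regions — skin ⊃ fat ⊃ muscle ⊃
{tibia, fibula} — immersed in a lossy matching medium, each with a bulk
complex relative permittivity at the single operating frequency of
0.8 GHz (time convention e^{+jωt}, so ε = ε′ − jε″ with ε″ ≥ 0):

| region | ε at 0.8 GHz |
|---|---|
| skin | 42 − j18.8 |
| fat | 11 − j2.3 |
| muscle | 55 − j20.5 |
| healthy bone (BVF 0.50) | 13 − j3.0 |
| glycerin/water 80:20 medium | 26 − j18 |
| ultrasound-gel medium | 71.4 − j10.3 |

Bone permittivity is tied to BVF through a nine-row table spanning
BVF 0.50 (13 − j3.0, healthy) to 0.10 (23 − j3.4, severe loss) in 0.05
steps; between rows both parts are interpolated linearly, and the
printed rows always win over the interpolant. Healthy bone is a single
bulk value (no cortical/trabecular split).

Real anatomical contours traced from MRI are not available, so the
generator uses smooth parametric stand-ins: an elliptical outer boundary
(semi-axes 55 × 50 mm, a mid-calf scale), constant-thickness skin
(2 mm) and fat rings, and circular bones placed anatomically — the
tibia anteromedial (center (18, 10) mm, radius 11 mm) and the fibula
lateral and close to the surface (center (−26, −8) mm, radius 6 mm).
The three fat-thickness classes use 4 / 8 / 14 mm rings (thin / medium
/ thick). A low-order cosine perturbation of the ellipses is available
for less idealized shapes but defaults to zero. These contours share
the topology and scale of the real cross sections but not their exact
shapes; quantities that depend on the precise geometry (e.g. the exact
BVF at which the fibula stops being detectable) can therefore differ
from measurements on MRI-traced models, and the package's own sweep
results should be read with that caveat.

## Forward problem

The out-of-plane field of the TMz polarization satisfies the scalar
Helmholtz equation ∇²E + k₀²ε_r(r)E = −f. It is discretized with
linear triangles; transmitters are unit line currents entering the weak
form as barycentric point loads, and 24 collocated point transceivers
sit on a 10 mm outward offset of the skin contour, uniform in angle. A
first-order absorbing condition ∂E/∂n = −jk_b E closes the problem on
a circle half a medium-wavelength beyond the antennas. The background
matrix is factorized once (SuperLU) and reused for all transmitters and
all inversion iterates; the collocated receiver of the active
transmitter is excluded from the data (self-measurement sits on the
source singularity).

Two numerical choices matter for accuracy at practical mesh densities:

* **Mass blending.** The element mass matrix is the 50/50 blend of the
  consistent and row-lumped matrices. This cancels the leading-order
  numerical dispersion of linear elements; empirically it is the best
  blend, halving the field error against the analytic line-source
  solution compared with either extreme.
* **Mesh sizing.** Edge lengths follow the wavelength rule
  λ/10 = c/(10 f √ε_r,max) with ε_r,max the largest real permittivity
  anywhere in the scene (tissues *and* medium). The rule is an upper
  bound, and the in-package point-cloud Delaunay mesher produces less
  regular triangles than a frontal mesher, so all default meshes are
  generated at 0.8 × the bound. With both choices the solver agrees
  with the 2D line-source Green's function −(j/4)H₀⁽²⁾(kr) to ~1% and
  with the Mie series for a dielectric cylinder to ~3.5% (relative L2),
  converging second order under refinement.

The mesher places nodes on every tissue contour (corner-preserving
arc-length resampling at the target spacing), fills the disc with a
hexagonal lattice kept clear of the contours, Delaunay-triangulates the
cloud, and tags triangles by the region containing their centroid. It
is deterministic for fixed inputs.

## Inversion

The contrast-source inversion (CSI) functional is the sum of a
normalized data mismatch F_S and a normalized domain (state-equation)
mismatch F_D, with contrast χ = ε/ε_b − 1 defined on the imaging-domain
nodes (the leg interior) relative to the background ε_b — homogeneous
matching medium by default, or an inhomogeneous prior scene. Contrast
sources w_t = χ⊙E_t live on the same nodes; the operator L maps them to
scattered fields through the factorized background system.

Per iteration, each transmitter's w_t takes one Polak–Ribière conjugate
gradient step with an exact (closed-form) complex line search — the
cost is quadratic along any direction, so the step can never increase
F_S + F_D. The contrast update is the closed-form minimizer of the
F_D numerator, or, with multiplicative regularization (MR, the default),
one CG step on the product of the domain cost and a weighted-L2 total
variation factor: weights come from the previous iterate's contrast
gradient, the steering parameter δ² = F_D/h̄² (mean mesh edge length h̄)
shrinks as the fit improves, a uniform contrast incurs no penalty, and
the quartic line search falls back to the analytic update if it fails to
descend. Initialization is by backpropagation; iterations stop when the
relative change of F_CSI drops below 10⁻⁴ or at the iteration cap
(512 in the pipeline, the CG restarting every 50 steps or on a
non-descent direction). No positivity or passivity bound is imposed on
χ by default (an ε″ ≥ 0 clamp is available as a flag).

Synthetic data are always generated on a finer, independently generated
mesh (λ/10 rule) than the inversion runs on, to avoid the inverse
crime. The inversion mesh is sized at λ/9 with the *scene's* ε_r,max
rather than the matching medium's: the imaged interior contains muscle,
whose wavelength is much shorter than the medium's, and the 12-mm
fibula must span 2–3 node spacings to be representable at all. A
mesh sized by the medium alone (λ(26)/7 ≈ 10 mm) leaves the fibula
subgrid and can never reproduce its loss-map signature.

## Bone extraction ("expert-eye" procedure)

Extraction operates on the reconstruction rasterized to a 1-mm pixel
grid (linear interpolation on the inversion mesh), because the
procedure is defined on images and node-level masks on the coarse
inversion mesh would collapse to a handful of samples. The steps:

1. **Localize on the loss map.** Candidate bone pixels have ε″ below
   the midpoint of the scenario's bone loss (≈3) and the muscle loss
   (20.5). In automated mode, candidates are restricted to a search
   disc of radius bone-radius + 5 mm around the expected bone center
   and the 8-connected component nearest that center is kept; manual
   mode takes a user polygon, standing in for the radiologist's
   outline.
2. **Mask the real-part map** with the selected region.
3. **Quartile filter.** Masked values above their first quartile
   (25th percentile, linear interpolation at position 0.25(n−1)) are
   discarded — the rim of any ROI is muscle-contaminated, and the rule
   keeps the low quartile, never returning an empty set.
4. **Average** the kept values: the bone's estimated ε′.

Detectability is automated: a bone is "detected" when the automated ROI
is nonempty *and* its filtered mean stays below the midpoint of the
actual bone and muscle real permittivities. Manual masks skip the gate
(a human who outlines a region has already judged it visible). The two
modes deliberately coexist: detectability sweeps use the automated
rule, while RMSE tables compare both — automated means where defined,
and manual-outline means (true bone contour as the stand-in polygon)
for the small fibula, whose estimates are muscle-contaminated enough to
fail the midpoint gate even in scenarios a human reader would call
detected.

RMSE per (model, bone) is the root-mean-square of (extracted − actual
ε′) over the detected scenarios of the nine-BVF sweep. On ground-truth
images the procedure returns the table values exactly (RMSE 0), which
is the oracle separating extraction errors from reconstruction errors.

## Experiments and problem sizes

The pipeline reproduces four experiment classes, all deterministic per
(config, seed): the nine-scenario BVF sweep per leg model (~3 min per
model: forward mesh ≈ 2400 nodes, inversion mesh ≈ 2000 nodes with
≈ 570 contrast unknowns, 512 CSI iterations per scene), the antenna
sweep (24/18/12), the thick-fat fat-prior pair, and the matching-medium
comparison. The measurement noise model (complex white Gaussian at a
prescribed SNR) is available but off by default, matching the
noise-free synthetic study design.

Observed headline numbers at these sizes: tibia RMSE ≈ 1.0 for both
thin- and medium-fat models with a strictly monotone rise of the
extracted ε′ as BVF falls; fibula estimates 15–20 units high
(manual-outline RMSE far above the tibia's, reproducing the reported
ordering); the automated fibula call succeeds on the thin-fat model
down to BVF 0.35 and fails below, fails throughout the medium- and
thick-fat models, and is lost when the antenna count drops to 12. The
single-cylinder recovery benchmark reconstructs the mean real
permittivity of a λ/3 disc to better than 1%.

## Known limitations

* The phantom geometry is parametric, not anatomical; boundary-shape
  effects on detectability thresholds are not captured. The thin-fat
  fibula cutoff at BVF 0.35 is reproduced, but the detection margins
  near the boundary are below 1% of the threshold, so the cutoff should
  be expected to move by a grid step under small changes to geometry or
  discretization.
* Single frequency, 2D scalar physics, point antennas: no dispersion,
  no 3D scattering, no antenna modeling (S-parameters, coupling).
* The MR steering-parameter recipe is one member of the weighted-L2 TV
  family; other published variants differ in detail.
* First-order absorbing boundary: adequate in lossy media (reflections
  are attenuated twice over a wavelength of travel), poor in low-loss
  ones.
* The fibula's automated detectability is marginal by construction —
  its filtered mean rises roughly in parallel with the midpoint
  threshold as BVF falls, so the call flips on sub-1% margins near the
  boundary; this mirrors the inherent subjectivity the manual procedure
  replaces.
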