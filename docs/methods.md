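# Methods

This note documents the models and procedures fwetract implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic phantom cohort does and does not establish about real data.

## The bi-tensor free-water model

Each voxel's diffusion-weighted signal is modelled as a two-compartment
mixture,

    S(b, g) = S0 [ (1 − f) exp(−b gᵀ D g) + f exp(−b d_iso) ],

with `D` the tissue diffusion tensor (mm²/s), `f ∈ [0, 1]` the free-water
fraction and `d_iso = 3.0 × 10⁻³ mm²/s` the diffusivity of free water at
body temperature (fixed, configurable). The corrected scalars FW-FA and
FW-MD are the FA/MD of `D` alone, computed from its eigenvalues with
negative eigenvalues clamped to zero (a clamp counter is kept).

### Single-shell fitting and its identifiability

With a single non-zero b-value the decomposition `(f, D)` is severely
ill-conditioned: at b = 2000 s/mm² the free-water signal is attenuated to
exp(−6) ≈ 0.25%, so `f` acts almost purely as a scale on the tissue term and
trades off against the tensor's diffusivities. Strictly, anisotropy makes
the decomposition identifiable in the noiseless limit (the constant water
term cannot be absorbed by an exponential-quadratic), but at realistic SNR
the data-term minimum is biased. The fit therefore follows the standard
single-shell recipe: an informative initialization carries the compartment
split, spatial regularization stabilizes it, and the optimizer is a
conservative local descent that refines rather than re-decides.

Concretely, the objective is

    Σ_voxels Σ_volumes (A_pred − A_meas)² + λ Σ_voxels ‖∇f‖²,

where `A` is the signal normalized per voxel by the mean b = 0 signal
(making λ independent of scanner scale), and the smoothness term is a
Tikhonov penalty on the finite-difference gradient of `f` over in-mask
neighbour pairs — a deliberately simple stand-in for curvature-flow
regularizers with the same qualitative effect. Minimization is projected
gradient descent: `f` is parameterized through a logistic transform to stay
in (0, 1), tensors are projected onto the PSD cone by eigenvalue clamping
after each step, and a backtracking line search accepts only
objective-decreasing steps, so the recorded objective sequence is
non-increasing by construction. A block-coordinate alternative (exact
per-voxel `f` solve + log-domain tensor OLS) was evaluated and rejected: it
converges efficiently to the *biased* global minimum, moving `f` away from
truth on phantoms.

### Initialization

`f` is initialized per voxel by linear interpolation of the mean weighted
attenuation between two references: the spherical-mean attenuation of a
typical white-matter tensor (axially symmetric, FA 0.5, MD 0.75 × 10⁻³
mm²/s by default) and the pure-water attenuation exp(−b·d_iso), clipped to
[0.01, 0.99]. Using the spherical mean of an anisotropic reference rather
than exp(−b·MD) of an isotropic one matters at b = 2000: the convexity gap
between the two is worth ≈ 0.1 in `f`. Tensors are then initialized by
ordinary least squares on the log attenuation after subtracting the
initialized water signal. Voxels with zero signal are dropped from the
mask. Because the data term is nearly flat in `f`, the accuracy of the
recovered FWF is governed by how well a voxel's true tissue tensor matches
this reference — a known property of single-shell free-water estimation,
not of this implementation.

### Fit parameters

| parameter | default | meaning |
|---|---|---|
| `d_iso` | 3.0e-3 mm²/s | free-water diffusivity (body temperature) |
| `lambda_smooth` | 0.5 | weight of the spatial ‖∇f‖² penalty (attenuation units) |
| `max_iter` | 100 | outer gradient iterations |
| `tol` | 1e-8 | relative objective-change stopping rule |
| `init_tissue_fa`, `init_tissue_md` | 0.5, 0.75e-3 | reference WM tensor for the f-initialization |

## Tractometry

Streamlines are resampled to `n_nodes = 100` points at equal arc-length
spacing (endpoints preserved exactly); node k then refers to the same
relative position along the tract in every subject and hemisphere.
Streamline orientation is harmonized per bundle (each streamline keeps the
endpoint ordering nearer a deterministic canonical start; homologues can be
oriented against the mirrored canonical start), which makes pairing nodes by
index across hemispheres meaningful.

- **Metric values** are sampled by trilinear interpolation at every
  resampled point and averaged per node with equal weight across
  streamlines. A core-weighting hook exists but the default is the
  unweighted mean — simpler, and exactly testable.
- **Involvement fractions** define a node's "spatial extent" as the multiset
  of its resampled streamline points; the fraction per compartment is the
  share of points whose *nearest voxel* carries that label. Labels are
  never interpolated. The combined fraction uses the union of enhancing,
  necrotic and edema labels.
- **Missingness**: points outside the volume are excluded from node means;
  a node with no valid points is missing (NaN) and missingness propagates —
  nothing is imputed.

A node is *involved* when its fraction strictly exceeds the threshold
(default 5%, "more than 5%"); a node pair is *eligible* for asymmetry when
the ipsilateral combined fraction is strictly below the same threshold.
Both readings are literal and kept distinct: a node at exactly 5% is
neither. Both thresholds are configurable.

## Asymmetry and distance analysis

Directional percent asymmetry at paired nodes:
`A = (ipsi − contra) / ((ipsi + contra)/2) × 100`, positive when the
tumor-side value is higher; undefined when the pair sums to zero; bounded in
[−200, 200] for non-negative inputs. Collapse is two-stage everywhere:
node asymmetries are averaged within a tract over eligible nodes, then
per-tract means are averaged (unweighted) across tracts. A pooled-node
variant exists for comparison but is never the default — the two differ
whenever tracts contribute unequal node counts.

Along-tract distance from the tumor margin is measured in node units: the
involved-node set (strict > threshold, combined compartments) is the
within-tract margin; each node's distance is the minimum index difference
to an involved node. Tracts with no involved node have no margin and are
excluded from the distance analysis (an opt-in mode assigns them to the
farthest bin instead). Distances are grouped into closed segments 1–5,
6–10, 11–15, 16–20 and ≥ 21 nodes, averaged per tract then across tracts,
one value per segment, metric and subject. Eligibility filters on
ipsilateral involvement only (contralateral involvement is ≈ 0 for
unilateral tumors); a defensive option screens the contralateral side too.

Subject-level summaries of direct involvement pool both hemispheres of a
bilateral tract group (200 nodes when both present): `involved` is true when
any pooled node exceeds the threshold, and the proportion is the involved
share, recomputed per threshold in the 1–15% sensitivity sweep.

## Inference layer

Omnibus Kruskal–Wallis (tie-corrected, χ² p-values), pairwise two-sided
Mann–Whitney U (exact for n ≤ 10 per group without ties, normal
approximation with continuity and tie correction otherwise), Shapiro–Wilk
normality screening, Spearman correlation and dummy-coded
OLS/logistic regression with glioblastoma as the reference level are
delegated to scipy.stats and statsmodels. Degenerate inputs are flagged,
never silently accepted: all-identical samples report p = 1 with a flag,
perfect separation flags the logistic fit, rank-deficient designs raise
with the collinear column names.

Benjamini–Hochberg FDR is implemented in-repo because the family
stratification carries the analysis's multiplicity logic: within each
family of m tests, `q_(i) = min_{j≥i} (p_(j) · m / j)` on sorted p-values,
mapped back to input order; families are corrected independently and family
labels are explicit inputs, never inferred. Asymmetry comparisons form one
family per diffusion metric; involvement comparisons one family per tumor
compartment. Asymmetry regressions omit age/sex covariates since asymmetry
is computed within subjects.

## The synthetic phantom cohort

The generator produces the conditions the analysis assumes, not realistic
anatomy:

- **Grid**: 64³ voxels at 2 mm isotropic, centred so x = 0 is the
  midsagittal plane; the brain mask is the full grid.
- **Acquisition**: 55 directions at b = 2000 s/mm² plus one b = 0 volume;
  directions from a spherical Fibonacci lattice under a seeded rotation.
- **Tumors**: nested concentric ellipsoids (necrotic ⊂ enhancing ⊂ edema)
  anchored on one tract at a node drawn from the middle of its length,
  with per-subject lognormal size jitter (sd 0.1). Baseline radii 5/8/14 mm
  scaled per group ×1.2 (glioblastoma), ×0.85 (astrocytoma), ×0.6
  (oligodendroglioma); oligodendrogliomas are non-enhancing with
  probability 0.9. This reproduces the enhancing/necrotic volume ordering
  the analysis discriminates on. An irregular-blob option perturbs the
  ellipsoid distance field with smoothed noise while preserving nesting.
- **Bundles**: ten bilateral tract groups as stacked parasagittal arcs
  (10 mm vertical separation, |x| ≈ 20 mm), 10 streamlines each with smooth
  jitter of 1.5 mm; the right homologue is the exact mirror image of the
  left, so profiles are mirror-symmetric by construction when no effect is
  injected.
- **Metric fields**: white-matter baselines FA 0.5, MD 0.75 × 10⁻³ mm²/s,
  FWF 0.10; FWF 0.45 in edema, 0.25 in enhancing tumor, 0.60 in necrotic
  core; FA 0.15 inside the solid tumor. Along ipsilateral tracts FA is
  multiplied by `1 + a·exp(−d/τ)` with `d` the along-tract node distance to
  the tumor margin and `τ = 8` nodes; MD gets the opposite-signed factor.
  Peak asymmetries default to a = −4% (glioblastoma), −2% (astrocytoma),
  +5% (oligodendroglioma): the signs and proximal dominance are the
  structure the pipeline must recover; the magnitudes are free choices of
  this package at desk scale, not measured values. Voxel-wise multiplicative
  Gaussian noise (sd 3%) emulates the residual measurement noise fitted
  maps carry, so distal segments behave as a genuine null rather than a
  deterministic artifact.
- **Signals** (optional): bi-tensor forward model from axially symmetric
  tensors built from (FA, MD, tract tangent), α = FA/√(3 − 2 FA²), with
  Rician noise at SNR 40 defined against the b = 0 signal.
- **Demographics**: ages Normal(62, 10) / (46, 10) / (44, 10) by group,
  40% female — the age ordering mirrors the clinical pattern and feeds the
  regression layer.
- **Determinism**: everything derives from the master seed through spawned
  seed sequences; the cohort manifest is reproducible byte-for-byte.

Default cohort size is 30 (14 glioblastoma / 8 astrocytoma / 8
oligodendroglioma) — deliberately oligodendroglioma-enriched relative to
clinical prevalence so the three-group comparisons are exercised at desk
scale.

**What passing on phantoms shows — and does not.** The phantom validates
the *machinery*: formulas, counting rules, distance logic, averaging order,
multiplicity control, and that the injected directional structure survives
the full profiling-and-asymmetry pipeline. It does not validate anatomical
bundle recognition (bundles carry known identity), preprocessing,
scanner artifacts, crossing fibers or partial-volume gray matter (all out
of scope), and it cannot certify the accuracy of single-shell free-water
estimates on real tissue, where the true tissue tensor deviates from the
initialization reference.

## Numerical choices and degenerate inputs

- Geometry is world RAS mm throughout; voxel indices 0-based; node indices
  1-based (so distance segments read 1–5, 6–10, …).
- Label lookup: nearest voxel (rounded voxel coordinates); metric lookup:
  trilinear.
- Tensor scalars: negative eigenvalues clamp to 0; FA clipped to [0, 1];
  all-zero tensors give FA 0.
- Asymmetry with ipsi + contra = 0 is missing; zero-variance inputs to
  Spearman are missing with a flag; Shapiro–Wilk outside 3 ≤ n ≤ 5000
  raises.
- CSV writers use fixed 9-significant-digit formatting and stable row
  ordering; empty fields encode missing values; analysis rows carry the
  threshold and config hash that produced them.
- Problem sizes used by the test suite and the acceptance script — a 20³
  two-block phantom for the free-water fit and the 30-subject default
  cohort for the end-to-end analyses — are the package's desk-scale
  defaults; all are configurable upward.

## Known limitations

- The free-water fit's accuracy is initialization-dominated (inherent to
  single shell); multi-shell data would remove this, and the fitter accepts
  it, but no multi-shell phantom is provided.
- Tract geometry is schematic; involvement patterns per named tract carry
  no anatomical meaning in the phantom.
- The Tikhonov smoothness penalty blurs genuine f edges at large λ; the
  default 0.5 is chosen for stability, not edge preservation.
- Rician noise is applied to magnitude signals voxel-wise; no spatial noise
  correlation, eddy currents or motion are simulated.
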