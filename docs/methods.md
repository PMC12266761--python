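# Methods

This note documents the quantitative model behind `mitomorph`: what each
metric means, how the estimators work and why they were chosen, what the
synthetic phantoms do and do not emulate, and the numerical tolerances the
test suite enforces.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based; voxel `(i, j, k)` sits at physical
position `(i·sz, j·sy, k·sx)` µm with `spacing = (sz, sy, sx)`. TIFF page
order is z. The default spacing, `(0.09, 0.05, 0.05)` µm, reflects typical
SBF-SEM acquisition where the cutting (z) step is coarser than the lateral
pixel pitch; spacing is a required field of on-disk run configs — there is
no silent fallback, because every 3D metric depends on it. All lengths are
µm, areas µm², volumes µm³.

## 3D metric panel

For each labeled organelle:

- **Volume** `V` = voxel count × `sz·sy·sx`. Exact for the mask; for a
  digitized ball of radius r voxels the relative error vs. `4πr³/3` is below
  0.5 % at r = 10.
- **Surface area** `SA`: marching cubes at the 0.5 level of the zero-padded
  binary mask, followed by 20 iterations of Taubin smoothing
  (λ = 0.5, µ = −0.53) of the mesh in index space, then anisotropic scaling
  of the vertices to µm. Rationale: marching cubes on a *binary* mask
  produces a staircase mesh whose area overestimates smooth surfaces by
  8–9 % almost independently of size; Gaussian pre-smoothing of the mask
  trades this for a shape-dependent shrinkage (−13 % on small cuboids) and
  a persistent ~1–2 % bias at large radii. Taubin smoothing — the shrink-free
  two-pass Laplacian — removes the staircase jitter without moving the
  surface: measured errors are +0.4…+0.8 % for spheres at radii 5–40 voxels,
  −2.6 % for a 40×30×24 cuboid, and −0.2 % for a sphere mask measured under
  2:1 anisotropic spacing against the exact prolate-spheroid area.
- **Slice perimeter**: per occupied z-slice, the sub-pixel (marching-squares)
  contour length of the slice mask, averaged across slices (`mean`;
  `max`/`sum` selectable). A 3D "perimeter" for contour-traced organelles is
  not uniquely defined; the per-slice mean matches how such data are
  natively traced, slice by slice.
- **Sphericity** `ψ = π^(1/3)(6V)^(2/3)/SA`, 1 for a sphere, < 1 otherwise.
- **Complexity index** `MCI = SA³/(36π V²) = ψ⁻³`, exactly 1 for a sphere.
  Note on the constant: part of the literature prints `SA³/(16π² V²)` while
  also stating a sphere minimum of 1; those are incompatible — the 16π² form
  gives 9/(4π) ≈ 0.716 for a sphere and its product with ψ³ is a constant
  0.716, not 1. The package uses the self-consistent 36π constant (so
  `MCI·ψ³ = 1` holds at machine precision, a property the test suite
  asserts for every quantified object) and emits the 16π² variant as the
  auxiliary `mci_16pi2` for comparability.
- Auxiliary columns: raw `SA/V` (µm⁻¹) and mean cross-sectional area, since
  2D-style "area" reported for 3D organelles is ambiguous between the two.

Objects touching the region boundary are kept but flagged (`touches_edge`),
with a config switch to exclude them; objects thinner than 2 voxels along
any axis are flagged low-confidence for the isosurface. Scale covariance is
exact by construction: spacing enters only as a linear map on mesh vertices
and contour segments, so multiplying spacing by s multiplies V by s³, SA by
s², perimeter by s and leaves ψ and MCI bit-identical.

## 2D TEM panel

Area is pixel count × pixel area (exact for the mask). Perimeter is the
marching-squares contour length of a Gaussian-smoothed copy of the mask
with size-scaled width σ = clip(0.5·√r_eq, 1, 3) px (r_eq the
equivalent-circle radius): a fixed σ leaves a constant staircase-ripple
bias (~0.4 % at σ = 1) so measured circularity plateaus ~1 % below 1 no
matter the resolution, while the size-scaled σ drives both the ripple and
the curvature bias (O(σ²/r²)) to zero — measured |1 − C| for digitized
circles falls monotonically 0.034 → 0.0002 over radii 8 → 128 px. The cost
is a modest overshoot for small convex shapes; the recorded discretization
bound is `C ≤ 1 + C_EPS` with `C_EPS = 0.04` at r_eq ≥ 8 px. Masks too thin
to survive smoothing fall back to the binary contour.

Circularity is `4πA/P²`. The cristae-volume proxy is Σ cristae area /
mitochondrial area (per mitochondrion and pooled per field/ROI); it is a
dimensionless ratio, invariant to pixel size. Cristae scores (1–4, 4 =
healthy) are observer-assigned input data: the package validates the range,
joins them to cristae, and aggregates per-group mean/median/histograms —
it never infers a score from pixels, which would be invention. Cristae are
assigned to the mitochondrion label under their pixels; cristae on
background are orphans, reported in QC and excluded from proxies. 2D
connectivity is 8-connected foreground / 4-connected background.

## Phantoms and ground truth

Shape families: sphere, ellipsoid (mildly triaxial, random orientation),
capsule ("tube": cylinder + hemisphere caps), ring torus, and branched
(3–4 capsule arms from a junction). Sizes are log-normal — organelle sizes
are strictly positive and right-skewed — with medians chosen for
intermyofibrillar mitochondria (volumes ~0.1–1 µm³): sphere radius median
0.30 µm, ellipsoid minor axis 0.25 µm with elongation median 2.0, tube
radius 0.18 µm and length 1.2 µm. Draws are truncated at ±2.5σ in log
space: an organelle taller than the imaged slab could never appear
untruncated in a ~50-slice ROI, and the generator guarantees no object is
cut by the boundary.

Ground truth: closed forms for sphere/capsule/torus; ellipsoid surface via
Gauss–Legendre quadrature of the parametric integral (relative error
< 2×10⁻⁶ at order 64, i.e. 10³–10⁴× tighter than the estimators it
checks); ellipse perimeter likewise by quadrature of the arc-length
integral rather than Ramanujan's approximation, so the oracle is strictly
more accurate than anything under test. Branched unions have no closed
form: their ground truth is numeric (fine-grid volume at 8 samples per arm
radius; surface by Monte-Carlo sampling of each arm's surface with
rejection of points inside sibling arms), tagged `gt_method="numeric"` and
never used as a tight oracle.

Placement: rejection sampling with conservative bounding-sphere separation,
largest shapes first (small ones slot into gaps), a 1-voxel boundary
margin, and a hard cap of 1000 attempts per object — a deterministic
"region too crowded" error beats silent truncation.

The cohort simulator draws per-patient regions from child seeds of one root
seed. The "old" group's linear dimensions are scaled by
`volume_shift^(1/3)` (default 1.5× in volume) and its elongation by
`elongation_shift` (default 0.6), with the elongation change made
volume-preserving (minor axes / tube radius compensated) so the two effects
are orthogonal: volume up, sphericity up, complexity down — the aging
phenotype — with independently tunable sizes. With both shifts at 1 the
groups are exchangeable, which the test suite uses for type-I calibration
(rejection rate of the pooled Mann–Whitney within the binomial 99 %
envelope of α over 200 seeds). `voxelize=False` returns the identical
analytic populations without rasterization (the RNG draws shapes before
placing them), which is what makes 200-seed calibration affordable.

What the phantoms do **not** emulate: grayscale texture, segmentation error
(labels are perfect), mitochondria–ER contact geometry, within-patient
spatial correlation of sizes, and networks/branch topology beyond the
simple branched family. A green test therefore establishes estimator
correctness on clean masks, not robustness to tracing error.

## Statistics

Mann–Whitney U is two-sided; exact null enumeration when min(n₁,n₂) ≤ 8
and the pooled sample is tie-free, else the normal approximation with
tie-corrected variance and 0.5 continuity correction (the measured
exact-vs-asymptotic gap at the 8-vs-8 boundary is ≤ 0.011). Both inference
modes are always reported: pooled organelles (more powerful, vulnerable to
pseudoreplication) and per-patient means (the dots in cohort figures);
single-patient groups are flagged rather than silently tested. Group
summaries are mean ± SEM (ddof = 1).

One-way ANOVA post hoc uses the studentized range (Tukey, all pairs) or
Dunnett's multivariate-t (each group vs. a named control); Dunnett's
distribution is integrated by randomized QMC inside scipy, so the stream is
pinned for bit-reproducible reports.

The two-stage adaptive FDR procedure runs a linear step-up at
q′ = q/(1+q), estimates the true-null count m₀ = m − r₁, and reruns the
step-up at q′·m/m₀ (no rejections if r₁ = 0, all if r₁ = m). Its
discoveries provably contain the plain Benjamini–Hochberg discoveries at
the same q, and lowering q never adds discoveries; both properties are
asserted empirically, and the implementation is cross-checked against an
independent brute-force execution and against `statsmodels`' `fdr_tsbky`.

Stars: `*` p ≤ 0.05, `**` ≤ 0.01, `***` ≤ 0.001, `****` ≤ 0.0001.

## Mito-typing

Per patient, bin b of n holds the organelle whose volume is nearest the
(b + ½)/n quantile of that patient's own volume distribution (ties break on
the smaller label). Quantile representatives — rather than all organelles
sorted — keep rows comparable across patients with different counts. Rows
are padded and flagged when a patient has fewer organelles than bins.
Thumbnails are maximum-intensity silhouettes along a configurable axis with
a spacing-derived scale bar.

## Determinism and tolerances

All randomness descends from one root seed through `numpy` seed sequences;
re-running any stage with the same config and seed reproduces byte-identical
CSVs (manifest paths are stored relative for location independence).
Key enforced tolerances: sphere ψ within 2 % and MCI within 6 % at radius
15 voxels; sphere SA within 3 %; cuboid SA within 5 %; `MCI·ψ³ = 1` and
scale covariance at 1e-12 relative; digitized circle circularity within
2 % at radius 20 px; discretization bounds ψ ≤ 1.02 and C ≤ 1.04 as
recorded above.

## Known limitations

- Surface areas of objects thinner than ~2 voxels are low-confidence (and
  flagged); the slab z-resolution bounds which organelles are measurable.
- The bounding-sphere placement test is conservative: elongated shapes are
  spaced further apart than strictly necessary, so phantom regions are less
  crowded than real intermyofibrillar packing.
- The branched family's numeric ground truth carries ~0.5 % uncertainty;
  it is excluded from tight oracle tests.
- Circularity of convex shapes can exceed 1 by up to 4 % below ~8 px
  equivalent radius; published TEM tracings are usually far above this.
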