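# Methods

## Coordinate conventions and projection geometry

Room coordinates are patient axes relative to the linac isocenter, ordered
(LR, SI, AP) in mm: LR positive toward patient left, SI superior, AP
anterior. The kV source and flat-panel imager rotate rigidly about the SI
axis; at gantry angle θ = 0° the source is anterior and the beam travels
anterior → posterior. The beam frame at θ is the orthonormal triple

- a(θ) = (cos θ, 0, sin θ) — resolved lateral direction,
- b = (0, 1, 0) — resolved vertical direction (always SI),
- c(θ) = (−sin θ, 0, cos θ) — unresolved depth direction toward the source.

A point p projects to imager-plane coordinates
(u, v) = (a·p, b·p) · sdd/(sad − c·p), where sad is the source–isocenter
and sdd the source–imager distance. No vendor convention is implied; the
same convention is used by the simulator and the tracker, which is the only
requirement for a self-consistent study. Defaults are a standard C-arm
geometry, sad = 1000 mm and sdd = 1500 mm, with a 0.8 mm imager pixel so
that 25 px ≡ 20 mm (the equivalence built into the outlier filter), and a
512 × 384 px panel. The imager v axis is aligned with SI at every gantry
angle, as is the case for a gantry-mounted panel rotating with the source.

Imager measurements are expressed at isocenter scale by dividing by the
nominal magnification sdd/sad. This is exact only at zero depth; the
estimation step optionally applies one refinement pass that re-scales each
observation with the magnification at its estimated depth (default: one
pass).

## Digital phantom

The phantom replaces patient CBCT scans, which cannot be redistributed. It
simulates the lead-tip trajectory and renders it into kV projections with
exact ground truth.

**Motion model.** Position at time t is

baseline + drift·t + A_resp ∘ resp(t) + A_card · sin(2π f_card t + φ),

with per-axis amplitudes. The respiratory waveform is cos⁴(πt/T + φ) for
free breathing and abdominal compression — the standard radiotherapy
motion-literature shape, with a long end-exhale dwell and range [0, 1] — a
slow low-amplitude sinusoid for breath-hold residual motion, and a fast
small sinusoid for high-frequency ventilation. Cardiac motion is a single
sinusoid; real cardiac motion is non-sinusoidal, which is acceptable for a
surrogate phantom. Per-regime defaults (respiratory amplitude in mm
(LR, SI, AP); period in s):

| regime | amplitude | period | rationale |
|---|---|---|---|
| DIBH | (0.3, 1.0, 0.5) | 12 | residual drift within a breath-hold |
| FB | (2, 8, 3) | 4 | typical free-breathing excursion |
| AC | (1, 4, 1.5) | 4 | compression damps FB by ~half |
| HFV | (0.5, 1.5, 0.8) | 0.24 | shallow, ~250/min ventilation |

Cardiac default is (1, 1.5, 1) mm at 70 beats/min. A scan is 368
projections over a 360° arc in 60 s by default.

**Rendering.** The lead tip is a cylinder (default radius 1 mm, length
8 mm, both configurable since real tip geometry varies per lead model).
Each pixel receives contrast × chord length of a ray through the cylinder.
Rays are parallel within the footprint — divergence across a ~10 mm object
at sad = 1000 mm is negligible — but the bundle is anchored at the *local*
magnification sdd/(sad − w₀) of the object depth, so the rendered blob
centroid coincides with the exact divergent forward projection (worst
centroid error ≈ 0.15 px over ±20 mm offsets; anchoring at the nominal
magnification instead leaves an ≈ 0.7 px systematic shift at large depths).
Optional clutter (straight high-contrast wire segments) is added before
white Gaussian noise. Stacks are written as multi-frame 16-bit TIFF with a
global offset/scale recorded in the image description.

**What the phantom does not emulate:** anatomical background (ribs,
diaphragm, mediastinum), scatter and beam hardening, detector lag, ECG-like
cardiac waveforms, or lead flex. Passing tests therefore demonstrate the
correctness of the geometry, matching, filtering and estimation machinery
under controlled contrast/noise/clutter — not clinical segmentation
performance on patient images, where visibility losses and overlapping
hardware are the dominant failure modes.

## 2D segmentation

The planning tip is forward projected per angle and a 70 × 70 px search
region extracted, shifted (not padded) to stay inside the image so NCC
statistics never see synthetic padding. The template is the cylinder
rendered noiselessly as seen at that gantry angle (tight bounding box plus
2 px margin). The bank rotates the lead axis in-plane about the beam axis
in 5° steps — a symmetric set {(k − (n−1)/2)·5°}, n = 8 for DIBH and 20
otherwise, since breath-hold leaves less cardiorespiratory tilt — at
isotropic scales {0.9, 1.0, 1.1}. Rotations are realized by rotating the
cylinder axis and re-rendering rather than by image-space interpolation,
which keeps every template exact.

NCC is the Pearson correlation of the template with each covered patch
(zero-variance patches score 0), computed with scikit-image's
`match_template`; a brute-force double-loop implementation serves as the
test oracle (agreement ≤ 2e−15). The global argmax over placement ×
rotation × scale wins; exact ties break toward the smallest |rotation
offset| (negative first), then the scale nearest 1.0 (smaller first), then
the smallest row-major placement. The reported position is the
intensity-weighted centroid of the winning template footprint — the
centroid of the segmented area, not the placement corner. Matching is
integer-pixel by design; on a static target this leaves a constant
fractional-pixel quantization bias (≈ 0.1–0.2 mm), which bounds the
accuracy of anything derived from segmentations alone. Every frame emits a
match with its score; an optional minimum-NCC visibility threshold
(default off) pre-flags low-score frames.

## Online SI outlier filter

Gross mismatches (wires, overlapping hardware) land far from the tip,
predominantly along SI where respiratory excursion is largest. The filter
keeps a running mean of accepted SI pixel values, updated incrementally so
the scheme remains real-time capable, and rejects segmentations deviating
more than 25 px (20 mm) from it. The first 10 segmentations are accepted
unconditionally while the mean initializes (the initialization is not
otherwise determined; the warmup length is a parameter). Rejected
segmentations never update the mean and are flagged, not removed. Only SI
is filtered; no lateral gate is applied.

## Maximum-likelihood Gaussian 2D → 3D estimation

Accepted segmentations are backprojected to isocenter scale at nominal
magnification, giving per-angle resolved observations (û, v̂). Target
positions over the scan are modeled as one global 3D Gaussian N(μ, Σ) —
one model per scan, no time dependence. At angle θ the observation is the
marginal of this Gaussian onto span(a, b):

mean (aᵀμ, bᵀμ), covariance [[aᵀΣa, aᵀΣb], [bᵀΣa, bᵀΣb]] + σ²ₘI.

σ²ₘ (default 0.25 mm², ≈ half-pixel localization noise at isocenter scale)
is an isotropic measurement-noise variance; because (a, b, c) is
orthonormal it is equivalent to conditioning a 3D Gaussian with covariance
Σ + σ²ₘI₃, which is the identity the quadrature oracle in the tests
exploits. It also keeps the per-angle covariance invertible in degenerate
(static-target) cases and stops Σ from absorbing segmentation jitter.

The nine free parameters (μ plus the lower-triangular Cholesky factor of
Σ with log-diagonal — unconstrained, PSD by construction) minimize the sum
of bivariate-normal negative log densities via L-BFGS (gradient norm 1e−6,
relative NLL change 1e−14, max 500 iterations; non-convergence raises an
error carrying the last iterate). A variance floor of 1e−4 mm² on the Σ
diagonal guards the static case. Initialization is closed-form: μ_SI is
the mean v̂; (μ_LR, μ_AP) solve the least-squares system
û = cos θ·μ_LR + sin θ·μ_AP; Σ starts at 25 mm²·I. Cross-covariances can
be frozen at zero (`fit_cross=False`); the default fits all nine
parameters, since cardiorespiratory motion correlates the axes and the
correlation is exactly what makes depth conditioning informative. A
warning is raised when observations span under 30° of arc, where the
unresolved-axis parameters are weakly identifiable.

Per projection, the depth is the conditional mean
ŵ = cᵀμ + kᵀC⁻¹((û, v̂) − m_uv) with k = (aᵀΣc, bᵀΣc), and the 3D
estimate is û·a + v̂·b + ŵ·c — the resolved components stay exactly at
their observed values (with refinement disabled). The optional refinement
pass re-scales (û, v̂) by (sad − ŵ)/sad and re-conditions once.

The reference trajectory ("ground-truth estimation") runs the identical
fit-and-condition path on the phantom's exact 2D projections; the raw
variant runs it on all segmentations with filtering disabled. Rejected
frames produce no estimate (no interpolation) and are listed as skipped.

## Metrics

2D success: per-axis pixel errors scaled by the pixel spacing; a frame
succeeds when *both* axes are strictly below 2 mm (the CT slice
thickness); the two directions are tested separately, not as a Euclidean
distance. Displacement: absolute per-axis deviation from the scan-mean
position, summarized by 5th/50th/95th percentiles with linear
interpolation between order statistics. 3D error: signed per-axis
differences on common frames; success requires all three axes strictly
below 2 mm. Wilcoxon signed-rank: zeros dropped, midranks for ties; exact
two-sided p by enumeration of all 2ⁿ sign assignments for n ≤ 12, normal
approximation with tie correction (no continuity correction) otherwise.
The in-package implementation exists because the exact-with-midranks /
approximate hybrid is pinned by the evaluation design; scipy's
implementation cross-checks it in the tests where the definitions
coincide.

## Numerical and design notes

- Problem sizes: the validation suite uses 368-projection scans for
  end-to-end checks (the typical per-scan projection count) and 24–120
  projection scans for unit-level pipeline tests; quadrature oracles use
  2×10⁵-point trapezoid grids.
- Determinism: every stochastic component takes a seed or
  `numpy.random.Generator`; dataset generation is byte-reproducible for a
  fixed seed and config.
- Degenerate inputs: points at or behind the source, sub-70×70 images,
  zero-variance templates, empty observation sets and all-zero Wilcoxon
  differences raise typed errors with context rather than propagating NaNs.
- The cluttered acceptance scenario (tilted lead, bright crossing wire,
  higher noise) is constructed so that foreshortened views genuinely
  mislead the matcher — it exercises the filter and the filtered-vs-raw
  comparison on realistic failure behavior rather than injected labels.

## Known limitations

- The Gaussian position model is stationary within a scan; slow baseline
  drift inflates Σ rather than being tracked.
- Integer-pixel matching bounds static accuracy at the quantization scale
  (≈ 0.2 mm SI at the default geometry).
- The filter's running mean can be captured by a long early run of
  consistent outliers (warmup accepts unconditionally).
- Depth conditioning degrades toward the uninformative prior mean when
  axes are uncorrelated and isotropic; its accuracy on real data depends
  on how Gaussian and how correlated the true motion is.
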