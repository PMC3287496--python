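# Methods

## Model and assumptions

All filters in this package integrate the anisotropic diffusion PDE
∂I/∂t = div(c·∇I) with an explicit 4-neighbor Euler scheme on the pixel
grid, under zero-flux (symmetric reflection) boundary conditions. The
underlying noise model is fully developed multiplicative intensity
speckle: the observed image is I₀ = clean × n with n unit-mean,
signal-independent, and coefficient of variation 1/√L for L "looks".
Under this model the ratio statistic q = s/mean (the instantaneous
coefficient of variation, ICOV) is approximately the speckle scale
q₀(t) in homogeneous regions regardless of their brightness, which is
what makes coefficient-of-variation-driven diffusion appropriate for
speckle where gradient-driven (Perona–Malik-type) diffusion is not: raw
gradients scale with local intensity, q does not.

Per iteration the engine (1) estimates the squared ICOV field q²,
(2) updates the speckle scale q₀(t), (3) maps (q², q₀²) to a diffusion
coefficient field c ∈ [0, 1], and (4) applies one explicit step. The
four methods differ only in steps (1) and (3):

- **srad** — differential ICOV (one-sided gradients and the 4-neighbor
  Laplacian); c = 1/(1 + (q²−q₀²)/(q₀²(1+q₀²))).
- **dpad** — windowed ICOV: unbiased variance over squared mean on a
  5×5 square window; c = (1 + 1/q²)/(1 + 1/q₀²).
- **tauber** — differential ICOV with the Tukey biweight kernel applied
  to the SRAD normalized excess S = (q²−q₀²)/(q₀²(1+q₀²)); c = ½(1−S)²
  for S ≤ 1, else exactly 0.
- **rdpad** — diamond-window ICOV with the Tukey kernel applied to the
  robust ratio R = (q²−q₀²)/(q₀²(1+q²)); c = ½(1−R)² for R ≤ 1, else
  exactly 0, equivalently zero for q² > 2q₀²/(1−q₀²) when q₀² < 1.

The algebraic identity c_dpad = 1/(1+R) (exact for the unclamped DPAD
form; property-tested to 10⁻¹²) shows rdpad and dpad agree near q ≈ q₀
up to the ½(1−R)² vs 1/(1+R) reparameterization; they part ways at large
q, where rdpad's coefficient hits exactly zero ("edge-stopping") while
dpad's stays positive. That hard zero is the mechanism behind both of
rdpad's headline properties: sharper retained edges and insensitivity to
the iteration count.

### The diamond ICOV

The rdpad estimator reads the 13 pixels at city-block distance ≤ 2
(the diamond inscribed in the 5×5 square; ordering: center, the
distance-1 ring N/W/E/S, the distance-2 ring row-major) and computes

    q² = (1/12) Σ_{m<n} (vₙ − vₘ)²  /  Σ_m vₘ² .

Two deliberate points. First, the 13-cell diamond is adopted as the
unique standard 13-cell subset of a 5×5 window; the formula is invariant
to the ordering of v₁..v₁₂ (property-tested), so the fixed ordering only
pins down determinism of the `diamond_window` accessor. Second, the
denominator is the raw sum of squares Σv², not 13·mean² — this is not a
conventional variance/mean² estimator (it is smaller by roughly a factor
13 in homogeneous regions and bounded above by 13/12), but it is the
form the method defines, and it is implemented literally. The practical
consequence is only a rescaling of the q²-vs-q₀² operating point, partly
absorbed by the shared q₀ schedule. The implementation evaluates the
pair sum through the exact identity Σ_{m<n}(vₙ−vₘ)² = 13Σv² − (Σv)²,
verified against exhaustive 78-pair enumeration.

## Parameters

| parameter | default | units | notes |
|-----------|---------|-------|-------|
| `dt` | 0.05 | diffusion time / iteration | explicit-scheme stability requires dt ≤ 0.25 when c ≤ 1 (enforced); 0.05 is the conventional working value |
| `n_iter` | 300 | iterations | the standard protocol length; rdpad is designed to tolerate much larger values |
| `q0_initial` | 1 | — | coefficient of variation of fully developed (L = 1) intensity speckle |
| `rho` | 1/6 | 1 / diffusion time | decay rate of q₀(t) = q₀·e^(−ρt) |
| `q0_mode` | `decay` | — | `median` re-estimates q₀ each iteration as √median(q²) |
| `looks` (phantom) | 1 | — | gamma-speckle shape; noise CV = 1/√looks; 1 is the strongest, fully developed case |

**q₀ runs in diffusion time.** The decay schedule is evaluated at
t = n·dt, not at the iteration index n. The rate ρ = 1/6 belongs to the
time variable of the PDE; evaluated per iteration at dt = 0.05 it would
collapse q₀ to e⁻⁵⁰ within 300 iterations and freeze every filter after
a few dozen steps. With t = n·dt, q₀(300 iterations) = e^(−2.5) ≈ 0.08
and the filters behave as designed. This is the package's own reading of
an underdetermined convention and is recorded here deliberately; the
`q0_schedule` function itself is the plain closed form of whatever
argument it is given.

**q₀² ≥ 1 at start-up.** With q₀ = 1 the algebraic cutoff
2q₀²/(1−q₀²) is undefined; the rdpad rule then falls back to the
equivalent R ≤ 1 test and logs a one-line warning (this fires on the
first iteration of every default run, harmlessly — q₀ drops below 1
immediately afterwards).

## The phantom generator

`make_phantom` renders piecewise-constant geometry (axis-aligned
rectangles and disks on a constant background, all levels strictly
positive) and multiplies by i.i.d. unit-mean gamma noise with shape L —
the standard L-look intensity-speckle model consistent with the
Lee/Kuan estimators the SRAD/DPAD lineage derives from. Edge and
homogeneous pixel sets are derived from the clean geometry by a
4-neighbor equality scan, so the contrast metric can be evaluated on
exactly the pixels where each claim lives. Generation is pure: the same
arguments and seed reproduce the noisy image bit for bit.

What the phantom does **not** emulate: Rayleigh amplitude statistics,
log-compression of B-mode display pipelines, spatial correlation of the
point-spread function, attenuation, or beam-geometry artifacts. Passing
tests on the phantom therefore demonstrate the filters' mathematical
behavior under the stated noise model — edge-stopping, iteration
insensitivity, contrast collapse in homogeneous regions — not clinical
performance on scanner data, where speckle is spatially correlated and
compressed.

## Evaluation metrics

Region contrast Cw = (1/m) Σ_w |c(x,y)|·log(1+|c(x,y)|), with c the
4-neighbor Laplacian contrast 4I − (N+S+E+W) and natural log. The
absolute value in both factors is a deliberate repair: the signed
contrast is frequently ≤ −1, where log(1+c) is undefined, and speckle
drives c symmetrically in both directions. Evaluated over the
homogeneous set, Cw measures residual speckle; over the edge set it
measures surviving structure. One caveat discovered under the strongest
noise setting (looks = 1): the *noisy* edge-set Cw is dominated by
speckle contrast (≈ 3150 here, versus ≈ 1170 for the clean image), so
no filter that actually removes speckle can retain a large fraction of
the noisy edge value; the meaningful comparison is the ordering between
filters at fixed protocol, and that is what the tests assert
(rdpad ≈ 2.7× dpad on the standard phantom).

Also provided: MSE/PSNR against the clean reference, horizontal line
profiles, and the iteration-sensitivity statistic (mean absolute pixel
difference between two snapshots of one run, here at 300 vs 1000
iterations).

## Numerical choices

- All arithmetic in float64; integer images converted on load, never
  modified in place; metrics computed on the float pipeline only.
- Coefficients clamped to [0, 1]: the raw robust forms reach 2 at
  R = −1 and raw SRAD exceeds 1 for q < q₀; the clamp preserves the
  dt ≤ 0.25 extremum principle (empirically tested on random images
  across dt ∈ [0.05, 0.25]) and the c ≤ 1 convention.
- Division safety: images floored at 10⁻⁶ × max before ratio
  statistics; q² floored at 10⁻¹² before 1/q²; the median q₀ estimate
  floored at 10⁻⁸ so q₀(t) > 0 always holds (a zero-majority q² field
  would otherwise return exactly 0).
- Numerically negative q² (possible in the differential SRAD form and
  in variance round-off) clipped to 0.
- Borders: symmetric reflection for every windowed, differential and
  stepping operator (zero-flux).
- The diffusion step weights the south/east fluxes by the neighbor's
  coefficient and the north/west fluxes by the center's own — the
  one-sided-coefficient scheme of the SRAD reference lineage.
- Output of each step floored at 0 (intensities are nonnegative).

## Problem sizes

The test suite and the acceptance script use a 128×128 single-disk
phantom at looks = 1, seed 0 (script: seeded from the command line),
dt = 0.05, with runs to 1000 iterations and comparisons at 300 — small
enough to run the whole suite in seconds while leaving every qualitative
contrast comfortably large (homogeneous Cw falls to < 1 % of noisy;
edge and drift orderings hold across seeds). Oracle tests run exhaustive
scalar-loop recomputations on 5×5 patches and small random images.

## Known limitations

- 2-D only; no 3-D windows or time stepping.
- Explicit Euler only (no AOS/implicit schemes), so large effective
  diffusion times need many iterations.
- The q₀ decay schedule is an open convention of this filter family;
  results at fixed iteration count depend on it. The data-driven
  `median` mode is provided as the alternative.
- The diamond-ICOV denominator is implemented literally (see above);
  users porting parameters from variance/mean²-based implementations
  should expect a different q² scale for the rdpad estimator.
- Quantitative values measured on real scanner images (with manually
  selected evaluation regions) are not reproducible from this package
  alone; the synthetic protocol reproduces the orderings and
  qualitative behavior, not those printed values.
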