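# Methods

## The model

salseg segments a 2-D image by evolving a level-set field φ whose zero
contour is the segmentation boundary (interior-positive convention:
φ > 0 inside). The evolution is a pure advection equation

    ∂φ/∂t = α · F · |∇φ|,

discretized with explicit Euler steps of size Δt, with |∇φ| computed by
central differences (one-sided at image borders). The driving force F
is a weighted blend of three per-pixel terms, each normalized to
[−1, 1] so that the blend weights act on a common scale:

1. **DoG edge force** `F_DoG = G_σ1∗I − G_σ2∗I`, σ1 < σ2, divided by
   its maximum absolute value. Its sign is positive on the bright side
   of an edge and negative on the dark side, so its zero-crossing set
   is an edge map that attracts the contour.
2. **Signed pressure force** `F_SPF = (I − (j1+j2)/2)/max|·|` with
   j1, j2 the interior/exterior intensity means weighted by the
   regularized Heaviside `H_ε(φ) = ½(1 + (2/π)·arctan(φ/ε))`. It
   expands the contour where the pixel is brighter than the mid-mean
   and shrinks it where darker (for j1 > j2).
3. **Adaptive saliency force** of the identical signed-pressure form,
   driven by the saliency map `S = |mean(I) − G_σsal∗I|` and its
   Heaviside-weighted means s1, s2. It supplies a cue that survives
   texture and weak edges: visually distinctive regions deviate from
   the global mean.

The default blend groups the two intensity-derived terms under `s`:

    F = s·(w·F_DoG + (1−w)·F_SPF) + (1−s)·F_SAL.

This grouping makes `s` a clean intensity-vs-saliency dial and keeps
the combined force inside [−1, 1] (a convex combination). The
alternative, un-grouped form `s·w·F_DoG + (1−w)·F_SPF + (1−s)·F_SAL`
— in which `s` does not attenuate the SPF term and the blend can reach
magnitude 2.25 — is kept behind the `literal_eq2` flag for users who
want that exact weighting; it is not the default because it makes the
two dials interact in a way the parameter descriptions contradict.

The saliency force's denominator uses the deviation of S itself,
`max|S − (s1+s2)/2|`; normalizing by an intensity deviation instead
would not bound the ratio by 1.

## Initialization and the seed ROI

φ starts as a binary constant: +ρ strictly inside the seed ROI, 0 on
the ROI's one-pixel inner boundary (4-adjacency — the thinnest discrete
realization of a zero set), −ρ outside. ROIs are rectangles, circles,
or arbitrary binary masks. Because the initialization is sign-symmetric
up to the (φ, α) → (−φ, −α) flip, the interior-positive choice loses no
generality; the test suite verifies the flipped run mirrors φ exactly
at every iteration.

## Regularization and the selective-binary reset

After each Euler step φ is reset to ρ·sign(φ) and then smoothed with a
Gaussian kernel (σ_reg). The smoothing replaces both the curvature
penalty and re-initialization to a signed distance function; the reset
deserves its own justification. Without it, the Euler updates grow the
interior and exterior amplitudes of φ at different exponential rates
(the force magnitudes inside and outside the object differ), and
Gaussian smoothing of an unbalanced ±amplitude profile drags the
zero-crossing toward the weaker side at a rate of a few pixels per
iteration — the contour then creeps across flat background *against*
the force sign, eventually swallowing neighboring objects. In a direct
experiment on the two-disk scene the un-reset contour leaked across a
40-pixel gap and captured essentially all of the second disk. The
reset keeps the two plateaus at exactly ±ρ, so the smoothed interface
is symmetric, its zero-crossing stays put in the absence of force, and
|∇φ| vanishes a few σ_reg away from the interface. That locality is
precisely what makes seeded segmentation selective: plateau regions
receive zero update regardless of the force, so an object is captured
only if the advancing front physically reaches it.

## Parameters

| name | default | meaning |
|------|---------|---------|
| s | 0.9 | intensity group vs saliency weight (dimensionless, [0,1]) |
| w | 0.5 | DoG edge vs SPF region weight within the intensity group |
| σ1, σ2 | 1, 2 | DoG Gaussian widths (px); widen the gap for noisy images |
| σ_reg | 1 | level-set smoothing width (px) |
| σ_sal | 2 | saliency-map blur width (px); no canonical value exists, 2 px keeps the map aligned with object scale while suppressing pixel noise |
| ρ | 1 | initialization amplitude |
| ε | 1.5 | Heaviside width; controls how soft the region membership is |
| α | 20 | force gain; image-dependent in general, 20 balances speed and stability at Δt = 1 |
| Δt | 1 | Euler step |
| max_iterations | 300 | hard cap |
| tol, patience | 1e-4, 5 | stop when the changed-mask fraction stays below tol for patience iterations |

The stopping rule is a deliberate design choice: the changed-pixel
fraction is cheap, monotonicity-free and directly measures contour
motion; typical suite scenes converge in 17–26 iterations.

Gaussian convolutions truncate the kernel at radius ⌈3σ⌉ with reflect
(half-sample symmetric) boundary handling, which preserves the total
field sum; all normalizing denominators carry a 1e-10 guard so constant
inputs yield zero force fields rather than NaNs. A region whose
Heaviside mass falls below 1e-6 of the pixel count triggers a logged
degenerate-region warning. Metrics with zero denominators are reported
as missing values, never coerced to 0 or 1, so set averages are not
corrupted. Dice and F1 are computed from the same formula
2TP/(2TP+FP+FN) and will always agree.

RGB inputs are collapsed to Rec. 601 luminance before any force is
computed: all force definitions are written for a scalar image, and
the SPF/SAL ratio forms are invariant to affine intensity rescaling,
so the [0,1] normalization changes nothing mathematically while fixing
the meaning of ε and α across bit depths.

## Synthetic scenes: what they emulate and what they do not

The generator renders piecewise-constant scenes (disks, rectangles),
multiplied by a smooth bias field `1 + strength·(ramp − ½)` (linear or
Gaussian-bump ramp — the multiplicative convention of the
bias-field/intensity-inhomogeneity literature), then corrupted by
Gaussian or salt-and-pepper noise from a seeded generator and clipped
to [0,1]. Ground-truth masks are the exact pre-degradation object
supports, so they are independent of bias and noise. The standard
suite covers the regimes the method claims: a homogeneous two-phase
object, the same object under a strength-0.5 bias field, under bias
plus σ=0.05 Gaussian noise, under 2% salt-and-pepper noise, a
two-object scene for the selectivity check, and a weak-boundary scene
with contrast 0.10. Suite scenes are 256×256, objects of radius
38–60 px, foreground/background 0.9/0.1 — sizes chosen so that scene
statistics (region areas, edge lengths) are stable while a full
segmentation runs in well under a second.

What the suite does **not** emulate: textured interiors, cluttered
natural backgrounds, vector-valued (color-contrast) saliency,
partial-volume boundaries, or 3-D anatomy. Passing these tests shows
the forces, the evolution and the selectivity mechanism are
implemented correctly and behave as designed under inhomogeneity and
noise; it does not certify accuracy on any particular clinical
dataset.

## Numerical and degenerate-input notes

- The run is fully deterministic: identical image, ROI and parameters
  reproduce the output mask bit-for-bit.
- Binarize-then-smooth rounds off sharp 90° corners of a seed
  rectangle by one pixel; on a constant image (all forces zero) the
  output is the seed interior minus those corners.
- arctan-Heaviside tails: at |φ| = ρ = 1 with ε = 1.5 the membership
  weights are soft (H ≈ 0.65/0.35), so j1 and j2 are blended rather
  than crisp region means during early evolution; this is intended —
  it is what lets a small seed "feel" the whole object.
- A ROI touching the image border is rejected for circles (must fit
  inside) and clamped semantics are never guessed: out-of-bounds
  geometry is a validation error.

## Known limitations

- Purely global region statistics: two-phase scenes are the design
  target; multi-phase images are handled only through the saliency and
  edge cues.
- The explicit Euler step with α ≈ 20 is stable only because of the
  per-iteration reset and smoothing; removing either requires a much
  smaller α.
- Selectivity depends on spatial separation: objects whose supports
  touch the advancing front are captured.
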