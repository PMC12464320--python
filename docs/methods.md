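# Methods

## The iMIC distribution model

A droplet single-cell AST experiment exposes ~N individually encapsulated
cells to each concentration *c* of an antibiotic ladder and records, per
droplet, endpoint growth / no-growth. Writing N(c) for the total droplet
count and N₊(c) for the growth-positive count, the analysis works on the
normalized resistance profile

    f₊(c) = N₊(c)/N(c),    F_R(c) = f₊(c)/f₊(0),

which estimates the survival function of the per-cell individual MIC
(iMIC): F_R(c) = P(iMIC > c). The fitted form is the Gompertz-type
survival curve φ(c) = exp{−(c/p₁)^p₂}, i.e. the iMIC is modelled as
Weibull-distributed with scale p₁ (concentration units) and shape p₂
(dimensionless). The fitted-curve and closed-form statistics follow:

| statistic | expression |
|---|---|
| mode | p₁(1 − 1/p₂)^(1/p₂) for p₂ > 1, else 0 (degenerate, flagged) |
| raw moments | E[c^k] = p₁^k Γ(1 + k/p₂), evaluated via log-gamma |
| mean, SD | μ = E[c]; σ² = E[c²] − μ² |
| skewness | γ = (E[c³] − 3μσ² − μ³)/σ³ |
| kurtosis | Pearson μ₄/σ⁴ from the same raw moments |
| threshold c(ε) | p₁(−ln ε)^(1/p₂), with φ(c(ε)) = ε to machine precision |
| DoH | (iMIC)_all / (iMIC)_start |
| RMSD, CoV | σ/mode, σ/μ |

Every closed form is cross-checked at runtime by adaptive quadrature of
the density (`Moments.errors`); the reported error estimates are the
absolute closed-form-vs-quadrature discrepancies, typically ≲1e−10.

Assumptions: one cell per occupied droplet decides growth (justified by
Poisson loading, see below); endpoint readout only — dormant or very slow
growing cells are indistinguishable from dead ones; iMIC values are i.i.d.
across cells (no spatial or lineage structure).

## Threshold policy

"Complete inhibition" is asymptotically unreachable on a curve of this
form, so the named threshold concentrations are survival levels ε:

- `eps_start = 0.99` — (iMIC)_start, the first detectable drop in the
  fitted curve. The level is a calibration choice, not a published
  constant: published start values sit near φ ≈ 0.99, and the precise
  level is exposed as policy (`ThresholdPolicy`) rather than hard-coded.
- `eps_total = 0.05` — (iMIC)_total, directly from the definition "growth
  inhibited in >95% of droplets".
- `eps_all = 0.001` — (iMIC)_all, the operational stand-in for complete
  inhibition. Whenever c(eps_all) exceeds the highest tested
  concentration the value is reported **ND** (the fitted tail is then an
  extrapolation with no data beneath it) and the experimentally observed
  (iMIC)_exp — the lowest tested concentration with zero positive droplets
  in every replicate, and none above it — substitutes in the DoH.

## Fitting

Unweighted least squares on the averaged F_R points (c = 0 included;
inverse-variance weighting from replicate SDs available), over log(p₁),
log(p₂) to keep both parameters positive, Levenberg–Marquardt with
multi-start: p₂⁰ ∈ {1, 2, 4, 8} and p₁⁰ at the grid point whose F_R is
nearest 0.5. Best RSS wins, ties to the smaller shape. Counts are averaged
across replicates *before* normalization (the per-replicate
normalize-then-average path is provided for sensitivity analysis; the two
differ because the control divisor is itself noisy). A profile that never
falls below 0.5 triggers a poorly-constrained warning, and a fitted scale
beyond the tested ladder is flagged `extrapolated` — never a silent
plausible fit.

Recovering (p₁, p₂) from a printed (mode, mean) pair inverts
mode/mean = (1 − 1/p₂)^(1/p₂)/Γ(1 + 1/p₂). This ratio is non-monotone
(maximum ≈ 1.0460 at p₂ ≈ 6.50), so ratios above 1 have two roots;
`solve_shape_scale` defaults to the rising-branch (smaller p₂) root, which
corresponds to the visibly dispersed distributions this analysis targets
(the high branch implies a CoV several times smaller than the published
dispersion statistics), with `branch="high"` exposed. A related numerical
caveat: the mean–mode crossing (p₂ ≈ 3.31) and the zero-skewness shape
(p₂ ≈ 3.60) do not coincide, so "mode < mean iff skewness > 0" is a
heuristic that fails in the narrow band between them.

## Sample comparison

The p-value between a sample and the control is an operational convention,
not an inferential claim: a paired two-sided t-test on the two fitted
curves evaluated on a shared 50-point grid spanning [0, min(c_max)].
It measures systematic separation of the fitted curves and depends on the
grid; identical curves give p = 1 by convention. A replicate-level
alternative (t-test on per-replicate fitted parameters scaled by the
control means) is available via `method="replicates"`.

## Synthetic data

`simulate_counts` emulates the sampling structure the analysis assumes:

- occupancy per droplet ~ Poisson(λ), λ = CFU/mL × droplet volume;
  defaults 1e5 CFU/mL × 1 nL ⇒ λ = 0.1 (≈90% empty, 9% single);
- per-cell iMIC ~ Weibull(p₁, p₂), by construction the distribution whose
  survival is φ — the generator treats the fitted family as exact;
- default truth (p₁, p₂) = (9.8, 4.4), three replicates of 5,000 droplets
  per concentration on a linear ladder 0–20 stepped finely around the
  scale, mimicking a concentration series bracketed tightly around the
  expected MIC;
- `single_only` (default): every occupied droplet behaves as one cell, so
  E[N₊(c)/N₊(0)] = φ(c) exactly. `max_of_k` lets the most tolerant of k
  co-encapsulated cells decide, probing the (small, ~0.5% of droplets at
  λ = 0.1) upward bias multi-occupancy would cause.

`generate_droplet_images` renders schematic bright-field frames:
non-overlapping discs (interior 150, dark rim 40, background 110, on a
0–255 grey scale) with Gaussian camera noise (SD 2 grey levels default)
and, in occupied droplets, pixel-scale granular texture of SD
`texture_contrast` (default 20, i.e. 10× the camera noise). What this does
*not* emulate: optics (PSF, defocus, shading), densely packed or
overlapping droplets, debris, illumination gradients, and partially
textured interiors from small microcolonies. Classifier error rates
measured on these images therefore demonstrate the correctness of the
detection → GLCM → clustering chain under its design assumptions, not the
error rate on any real microscope's output.

## Image analysis

Detection is a Hough circle transform on Canny edges (σ = 2) over the
configured radius range, greedy non-maximum suppression, and a
fully-inside-the-frame boundary rule; a connected-component fallback
handles images where the edge transform finds nothing. Texture features
are computed on non-overlapping 16 px patches tiling the square inscribed
in each droplet (so rim and background pixels never contaminate a patch),
grey values quantized to 64 levels on a fixed global scale, GLCM at offset
1 px along 0° and 90°, symmetric and normalized; per-droplet features are
the patch means of dissimilarity Σ P(i,j)|i−j| and homogeneity
Σ P(i,j)/(1+(i−j)²). Droplets too small for one patch are excluded from
clustering and flagged. 2-means runs on standardized features over the
whole image set jointly; the cluster with higher raw mean dissimilarity is
"positive" (a naming rule invariant to k-means' arbitrary cluster
indices). False-negative/false-positive rates are reported relative to the
detected-positive count by default (matching the presentation convention
of the original fluorescence validation), with an all-droplets denominator
as an option. GLCM hyperparameters (patch size, offsets, levels,
standardization) are package defaults chosen from standard texture-analysis
practice, all configurable.

## Problem sizes and determinism

Defaults throughout are the study conditions: λ = 0.1, 3 replicates,
5,000 droplets per concentration; the image benchmark uses 40 frames of
50 droplets (2,000 droplets, ~9% occupancy). Parameter-recovery checks run
100 simulated experiments at these sizes (a few seconds; the count
simulation is vectorized). All randomness flows through
`numpy.random.default_rng` seeded from the config or function argument:
identical seeds give bit-identical tables, images and reports.

## Known limitations

- The Weibull family is exact in the generator by construction; real iMIC
  distributions need not be Weibull, and the closed-form statistics are
  conditional on the fitted family.
- Endpoint binary readout cannot see persisters or slow growers; their
  iMIC mass is censored downward.
- (iMIC)_start depends strongly on the ε_start calibration because the
  fitted curve is nearly flat there; DoH inherits that sensitivity.
- The curve-based comparison p-value is grid-dependent and should be read
  as a separation diagnostic only.
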