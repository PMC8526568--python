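# Methods

## 1. Imaging arm

### 1.1 Sensor models

The GTP sensor is modeled as a single-site saturating ratiometric
reporter: at free-GTP concentration `c` (µM) the excitation ratio is

    r(c) = r_min + (r_max − r_min) · c^h / (Keff^h + c^h)

with `Keff = 32.3` µM for the GTP-sensitive variant (GEVAL30), Hill
coefficient `h = 1` by default (only Keff and an approximate saturation
range are known for the real sensor; the hyperbola is the minimal model
consistent with both, and `h` is configurable). The Null variant is the
same molecule with ligand binding abolished: `r(c) = r_min` everywhere.
`r_min = 1`, `r_max = 3` are arbitrary but harmless defaults — every
downstream statistic is invariant to the ratio scale.

The RAC1 FRET sensor needs no ligand model: its latent per-pixel
activity field *is* the quantity the FRET index estimates.

### 1.2 Forward model (synthetic microscope)

Each scene is a five-channel, 30-frame, 1-min-interval acquisition of
one cell (elliptical body plus one protrusion lobe, ~10⁴ mask pixels on
the default 180×180 grid). Per frame the latent fields are pushed
through, in order:

1. channel formation — donor `D`, FRET `= activity·D`, acceptor
   `= 0.8·D` (a single-chain sensor: both fluorophores share one
   abundance field), and the GTP-sensor pair
   `Ex409 = G·r/(1+r)`, `Ex494 = G/(1+r)` so their ratio is exactly the
   sensor response `r`;
2. spectral bleed-through into the FRET channel: `+ α·D + β·acceptor`
   (defaults α = 0.2, β = 0.1);
3. per-channel double-exponential photobleaching
   `a₁e^(−k₁t) + a₂e^(−k₂t)`, `a₁+a₂ = 1`; the FRET channel bleaches
   faster than the donor so the FRET index genuinely drifts;
4. affine misregistration of the GTP-sensor camera (≈0.2° rotation plus
   a sub-2-px shift), with bead fiducials generated consistently;
5. multiplicative shading (smooth unit-mean field, amplitude 0.3),
   additive dark current (100 counts plus a fixed 2% pattern), Poisson
   shot noise and Gaussian read noise (sd 2 counts).

Latent fields are spatially smoothed Gaussian random fields (correlation
length 8 px) evolving as AR(1) in time (coefficient 0.8, resembling
1-min live-cell dynamics). The in-mask correlation between GTP and
activity equals the requested ρ **exactly in every frame**: the
independent component is orthogonalized against the realized
(clipped, offset-adjusted) GTP field before mixing. This makes the
generator's ground truth sharp — any deviation of recovered r from ρ is
attributable to the measurement model, not generator sampling error.

Latent scales: GTP ~ 32 ± 9 µM (fluctuating around Keff, where the
sensor is most responsive), activity ~ 1.5 ± 0.3. Photon budgets
(donor 5000, GTP-sensor 20 000 counts) put index noise well below the
latent field variation, so Pearson attenuation from shot noise is a few
percent at most — deliberately "noise-moderate" conditions.

Single-fluorophore control stacks (donor-only, acceptor-only) share the
session's dark frames and shading references and are rendered without
bleach, as a short control acquisition would be.

**What the generator does not emulate:** optical PSF blur, 3-D
structure/z-stacks, cell motion or shape change (the mask is static),
photophysics beyond double-exponential bleaching, and time-varying
bleed-through. Passing tests therefore demonstrate correctness of the
correction algebra and statistics under these idealizations, not
robustness to segmentation drift or deconvolution artifacts in real
movies.

### 1.3 Correction chain

Fixed order, asserted by the runner: dark → shading → registration →
background → segmentation → validity → indices → photobleach →
correlation → summary.

- *Dark subtraction* clips negatives to 0 (ratio stability; whether the
  original protocol clipped is unknowable, and for realistic dark
  offsets the clip is inactive in-cell).
- *Shading* divides by the unit-mean uniform-dye reference; references
  are validated strictly positive with mean 1 ± 1e−6.
- *Registration* is estimated once per session from ≥3 non-collinear
  bead pairs by least squares and applied to the GTP-sensor channels
  (bilinear resampling; out-of-frame pixels invalidated). No per-frame
  drift correction — one transform per session.
- *Background*: per-frame, per-channel mean of a cell-free rectangle is
  subtracted. The "background range" used for pixel exclusion is
  operationalized as mean + k·sd of that region, `k = 2` by default; a
  pixel is excluded if it fails in **any** of the five channels
  (ratio images are unstable wherever any constituent channel carries
  no signal).
- *Segmentation*: per-frame Otsu threshold on the donor channel
  (highest SNR), with a temporal running median (window 5, odd,
  edge-truncated) smoothing the threshold series — a light stand-in for
  threshold-stabilizing segmentation tools; toggleable off. The largest
  connected component is kept.

### 1.4 Indices

The FRET index is the explicit bleed-through-corrected ratio
`R = (FRET − α·D − β·A)/D` used per pixel (α, β from zero-intercept
regressions over expressing pixels of the control stacks; slopes a hair
below zero are clamped to 0, slopes < −0.01 or ≥ 1 are errors). The GTP
index is the plain 409/494 ratio. Denominator pixels below
`1e−6 × frame max` are invalidated.

Photobleach correction fits the in-mask whole-cell mean index series to
a double exponential (non-negative amplitudes and rates; multi-start
over a log-spaced rate grid `[1e−4, 1]` per minute, lowest SSE wins;
single-exponential fallback, then uncorrected-with-flag) and divides
each frame by `m(t)/m(0)`. The correction is a per-frame scalar, so it
preserves within-frame spatial patterns exactly — pixel-wise Pearson r
is provably unaffected; the correction matters for display and for any
absolute-ratio comparison. It is applied to both indices by default
(both are ratios of bleaching fluorophores), configurable.

Display scaling (5th–95th percentile bounds, shifted so the low end maps
to 1, with the low bound optionally taken from a Null-sensor stack) is
rendering-only and never feeds statistics.

### 1.5 Statistics

The correlation unit is the frame: one Pearson r per image over jointly
valid pixels, requiring ≥100 pixels (stabilizes the sampling error of r
below ~0.1); frames failing the count or with zero variance are skipped
with a warning. Cells are summarized by the mean/median/quartiles of
their retained frames (≥5 required). Group comparisons of per-cell mean
r use the two-sided Mann–Whitney test — exact midrank enumeration when
both groups have ≤8 cells, tie-corrected normal approximation with
continuity correction otherwise (the exact path gives p = 1 for
identical samples instead of failing on ties). CB/CP ratio tables are
compared by two-tailed paired t, or Welch's unequal-variance unpaired t
(the safer default when only "unpaired Student's t" is specified).
All p-values are two-sided.

## 2. Coevolution arm

### 2.1 Couplings

Ortholog sets (aligned FASTA, `>SPECIES|accession` headers) are joined
on shared species, A-columns then B-columns. Columns with >50% weighted
gaps are removed (recorded). Sequences are reweighted at 80% identity
(weight = 1/#neighbors); the pseudocount mixes empirical frequencies
with uniform at relative weight 0.5.

Mean-field DCA (default): couplings are the negated inverse of the
pairwise frequency covariance matrix over the 20 non-gap states (gap is
the reference state). Pseudolikelihood DCA: per-column softmax
regressions fitted by nonlinear conjugate gradient with L2 penalty 0.01,
couplings symmetrized across the two conditionals. Either way the
pair score is the Frobenius norm of the 20×20 block in the zero-sum
gauge (gap state excluded from the norm), followed by the
average-product correction computed over the full column×column matrix;
only the inter-protein block is reported. Mean-field is the default for
speed at desk scale; pseudolikelihood is the higher-fidelity option.

A singular covariance (only possible at extreme sample sizes) triggers
one retry at pseudocount 0.7, logged.

### 2.2 Convolution, threshold, randomization

The inter-protein block is smoothed with a 2-D Gaussian (σ = 2 columns
by default — about the width of one helical turn's worth of alignment
positions; the width is not prescribed anywhere authoritative, so it is
a documented default). The interface threshold is the minimum of the
top 5% (`⌈0.05·N⌉` values) of the convolved block.

The randomization test reassigns protein-A sequences to species at
random (protein B untouched), rebuilds the concatenated alignment and
recomputes couplings + convolution per replicate (100 by default). The
exceedance statistic is selectable, because the source procedure can be
read two ways: `"max"` (default — the replicate's convolved maximum
beats the original threshold), `"count"` (at least as many cells above
threshold as the original top set), or `"top_fraction_min"` (the
minimum of the replicate's own top 5% beats the threshold). The p-value
is the plain counting ratio k/N (3/100 → 0.03 exactly); the add-one
estimate (k+1)/(N+1) is reported alongside for users who prefer the
never-zero convention.

With the `"max"` statistic the null p-distribution is strongly
conservative (the original's maximum is by construction inside its own
top 5%, so null replicates drawn from the same distribution usually
exceed the threshold too, pushing p toward 1) — appropriate for a test
whose job is to certify strong positives, and verified by the
independent-genealogies calibration in the test suite.

### 2.3 Simulator

Both proteins evolve down one shared random **Yule (pure-birth) species
tree** (rate 1, ultrametric, leaf labels randomly assigned). A pure
coalescent genealogy was rejected as the tree model: its burst of recent
mergers leaves most leaves ≥80% identical to dozens of others,
collapsing the effective sequence count to single digits — nothing like
a one-ortholog-per-species alignment, where splits follow speciations.
Columns substitute independently (Jukes–Cantor-style, uniform over 20
states) at `mutation_rate = 0.2` expected events per column per unit
tree time, giving ~20% mean pairwise identity and an effective sequence
count near 290 of 500 — the deeply diverged regime where coupling
analysis is ordinarily applied. Planted inter-protein pairs
co-substitute through a pair-specific state bijection with probability
`coupling_strength` whenever the A-side changes. Planted pairs are
auto-placed ≥8 columns apart so their convolved signals stay distinct.

`shared_tree=False` evolves the two proteins on independent genealogies
— the fully signal-free null for calibrating the randomization test.
With a shared tree, even zero-coupling proteins carry joint phylogenetic
signal, and the species shuffle (correctly) detects it.

Contact predictions from a convolved map use greedy non-maximum
suppression (Chebyshev separation `2σ+1`) so one interface patch yields
one prediction; precision@k counts a prediction correct within Chebyshev
distance 1 of a planted pair (convolution can shift a peak by a cell).

## 3. Numerical and scale choices

- All randomness flows from explicit seeds through
  `numpy.random.default_rng`; per-cell seeds are derived arithmetically
  and stay below 2³¹. Same config + seed ⇒ bit-identical outputs.
- Affine estimation: `numpy.linalg.lstsq`; collinearity detected by
  rank of the centered source points.
- Photobleach fit: `scipy.optimize.curve_fit` with box bounds, 15-start
  rate grid.
- Benchmarks in the test suite run at the study scale where the claim
  demands it (30-frame ~10⁴-pixel scenes; 500-species 60+60-column
  alignments for interface recovery) and at reduced scale where only the
  mechanism is under test (randomization-test calibration uses
  16+16-column, ~100-species alignments with 10 replicates; the full
  100-replicate test at study scale is a `lgt coevolve randomize` call
  away).

## 4. Known limitations

- The imaging simulator's cell is static; segmentation is never stressed
  by edge motion, the hard part of real movies.
- Bleed-through is corrected with time-constant α, β while channels
  bleach at different rates; the resulting late-frame residual is a
  per-frame offset plus terms proportional to spatially constant channel
  ratios, which Pearson r ignores but absolute index values do not.
- Mean-field DCA at very small effective sample sizes rides on the
  pseudocount; planted-pair recovery below ~50 effective sequences is
  not expected and not claimed.
- The randomization test's `"max"` statistic is conservative under the
  null; its p-values are certificates against false positives, not
  well-calibrated tail probabilities.
- The exact Mann–Whitney path enumerates C(n_a+n_b, n_a) rank splits and
  is restricted to groups of ≤8 for that reason.
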