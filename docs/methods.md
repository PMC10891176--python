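# Methods

`mottle` quantifies how variable a species' wing coloration is — within
and between species — from calibrated photographs, and asks whether
ecology explains that variability once shared ancestry is accounted
for.  This note documents the models, the numerical choices, and what
the synthetic test bed does and does not establish.

## Image calibration

Specimen photographs include a 'middle grey' card of nominal
reflectance 0.40.  Each channel is multiplied by
`gain_c = 0.40 / mean_c(grey region)`, converting camera counts to
approximate linear reflectance and removing unknown exposure and white
balance.  The default is per-channel gains (white balancing); a
luminance-only gain is available for workflows that must preserve the
raw colour balance.  Two deliberate choices:

* **No gamma linearisation.**  Channels are treated as linear camera
  responses throughout and no vision model is applied.  This keeps the
  pipeline faithful to raw-camera-value analysis but means the metrics
  are camera-referred, not receptor-referred.
* **No clipping above 1.**  Specular pixels keep their super-unity
  reflectance for pattern analysis (clipping would bias band energies);
  only the HSV conversion clamps channels to [0, 1] at computation
  time.

Images are bilinearly resampled to a standard 10 px/mm before analysis
(ROI masks with nearest-neighbour), so one spectral band corresponds to
a fixed physical scale for every specimen.

## Colour summaries

Calibrated RGB is converted to hexcone HSV (hue in degrees, saturation
and brightness in [0, 1]) and averaged over the wing ROI.  Hue is an
angle; two conventions are offered:

* `linear` (default): the arithmetic mean of degree values.  This
  reproduces what any downstream statistic computed on plain numeric
  hue columns sees, and is therefore the convention the species-level
  cv is built on.
* `circular`: the proper circular mean with resultant length, for
  sensitivity analysis.

When a wing's hues straddle the 0/360 seam the linear convention is
ill-defined and a `HueSeamWarning` is raised; the flag propagates into
the metrics table.  Achromatic pixels carry hue 0 by convention and are
included in hue means (an exclusion switch exists).

## Granularity (pattern) analysis

The luminance channel `(R+G+B)/3` of the wing ROI is analysed in 100
wavelength bands, one-pixel increments from 1 to 100 px — i.e. 0.1 mm
steps from 0.1 to 10 mm at the standard resolution.  Band `i` collects
the 2-D DFT power (|F|²/N², mean subtracted) over the annulus of
wavelengths λ = 1/|f| ∈ [i, i+1) px.  With this normalisation the band
energies sum to the patch variance (Parseval; DC excluded), so energy
is in squared-reflectance units.  Three descriptors summarise the
spectrum:

* dominance (maxPower) — energy of the most energetic band;
* marking size (maxFreq) — that band's scale in mm (ties resolve to the
  smallest scale; an all-zero spectrum yields NaN with a degeneracy
  flag, never a silent first band);
* contrast (sumPower) — energy summed over all bands.

Numerical choices: the annular band-pass is applied by binning the
power spectrum rather than running 100 spatial convolutions (equivalent
by Parseval, O(N log N) once; an explicit-loop oracle enforces the
equivalence in the tests).  Non-rectangular wings are handled by
cropping the mask's bounding box and filling outside-mask pixels with
the interior mean luminance, with no window function — matching the
pragmatic handling of masked regions in granularity toolchains; a Hann
window is available for edge-effect sensitivity analysis.  Wavelengths
≥ 101 px and the DC term are excluded from all three descriptors.

Before spectral analysis the luminance is quantised to 20 equally
spaced levels spanning its min–max range (endpoints preserved, so a
two-tone patch is unchanged).  Banded-luminance pre-processing of this
kind is ambiguous across toolchains, so the level count is a parameter
(`n_levels`, 0 disables) and the value used is recorded with the
spectrum.  Whether band energies should additionally be normalised per
band width is equally ambiguous; raw Parseval-normalised sums are used.

## Trait table

Per species × wing × metric, the table records the mean (x), the
coefficient of variation (cv = sample s.d. (n−1) / mean), and n.
Morphs and sexes are pooled within species.  Species below a
configurable sampling floor (default 14 specimens, a realistic minimum
for museum material) are flagged, not dropped; species with fewer than
two specimens have no defined cv and are excluded with a logged reason.
cv is undefined for means within 1e−12 of zero and such cells are NaN.
Wing area (ROI pixel count / px_per_mm²) rides along as a seventh
metric so a size effect can be tested alongside colour and pattern.

## Simulation-based phylogenetic ANOVA

Species values are not independent: relatives resemble each other, so
an ordinary ANOVA across species inflates type-I error whenever the
grouping factor is phylogenetically clustered.  The test keeps the
familiar one-way F statistic but replaces its parametric null with the
distribution of F computed on traits simulated under Brownian motion
(BM) along the ultrametric tree: tip vectors are multivariate normal
with covariance σ²C, where C[i,j] is the shared root-to-tip path length
of tips i and j.  The p-value is

    p = (1 + #{F_sim ≥ F_obs}) / (nsim + 1),

the standard add-one Monte-Carlo estimator, which can never be exactly
zero; its resolution is 1/(nsim+1).  Because F is invariant to affine
transforms of the trait, the null is simulated at unit rate — no BM
rate needs to be estimated from data.  Null traits are pure BM with no
group structure (the standard null; re-centring per group is not done).

Post hoc pairwise comparisons use pooled-variance t statistics with the
overall within-group mean square; their two-tailed null values come
from the same BM simulations (one seed governs everything) and are
Holm–Bonferroni adjusted across pairs.  Effect sizes are η² =
SSB/(SSB+SSW).  Degenerate inputs: a constant trait is reported as
F = 0 with a flag (relative variance below 1e−20 counts as constant, so
rounding residue in the sums of squares cannot masquerade as signal),
and its p is 1 by construction.

Multiple testing across the battery: Holm is applied within each
hypothesis × statistic-type family (the metric × wing cells tested
together); raw simulation p-values are reported alongside because
family boundaries are a judgement call.

Trees must be ultrametric within a relative tolerance of 1e−6 of their
depth; validation failures name the most discrepant tips.  Species
missing a factor level are dropped from that hypothesis with a logged
count; a trait species absent from the tree is an error.

## Synthetic data generator

The generator replaces museum imagery with textures whose ground truth
maps directly onto what the pipeline measures.

* **Texture.**  White noise convolved with an isotropic Gaussian kernel
  and affinely mapped to the target amplitude.  A kernel of spatial
  s.d. σ gives smoothed noise the power spectrum ∝ exp(−4π²σ²f²);
  binned over wavelength annuli the energy density is
  ∝ λ⁻³ exp(−4π²σ²/λ²), which peaks at λ = π√(8/3)·σ ≈ 5.13 σ.  The
  kernel is therefore sized σ = scale/(π√(8/3)) so the granularity
  spectrum peaks near the requested marking scale.  The per-band peak
  estimate still carries substantial realisation noise (relative s.d.
  ≈ 0.2 at 30 × 20 mm), which inflates measured marking-size cv in
  both groups equally.
* **Within-species dispersion.**  Positive parameters (marking scale,
  contrast amplitude) are drawn per specimen from log-normals with the
  species median and cv; log-normals keep draws positive and map cv
  onto the log-scale s.d. as σ_log = √log(1+cv²).  No distributional
  form is dictated by real data here — this is a modelling choice.
* **Colour.**  A base HSV colour per specimen (Gaussian noise around
  the species base), converted to RGB; the texture is added equally to
  all channels so it carries luminance pattern while leaving hue
  largely untouched.
* **Trees.**  Pure-birth, with the clock run past the last birth by a
  partial waiting time so terminal branches are positive, then rescaled
  to depth exactly 1 (F statistics are invariant to global time
  scaling, so the normalisation costs nothing and removes unit
  bookkeeping).  Species are placed on tips in seeded random order, so
  group factors are not confounded with clades.
* **Determinism.**  Every generator is a pure function of its seed
  tuple; one global seed expands into per-object seeds through
  `numpy.random.SeedSequence` with a fixed counter scheme, so any
  single image can be regenerated without replaying the dataset.

The default two-strategy study conditions (`default_strategy_specs`)
follow realistic museum sampling: 20 species per strategy, 30 specimens
per species (sampling floors of 14–30 are typical for curated
collections).  The two groups' generators are identical except for the
within-species marking-scale cv — 0.35 for camouflaged-like versus 0.10
for aposematic-like species — making that dispersion contrast the
single designed effect; colour, contrast amplitude and wing size share
one between-species distribution (cv ≈ 0.15 of the generative means),
base hues sit in the warm brown band well away from the 0/360 hue seam,
and diel-activity is assigned correlated with strategy (camouflaged
species mostly nocturnal) while diet cycles independently.

**What the synthetic bed does not emulate:** photography artefacts
(vignetting, specular glare, chromatic aberration), specimen damage and
fading, anisotropic patterning (stripes versus spots), UV reflectance,
and real phylogenetic signal in the traits themselves (species means
are drawn i.i.d., not evolved on the tree).  Passing tests therefore
demonstrate that the measurement chain and the statistics behave as
specified — not that the biological conclusions would survive those
real-data complications.

## Problem sizes used in the checks

The verification suite runs at desk scale, chosen so the full suite
completes in minutes while keeping each check statistically meaningful:
spectral oracles on 256×256 patches; BM covariance recovery at 10,000
replicates; star-tree calibration with 40 tips and nsim = 2000; type-I
calibration with two clades of 10 over 500 replicate datasets
(nsim = 200 each); and the end-to-end recovery study at 40 species ×
30 specimens × forewing over 20 seeds with nsim = 500.  The headline
museum analysis this mirrors (thousands of images, 82 species,
nsim = 1000) is reproducible with the same code by pointing a manifest
config at the real dataset.

## Known limitations

* Linear hue statistics are the default for fidelity to plain-numeric
  toolchains, but they are wrong near the hue seam; the warning flag
  should be taken seriously on red-magenta material.
* The mean-fill/no-window treatment of masked wings leaks some energy
  into long-wavelength bands at the mask boundary; the Hann option
  quantifies the sensitivity.
* The BM null is the classic constant-rate model; rate heterogeneity,
  OU-style constraint, and phylogenetic regression are out of scope.
* Marking size is quantised to 0.1 mm bands; species whose true
  dispersion is much smaller than a band width will have their cv
  dominated by quantisation and peak-estimation noise.
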