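# Methods

## Problem and model

The pipeline classifies maize seedlings as glyphosate-resistant (RT:
resistant, treated) or glyphosate-sensitive (ST: sensitive, treated) from
leaf reflectance in the 450–902 nm range, and asks how well a linear
classifier trained on one experiment transfers to another experiment whose
spectra are distribution-shifted. Water-sprayed controls of both cultivars
(RW, SW) anchor the null: with an effective resistance gene, RT, RW and SW
are spectrally indistinguishable, and only ST develops a senescence
signature over 2–8 days after treatment (DAT).

Features are 16 vegetation spectral indices — arithmetic combinations of a
few bands that summarise pigment and canopy-structure status (NDVI, GNDVI,
RDVI, EVI, NRI, TVI, PRI, ARI, PSRI, SIPI, TCARI, OSAVI, TCARI/OSAVI,
MCARI, ZM, CRI550), each with its canonical literature formula held in a
data-driven registry so an alternative index set is a configuration change,
not a code change. Band lookup maps a requested wavelength to the nearest
grid band (error if farther than 5 nm; ties to the lower band). The blue
bands of EVI and SIPI are mapped to 450 nm, the floor of the trimmed range.
A zero denominator makes an index *undefined* (NaN, row flagged and excluded
from modelling); a missing band is an error — two different failures kept
deliberately distinct.

## Preprocessing

Reflectance is `(raw − dark) / (white − dark)` per pixel and band, with no
clipping: out-of-range values are evidence of measurement problems and are
handled by the outlier screen, not silently repaired. Plant pixels are
those with reflectance > 0.1 at the band nearest 792 nm; stems are removed
by user-supplied rectangles (half-open, 0-based pixel coordinates;
out-of-bounds rectangles are an error, not a clip). Leaves are 8-connected
components of at least 50 px (neither choice is dictated by the data
source; both are configurable), labelled in raster order of their first
pixel so labelling is a pure function of the mask. Each leaf's spectrum is
the per-band arithmetic mean over its pixels, trimmed to 450–902 nm
inclusive (227 bands on a 2 nm grid spanning 380–1030 nm).

The outlier screen is a concrete rendering of a shape-and-reflectance
sanity check: reject if any band is < 0 or > 1.2, if mean NIR (780–900 nm)
reflectance is < 0.15 (background, not leaf), or if the spectrum's
Euclidean distance to its (experiment, group, DAT) mean exceeds 4× the
stratum's median distance. The distance rule is applied once, not
iterated, so the retained set is deterministic and stable under re-runs.

## Screening statistics

Per (index × DAT × experiment): a one-way ANOVA across the four groups,
then six Welch two-sample t-tests (robust to unequal variances; the
pairwise statistic is pluggable) in the fixed order RT-RW, RT-ST, RT-SW,
RW-ST, RW-SW, ST-SW, Holm–Bonferroni adjusted *within that stratum's six
pairs* at α = 0.05 — matching a per-panel letters display rather than a
global correction across indices. Letters come from an insert-and-absorb
algorithm verified exhaustively against a brute-force minimal
letter-partition oracle for four groups. Degenerate inputs are explicit:
identical data give F = 0, p = 1; zero within-group variance with a
between-group difference reports F = ∞, p = 0.

## Partitioning and transfer tasks

Within-experiment models use a Kennard–Stone 4:1 train/test split: the
greedy max–min Euclidean selection, first pair = most distant pair, every
tie broken by lowest row index, distances on raw index values —
standardization happens only inside the SVM step, though a `standardize`
flag is provided for the chemometric convention. The
train count is round-half-up of 0.8·n. Transfer tasks take a full source
experiment against a single-DAT slice of another experiment: 3 experiments
× 2 directions × 4 DATs = 24 tasks.

## TCA and the model variants

The primal TCA solves `(XᵀLX + μI)⁻¹ XᵀHX` for the top-m eigenvectors,
where L is the MMD block matrix and H the centring matrix; m = 5
components by default, μ = 1 (the conventional default for this
regulariser, exposed as a parameter).
Complex eigen-components (numerical artifacts of the non-symmetric
product) are truncated to their real parts, the retained columns
re-orthonormalised by QR, and each column's sign fixed so its
largest-magnitude entry is positive — making the fit a deterministic
function of its inputs. A generalized-eigenproblem solver provides an
independent cross-check route in the tests.

The classifier is a soft-margin linear SVM (C = 1, no hyperparameter
search, decision ties to the positive class RT). Standardization is *on*
only for the no-transfer variant: TCA embeddings are already commensurate,
and an updated source concatenates two feature distributions that a single
mean/variance would misrepresent. The four variants are:

- `SVM` — train on the standardized full source, predict the target slice;
- `TCA_SVM` — TCA on (source, target), SVM on the embedded source;
- `Update_SVM` — move a seeded simple-random fraction (level × target size,
  round-half-up, default 50 %) of the target into the source, evaluate on
  the remainder; the update is *not* class-stratified by default (a
  stratified mode exists behind a flag), and stochastic
  variants are repeated over a seed list (default 10) and summarised by the
  mean;
- `Update_TCA_SVM` — update first, then TCA on (augmented source, reduced
  target), then SVM. The update-then-TCA order is fixed; the reverse order
  is deliberately not the default.

Metrics use RT as positive: accuracy, precision, recall, F1, FPR. Undefined
ratios (zero denominators) are NaN end-to-end; report rendering prints the
literal "NaN" and aggregation skips them while counting exclusions.

## Synthetic generator

The generator emulates the study design, not leaf optics: a healthy-leaf
curve (visible level 0.08, NIR plateau 0.55, logistic red edge at 715 nm
with 10 nm width, Gaussian chlorophyll dip 0.05 at 670 nm σ = 25 nm,
carotenoid dip 0.03 at 500 nm σ = 20 nm) shared by RT/RW/SW at every DAT.
ST diverges linearly after an onset at 4 DAT: chlorophyll dip −0.01/day,
red edge −5 nm/day, NIR plateau −0.03/day — magnitudes chosen once as
realistic senescence rates that make 2 DAT a true null and 6–8 DAT
separable, the timeline a glyphosate trial of this design exhibits. Plant and leaf random
effects are Gaussian multiplicative perturbations of dip depth and plateau
(sd 10 % and 5 % of the parameter), giving within-group variance for the
screening statistics to act on.

Each of the three default experiments applies a domain shift — gains
{1.00, 0.92, 1.08}, offsets {0, +0.02, −0.015}, wavelength-registration
shifts {0, +2, −2} nm, per-band noise sd {0.006, 0.010, 0.008} — sized to
break a naive cross-experiment SVM while leaving enough shared structure
for TCA and source updating to recover. The wavelength shift is applied by
evaluating the analytic curve at shifted wavelengths, so noiseless
between-experiment differences equal the composed affine + registration
transform exactly (a tested invariant). Spectra are clipped to
(0.001, 0.999) to keep reciprocal indices (ARI, CRI550) finite.

`render_cube` lays leaves out as non-overlapping ellipses with a stem
rectangle each on a flat 0.05-reflectance background (below the 792 nm/0.1
threshold by construction), and converts reflectance to raw counts through
the same affine model the calibration inverts. What the generator does
*not* emulate: radiative-transfer realism, leaf geometry and specularity,
illumination gradients, wavelength-dependent instrument response, or
correlated (non-white) noise. Passing tests therefore demonstrate that the
pipeline's logic is correct under the assumed structure, not that the
specific accuracy numbers carry over to real imagery.

## Problem sizes and numerical choices

Tests run the generator at reduced size (8 plants/group, 2 leaves) except
for the trend checks, which use the full default (40 plants/group, 3
leaves, ≈1,920 spectra/experiment) with 10 seeds for the significance
timeline and 10 update draws for the variant ordering at 6 DAT — sizes at
which the qualitative contrasts are far from their decision thresholds.
Oracle agreements are exact-match (Kennard–Stone), 1e-10 (ANOVA) and 1e-8
(TCA eigensystem). ENVI I/O is a minimal BIL float32 reader/writer
sufficient for round-tripping rendered cubes.

## Known limitations

- No real imagery ships with the package; all quantitative trend results
  here are statements about the synthetic generator.
- The 16-index set uses canonical formulas; a given study's exact
  index list may differ in a few members, which is why the registry is
  data-driven.
- Holm correction is applied over the 6 pairwise tests per stratum; other
  family definitions (e.g. across indices) would be stricter.
- TCA is the linear primal variant only; kernelized and semi-supervised
  variants are out of scope.
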