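# Methods

## Isotope tracing model

A metabolite with *n* carbons is observed as intensities at nominal mass
shifts m+0…m+n. Two processes put mass into a molecule: tracer carbons
(from U-¹³C₆ glucose, via the pathway under study) and natural heavy
isotopes. Only carbon's natural abundance is corrected (default
p = 0.0107 per carbon): at unit SRM resolution the isotopes of other
elements are not resolved from the carbon envelope, and modeling them
without resolving them adds parameters without information. Tracer purity
is accepted as a parameter but defaults to 1.0.

The forward model is the lower-triangular matrix C with column *k* equal to
the Binomial(n−k, p) mass-shift distribution offset by *k*: the *k* tracer
carbons are already heavy and cannot shift further; each of the remaining
n−k carbons is heavy with probability p independently. Columns sum to 1
and C(p=0) = I. The inverse problem `C·x ≈ observed` is solved by
non-negative least squares (scipy's active-set NNLS) and renormalized to
sum to 1. NNLS rather than `C⁻¹·observed` because inversion yields
negative fractions whenever noise pushes an isotopologue below its
natural-abundance expectation; the constraint is the physically meaningful
estimator and is exact (≤1e−9) on noiseless data. For n ≤ 6 the matrix is
verified in the test suite against brute-force enumeration of every
heavy-atom placement.

"Fractional incorporation = (¹³C/¹³C+¹²C) × 100" admits two readings, and
both are implemented as distinct, named quantities rather than guessed
between: `labeled_fraction` = 100·(1−f₀) (fraction of molecules carrying
any label) and `mean_enrichment` = 100·Σ k·f_k / n (per-carbon atom
enrichment). `labeled_fraction` is the default reported quantity because
condition figures in this kind of study plot m+0 against m+k isotopologue
stacks, which is molecule-level information.

Condition contrasts run a two-sample t-test per metabolite per
isotopologue index, plus one on the derived labeled fraction. The pooled
(equal-variance) Student form is the default — matching the study's named
test — with Welch behind a flag. Degenerate inputs follow explicit
conventions: zero variance in both groups with equal means gives p = 1;
with unequal means, p = 0 and a runtime warning. No multiple-testing
correction is applied by default (none is applied in this experimental
design's convention); a Benjamini–Hochberg helper exists, clearly labeled
an extension. The TCA shift view restricts contrasts to m+2/m+4 (m+5 for
citrate), the isotopologues that accumulate over successive cycle turns.

## Imaging model

Segmentation is the standard marker-based watershed recipe: Gaussian
smoothing (σ = 2 px), Otsu global threshold, Euclidean distance transform,
local maxima with a minimum separation (default 10 px, of the order of a
nucleus radius) as markers, watershed on the inverted distance map, then
removal of regions under 40 px and contiguous relabeling. A blank or
constant field returns an empty label map, not an error.

Positivity uses the control-derived threshold mean + 1 SD with the
*sample* (n−1) standard deviation — the conventional estimator on a cell
population — and a strict `>` comparison, so a cell exactly at the
threshold is negative. Scored against its own threshold, a Gaussian
control population flags 1−Φ(1) ≈ 15.87% of cells; this null calibration
is a property test. Percent positive is invariant under any affine
rescaling applied jointly to control and treated intensities, since the
threshold co-scales.

Foci are local maxima within a nucleus mask. The channel is first smoothed
with a σ = 1 px Gaussian — a matched filter for spot-like signals that
suppresses single-pixel noise maxima, without which a prominence cut at a
few noise SDs over-counts — then maxima at least `min_distance` (3 px)
apart are kept when they exceed the nucleus background (median smoothed
intensity inside the mask) by at least the prominence. Default prominence
is 3 × a robust noise SD (1.4826 × median absolute deviation of the raw
image). Counts are monotone non-increasing in prominence. Each focus
reports its raw peak intensity and an area proxy (connected pixels above
half-prominence around the peak). Z-stacks are max-projected before
detection; restorative deconvolution is out of scope and the synthetic
fixtures are generated without blur that would require it.

## Platinum quantitation

Signal ratio = (sum of Pt counts at masses 194, 195, 196) / Ir counts at
193 by default; single-mass policies are available by flag. Summation uses
all monitored counts and is insensitive to the isotope split. Calibration
is weighted least squares of ratio on nominal ppb with w = 1/x² — x being
the nominal standard concentration, the ICP-MS convention — which
equalizes relative error across the 0.125–50 ppb serial dilution; under
noise with SD proportional to concentration this beats unweighted OLS at
the low end (a property verified by simulation in the tests). The
intercept is fitted, not forced through zero, with a forced-zero flag.
Back-calculation inverts the line; negative estimates clip to 0 ppb with
an explicit flag (blanks legitimately scatter around zero), and estimates
below the lowest standard are flagged rather than suppressed. The
DNA-bound fraction is 100 × bound/total after optional per-sample
normalization.

## Endpoint assays

Surviving fraction: PE = control colonies / control cells plated (mean
over control dishes); SF = (colonies/plated)/PE per dish, summarized per
condition — SF(control) = 1 identically and SF is invariant to scaling
plated cells and colonies together. Senescence: percent positive per
high-power field, averaged over fields with SD; zero-cell fields are
excluded with a warning, and an error is raised only if a condition loses
every field. Redox ratios are element-wise reduced/oxidized on paired
replicates. Control normalization optionally divides each well by a
cell-number surrogate first. Condition summaries report SD; MID contrast
tables report SEM, matching the error-bar conventions of the respective
endpoint figures in this study design.

## Synthetic data: what it emulates, and what it does not

The tracing generator forward-convolves true MIDs with the
natural-abundance matrix, scales by a pool size (10⁶ intensity units), and
applies multiplicative lognormal noise with unit mean and the requested CV
(default 0.05) — positive intensities with CV-stable error, the empirical
behavior of SRM peak areas. Lactate's true MID is the mixture
(1−d)·pyruvate + d·δ(m+0) with d the unlabeled media-pyruvate share of
the lactate pool. The default scenario uses d = 5/18, which turns 90%
labeled pyruvate into 65% labeled lactate — the signature of labeling in
the presence of an unlabeled pyruvate media pool; the media pyruvate
concentration itself is not part of the model, so d is a free parameter
with this value as its default. Cisplatin conditions suppress the
labeled-lactate flux (default 35% of labeled mass moved to m+0) and raise
citrate m+2/m+4 and pentose-phosphate labeling, the compensatory shunting
pattern. What the generator does not emulate: chromatography, ionization
or detector physics, metabolite pool-size changes between conditions, or
correlated noise across isotopologues — so passing recovery tests show
the *mathematics* is right under realistic noise, not that the pipeline is
robust to instrument drift.

The imaging generator places disk nuclei (default radius 8–14 px) by
rejection sampling with a 4 px margin, raising an explicit error if the
requested count cannot be placed within the retry budget — never silently
truncating. Disks rather than ellipses keep the ground truth unambiguous.
Per-nucleus γH2AX base intensity is normal (mean 300, SD 60 a.u.;
condition shift additive); foci are symmetric 2-D Gaussians (σ = 1.5 px,
amplitude 900 a.u. — far above the default 12 a.u. background noise, so
detection is well-posed by construction) placed within 0.7·r of the
center with a best-effort minimum separation of 6 px so that distinct true
foci are resolvable by a detector with a 3 px minimum distance. Real
nuclei are neither disks nor uniform, real foci overlap; exact-count
recovery here validates the detector's logic, not its performance on
clinical images.

The calibration generator produces ratio = slope·c + intercept + ε with
ε ~ N(0, relative_noise_sd·c) — the noise SD is proportional to
concentration in *ratio units per ppb*, so a value near the slope means
~100% relative error; the default scenario uses 2% of the default slope
(4 × 10⁻⁴), a 2% CV at every level. Negative generated ratios clip to 0
and are flagged in the ground truth. Default samples are paired
whole-cell/DNA-extract concentrations with a bound:total ratio drawn
around 6%, reproducing the observation that DNA-bound platinum is a small
(<10%) fraction of the cellular total.

All generators draw from `numpy.random.default_rng` seeded through
`SeedSequence`; one top-level seed is split per sub-generator, and a fixed
seed reproduces outputs byte-identically.

## Pipeline

Stages (generate → isotope → imaging → ptquant → assays → report) exchange
tidy TSV/CSV tables in the run directory, so any downstream stage re-runs
bit-identically from persisted intermediates. The report stage writes a
Markdown summary, PNG isotopologue bar charts (mean ± SEM), and
`recovery.json` with bias and MAE of labeled fractions and Pt
concentrations against the generator's ground truth. Default problem
sizes — 3 replicates per tracing condition, 4 fields of ~30 nuclei per
imaging condition, 5 calibration standards plus 8 samples — mirror the
scale of one experiment in this study design while keeping a full run
under ten seconds.

## Known limitations

- Correction assumes the carbon count is known and the spectrum complete
  (m+0…m+n all measured); partially acquired envelopes are not supported.
- The watershed marker separation must be tuned to nucleus scale; heavily
  clumped nuclei beyond small-neck overlaps will merge or over-split.
- Foci counting assumes spot-like, roughly symmetric foci; pan-nuclear
  staining patterns report as zero or few foci, not as a distinct class.
- The 1/x² weighting presumes noise SD roughly proportional to
  concentration; for shot-noise-limited (square-root) regimes 1/x would be
  more appropriate and is available.
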