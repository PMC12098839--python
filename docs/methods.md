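# Methods

## Problem setting

TMTpro 18-plex labeling encodes 18 samples in one LC-MS run; on MS2
fragmentation each peptide releases 18 reporter ions between m/z 126 and
136 whose intensities carry the per-sample quantitation. Eight of the
reporter "channels" come in same-nominal-mass pairs (127N/127C …
134N/134C) that differ only by a 15N-vs-13C substitution, 0.0063 Da
apart; separating such a pair requires a resolving power of roughly
45,000 at reporter m/z. Two failure modes corrupt this readout. Dim
scans lack the ions to profile a peak, so apparent resolving power and
signal collapse together. Saturated scans — reporter intensities around
10^6 detector units — coalesce the two isotopolog peaks of a pair into a
single distorted peak lying between the pair's theoretical positions,
again below the 45 K gate, and with intensities that cannot be
apportioned between the two channels. `plexquant` implements the
quantitation workflow around these two facts, plus the downstream
age/sex trend statistics for cohort designs of the form
3 ages x 2 sexes x replicates per tissue.

## Reference table

Channel m/z values are vendor-published constants compiled into
`reference.py` and verified in the test suite against the
isotope-substitution identity
`mz(channel) = mz(126) + n13C*(m13C - m12C) + n15N*(m15N - m14N)`;
all eight pair spacings equal
`(m13C - m12C) - (m15N - m14N) = 0.00632 Da` to within 1e-4. The Results
narrative this package reproduces prints a merged peak at m/z 130.1386
as "0.0038 Da right of 130N and 0.0025 Da left" of the next reporter up;
those offsets are numerically consistent with 130C as the upper
neighbor, so the package always resolves neighbors by m/z from the
table, never by label.

## Matching and extraction

A reporter observation is the in-window peak minimizing |mz − exact m/z|
under a symmetric peak-match tolerance (PMT), ties broken by higher
intensity. Two tolerances matter: 0.001 Da for quantitation and 0.003 Da
as a wide/diagnostic window. The matcher deliberately allows one
observed peak to satisfy two channels — exactly what happens to a
coalesced pair at the wide tolerance, and the reason the narrow window
is the quantitation default. Whether the nearest or the most intense
in-window peak should win is underdetermined by the workflow being
reproduced; nearest-by-m/z is used because it reproduces the published
offsets accounting, and the tie-break only matters for pathological
scans. When input (plain mzML) carries no vendor noise values, S/N can
be estimated from a user-supplied per-scan noise constant; records are
then flagged `sn_estimated`.

## PSM filtering

A PSM is removed when any *matched* reporter ion has resolving power
below 45,000, or when the total S/N summed over the 18 channels is below
1440. The two criteria are OR-combined: they flag largely disjoint
populations (saturated high-S/N scans vs dim low-S/N scans), which is
visible as a bimodal distribution of log10 total S/N among
low-resolution PSMs. Design choices, made where the source wording was
ambiguous:

- removal thresholds are strict (`<`), so boundary values (total S/N
  exactly 1440, resolution exactly 45,000) pass;
- channels absent from a scan cannot fail the resolution gate — they
  already contribute zero S/N;
- the 1440 constant equals an average S/N of 80 per channel over 18
  channels; that reading is an interpretation recorded here, not a fact
  about the instrument;
- one description of the S/N cut prints "1400" where every other
  statement uses 1440; treated as a typo for 1440.

The bimodal split reported by `low_resolution_sn_profile` is a 1-D
two-means partition of log10 total S/N — a diagnostic summary only; the
filter never depends on it. Filtering removes PSMs; it never attempts to
correct coalesced intensities back into per-channel values.

`detect_coalescence` flags an isotopolog pair when no peak lies within
the quantitation PMT of either member but exactly one peak lies strictly
between the members' theoretical m/z. On the published worked example (a
lone peak at 130.1386) it returns offsets 0.0038/0.0025 Da.

## Roll-up and normalization

Protein abundance per channel is the sum of retained PSMs' S/N values.
Summation commutes through the peptide level, so PSM→protein directly
equals PSM→peptide→protein. Peptides shared between protein groups are
assumed resolved upstream by parsimony; a multi-protein PSM contributes
to each listed protein and triggers a warning. Channels are normalized
for equal loading by scaling each column so all totals equal the mean of
the original totals — any common target is equivalent for downstream
log-linear models; the mean keeps values on the original scale. The
transform to modeling scale is log2(value + pseudo) with pseudo
defaulting to 0 (the single-batch 18-plex design needs no batch
correction, and zeros are rejected explicitly rather than silently
shifted).

## Simulators

**Reporter scans.** Peaks are placed at theoretical m/z with resolving
power scaled Orbitrap-style as R(mz) = R_nominal * sqrt(200/mz), default
80,000 at m/z 200 (≈100,000 in the reporter region). A pair coalesces
when either member reaches the saturation intensity (default 10^6): the
two peaks are replaced by one at the intensity-weighted centroid (plus a
configurable asymmetric bias, default 0), intensity equal to the sum
(total ion current is conserved), and resolving power drawn uniformly
from [15,000, 40,000] — below the 45 K gate by construction so the
filter's sensitivity is testable. That range, the weighting rule and the
trigger are modeling choices: the source material attributes coalescence
to ions reaching ~10^6 without giving a functional form, and does not
characterize the quantitative distortion of merged intensities, which is
why the bias is an exposed parameter rather than an asserted mechanism.
Note a perfectly symmetric pair (equal member intensities) merges to a
centroid ~0.0032 Da from both members — outside even the 0.003 Da
window; matched coalescences in practice come from asymmetric pairs.
Per-peak noise is log-normal (median 100, sigma 0.3 in log units).

**Cohorts.** The default design is one tissue of 18 samples — ages
{3, 12, 20} months x sexes {F, M} x 3 replicates — mapped onto the 18
channels. Protein log2 abundances are intercept (N(10, 1.5²), i.e. S/N
~1000 scale) plus planted effects plus N(0, residual_sd²) noise,
residual_sd defaulting to 0.2 log2 units. Planted effects: 15% of
proteins get a continuous age slope ~ N(0, 0.04²) per month (forced away
from zero at half an SD so "has a slope" means it; ~0.7 log2 units
across 3→20 months at the SD), 5% get a non-continuous step pattern
(one of Up-Down, Down-Up, Flat-Up, Flat-Down, Up-Flat, Down-Flat with
step size 0.8), 10% a sex effect ~ N(0, 0.5²), 5% an age-by-sex
interaction, and (for multi-tissue specs) 5% an age-by-tissue slope
deviation. Peptide observations are the protein value plus a peptide
offset N(0, 1) and measurement noise N(0, 0.1), exponentiated to the S/N
scale, **plus an additive background floor** (default 4 S/N units). The
floor is what makes low-abundance peptides' log-scale trends attenuate
toward zero — the coefficient-shrinkage phenomenon that motivates S/N
filtering — and setting it to 0 recovers exact planted slopes on
noise-free data. What the simulator does *not* emulate: chromatography,
precursor selection and co-isolation interference, isotope-impurity
cross-talk between channels, missing peptides, and non-Gaussian
residuals. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to those
real-data complications.

All randomness flows from explicit seeds through `numpy` Generators; no
global state.

## Trend statistics

Per protein within a tissue, ordinary least squares on log2 abundance:

    y = intercept + age + sex              (Eq. main)
    y = intercept + age + sex + age:sex    (Eq. interaction)

with age either continuous (months, one slope) or categorical (k−1
indicators); sex is an M = 1 indicator so the sex coefficient is the
male−female log2 difference. Each term is tested by the partial F-test
against the model without it, and p-values are BH-adjusted across the
proteins of one tissue per test type (the multiple-testing family).
Because all proteins share one design matrix, fits are vectorized with a
single pseudoinverse (10,000 proteins in well under a second).

**BIC classification.** Continuous vs non-continuous trajectories are
compared with the Gaussian linear-model BIC,
`n*ln(RSS/n) + (k+1)*ln(n)`, where k counts the regression coefficients
including the intercept and the +1 is the residual variance (the
convention is fixed so BIC values are reproducible bit-for-bit; the
constant `n*ln(2π)+n` term is omitted identically in both models and
cancels in the comparison). Lower BIC wins; exact ties go to the more
parsimonious continuous model. Classification requires ≥ 3 distinct ages
(with 2 the codings are equivalent). In the whole-matrix pipeline the
class is reported only for proteins significant at the age FDR threshold
under *either* age coding — a purely non-monotone protein (Up-Down) has
no power under the continuous test, and the source does not state which
coding gates its classification figure.

**Stepwise categories.** Proteins passing the stricter categorical-age
gate (FDR < 0.01) are labeled per adjacent age interval: the categorical
model's successive-difference contrast is tested with a t-test at
`step_alpha` (default 0.05 — not stated in the source; exposed in
config), giving Up/Down when signed and significant, else Flat, joined
as e.g. "Down-Flat". A t on a single-df contrast is equivalent to the
single-df F drop.

**Cross-tissue consistency.** The joint model
`y = intercept + age + sex + tissue + age:tissue` is fit for proteins
observed in all tissues. The marginal age effect is tested between the
main-effects models with and without age; the interaction by comparing
the joint model to the main-effects model. (Testing the age main effect
with the interaction retained would make the answer depend on the
arbitrary reference tissue under treatment coding, so the hierarchical
version is used.) After BH adjustment across proteins, a protein ages
consistently when fdr_age < 0.1 **and** fdr_interaction > 0.2; it is
tissue-distinct when the interaction FDR falls below the significance
threshold. Both thresholds are configurable.

**Over-representation.** Gene-set enrichment of a selected protein list
against a universe uses the upper-tail hypergeometric probability
P(X ≥ k), BH-adjusted across sets; gene sets come from standard GMT
files. Ranked GSEA and annotation retrieval are out of scope.

## Numerical and degenerate-input conventions

- Nearest-match ties broken by intensity; matching independent of input
  peak order (scans are kept m/z-sorted).
- Normalization refuses zero-total channels by name; log2 with pseudo 0
  refuses non-positive cells and lists them.
- F-tests guard against non-nested or saturated comparisons; RSS
  differences are clamped at 0 against floating-point noise.
- BIC is undefined at RSS = 0 (perfect interpolation) and raises.
- The two-means S/N split flags degenerate (empty or constant) inputs
  instead of inventing modes.

## Problem sizes in tests

The test-suite simulations use 200–500 proteins for classification-rate
checks, 10,000 proteins for type-I-error calibration of the F-test
(rejection fraction 0.05 ± 0.01, Kolmogorov distance < 0.02 to uniform),
and seeded generators throughout, chosen to keep rates' sampling noise
well inside the asserted margins.

## Known limitations

- The saturation model is binary (threshold trigger) with a uniform
  merged-resolution draw; real coalescence is intensity-graded.
- No isotope-impurity correction matrix (the reproduced workflow does
  not apply one).
- The filter removes whole PSMs; partial channel-level recovery of
  merged pairs is deliberately not attempted.
- mzML input takes intensities only; vendor noise and resolution arrays
  are not part of standard mzML, so resolution-based filtering requires
  the tabular PSM input (or simulator output), and S/N from mzML is an
  estimate.
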