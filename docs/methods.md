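# Methods

## The problem

Species delineation in *Streptomyces* rests on pairwise genome-relatedness
metrics with conventional cut-offs: 70% (digital) DNA–DNA hybridization,
95–96% average nucleotide identity, and — where genomes are unavailable —
a multilocus (MLSA) evolutionary distance over five housekeeping genes,
historically bounded at 0.007 substitutions/site. These scales are not
interchangeable by fiat: the mapping between them must be estimated. This
package estimates it from a curated table of 80 type-strain pairs and
packages the resulting decision rule.

## Data

The packaged table (`src/strepdelim/data/streptomyces_pairs.tsv`) holds 80
type-strain pairs with ANIm (%), MLSA distance (substitutions/site, 3 dp)
and dDDH (%). All pairs were pre-selected to ANIm ≥ 90%, the regime where
MUMmer-based ANI is considered reliable; the table therefore says nothing
about more distant pairs. The source material is inconsistent about
whether the table holds 78 or 80 pairs (its caption vs. its body and
text); all 80 curated rows are shipped and the discrepancy is documented
rather than resolved. Strain labels are opaque strings (type-strain
superscript T rendered as a plain trailing `T`); no nomenclatural
normalization is attempted, and duplicate detection treats (A,B) and
(B,A) as the same pair.

ANIm and dDDH are consumed as numbers: computing them requires external
whole-genome tools and is out of scope, as are alignment and trimming of
the gene sequences (inputs to the MLSA module must arrive pre-aligned and
pre-trimmed).

## MLSA distance

Five gene alignments (*atpD, gyrB, recA, rpoB, trpB*) are validated —
equal lengths within a gene, length divisible by 3 (the only in-frame
check applied), identical strain sets across genes — and concatenated
head-to-tail in that fixed order. Pairwise distance is Kimura's
two-parameter estimate `d = -1/2·ln[(1-2P-Q)√(1-2Q)]` with P and Q the
transition and transversion proportions among compared sites.

Numerical and edge-case choices:

* **Pairwise deletion.** Any site where either sequence is not A/C/G/T
  (case-insensitive; U folds to T) is excluded from that pair's
  comparison. This is the common MEGA-style default; the alternative
  (complete deletion across all strains) would change distances only in
  the third decimal on realistic data but is not offered.
* **Saturation.** If `1-2P-Q ≤ 0` or `1-2Q ≤ 0` the distance is
  undefined; the package raises an error for a single pair and, in a
  distance matrix, flags the cell (NaN plus a per-pair failure record)
  rather than dropping or infinities. The working range of the curated
  table (MLSA ≤ 0.05) is far from saturation, so a saturated pair
  indicates bad input, not deep divergence worth representing.
* Distances pooled from per-gene site counts equal the distance on the
  concatenation exactly (the counts are additive); the test suite asserts
  this identity.

## Exponential cross-metric regression

Each metric pair is linked by a single-term exponential `y = a·e^{b·x}`
(no offset), the simplest form consistent with the observed curvature that
also reproduces the near-perfect dDDH–ANIm correlation (R² ≈ 0.998).
Fitting minimizes the residual sum of squares on the **original** scale
(Levenberg–Marquardt via `scipy.optimize.curve_fit`, ≤ 200 iterations),
initialized from ordinary least squares of ln y on x; R² = 1 − RSS/TSS is
likewise reported on the original scale, matching how interactive fitting
software conventionally reports nonlinear R². No weighting and no outlier
removal: all 80 points enter every fit, including the pairs that deviate
from the dDDH rule.

The response may contain exact zeros (MLSA = 0.000 for indistinguishable
pairs): the original-scale objective is well-defined there, so only the
log-linear initialization is restricted to the positive observations;
negative responses are rejected. A constant positive response degenerates
cleanly to `b = 0, a = ȳ`. When the total sum of squares is zero, R² is
defined as 1 if the fit is exact and −∞ otherwise.

Three directions are fitted for calibration: dDDH as response of ANIm
(inverted at dDDH = 70 to place the ANIm cut-off at ≈ 96.6%), and MLSA as
response of dDDH and of ANIm (the dDDH fit evaluated **forward** at 70
places the MLSA boundary at ≈ 0.008). Treating dDDH as the response of
MLSA and inverting does not reproduce the published boundary — the
direction matters because the fits are not inverses of each other — so
the calibration directions are fixed, while `fit_exponential` accepts any
direction. Note that the three pairwise exponential links cannot all hold
exactly at once (two of them compose to a double exponential); they are
independent empirical approximations, each adequate over the observed
range.

## The delineation rule

`classify` applies, in order:

1. **Genome metrics present** (dDDH and/or ANIm): conspecific if either
   metric reaches its cut-off (70% dDDH or 96.7% ANIm — either-metric
   sufficiency); borderline if below both cut-offs but inside a band just
   below either one; otherwise distinct. Genome metrics take precedence
   over the MLSA tier whenever supplied — the calibration data themselves
   contain a pair (MLSA 0.007) whose status was decided on dDDH grounds.
2. **MLSA only**: conspecific below 0.008; distinct at or above 0.014;
   in between, the verdict is that genome metrics must be obtained.

The borderline band widths (2.0 dDDH points, 1.0 ANIm points, both
configurable) are a reconstruction: the source criterion is only "less
than but close to" the cut-offs. The defaults select exactly the five
curated pairs whose status required polyphasic re-examination (dDDH in
[68, 70) or ANIm in [96.7 − 1.0, 96.7)), which is the behaviour the rule
is meant to encode. A borderline verdict is terminal here: phenotypic,
chemotaxonomic and phylogenomic follow-up is out of scope, so the package
reports that such evidence is required and never emits a taxonomic act
for these pairs. When the two genome metrics conflict across their
cut-offs (one above, the other below its cut minus the band), the verdict
is still conspecific but the rationale records the conflict; the curated
data never exercise this case, so the either-sufficiency reading is an
interpretation, not an observed rule.

Every verdict carries a rationale string tracing the rule that fired.

## Synthetic data

The simulator exists so that every pipeline stage is testable against
known ground truth without any downloads.

* `simulate_pair(length, p, q, seed)` draws sequence A uniformly over
  A/C/G/T and flips each site of B independently: to the transition
  partner with probability p, to either transversion partner (equiprobably)
  with probability q. Divergence is parametrized directly by the
  site-change proportions, so the closed-form K2P value at (p, q) is the
  exact generating distance — no rate matrices or branch lengths. Default
  study conditions in the validation script: length 10 000, p = 0.04,
  q = 0.02 (true d ≈ 0.0629, the mid-range of the curated table), 50
  replicates.
* `simulate_metric_table(n, ...)` draws ANIm uniformly on [90, 100],
  produces dDDH through the exponential link with additive Gaussian noise
  (σ = 0.5 by default, matching the visual scatter of the calibration
  data), truncates to [0, 100] recording which records were clipped, and
  derives MLSA from dDDH through a second noisy exponential link. Default
  link parameters are the values fitted to the curated table
  (a = 0.0028, b = 0.1048; MLSA link a = 0.287, b = −0.0508, σ = 0.002);
  n = 80 matches the curated sample size.

What the simulator does **not** emulate: indels (gap handling is covered
by deterministic gap-injection fixtures instead), compositional bias
(base usage is uniform), rate variation across sites and genes, and any
phylogenetic correlation between pairs. Passing the recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to real-data violations of it.

All generators are deterministic under a fixed seed; the replicate seeds
of the recovery experiment are spawned from one `SeedSequence`.

## Validation and reproduction

The test suite checks, among others: hand-computed K2P values
(P = 0.04, Q = 0.02 → 0.06289; one transition in nine sites → 0.12566);
the inflation property d ≥ P + Q; near-unbiasedness of the distance
estimator (|relative bias| < 2% at 10 kb over 50 replicates); exact
recovery of noiseless exponential data; superiority of the nonlinear fit
over a dense (a, b) grid-search oracle; recovery of the generating link
rate within 5% from noisy tables over 20 seeds; and reproduction of the
published enumerations (7/4/9 pairs), R², translated thresholds,
borderline set and synonym verdicts on the packaged table. The
goodness-of-fit check on simulated change frequencies uses three fixed
seeds and requires two to pass at α = 0.01, since a 1%-level test rejects
~1% of seeds even for a correct generator.

`strepdelim reproduce` reruns all of these deterministic quantities and
compares them to stored reference values with reconstruction tolerances
(R² ± 0.002, ANIm at 70% dDDH ± 0.3, MLSA at 70% dDDH ± 0.003, counts
exact). The tolerances acknowledge that the published figures come from
rounded table values and an interactive fitting tool whose exact settings
are unrecorded; our refit reproduces them within those margins
(R² 0.99790 vs 0.99756; 96.57 vs ≈ 96.7; 0.0082 vs ≈ 0.008).

## Known limitations

* The calibration is genus-specific (*Streptomyces* type strains,
  ANIm ≥ 90%); thresholds should not be transported to other taxa without
  re-calibration.
* The MLSA ↔ genome-metric fits have R² ≈ 0.87–0.88: MLSA distance is a
  usable triage statistic, which is exactly why the rule has an
  indeterminate middle tier rather than a single cut-off.
* The borderline band widths are reconstructed, not measured; users with
  different risk tolerance should adjust them via `Thresholds`.
* The regression reports no confidence intervals; the calibration numbers
  are point estimates from one 80-pair sample.
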