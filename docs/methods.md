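# Methods

## The measurement being modelled

Endpoint-fluorescence SNP genotyping (TaqMan-, KASP- and rhAmp-style
chemistries) reads two allele-specific reporter dyes per well after PCR.
Plotted as (signal_x, signal_y) — the allele-1 and allele-2 normalized
fluorescence, e.g. FAM Rn and VIC Rn — the samples of one assay fall into
three clusters: homozygote A11 near the X-axis, homozygote A22 near the
Y-axis, and heterozygote A12 along the diagonal, while no-template controls
(NTCs) sit in a low-fluorescence cloud near the origin.  All geometry in this
package is anchored at the per-assay NTC centroid (x1, y1):

* separation angle  `alpha = atan2(dy, dx)`, `dx = x - x1`, `dy = y - y1`
  (equals the plain `arctan(dy/dx)` whenever `dx > 0`; atan2 keeps vertical
  lines well defined).  Restricted to [0, pi/2]; tiny negative deltas
  (|d| < 1e-12) are floored to zero before the angle is formed.
* NTC distance  `D = sqrt(dx^2 + dy^2)`.
* compactness  `S` = sample standard deviation (divisor n-1) of member
  distances to the cluster centroid; undefined (missing, never 0) for
  clusters with fewer than two members.

Angle and compactness comparisons are conventionally based on the A11
cluster only; NTC distance uses all called clusters.  Per-point angles are
averaged arithmetically: all values live well inside [0, pi/2], far from any
wrap-around, so circular statistics are unnecessary.

## Synthetic plate generator

No raw fluorescence data is publicly deposited for this kind of three-way
platform comparison, so the generator *is* the data source and its defaults
define the study conditions: 94 samples + 2 NTC wells per assay (one 96-well
block, four blocks per 384-well plate) x 29 assays x 3 platform profiles,
i.e. 2,784 wells per platform.

Each platform profile places genotype centroids at polar coordinates
(gain x r_label, angle_label) from the NTC center, with r_A11 = r_A22 = 1 and
r_A12 = 1/sqrt(2) so the heterozygote's single-channel signal matches a
homozygote's.  Called wells get isotropic Gaussian noise (`noise_sd`); wells
that fail amplification are drawn from the NTC distribution; "invalid" wells
amplify weakly, at a radius uniform between 2 x ntc_sd and 0.25 x gain along
their genotype's direction.  Genotype truth is drawn once per sample x assay
and shared across platforms (genotype is a property of the DNA; dropout is a
property of the chemistry and is drawn per platform).  One root seed feeds a
`numpy` SeedSequence; per-platform streams are spawned deterministically, so
runs are bit-reproducible.

The default three-platform scenario encodes the qualitative contrasts the
chemistries are known for, not any measured table:

| profile | gain | A11 angle (rad) | noise_sd | fail rate | invalid rate |
|---------|------|-----------------|----------|-----------|--------------|
| rhAmp   | 5.0  | 0.19            | 0.30     | 3.0%      | 7/2726       |
| KASP    | 1.5  | 0.19            | 0.075    | 6.5%      | 13/2726      |
| TaqMan  | 1.9  | 0.35            | 0.038    | 7.0%      | 57/2726      |

gains order rhAmp >> TaqMan > KASP (rhAmp's much higher fluorescence),
TaqMan has the tightest clusters but the widest A11 angle, and the failure /
invalid rates mirror the observed per-platform call-rate contrasts.  The
noise levels are set so that clusters are separated by many within-cluster
SDs — the regime in which commercial auto-callers operate.  A diversity
panel of inbred wheat lines is almost fully homozygous, so the default
heterozygote model is a fixed 5% A12 fraction (a Hardy–Weinberg mode exists
for outbred designs).  Optional per-assay jitter of the centroid angles is
exposed (`assay_angle_jitter_sd`) but defaults to 0.

What the generator does **not** emulate: PCR kinetics, probe thermodynamics,
assay-specific cluster rotation or skew, correlated plate effects,
non-isotropic noise, and contamination.  Passing tests therefore demonstrate
that the analysis machinery is correct under the stated cluster model, not
that the caller would reach the same accuracy on any real instrument export.

## Allele caller

Commercial cloud callers are black boxes; the caller here is deliberately
transparent and uses the same discrimination axis as the reported metrics
(the NTC-anchored angle).  Per assay x platform:

1. **FAILED** — wells within `failed_radius_mult` (3.0) NTC spreads of the
   NTC centroid.  With only two NTC wells the RMS-spread estimate is very
   noisy (a proportional-only rule misses ~10% of true failures regardless
   of scale), so an absolute floor of `ntc_floor_frac` (5%) of the assay's
   90th-percentile NTC distance always applies.  A well exactly at the NTC
   centroid is FAILED under every parameterization.
2. **INVALID** — remaining wells with NTC distance below
   `invalid_radius_frac` (25%) of the 90th-percentile NTC distance of the
   amplified wells: amplified, but too dim to classify.
3. **Genotypes** — k-means (k = 3) on (angle, log NTC distance) with fixed
   initial centroids at 15/45/75 degrees on the observed median radius, so
   calling is deterministic, order-independent and invariant to a common
   rescaling of both channels.  Clusters are labelled A11/A12/A22 in
   ascending mean angle.  Two merge rules guard against spurious splits:
   a cluster with < 2 members joins its angular neighbour, and two adjacent
   clusters merge when their mean-angle gap is below 4 pooled within-cluster
   angle SDs *and* below an absolute ceiling of pi/12 rad.  The second rule
   exists because on heterozygote-free assays (common in an inbred panel)
   k-means reliably splits one homozygote cloud into two viable halves —
   which sit ~2.7 pooled SDs apart, versus > 10 for genuine neighbouring
   genotype clusters; the absolute ceiling keeps genuinely noisy clusters
   intact.  With fewer than three final clusters, labels are the ordered
   subset of {A11, A12, A22} whose idealized angles (15/45/75 degrees) best
   match the observed cluster means.  Fewer than three amplified wells makes
   the assay uncallable (all amplified wells INVALID).

**Call quality** is the posterior probability of the assigned cluster under
an isotropic Gaussian mixture fitted to the final clusters (weights =
cluster proportions, per-cluster variance floored at (1e-9 x assay scale)^2
so the noise-free limit yields quality exactly 1).  This is the closest open
analogue of the proprietary "probability of the most likely call" scores.
Quality is recorded only for genotype calls; FAILED/INVALID/NTC rows carry a
missing value.

## Platform comparison

One-way fixed-effects ANOVA under a completely randomized design, computed
per metric.  The replication unit follows the natural granularity of each
quantity and is configurable: call quality is per called well (thousands of
residual df), while angle, compactness and NTC distance are per cluster (one
observation per assay x platform cluster).  Degenerate inputs are defined,
not errors: zero within-variance gives F = 0, p = 1 when group means agree
and F = +inf, p = 0 otherwise (note that simulated noise-free data usually
lands an ulp away from exact zero, producing astronomically large finite F).

Fisher's LSD mean separation uses the per-pair threshold
`t(1-alpha/2, df_w) * sqrt(MS_w (1/n_i + 1/n_j))`, which handles the unequal
group sizes that unequal failure counts produce.  The letter display is
built from maximal cliques of the pairwise non-significance relation
(exhaustive over <= 16 groups), which guarantees exactly that two groups
share a letter iff their difference is within their pairwise LSD; letters
run from "a" downward in descending-mean order.  Like any pooled-variance
LSD, the pairwise tests are mildly anti-conservative when group variances
are heteroscedastic — in the default scenario TaqMan's per-cluster angle
variance is much smaller than rhAmp's, and the truly-equal rhAmp/KASP angle
means get split at roughly twice the nominal 5% rate across seeds.  No
multiple-testing correction is applied across the four metrics (matching
field practice for this design); reports carry a note saying so.

Genotype concordance between two platforms counts only sample x assay cells
genotyped A11/A12/A22 by *both*; FAILED and INVALID cells enter neither
numerator nor denominator, heterozygote-homozygote mismatches are
discordant, and an empty intersection yields a missing value, not 0.

## Cost model

Per-reaction cost = assay_price/assay_reactions +
mastermix_price/mastermix_reactions, computed in exact decimal arithmetic
and rounded half-up to the cent for display; ranking always uses the raw
value so rounding can never reorder platforms.  DNA-extraction cost is
excluded.  The built-in reference specs are the published list prices for
5 ul reactions: TaqMan $259/2,000 + $554/2,000 -> $0.41; KASP $64.20/5,000 +
$1,382.50/10,000 -> $0.15; rhAmp $75.60/5,000 + $1,038.60/10,000 -> $0.12.

## Numerical and validation choices

* Plate/call CSVs serialize floats with 17 significant digits, so write ->
  read round-trips are bit-exact (property-tested on random well grids).
* The angle implementation is checked against a 50-digit `mpmath` arctangent
  oracle on 1,000 random points; ANOVA against a statsmodels OLS fit on 50
  random datasets at 1e-8 relative; LSD letters against brute-force all-pairs
  comparison; the caller against the generator's planted truth.
* Monte-Carlo sizes used by the test suite, chosen to keep the full run in
  tens of seconds while leaving comfortable statistical margins: 10,000 null
  replicates for the ANOVA type-I calibration (0.05 +/- 0.01 band) and 200
  seeded replicates for power, where a planted A11 angle difference of 3x
  the per-cluster observation SD (the ANOVA's replication unit) must be
  detected at alpha = 0.001 in >= 95% of replicates; the measured rate is
  200/200.  Power replicates use 2 platforms x 20 assays x 64 samples with a
  25% heterozygote fraction, which keeps every genotype cluster populated.

## Known limitations

* The caller assumes the three clusters are angularly ordered and roughly
  isotropic; rotated or strongly elliptical clusters (some real chemistries)
  would need a covariance-aware mixture.
* Quality scores on well-separated synthetic clusters are ~1 almost
  everywhere, so their distribution is far narrower than real instrument
  quality scores; only their ordering (correct > incorrect calls) is
  meaningful, and it is what the tests assert.
* With two NTC wells the FAILED threshold leans on the absolute floor; on
  real plates with many NTCs the proportional rule would dominate.
* The LSD letter pattern between platforms with truly equal planted means is
  a sampling-dependent alpha-level event by construction and varies with the
  seed.
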