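# Methods

This note records the models, parameter defaults and design choices behind
`pulkit`, and what the synthetic-data tests do and do not demonstrate.

## Growth phenotyping

**Model.** Curves are hourly OD600 readings of anaerobic batch cultures.
Because readings above ~0.8 leave the spectrophotometer's linear range, the
culture is diluted and immediately re-measured; each reading therefore
carries a dilution factor, and analysis begins by stitching
(`OD = measured x factor`).

**Exponential-phase detection.** The specific growth rate is defined by the
two-point formula `(ln A_max - ln A_min)/(T_max - T_min)` applied to the
minimum and maximum OD *within the exponential phase*.  Locating that phase
is the only discretionary step.  We slide every window of >= `min_points`
consecutive usable points (OD >= `od_floor`, default 0.02 — log-OD is
unstable near the blank) over log-OD, fit a least-squares line, and keep
windows with R² >= `r2_min`; among those, the window with maximal slope is
chosen, with a fall-back to the best-R² window on curves too noisy for any
window to qualify.  Constant windows are treated as perfect zero-slope fits
so flat curves yield rate 0 rather than an undefined R².

Defaults are `min_points = 5`, `r2_min = 0.995`.  Shorter windows with a
looser gate systematically overestimate the rate on noisy data: a 3-point
window can pass R² = 0.98 by chance on a run of measurement noise, and
selecting the maximum over many such windows inflates the estimate by
~20% at OD noise SD 0.02.  Five-point windows at R² >= 0.995 cut that bias
to <= 5% while remaining exact on noiseless curves for rates up to 1.0/h —
at 1.0/h a culture starting at OD 0.05 and plateauing at 4.0 spends only
about five hourly samples in exponential phase, so longer windows would
break exact recovery of fast growers.  Ties among equal extreme values are
broken toward the shortest span (last occurrence of the minimum, first of
the maximum) so that a window brushing the lag or plateau does not dilute
the two-point slope.  With this rule the per-curve scatter of the estimate
at noise SD 0.02 is ~8% (driven by the two endpoint readings), so recovery
statements are about the mean over seeds, not individual curves.

**Classification.** Growth is *excellent* when rate >= 0.5/h and maxOD >= 3
OD units, *poor* when rate < 0.5/h and maxOD <= 1.5, otherwise *good*;
the rules are checked in that order and partition the plane.  `maxOD` is
the highest dilution-corrected reading of the whole curve (not the
endpoint, which may sit after a post-peak decline).  Replicates are
phenotyped individually, then averaged with standard errors; the category
is assigned from the means.

**Expected growth.** For a polysaccharide with monosaccharide weight
fractions w_i and per-monosaccharide metrics m_i (rate or maxOD), the
expectation is Σ w_i·m_i.  Weights are renormalized to sum to 1 because
manufacturer composition sheets mix fraction and percentage conventions.

## Induction profiling

**Normalization.** CPM and TPM are computed exactly (columns sum to 1e6).
Between-sample scaling uses TMM: the reference sample is the column whose
75th-percentile count proportion is closest to the mean of those
percentiles; per sample, gene-wise M-values (log2 ratio of proportions vs
the reference) and A-values (mean log2 abundance) are computed on genes
observed in both, the upper and lower 30% of M and 5% of A are trimmed,
and the factor is 2 to the precision-weighted mean of the surviving
M-values (weights = inverse binomial asymptotic variances), with factors
rescaled to geometric mean 1.  The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ~1e-6 on random matrices; the in-repo
test oracle is an independent brute-force reimplementation.  A sample
sharing no expressed genes with the reference receives factor 1 with a
warning.

**Induction estimate.** Induction is the log2 ratio of mean TMM-normalized
CPM per substrate versus the glucose reference, with a pseudocount
(default 0.5 CPM) added to both means so genes silent on glucose stay
finite.  This is a deliberate simplification: no negative-binomial GLM,
dispersion estimation or hypothesis testing is performed, because the
downstream readouts (heatmaps, the |log2FC| > 3 gene list, PUL target
calls) are threshold-based on fold-change, not on p-values.  The gene gate
uses strict inequalities (> 3 or < -3).

**PUL aggregation and calls.** Per PUL the summary statistic is the mean
log2FC of its susC/susD members — marker induction consistently dominates
that of effector genes, so the marker mean is the cleanest activation
signal; per-gene rows are always retained for heatmaps, with genes removed
by the expression filter reported as missing rather than zero.  Call rule
per PUL: the substrate with maximal marker log2FC is *confirmed* if above
the confirmation threshold (default 3, the same as the gene gate); other
substrates above it are *cross_activated*; substrates in (1, 3] are
*moderate* — induced but inconclusive, the band we use to operationalize
"modest but specific" cases such as homogalacturonan loci; the rest are
*not_induced*.  The moderate band's lower edge (1 log2 unit, ~2-fold) is
an interpretive choice, configurable.  A `specificity_margin` (default 1
log2 unit) flags cross-activated substrates whose induction comes within
the margin of the maximum, so near-ties are visible in reports rather than
silently resolved.

## qPCR preference analysis

**Quantification.** Relative expression is 2^-ddCt with dCt = Ct_target -
Ct_16S and the glucose-grown culture as calibrator; amplification
efficiency is fixed at 2.0 (no standard-curve correction).  Technical
wells are averaged within each biological replicate, then across
replicates, all on the Ct scale before exponentiation — the standard
nesting for triplicates with two technical repetitions.

**Dynamic classes.** Applied in order to the replicate-mean series:
(1) *inactive* if mean induction over all time points <= 5 (0 points);
(2) *active* if induction > 5 at every considered time point (1 point);
(3) otherwise *delayed* (0.5 points).  "Delayed" is thus the residual
class — mean above 5 but not above 5 throughout — which captures gradual
activation without inventing a slope test.  Two further choices the rules
leave open: replicate means are taken before time-averaging, and the
final time point can be exempted from the "active" requirement for
substrates depleted before sampling ends (default exemption list: starch
only; configurable).  The class order inactive < delayed < active is
monotone under pointwise increases of the series.

**Scoring.** A substrate's score is its summed points divided by the
number of mixture assays containing it, hence the arithmetic mean of
awarded points, bounded in [0, 1]; equal scores form tie groups in the
ranking (rendered "a, b > c").

## Synthetic data

The generators emulate the *study conditions*: a glucose reference plus
11 polysaccharide conditions in triplicate for the two strain scenarios,
negative-binomial counts (gamma-Poisson, gene-shared dispersion 0.05),
marker induction of 6 log2 units and effector induction scaled by the
effector:marker ratio (default 3:6) in target conditions, cross-activation
effects per the strains' qualitative induction maps, and mean library size
150,000 reads (the sequenced samples' 10–20 M reads scaled down 100x to
desk scale; depth only tightens the estimates, so recovery at 150 k is the
conservative case).  Library sizes vary lognormally (sigma 0.1); induction
acts multiplicatively on expected proportions, which are renormalized, so
induced scenarios carry the compositional bias TMM exists to remove.
Baseline expression is 200 CPM for markers, 100 for effectors and
lognormal around 50 for background genes, fixed by a scenario-construction
seed independent of the sampling seed.

The TF1-3 scenario encodes seven confirmable PULs (starch/pullulan and
xyloglucan strictly target-specific; arabinan cross-activated by pectic
galactan; two rhamnogalacturonan-responsive loci; galacto/glucomannan and
arabinogalactan) plus a homogalacturonan locus at effect 2 that must stay
in the moderate band.  The KHP1 scenario encodes that strain's map,
including the strongly and exclusively β-glucan-induced locus.  The KHP1
qPCR truth table lists 13 two-substrate mixtures with per-substrate
dynamic classes (active plateau 50-fold, inactive hover 2-fold, delayed
onset 5 h on a 2–8 h grid, lognormal noise CV 0.1); classifying and
scoring simulated series reproduces the preference ranking β-glucan,
starch, arabinoxylan, pectic galactan > arabinan > beechwood xylan >
arabinogalactan with scores 1.0 / 0.875 / 0.667 / 0.25.

Growth curves follow a piecewise lag–exponential–plateau model (not
logistic) precisely so the two-point rate formula is exact on noiseless
data; noise is additive Gaussian on the *measured* (post-dilution)
reading, and dilution by a factor (default 10) triggers whenever a
noiseless reading would reach 0.8.

**What passing tests do not show.** The generators do not model substrate
depletion, regulatory feedback, growth-phase-dependent expression, read
mapping artifacts, operon structure, or correlated noise between genes;
real libraries also differ in depth and 100x larger counts shrink
fold-change noise.  Recovery results therefore demonstrate the
correctness and calibration of the *analysis* under the stated stochastic
model, not performance guarantees on arbitrary real data.

## Problem sizes and determinism

Test and acceptance runs use the scenario defaults: the TF1-3 recovery
grid is 20 seeded simulations of ~200 genes x 36 samples; qPCR class
recovery uses 100 seeds per class; growth recovery 50 seeds.  Every
simulator consumes an explicit integer seed (scripts derive sub-seeds from
one master seed below 2^31), so all outputs are bit-reproducible.

## Known limitations

* Induction is mean fold-change, so no uncertainty accompanies a call;
  with two or three replicates a confirmed call near the threshold can
  flip between seeds.
* The exponential-window rule assumes >= 5 usable points in phase; cultures
  faster than ~1/h at hourly sampling violate this and would need denser
  sampling.
* The moderate band and the residual definition of "delayed" are
  operationalizations of qualitative descriptions and are configurable
  rather than canonical.
* TPM is provided for per-sample abundance tables; the induction pathway
  itself is CPM-based and ignores gene length (length cancels in
  within-gene ratios).
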