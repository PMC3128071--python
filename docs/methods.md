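# Methods

## Regions, orientation and filters

All coordinates are 1-based inclusive internally (the GFF3 convention; BED
input is converted on read). Multi-segment CDS annotations collapse to the
union span per gene id, so distances are measured between ORF boundaries:
the inter-CDS length of an adjacent pair is
`right.cds_start − left.cds_end − 1`, the number of nucleotides strictly
between the ORFs. Pairs with length ≤ 0 (overlapping or abutting ORFs) are
excluded; this operationalises "no overlap of the transcripts" at ORF level,
since UTR coordinates are generally unavailable.

Orientation is a total function of the two strands: (+,−) convergent, (−,+)
divergent, equal strands uni-directional. It is invariant under reading the
chromosome from the other end (flip both strands, swap left/right).

Adjacency is computed among protein-coding genes only by default
(`protein_coding_only`); the `all_features` mode lets non-coding annotations
break adjacency instead, because "no intervening genes" is genuinely
ambiguous about non-coding genes. Tandem-duplicate pairs — flanking genes
with a similarity hit whose bitscore is ≥ 50 in either direction (boundary
inclusive, maximum of the two asymmetric scores) — are flagged and excluded
from all statistics, and regions they flank cannot witness conservation in
either species. Repeat intervals flag a region when they overlap the open
interval between the ORFs by ≥ 1 bp.

## Conservation and age

A region of the focal species is conserved in another species when (a) both
flanking genes have orthologs there, (b) some ortholog combination is itself
a retained adjacent pair, and (c) each gene presents the same end (5' or 3')
to its region as its ortholog does. Formulating "same orientation" through
facing ends makes the test invariant to whole-chromosome reversals: a
neighbourhood carried to the opposite strand by an inversion still counts.
With one-to-many orthology, any witnessing combination suffices.

Regions conserved nowhere are young; all others are old. Age classes are
assigned by the most distal clade containing a conserving species — losses
in intermediate clades are ignored — using nested clades read off the rooted
species tree along the root-ward path from the focal leaf. When the tree
provides k attachment steps and n classes are requested, the farthest n−1
steps each form a class and the nearer steps merge into the youngest class;
on the 11-yeast tree with focal `sce` and n = 3 this yields
PO = {sba, sca}, VO = {cgl, kpo, zro}, XO = {kth, kwa, skl, ago, kla}.

## Length statistics

**Lower limit.** The left edge of a stratum's length distribution is
estimated by the empirical 1% quantile (linear interpolation between order
statistics, rounded to integer bp). The quantile is robust to a stray
mis-annotation; the sample minimum is available as `method="min"`, and is
the automatic fallback (with a warning) below n = 20. For a left-truncated
log-normal the low quantile sits slightly above the truncation point — on
5000 draws truncated at 150 bp (log10 mean 2.6, sd 0.2) the 1% quantile's
sampling distribution is centred near 164 bp with an sd of ~2 bp — so the
estimator brackets the truncation from above by a few bins at typical sample
sizes.

**Gaussian fits and the bimodality test.** Lengths are log10-transformed
and binned at 0.1 log10 units (configurable), with bin edges aligned to
multiples of the bin width. One or two scaled Gaussian curves (amplitude,
mean, sd per component — 3k free parameters) are fitted to the bin counts
by bounded least squares. Because bin counts are Poisson, residuals are
scaled by sqrt(max(count, 1)); without this the nested comparison is badly
anti-conservative (measured false-rejection ~17% at the 1% level, versus
under 3% with weighting). Two identifiability constraints keep the fit
well-posed: component sd is bounded below by one bin width (a narrower
component cannot be located within its bin), and component means are
bounded to the observed histogram range (a mean outside it can mimic an
arbitrary single-bin spike with a runaway amplitude). The optimiser uses
Jacobian-based parameter scaling, since amplitudes (counts) and sds (log10
units) differ by orders of magnitude. The k = 2 fit is multi-started: means at the
25%/75% sample quantiles, four seeded random perturbations, and a
degenerate split of the k = 1 optimum, which guarantees RSS₂ ≤ RSS₁
(nesting); the best RSS wins and components are reported in order of
increasing mean, with weights proportional to amplitude × sd. The two fits
are compared by the nested F-test
`F = [(RSS₁−RSS₂)/3] / [RSS₂/(n_bins−6)]` with p from the upper tail of the
F(3, n_bins−6) distribution. Measured on synthetic strata, the test retains
k = 1 on unimodal data and rejects it on clearly bimodal data in ≥ 90% of
replicates at α = 0.01.

**Summaries and cross-species statistics.** The per-stratum summary table
reports arithmetic means of raw bp (rounded to integers) alongside the
lower-limit estimate; fits operate on the log10 scale. Empty strata emit
rows with missing markers so no stratum silently disappears. The
coefficient of variation across species uses the n−1 sample sd divided by
the mean. The orientation-composition test is a df = 2 goodness-of-fit χ²
of (divergent, uni-directional, convergent) counts in a length window
against (0.25, 0.50, 0.25), the expectation when strands are independent
coin flips. Correlations are Pearson product-moment with the two-sided
t-test (df = n−2). The minimal-promoter estimate per species subtracts the
old convergent *lower limit* (the promoter-less baseline's left edge) from
the promoter-containing lower limits; subtracting the convergent *mean*
instead produces negative estimates for several compact species, which the
reporting op logs as a caveat whenever it runs.

## Neutral rearrangement model

The genome is a bag of inter-CDS lengths. Assuming the length distribution
is at equilibrium, the ancestral distribution is approximated by the total
(old + young) distribution observed now, and N_young regions are removed
from it. A region's breakage weight is its full length under Model A, or
`max(length − promoter_offset, 0)` under Model B (rearrangements inside the
minimal promoter space are taken to be lethal). The per-nucleotide rate is
`p = N_young / Σ (effective) lengths`, so a region's per-step break
probability is `P = p × effective length` (an error is raised if any
P > 1, prompting a smaller time step).

Two removal algorithms are provided. The default, *sequential*, draws
N_young regions without replacement with probability proportional to
effective length; it is implemented exactly via exponential-race keys
(`Exp(1)/w_i`, smallest N_young win), which is distributionally identical to
step-by-step weighted sampling. The alternate *bernoulli_sweep* mode runs
repeated sweeps in which each surviving region breaks independently with
probability P, truncating the final sweep by weighted choice if it
overshoots, until exactly N_old remain. The two modes agree in distribution
when N_young ≪ N_total. Each replicate (default 10, matching the averaging
convention of the histograms) uses an independent substream of the master
seed.

Simulated survivors are compared with the observed old lengths by the
two-sample KS statistic on raw lengths plus a per-bin excess table
(observed − mean simulated count on shared log10 bins). The
`right_tail_excess` readout sums the excess over bins within the observed
old range from its 75th-percentile length upward: bins beyond the old
maximum are dominated by long *young* regions that survive the simulated
removal, so including them measures young-tail contamination rather than
the maintenance of long old regions. A Monte-Carlo null for the KS
statistic (`ks_null_quantile`) re-simulates pseudo-observed old samples
under the model and returns the requested quantile of the resulting KS
distribution.

## Synthetic clades

The generator emulates the statistical structure the analysis assumes:

* **Ancestor.** Strands are iid fair coin flips (hence ~25/50/25
  orientation proportions); each gap is drawn from the per-orientation
  stratum spec. Defaults: convergent log-normal (log10 mean 2.30, sd 0.33,
  truncation 10 bp); uni-directional left-truncated log-normal (2.60, 0.33,
  truncation 160 bp); divergent two-component truncated mixture (2.45 sd
  0.13 and 2.95 sd 0.16, second-component weight 0.45, truncation 170 bp,
  clearly bimodal — shared vs. two independent promoters). CDS lengths are
  constant (1 kb) so extracted inter-CDS lengths equal the drawn gaps
  exactly.
* **Rearrangements.** Each event picks two junctions with probability
  proportional to gap length (uniform per-nucleotide breakage) and performs
  a reciprocal translocation, or an inversion when both cuts fall on one
  chromosome; the two broken gaps are replaced by fresh *young* draws whose
  spec is the old spec inflated (median × 1.6, log-sd × 1.3, truncation
  dropped), so young regions are longer and more variable by construction.
* **Stabilising selection.** `protect_top_fraction` (default 10% for the
  promoter-containing strata, 0 for convergent) makes the longest ancestral
  regions unbreakable, planting the right-shoulder excess of long old
  regions that a purely neutral removal cannot reproduce.
* **Orthology and truth.** Orthology is identity by descent (confidence
  1.0). `truth.json` records every extant region's birth branch,
  conservation profile (computed directly from the generator's adjacency
  structures, independently of the analysis code path) and the stratum
  parameters, so every downstream assertion has an oracle.

Generation is a pure function of (CladeSpec, seed).

What the generator does *not* emulate: nucleotide sequences, indel length
evolution within surviving regions (young/old length differences come
entirely from the draw specs), gene duplication and loss (orthology is
one-to-one), operon-like structures, and realistic chromosome counts.
Passing tests on these bundles therefore validate the machinery —
extraction, conservation logic, estimators, the simulator — under the
stated distributional assumptions; they do not certify the biological
conclusions on real genomes, whose annotations carry errors and whose
length evolution includes indels the model ignores.

## Problem sizes and determinism

The end-to-end checks use a 4-species clade with 4 × 800 genes per species
(~3200 regions, ~10% young), comparable to a compact yeast genome and large
enough for the bimodality test to have power at α = 0.01; the
age-recovery checks use an 11-species clade with 120 genes per species.
Monte-Carlo comparisons with the exhaustive-enumeration oracle use 10⁵
replicates on ≤ 6 regions; mixture-test calibration uses 200 replicates of
n = 1000. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` substreams; pipeline outputs are byte-identical
for identical inputs, config and seed.

## Known limitations

* The lower-limit estimator's exact published recipe is unknown; the 1%
  quantile is this package's choice and sits a few bp above a true
  truncation point by construction.
* The equilibrium-ancestor assumption (total distribution now ≈ ancestral
  distribution) is only approximate whenever young regions' lengths differ
  from ancestral ones; at several thousand regions per stratum the KS
  comparison can resolve this approximation error even when the removal
  model itself is exact.
* The F-test on binned counts is approximate (Poisson, not Gaussian,
  noise); with Pearson weighting its measured size is ~2.5% at nominal 1%,
  adequate for the qualitative unimodal/bimodal distinction it serves.
* One-to-many orthology is handled permissively (any witnessing
  combination); other resolutions are defensible and would be stricter.
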