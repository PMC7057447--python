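# Methods

## The model

Array methylomes report, per probed CpG, a beta-value in [0, 1] — the
fraction of methylated signal.  Two empirical features drive the
design: the genome-wide beta distribution is bimodal (most CpGs are
either essentially unmethylated or essentially fully methylated, with
a smaller middle group), and methylation is spatially persistent, so
adjacent CpGs usually share a state.  Both features are captured by a
two-state hidden Markov model along each chromosome:

* hidden states `LOW` and `HIGH` (low-/high-methyl), first-order
  Markov along the genomic order of probes;
* emissions `o | state ~ TN(mu_state, sigma_state^2)`, a normal
  truncated and renormalized to [0, 1].

The joint probability of an observation chain `O` and a state chain
`H` is `P(h_1) P(o_1|h_1) prod_i P(h_i|h_{i-1}) P(o_i|h_i)`.

A single two-state model cannot express three biological categories,
and replacing it by a three-state HMM tends to misassign the sparse
middle group.  The caller therefore runs **two layers** of the same
two-state model: layer 1 splits all sites into low/high classes; each
class is then tested for bimodality, and only if its beta distribution
is bimodal is a second two-state HMM run within the class (the class's
sites re-chained in genomic order).  Low class resolves to
{UMS, MMS}, high class to {MMS, FMS}; a unimodal class is labeled
UMS or FMS wholesale.  Within a bimodal class, the sub-state with the
smaller fitted emission mean takes the lower label, and the MMS labels
arising from the two classes are pooled into one category.

## Initialization, training, decoding

* **Hard split.** States are seeded by thresholding beta at 0.6, the
  empirical valley between the unmethylated and methylated modes of
  array beta distributions: `LOW` iff `o <= 0.6`.  (The opposite
  orientation, LOW above the cutoff, is available via
  `HmmConfig.invert_init` for convention comparisons; it contradicts
  the emission model's semantics and is off by default.)  Layer-2 runs
  use the class median instead of 0.6, since a one-sided class has no
  mass on both sides of 0.6.
* **Starting parameters.** Transition probabilities are the
  frequencies of state changes between adjacent sites (pooled across
  chromosomes, Laplace pseudocount 0.5 so that a state unobserved on a
  small input falls back to a uniform row); the initial distribution
  comes from the chain-start frequencies; emission moments are the
  per-group sample mean and sd.
* **Training.** Baum-Welch with the E-step in log space (explicit
  two-state log-sum-exp; no scaling-factor variant).  The `pi` and `A`
  updates are the standard closed forms.  The emission update
  maximizes the responsibility-weighted truncated-normal
  log-likelihood exactly: with sufficient statistics
  `W = sum w_i`, `S1 = sum w_i o_i`, `S2 = sum w_i o_i^2` the weighted
  negative log-likelihood is a smooth function of `(mu, sigma)` alone,
  minimized numerically (Nelder-Mead on `(mu, log sigma)`,
  warm-started at the weighted moments).  The incumbent and the
  moment-matched pairs are kept as candidates, so the update never
  scores worse than the current parameters and the EM ascent property
  holds exactly — a simple moment-matching update is a good
  approximation near the beta extremes but demonstrably breaks
  monotonicity on diffuse data, where truncation bias is large.
* **Convergence and guards.** Training stops when the total
  log-likelihood improves by less than `tol = 1e-4` (or at
  `max_iter = 100`).  Emission sds are floored at `sigma_floor = 1e-3`
  to prevent variance collapse on (near-)constant groups.
* **Decoding.** Viterbi in log space; ties break toward `LOW`, then
  toward the `LOW` predecessor, making decoding deterministic (ties
  have measure zero on real data).
* **Chains.** One chain per chromosome, parameters pooled across
  chains.  Spatial correlation is an intra-chromosomal argument;
  linking chromosome ends would fabricate adjacency.

## The bimodality gate

The gate between the layers must decide, from a class's betas alone,
whether a further split is warranted.  Two methods are provided:

* **dip** (default): Hartigan's dip statistic — the sup-norm distance
  from the empirical CDF to the nearest unimodal CDF — implemented
  in-package (`methylstates.dip`) with the classical
  convex-minorant/concave-majorant narrowing scheme.  The
  implementation is exact; the test suite checks it against an
  independent linear-programming formulation of the definition (for a
  mode fixed at a data point, "is there a convex-then-concave CDF
  within a +-d band of the ECDF" is an LP, and minimizing d per mode
  and taking the minimum over modes is the dip).  The p-value is
  calibrated by Monte-Carlo simulation against the uniform null
  (`n_boot = 200`, seeded; the uniform is the asymptotically least
  favorable unimodal distribution, so the test is mildly conservative
  for peaked alternatives).  Bimodal iff p < 0.05.
* **kde_peaks**: Gaussian KDE with Silverman bandwidth on a 512-point
  grid over [0, 1]; bimodal iff at least two local maxima exist and
  the minor peak reaches 10% of the major peak's height.  This
  operationalizes the visual "one peak vs. two peaks" reading.

Classes smaller than `min_n = 50` are declared unimodal by rule: a
split supported by so few sites would not be trustworthy, and both
methods lose power there.  This guard also applies at region level,
where it deliberately suppresses sub-splitting when only a handful of
regions exist.

## Region segmentation

Array probes cover only a small fraction of CpGs, densely inside CpG
islands and sparsely in the open sea, so a single gap threshold cannot
express "adjacent" on both terrains.  A site is **island-associated**
if it lies inside an island or within 300 bp of one (`flank = 300`);
the island annotation is an input (BED), as is any SNP-probe
blacklist.

1. **Build.** Adjacent CpGs join a region iff their gap is at or below
   the threshold for the pair — 300 bp if both are island-associated,
   the platform's open-sea gap otherwise (11,300 bp HM450K, 4800 bp
   EPIC; a GENERIC platform must set it explicitly) — and they carry
   the same final site-state.  A mixed island/open-sea pair takes the
   permissive open-sea threshold so island shores are not split.
2. **Filter.** Regions with fewer than 3 CpGs are dropped; so few
   sites cannot support a regional state.
3. **Re-merge.** Surviving neighbours whose boundary-site gap is within
   threshold are merged again and dropped CpGs inside the merged span
   re-absorbed, so that a one-or-two-CpG state flicker does not
   fragment a region.  By default only same-state neighbours merge
   (`remerge_same_state_only = True`): the step exists to heal
   flicker-induced fragmentation, and merging across genuinely
   different states would weld adjacent state runs together wherever
   probe density is high — on dense grids it collapses whole
   chromosomes into single regions.  The permissive variant remains
   available for comparison.  The step iterates to a fixpoint and is
   idempotent.
4. **Classify.** Region mean betas (unweighted over member CpGs),
   chained per chromosome, go through the same two-layer procedure,
   re-training the HMM at region scale — region-level beta
   distributions differ from site-level ones, so reusing site-level
   parameters would be wrong.  With fewer than
   `min_regions_for_hmm = 10` regions the HMM has nothing to learn
   from and a fixed-threshold fallback applies (mean < 0.25 UMR,
   > 0.75 FMR, else MMR) with a prominent warning.

Region spans run from the first to the last member CpG; nothing is
claimed about unprobed flanks.  Output BED uses 0-based half-open
coordinates; input positions are 1-based (Illumina manifest
convention).

## Preprocessing

Probes are excluded when the detection p-value exceeds 0.05, when they
map to chrX/chrY (tolerant of "X"/"chrX" spellings), or when their id
appears in a user-supplied blacklist (e.g. SNP-overlapping probes; no
list is bundled because such lists are assembly- and release-
specific).  Rows with missing beta are dropped, not imputed.
Filtering is idempotent, and coordinates are otherwise treated as
opaque — no genome assembly is assumed.

## The synthetic generator

`methylstates.synthetic` generates the study conditions every stage is
tested under: per chromosome, 40 CpG islands (600-1200 bp, probes
every 20-100 bp) separated by open-sea blocks of 10-40 probes spaced
500-4000 bp; a planted 3-state Markov chain over the strata
(unmethylated/middle/methylated) with self-transition 0.95, started
from its stationary distribution; and betas drawn from the truncated
normal `TN(mean_s, sd_s^2)` of the planted stratum, with default means
0.05/0.5/0.95 and sd 0.05.  Two chromosomes give ~3,200 CpGs and ~140
planted state runs — enough that both layer-1 classes clear the
bimodality gate's `min_n` at site level.  Defaults were chosen once to
mirror the probe-spacing and beta-distribution regimes of HM450K-class
arrays; `sd = 0` is honored exactly (betas equal the stratum means).

Betas are sampled from the truncated normal itself rather than by
clipping normal draws: at a stratum mean of 0.95 with sd 0.05,
clipping would place a ~16% point mass at exactly 1.0, a genuinely
bimodal artifact no array produces (the dip gate detects it and
rightly splits the class).

What the generator does **not** emulate: probe chemistry and
type-I/type-II effects, position- or intensity-dependent noise,
detection p-values beyond a constant, SNP artifacts, batch effects, or
inter-sample variation.  Passing tests therefore demonstrate that the
machinery recovers the model's own structure under realistic sparsity
and spacing — not robustness to array artifacts, which preprocessing
upstream of this package (normalization, QC) is expected to handle.

## Problem sizes and determinism

The test suite and the acceptance script run at deliberately modest
scale: 200 random decoder instances of length <= 12 against exhaustive
enumeration, 5,000-site chains for parameter recovery, a ~3,200-CpG /
~130-region synthetic methylome end-to-end, and a ~60,000-CpG run for
stationary-frequency checks.  Everything is deterministic given the
configuration: the only stochastic component outside the simulator is
the dip null calibration, which carries its own fixed seed
(`BimodalityConfig.seed`).

## Known limitations

* Middle-methylated calls depend on the bimodality gate; near the
  gate's significance boundary, small input changes can flip a whole
  class between {two labels} and {one label}.  The diagnostics expose
  the verdicts so such flips are visible.
* The two-layer procedure assumes at most three separable strata; a
  genuinely four-modal beta distribution would be folded into three.
* Layer 2 re-chains a class's sites across the gaps left by the other
  class, slightly overstating adjacency; the alternative (masking with
  the full chain) is noted but not implemented.
* Region classification inherits the sparsity of region counts: with
  few regions the HMM is replaced by fixed thresholds, which ignores
  the sample's global methylation level.
* Threshold constants (0.6 cutoff, gaps, min CpGs) are the published
  empirical values for HM450K/EPIC; other platforms need explicit
  settings.
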