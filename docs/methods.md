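# Methods

## Problem setting

Polysome profiling separates a cell's mRNA by ribosome load on a sucrose
gradient: well-translated messages sediment with polysomes, poorly
translated ones with the subpolysomal pool. Knocking down an initiation
factor — here the DEAD-box helicase eIF4A1 in MCF7 cells, but the
machinery is factor-agnostic — and sequencing both pools in both
conditions asks, per transcript: did the knockdown-vs-control log-fold
change differ between the polysomal and subpolysomal fractions? A
negative interaction (polysome loss on knockdown) marks a
helicase-dependent transcript; a positive one a helicase-independent
transcript. The package then asks what distinguishes the 5'UTRs of the
two sets: G/C content, length, predicted folding energy, upstream AUGs,
G-quadruplex potential and a small panel of structure-prone motifs.

## Observation model and model comparison

Upstream probabilistic quantifiers (e.g. MMSEQ) summarize each
transcript's log expression in sample *i* as a posterior mean *y_i* and
SD *s_i*. We treat these as noisy observations with known measurement
variance:

    y_i ~ Normal(x_i' beta, s_i^2 + sigma^2)

with a shared residual SD `sigma` absorbing biological replicate noise.
Two nested designs are compared per transcript:

* DE (one fraction, 8 samples): intercept-only vs intercept + condition;
* DoD (subpolysomal + polysomal, 16 samples): intercept + condition +
  fraction vs the same plus an interaction column that is 1 exactly for
  (knockdown, polysomal) rows. The interaction coefficient delta equals
  `(poly_KD − poly_ctrl) − (subpoly_KD − subpoly_ctrl)`.

Priors: coefficients are zero-centred Gaussians — intercept SD
`tau_intercept = 10` (effectively vague on the natural-log scale),
other coefficients SD `tau_coef = 1` (shrinks log-fold changes toward
0 with SD one log unit, a weakly-informative scale for siRNA
experiments); `sigma` is half-Normal with scale 1. All are
configurable; the defaults are a pragmatic reconstruction, since only
the observation contract — posterior mean and SD as outcome — and the
model-space prior are pinned down externally, not the exact coefficient
hyperpriors. Consequences are threshold-level, not numerically identical
to any particular upstream tool.

The evidence for each design integrates the coefficients analytically
given `sigma` (a Gaussian integral, evaluated via the Woodbury identity
on k-by-k systems) and `sigma` itself by deterministic fixed-node
quadrature: 64 log-spaced nodes on [1e-3, 10] with trapezoidal weights,
plus the `[0, sigma_lo]` sliver folded into the first node's weight
(below `sigma_lo` the integrand is constant to O(sigma_lo^2/s_min^2),
so the sliver is a rectangle). Without the sliver the truncation bias
can reach ~1e-3 nats when measurement SDs dominate; with it, quadrature
agrees with dense 2-D grid integration to ~2e-4 nats on random
one-column instances (checked in the acceptance suite at 1e-3).

The Bayes factor `BF = ML1/ML0` becomes the posterior probability of
the complex model with prior weight `p = 0.1`:

    P1 = p BF / (p BF + 1 − p)

computed on the logit scale for stability. Classification uses the
liberal threshold `P1 >= 0.2` plus the sign of `delta_hat`, the
posterior mean of the interaction coefficient under the complex model
(the ridge/precision-weighted estimate, averaged over the sigma grid
with marginal-likelihood weights). `delta_hat` exactly 0 at or above
threshold stays unclassified (tie rule; measure-zero in practice). The
GSEA-style ranking metric is `P1 x sign(−delta_hat)`, oriented so
helicase-dependent transcripts score toward +1; isoforms collapse to
one per gene by maximal `P1`, ties to the lexicographically smallest
transcript id.

## Synthetic data

`simulate_expression` emulates the quantities the pipeline consumes,
not the sequencing process: per transcript it draws a baseline
log-expression (uniform on [2, 10]), condition and fraction main
effects (Normal, SDs 0.25 and 0.5), and with probability
`frac_interaction = 0.2` a true interaction `delta = ±2` natural-log
units (random sign, fixed magnitude); observations add replicate noise
(`sigma_bio = 0.1`) and reported measurement noise with SD drawn
uniformly from [0.05, 0.2] — roughly the posterior SDs a quantifier
yields at moderate depth. Defaults describe a quadruplicate experiment
with a strong-shift minority; magnitudes of real translational shifts
are not calibrated to any particular dataset and are configurable.
Per-transcript RNG substreams are derived from (seed, transcript index)
so output is reproducible and order-independent.

What the generator does **not** emulate: count-based mean–variance
coupling, correlated measurement error across samples, isoform sharing
of reads, compositional normalization artifacts, or heavy-tailed effect
distributions. Passing recovery tests therefore demonstrates the
estimator's correctness under its own observation model, not robustness
to quantifier misspecification.

`simulate_utrs` draws iid bases at a target G/C fraction with
log-normal lengths (median 150 nt, log-SD 0.6, clipped to [20, 3000] —
the shape of human 5'UTR length distributions) and can overwrite a
literal motif at a random position with a given probability, recording
the plant as ground truth. Spontaneous motif occurrences are possible
by construction; planted truth is therefore a lower bound on scanner
positives, and tests that require exact agreement use compositions
where the spontaneous rate is negligible.

## UTR features

All matching is on uppercase DNA (U→T). G/C content excludes N from
numerator and denominator; uAUG counting is frame-agnostic and counts
overlaps. The motif grammar accepts IUPAC codes plus bounded
quantifiers; shipped patterns are the GGC-repeat `GC(GGC){3}G`, the G/A
consensus `GGAGG`, and a configurable U-run defaulting to `U{6,}` (the
exact published U-rich consensus is not recoverable, so the default is
a documented choice). G-quadruplex potential is
`GG N{1,7} GG N{1,7} GG N{1,7} GG` or the GGG-tract analogue; the
paired-GGAGG element is `GGAGG N{4,10} GGAGG`. Scanners are compiled
regexes with bounded quantifiers; presence is what feeds enrichment
(not match counts). Correctness is pinned by enumeration oracles that
chain tract start positions explicitly — presence never depends on any
particular backtracking order.

Folding is pluggable. `ViennaFolder` computes real thermodynamic MFEs
through the ViennaRNA package (Python bindings, falling back to the
`RNAfold` executable). `MaxPairingFolder` is a clearly non-thermodynamic
fallback: a Nussinov-style dynamic program maximizing canonical pairs
(AT/GC/GT wobble, minimum hairpin loop 3), scored at a fixed
pseudo-energy per pair (default −1 kcal/mol per pair). It exists so the
full pipeline runs and is testable with zero external state; its values
order sequences by pairing capacity only. The exhaustive oracle for it
enumerates every non-crossing structure on short sequences.

## Enrichment statistics

Continuous features use the two-sided two-sample Kolmogorov–Smirnov
test (exact null for groups of ≤25, asymptotic above); presence flags
use two-sided Fisher's exact tests under the standard rule (sum of
hypergeometric probabilities no larger than the observed table's). Both
are delegated to scipy; the test suite checks them against exact
permutation / rational-arithmetic enumeration, exhaustively for all 2×2
tables with total count ≤40. No multiplicity correction is applied to
the handful of motif tests by default (nominal p-values are reported);
Benjamini–Hochberg is available as an opt-in utility.

`reconstruct_table` inverts published group percentages into counts
(nearest integer, halves away from zero). Published percentages are
integer-rounded, so reconstruction is ambiguous by ±1 count; for one of
the shipped comparisons (GGC-repeat, 62% of 156 vs 35% of 49) the two
admissible reconstructions give two-sided p of 9.3e-4 (a=97) and
1.6e-3 (a=96). The package reports the point reconstruction and the
acceptance suite checks published values against the interval spanned
by admissible reconstructions. A further published comparison
(G-quadruplex presence, 80% vs 36%) is not reproducible by any standard
test on counts reconstructed at these group sizes — every reconstruction
yields p orders of magnitude smaller than the published 1.4e-3 — so it
is computed by the pipeline on data but not checked against the
published p.

## Numerical and design choices

* Quadrature is fixed-node and deterministic; results are invariant to
  transcript iteration order and reproducible from one seed.
* Bayes factors are held in log space; `P1` via the logistic of
  `log BF + logit(p)`.
* Degenerate Fisher margins (empty row or column) return p = 1.
* Balanced designs are enforced for the built-in design builders;
  unbalanced layouts are rejected rather than silently reweighted.
* Gene collapse and longest-UTR selection both break ties by
  lexicographically smallest transcript id, making outputs unique.
* The pipeline writes a manifest echoing config, seed, versions and
  class counts; partial outputs are removed if a run fails in a
  directory the run itself created.

## Problem sizes used by the shipped checks

The recovery check runs 1,000 transcripts (16 samples each); the
evidence-accuracy check 200 random one-column instances against a
20,001 × 2,401 stretched grid; the scanner check 10,000 random 100-nt
sequences; the Fisher sweep all 135,750 tables with N ≤ 40. These sizes
make each check individually decisive (binomial noise on the recovery
rate ~1%, grid truth ~1e-6 nats) while keeping the whole suite in the
minutes range on one CPU.

## Known limitations

* The coefficient hyperpriors of the original upstream tool are not
  public in detail; agreement with it is qualitative (same thresholds,
  same sign conventions), not bitwise.
* The evidence quadrature assumes measurement SDs are not all ~0
  together with `sigma_lo` large; with all-zero `s` and data variance
  below `sigma_lo` the sliver approximation degrades (not a regime
  posterior summaries produce).
* `MaxPairingFolder` is not a free-energy model; do not interpret its
  output thermodynamically.
* KS p-values with heavily tied data fall back to asymptotics and are
  approximate, as in any KS implementation.
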