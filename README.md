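# translatome

Polysome-profiling translatome analysis: per-transcript Bayesian model
selection on expression posterior summaries, 5'UTR sequence
characterization, and between-group enrichment statistics.

## What problem this solves

Polysome profiling fractionates a cell's mRNA by ribosome load. After
knocking down a translation initiation factor — the motivating case is
the DEAD-box RNA helicase eIF4A1 in breast cancer cells — and sequencing
the polysomal and subpolysomal pools under both conditions, the question
per transcript is a *difference of differences*: did the
knockdown-vs-control log-fold change differ between fractions? mRNAs
that leave polysomes on knockdown depend on the helicase for their
translation; a smaller group moves the other way. The two sets can then
be compared on their 5'UTR sequences — G/C content, length, predicted
folding energy, upstream AUGs, G-quadruplex-forming potential and a
panel of structure-prone motifs — to ask what makes a message
helicase-dependent.

The package is for computational biologists who have transcript-level
posterior summaries from a probabilistic quantifier (MMSEQ-style
`mean, SD` of log expression per sample) plus a factorial sample design,
and want a tested, reproducible route from those summaries to classified
transcripts and UTR enrichment reports. A seeded synthetic-data
generator with known ground truth stands in for raw sequencing data, so
the whole pipeline is testable offline.

## The model

For each transcript, sample *i* contributes a posterior mean *y\_i* and
SD *s\_i* of log expression, treated as a noisy observation with known
measurement variance:

```
y_i ~ Normal(x_i' β, s_i² + σ²),   β_j ~ Normal(0, τ_j²),   σ ~ Half-Normal(1)
```

Two nested designs are compared: an additive model (intercept +
condition + fraction) against the same model plus an interaction column
that is 1 exactly for (knockdown, polysomal) samples, whose coefficient
δ = (poly\_KD − poly\_ctrl) − (subpoly\_KD − subpoly\_ctrl). The β
integral of the marginal likelihood is done in closed form given σ; the
σ integral by deterministic fixed-node quadrature. The Bayes factor
BF = ML₁/ML₀ becomes the posterior probability of the interaction model
under prior weight p = 0.1:

```
P1 = p·BF / (p·BF + 1 − p)
```

Transcripts with P1 ≥ 0.2 (a deliberately liberal threshold) are
classified **dependent** if δ̂ < 0 (polysome loss on knockdown) and
**independent** if δ̂ > 0; everything else is **unclassified**. A signed
score P1 × sign(−δ̂) ranks genes for pre-ranked enrichment tools
(`.rnk` output), collapsing isoforms to the one with the highest P1 per
gene. See `docs/methods.md` for priors, quadrature details and the
synthetic-data model.

## Worked example

Simulate a quadruplicate knockdown experiment (200 transcripts, 20%
carrying a true shift of ±2 natural-log units) and run model selection:

```
$ translatome simulate --n-transcripts 200 --seed 7 --out-dir demo
wrote 200 transcripts to demo

$ translatome select --expression demo/expression.tsv --design demo/design.tsv \
      --out demo/results.tsv --rnk demo/dependence.rnk
{"n": 200, "classes": {"unclassified": 155, "dependent": 26, "independent": 19}}
```

155 transcripts show no credible interaction (their P1 stays near the
0.1 prior), while 26 + 19 = 45 clear the 0.2 threshold — the 41 planted
transcripts (all recovered, with the correct sign of shift) plus a few
borderline null transcripts admitted by the liberal threshold. Per
transcript the output records both model evidences, the Bayes factor,
P1, δ̂ and the class:

```
transcript_id  logml0   logml1   log_bf  bayes_factor  posterior_prob  delta_hat  class
TX000          -6.578   -8.225   -1.647  0.193         0.0210          0.063      unclassified
TX001          -20.973  -7.665   13.307  601472.6      0.99999         1.973      independent
```

TX001's expression rises specifically in the knockdown polysomal cell
(δ̂ ≈ +2): translationally upregulated when the helicase is removed,
hence helicase-independent.

The full pipeline — simulation or real inputs, model selection, UTR
features, enrichment — runs from a YAML config:

```
$ translatome run --config config.yaml --seed 17
```

writing per-transcript and per-gene tables, the `.rnk` ranking, a UTR
feature table, an enrichment report (KS tests on G/C content, length
and folding energy; Fisher's exact tests on motif presence) and a
manifest with seed, versions and class counts.

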