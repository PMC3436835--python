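# Methods

## Model

`mapqcal` treats mapping-quality estimation as probabilistic binary
classification. A mapping of read *r* is *accurate* when the aligner's
reported (reference, strand, leftmost position) equals the read's true
origin, within a position tolerance that defaults to 0 (exact). The model
is a logistic regression on eleven features per mapped SAM line, in this
fixed order: `intercept`, `slope`, `r_value` (OLS fit of base quality on
0-based base index — the intercept is literally the fitted quality of the
first base), `n_count` (uncalled bases), `n_matches`, `n_mismatches`,
`n_insertions`, `n_deletions`, `raw_mapq`, `mapq_missing`, `n_mappings`.
The fitted probability *p* of correctness is reported on the Phred scale,
`Q = -10·log10(1-p)`, capped (default 60) and rounded half-away-from-zero
into `[0, 254]` for SAM output; the sentinel 255 is never emitted.

Assumptions worth stating plainly: single-end reads; correctness is a
property of the primary coordinate triple only (no partial credit for
near-misses unless a tolerance is set); every mapped line, secondary
alignments included, is scored, and the mapping-multiplicity feature
counts all mapped lines for the read. Whether secondaries should be
scored at all is a genuinely open choice; scoring them supplies the
training set with informative negative examples and lets downstream
filters treat all candidate locations uniformly.

## Numerical choices

* **Fitting.** The L2-penalized binomial log-likelihood is maximized by
  damped Newton iteration (step-halving enforces a monotone penalized
  deviance; stop when the gradient infinity-norm ≤ `tol`, default 1e-8).
  Features are standardized to zero mean / unit spread internally —
  constant columns get unit spread — and the scaling is stored in the
  model, so coefficient magnitudes are comparable across features. The
  intercept is unpenalized. The default penalty 1e-6 only stabilizes the
  fit under quasi-separation; the plain maximum-likelihood solution is
  recovered as the penalty → 0.
* **Degenerate inputs.** Constant base qualities make the Pearson
  correlation undefined; the convention is slope 0, r 0, intercept = the
  constant. Mismatch counts prefer the MD tag (exact), fall back to
  NM − indel bases floored at 0, and report 0 with a logged warning when
  neither tag is present. MAPQ 255 becomes `raw_mapq = 0` with
  `mapq_missing = 1` rather than the literal 255, keeping the model
  linear in observed MAPQ. Probabilities are clamped to
  `[1e-10, 1 - 1e-10]` before log-scaling.
* **Soft clips** are excluded from match/mismatch counts (they are not
  aligned), while the quality-line fit uses the full read: read-level
  features are alignment-independent by design.
* **Thresholds.** Score comparisons are inclusive (≥) everywhere — the
  precision/recall sweep and the pileup MAPQ filter — so the maximum
  score is attainable. Precision over an empty positive set is defined
  as 1 (logged). p = 0.5 is the documented keep/discard default.
* **F statistic.** `f_paper(p, r) = 1/(1/p + 1/r)` reproduces the
  tabled SNP-calling summary exactly as printed; note it is half the
  conventional harmonic mean (it equals 0.5 at p = r = 1). The
  conventional `f1_score = 2pr/(p+r)` is provided under a distinct name.
* **Calibration binning** defaults to ten equal-width bins on p (an
  equal-count option exists). Each bin reports mean p, the mean
  Phred-scaled prediction, the theoretical accuracy `1 − 10^(−Q̄/10)`
  and the empirical accuracy; empty bins are reported with n = 0.
* **Cross-validation** uses a seeded random partition into k folds with
  sizes differing by at most one (default k = 5, i.e. 80%/20%).

## What the simulator emulates — and what it does not

The read simulator emulates Illumina-like 50 bp single-end reads whose
mean base quality declines almost linearly with base position. Mean
quality at 0-based position *i* is `intercept_mean + slope_mean·i` plus a
per-read intercept jitter and per-base noise, rounded and clipped to
[0, 40]. Defaults: intercept 34, slope −0.25 Phred/base, jitter sd 2,
noise sd 2, N rate 0.002 — parameters, not constants; they were chosen
once as a realistic profile for this read length and are exposed on
`QualityModel`. Substitution errors are injected per base with the
Phred-implied probability `10^(−q/10)`, so emitted qualities are correct
by construction; N bases carry quality 0. Truth coordinates are 1-based
leftmost on the forward strand, matching SAM `POS`, so labelling needs no
conversion.

Not emulated: indels and structural variants (the built-in aligner is
ungapped; indel features are exercised through hand-written SAM fixtures),
paired-end reads, GC or position-dependent coverage bias, empirical
machine-specific quality profiles, PCR duplicates. Consequently, passing
tests demonstrate that the recalibration machinery is correct and
calibrated *under this generative model*; they do not certify calibration
on any particular real instrument or aligner, for which the intended use
is retraining on reads simulated to match that instrument.

The repeat-rich reference generator plants segmental duplications
(default at the 100 kb evaluation scale: 15 families × 500 bp × 3 copies,
1% per-copy divergence, ≈22% repeat content) on a uniform-random
backbone. Diverged repeats are what make mapping genuinely ambiguous and
give the aligner-side features their signal. The 10 kb demo uses 2
families to keep a comparable repeat fraction.

## Study scales

Evaluation runs use a 100 kb reference, 50,000 training reads (~25×) and
a held-out set of 20,000 reads; the SNP experiment implants 100 SNPs and
evaluates on 50,000 reads, with training reads simulated from the
un-mutated reference so the model never sees the variant alleles. These
sizes make the full pipeline run in about a minute per experiment on one
CPU while keeping every prediction bin populated enough for binomial
interval checks.

## Built-in aligner and SNP caller

The brute-force aligner reports *every* position on either strand with
Hamming distance ≤ `max_mismatches` (default 5; N never matches),
best-first, up to `max_hits` (default 10). Exhaustiveness follows from
pigeonhole seeding — one of m+1 contiguous segments of a read with ≤ m
mismatches must match exactly — with every candidate verified base by
base. Its heuristic MAPQ (unique hit → 30, tied best → 0, otherwise
`min(30, 10·(d₂−d₁))`) is deliberately crude: it plays the role of the
"aligner-reported quality" being recalibrated. The pileup caller stacks
primary-alignment bases with MAPQ ≥ a threshold and calls a SNP where
depth ≥ 3 and the leading non-reference allele reaches 50% of called
bases; it performs no genotype-likelihood modelling. In the demo
comparison the raw arm filters at MAPQ ≥ 20 and the recalibrated arm at
quality ≥ 3 (p ≥ 0.5), identical depth/fraction filters on both.

## Determinism

One master seed fans out to all stochastic stages through stage-name-
keyed substreams (`SeedSequence([seed, crc32(stage)])`), so pipeline
outputs are byte-identical across reruns with the same configuration.

## Known limitations

* The log-odds is linear in the mapping count, while the true
  correctness probability of a tied mapping behaves like 1/m; the model
  therefore slightly overpredicts p for the worst (high-multiplicity)
  mappings, visible as a small negative bias in the lowest prediction
  bin on some runs.
* With ungapped alignments the leftmost-coordinate label comparison is
  exact; gapped aligners can shift leftmost coordinates, which is why
  the labelling tolerance is exposed as a parameter.
* The toy aligner truncates at `max_hits` mappings, so the multiplicity
  feature saturates there; reads from very high-copy repeats all look
  alike to the model.
* At desk scale both SNP arms of the demo can reach precision 1.0: the
  toy aligner's tie-aware MAPQ already suppresses most false positives,
  so the recalibration benefit shows mainly as recall rescued inside
  repeats.
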