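# Methods

This note documents the models, parameters, numerical conventions and
design choices behind `crmimic`, and what its synthetic-data experiments
do and do not establish about real data.

## The screening model

The pipeline treats drug-repurposing for calorie restriction as a
profile-matching problem at the *gene signature* level rather than the
gene level. Working with a curated panel of signatures (tens of gene
lists covering metabolism, transcription-factor programs and stress
responses) instead of ~20 000 genes reduces overfitting and keeps results
biologically interpretable. Each treated sample is reduced to a ternary
vector — per signature: induced (+1), unchanged (0), repressed (−1)
relative to its control group — and all downstream similarity operates on
these vectors.

### Ranking metric

A sample's probes are ranked by the log2 difference between the sample and
the mean of its control group. This is the simplest statistic consistent
with log2-scale RMA input; it needs no within-group variance estimate, so
it works for control groups as small as two animals, the practical floor
in the public datasets this design targets. Ties are broken by probe id
(ascending) so ranking is deterministic across platforms. Probes missing
in the sample or in all controls are dropped and counted; a sample with
fewer than half its probes usable is rejected as degenerate.

### Enrichment statistic

The classic GSEA running sum over the ranked probe list: at a hit (probe
whose gene is in the signature) it rises by `|r|^p` normalized by the sum
over hits, at a miss it falls by `1/(N − N_h)`. `ES+` is the maximum
positive deviation, `ES−` the minimum negative deviation; both one-sided
extremes of the same walk, so `ES+ ≥ 0 ≥ ES−` by construction. The weight
exponent `p` defaults to 1 (score-weighted hits, the canonical choice) and
may be set to 0 (uniform increments); if every hit carries weight zero
under `p = 1` the signature falls back to uniform increments, flagged in
the output. A signature with no mapped probes cannot be scored (call 0,
flag `not_represented`); a signature hitting *every* probe leaves the miss
decrement undefined and is likewise flagged rather than scored.

Probes without gene annotation carry a reserved `unannotated` token: they
remain in the ranked list (the permutation null shuffles gene labels over
a *fixed* probe universe, so the universe must not shrink) but can never
be signature hits. Gene identifiers match by exact string comparison
after uppercasing and whitespace stripping; cross-species symbol mapping
is deliberately upstream of this package. A probe mapped to several genes
keeps its first mapping, logged.

### Permutation null

Significance comes from permuting the probe → gene assignment — *not*
phenotype permutation, which would be hopeless with two or three controls.
A uniform relabeling places the signature's labels on a uniformly random
size-`N_h` subset of rank positions, so the implementation samples random
hit-position subsets directly; this is an exact reformulation, verified in
the tests against brute-force enumeration over all `C(N, N_h)` subsets.
P-values use the add-one estimator `(1 + exceedances)/(1 + n_perm)`, the
standard Monte-Carlo correction that can never return 0. Exceedance
counting uses a 1e−12 absolute tolerance so that permutations reproducing
the observed configuration count as ties regardless of last-ulp float
effects. The default `n_perm` is 100 000; the validation experiments use
10 000, which resolves p = 0.05 to ±0.4% (3 binomial SEs).

Permutation streams are pre-assigned per (sample, signature) pair by
hashing the labels into a seed derived from the master seed, so results
are independent of execution order and bit-reproducible. Because the null
distribution of `(ES+, ES−)` depends only on the sample's score vector and
the hit count, `score_study(null_sharing="sample")` optionally reuses one
permutation batch across the signatures of a sample that share a hit
count. The shared null is drawn from exactly the same distribution — only
the Monte-Carlo errors of a sample's p-values become correlated — and cuts
the cost of a 20-signature screen roughly twentyfold; the large synthetic
screen experiments use it. The default remains one stream per pair.

### Ternary calls

`+1` when the positive tail is significant at `α = 0.05`, `−1` when the
negative tail is, `0` otherwise. When both tails are significant the
strictly smaller p-value decides and an exact tie yields 0 — a neutral
rule demanded by symmetry for a case the screening procedure leaves
unspecified.

### Similarity and the condition-level hit rule

Ternary vectors enter the Pearson correlation as plain integers −1/0/+1
(no rank transform). Pearson correlation is undefined for a constant
(all-black) vector; such pairings are scored 0 — no evidence of
similarity — and counted, rather than dropped, because dropping them
would bias the lower quantile upward and inflate hit rates.

Group-to-group similarity is the full list of `|bait| × |probe|` pairwise
correlations summarized by its 5%, 50% and 95% quantiles under the
nearest-rank (lower) convention: the smallest value whose cumulative
fraction reaches the level. On the small pairing lists typical here
(group sizes 2–8) nearest-rank is exact, involves no interpolation
invention, and is conservative for the hit rule. The convention is
recorded in every similarity table (`quantile_method` column) so the
numbers are auditable. A condition is a positive hit iff its 5% quantile
is *strictly* positive.

### Compound-level screen

With `N` screened conditions of which `K` are positive, a compound tested
in `n` conditions with `x` positive gets the exact upper hypergeometric
tail `P(X ≥ x)`, computed by integer-binomial summation (no
approximation; cross-checked in the tests against scipy and brute-force
enumeration). Hits are called on the raw p at `screen_alpha = 0.05`,
matching a screen that reports per-compound tails without multiplicity
correction; a Benjamini–Hochberg flag (statsmodels) is available but off
by default. Conditions whose compound is on a configurable vehicle list
are excluded from `N`, `K` and the hit table; conditions lacking a
similarity summary go to an exclusions report instead of vanishing.
Totals are pooled per bait dataset (one screen per bait), recorded in the
hit-table metadata.

## Synthetic data generator

The generator emulates RMA-style microarray studies: per gene a baseline
drawn once from Normal(7, 1.5) on the log2 scale, 1–3 probes per gene
inheriting the gene baseline, replicate noise Normal(0, 0.25), and
additive planted effects `δ · direction` (default `δ = 1.0` log2 units) on
every probe of every gene of a planted signature in a treated group. The
default panel is 20 disjoint signatures of 50 genes over 2 000 genes;
groups default to 3 control and 3 treated replicates. All treated groups
share one vehicle control arm, as in toxicology screens where many
compounds share vehicle controls. `simulate_bait_and_probe` builds an
independent bait study and a compound probe study over shared
gene/probe/signature structure; mimetic compounds receive the bait's
direction map, optional decoys receive non-bait effects for specificity
testing. Ground truth (per-group planted directions, per-compound mimetic
flags) is serialized beside the data, and the recovery experiments read
truth from that record, not from the configuration.

What the generator does **not** model: batch effects, probe-level
background or saturation, correlated noise between genes, dose–response
structure within a compound, or count-based RNA-seq noise. Passing the
recovery experiments therefore shows the pipeline's statistics are
correct and well calibrated under Gaussian log2 noise with exchangeable
replicates — not that real screens reach the same sensitivity.

## Validation experiments and problem sizes

The `validation` module packages four experiments (used by the test suite,
`scripts/acceptance.py` and `analysis/05_validation_experiments.py`):

* **Null calibration** — no planted effects; the nonzero-call fraction
  over 520 (sample, signature) tests should stay near `2α`. Tests within
  a sample share one ranked list, so the realized rate fluctuates more
  than an independent-test binomial would suggest.
* **Planted recovery** — a +1.0 log2 induction (noise sd 0.25, 3
  controls) should be called +1 in ≥ 95% of replicates; in practice it is
  recovered essentially always at these settings.
* **Cross-experiment concordance** — two independent studies planting the
  same direction map yield strongly positive median profile correlation;
  the sign, not the magnitude, is the property carried over from
  real-data validation, where inter-laboratory protocol differences push
  the median well below 1.
* **Screen recovery** — 20 compounds × 4 conditions, 3 planted mimetics:
  all three recovered with at most one false-positive compound in ≥ 90%
  of seeds.

These experiments run at a reduced gene count (200–260 genes, one probe
per gene, signatures of 8–10 genes) chosen as the package's own
desk-scale default: the statistics under test (running-sum extremes,
subset-permutation tails, correlation quantiles, hypergeometric
enrichment) are invariant to the gene count once signatures are well
represented, and the reduced size lets a 25-seed screen experiment finish
in minutes on one CPU.

## Numerical conventions and degenerate inputs

* All result tables are TSV with 17-significant-digit floats; write/read
  round trips are bit-identical (readers use exact float parsing).
* GEO series-matrix files are read assuming log2-scale values; an opt-in
  auto-detect applies `log2(x + 1)` when the matrix maximum exceeds 30,
  and logs it. Nothing is transformed silently.
* Readers reject inconsistent input with named errors (duplicate probes,
  samples missing from the group map, control groups smaller than two,
  malformed GMT lines with their line number, non-numeric cells with
  their coordinates) rather than repairing it.
* Signatures with fewer than five genes trigger a warning; empty
  signatures are errors.
* The pipeline validates every parameter before any computation; a
  mid-run stage failure leaves partial outputs plus a `RUN.partial`
  marker naming the stage.

## Known limitations

* The ranking metric ignores within-group variance; a noisy probe and a
  stable probe with the same mean shift rank identically.
* Condition-level positivity with small groups reduces the 5% quantile to
  the minimum pairing, making single aberrant samples influential.
* No normalized enrichment score or FDR across signatures: p-values are
  raw and per-signature by design.
* Compound hits inherit whatever multiplicity behaviour the raw
  hypergeometric screen has; the BH option changes the hit flags only.
* Cross-species orthology mapping, probe-set summarization and array
  normalization are out of scope and must be done upstream.
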