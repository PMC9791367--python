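# Methods

## Perturbation network

The analysis consumes a wide expression table with, per deletion strain and
per measured gene, a log2 fold-change versus wild type (M) and an
FDR-adjusted p-value. P-values are used exactly as stored — they are
adjusted upstream of this package — and no re-adjustment is performed.
Missing cells stay missing: they never produce an edge, are excluded from
Euclidean sums, and their counts are logged rather than silently dropped.

A gene g is called significantly differentially expressed in the deletion
of d when |M[d, g]| >= log2(fold_change_min) and p[d, g] <= p_max, with
non-strict inequalities at both cutoffs. Defaults are fold_change_min = 1.7
(on the linear scale — the M-scale cutoff is log2(1.7) ≈ 0.766) and
p_max = 0.05. A config switch (`Thresholds(scale="log2")`) interprets the
fold-change cutoff directly on the M scale instead; the linear reading is
the default because M is defined as a log2 fold-change and the source
compendium's own convention is a linear 1.7-fold cutoff.

Focal genes are deletions passing three filters, applied sequentially and
counted separately: (1) the deletion significantly *decreases* its own
expression (significance plus M[d, d] < 0 — evidence the gene was correctly
deleted and expressed in wild type); (2) the deleted gene is measured on
the array; (3) at least one *other* deletion perturbs it (otherwise no
cis/trans contrast exists). Filter order matters only for the logged
counts, not for the resulting set.

## Pleiotropy measures

- cis count: DE genes in the focal deletion, excluding the focal gene.
- trans pair count: DE genes in the trans deletion, excluding the trans
  gene and the focal gene.
- parallel count: the trans pair count after removing *nested* effects —
  genes also DE in the focal gene's own deletion, which may act through
  the focal gene rather than alongside it. By construction
  parallel + nested = trans count, and this identity is tested against
  brute-force set enumeration.
- Euclidean distance: sqrt of the summed squared M values across measured
  genes — no cutoffs, wild type at the origin. A config switch uses linear
  fold-changes 2^M with wild type at the all-ones point instead; the log
  scale is the default since only there is "wild type at the origin"
  literally true. The cis distance excludes the deleted gene's own extreme
  self-coordinate by default (configurable) so it reflects downstream
  effects; the pair-context trans distance excludes the trans and focal
  coordinates, mirroring the count definition.

Per focal gene the contrast is median trans value minus cis value. The
median is the standard midpoint for even regulator counts. "Cis greater"
proportions use strict inequality — ties count as not greater, the
conservative choice given that small cis-greater fractions are the finding
of interest. The per-focal differences are tested with a one-sample
one-sided t-test (mean > 0); a Welch unequal-variance two-sample test is
exposed for comparing the cis and median-trans samples directly. Both are
thin wrappers over scipy.stats; identical degenerate samples return p = 1
as a well-defined no-difference case, while zero-variance differences
raise with advice to use a sign/permutation fallback.

## Permutation nulls

Both schemes conserve the number of nodes and edges. The degree-preserving
scheme independently shuffles each adjacency row (every edge is re-targeted
uniformly; out-degrees unchanged, self cells included in the shuffle). The
full-random scheme shuffles rows and then columns, which destroys the
out-degree distribution — after it, row sums are approximately binomial
and carry no heavy tail. On each permuted matrix the trans-regulator sets
are re-derived, focal genes with zero trans-regulators in that replicate
are dropped (a flag can restrict the pool to the originally focal genes
instead; the default re-derives eligibility from the measured +
self-decrease candidates, since permutation legitimately changes who the
regulators are), and the median over focal genes of (median trans count −
cis count) is recorded. Counts on permuted networks exclude self and focal
cells exactly as on the real network.

Replicates draw from independent PCG64 substreams spawned from a single
seed, so results are bit-reproducible and order-independent.

A note on a subtle offset: on a network with *exactly constant*
out-degrees the degree-preserving null concentrates at −1 rather than 0,
because every trans count excludes the self and focal cells while the cis
count excludes only the self cell, and constant degrees leave no room for
the size-biasing that otherwise compensates. The full-random null recovers
~0 through the binomial size-bias of the rows selected as regulators. Both
schemes agree that no paradox-scale contrast exists there, which is the
property the tests assert.

## Topology and fitness

The out-degree histogram includes the self edge by default (the fit is
over raw row sums; a flag excludes it) and K = 0 nodes are excluded from
the log-log fit, with their count logged. p(K) is the empirical frequency
among K > 0 deletions; gamma is the negated least-squares slope of
log10 p(K) on log10 K (slope and r² are base-invariant). This estimator is
exact on noiseless power-law input but biased downward on sparse samples,
where many distinct tail degrees carry a single count and flatten the
slope — visible on the 600-deletion synthetic network, where the planted
γ = 0.75 fits at ≈ 0.55. Parameter-recovery tests therefore use either
noiseless input or large (10⁵) multinomial samples, where the estimator is
accurate to ±0.1. Maximum-likelihood power-law fitting is deliberately not
offered: the least-squares log-log fit is the procedure under study.

Fitness enters as competitive fitness w relative to a reference strain
(= 1), used directly with no significance cutoff; beneficial deletions
(w > 1) yield negative costs and are retained. The regression is ordinary
least squares of w on log10(cis DE-gene count) over all deletions present
in both data sets, excluding zero counts (log undefined; counts logged).
Fitness-cost comparisons use cost = 1 − w per (focal, trans) pair and per
focal gene (median trans cost), with strict inequality and the same tie
convention as the pleiotropy proportions. A constant-fitness response is
reported as r² = 0 (no association) rather than NaN.

## Synthetic data

The generator plants the structures the analysis assumes, at a desk-scale
rendition of a real deletion compendium:

- 2,000 genes × 600 deletion strains (defaults; the real compendium is
  ~6,100 × ~1,480), deletions being the first 600 genes so all are
  measured on the array;
- non-self out-degrees drawn from a truncated discrete power law
  p(K) ∝ K^−γ on {1..k_max}, defaults γ = 0.75 (the exponent observed on
  the real network) and k_max = 300 (scaling the real maximum cis count,
  ~1,000 of ~6,100 genes, to 2,000 genes);
- targets chosen uniformly at random — no assortativity, the simplest
  model under which the degree distribution alone can generate the
  paradox;
- planted edges receive |M| ≥ 1.05·log2(1.7) plus a half-normal bulk
  centred so mean |M| ≈ 2 (sd 0.5), signs negative with probability 0.5,
  and p uniform below 0.05; non-edges receive sub-threshold M (clipped at
  0.95 of the cutoff) and p uniform above 0.05; every self cell gets
  M = −6 (a strong knockout signal) with p = 1e−12;
- a false_negative_rate fraction of non-self edges is pushed sub-threshold
  and a false_positive_rate fraction of non-edges promoted; with both
  rates zero, thresholding reproduces the planted adjacency cell for cell
  (a designed identity, and the recovery test);
- fitness w = 1 + slope·log10(K+1) + N(0, sd), slope −0.1 by default;
  `fitness_noise_for_target_r2` solves for the sd that makes the
  fitness-vs-log10(count) regression attain a chosen expected r² on a
  given degree sample, accounting for the +1 shift between the generative
  signal and the regression predictor.

P-values are assigned directly rather than simulated from replicate noise:
the analysis consumes only the (M, p) pair and the threshold rule, so
simulating the upstream test machinery would add no coverage. What the
generator does *not* emulate: media conditions beyond a label,
aneuploidy artifacts, the growth-rate expression signature, correlated
expression noise across genes, or assortative wiring (an in/out-degree
correlation knob could be added; the default is none). Passing tests on
synthetic data therefore demonstrate correctness of the machinery and the
degree-distribution mechanism, not biological conclusions about any real
compendium.

All generators are bit-reproducible from `spec.seed`; each component
(network, expression, fitness) uses its own named substream so pieces can
be regenerated independently.

## Numerical and I/O choices

- Expression files are written with 17 significant digits and parsed with
  a correctly-rounded string-to-float conversion, so write/read round
  trips are bit-exact; NaN is serialized as an explicit marker.
- The reader is dialect-driven (column labels, strain-header pattern,
  media encoding declared in a small YAML-able config); it assumes one M
  and one p column per strain, never reorders strains or genes relative to
  file order, and reports malformed headers, non-numeric cells (with
  row/column coordinates) and out-of-range p-values as distinct errors.
- Pipeline outputs carry no timestamps and use fixed float formats and
  sorted JSON keys, so a re-run with the same seed is byte-identical.
- Problem sizes in tests and in the acceptance script (600–1,300
  deletions, 20–100 permutation replicates, 10⁵ degree draws) are chosen
  as the smallest scales at which the studied effects are unambiguous.

## Known limitations

- Edges are perturbation effects, not direct regulation; no attempt is
  made to distinguish direct from indirect influence.
- One strain per deleted gene is assumed; replicate strains for the same
  gene must be resolved upstream or they are rejected.
- The least-squares degree-law fit shares the small-sample bias of the
  original procedure (see above).
- The growth-signature-corrected re-analysis is supported by pointing the
  pipeline at an already-transformed expression file; the transform itself
  is out of scope.
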