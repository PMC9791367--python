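# pleionet

Cis- vs trans-regulatory pleiotropy in gene-deletion perturbation networks.

## The problem

When a mutation changes a gene's expression it can act in *cis* (an
allele-specific change at the gene itself) or in *trans* (through a
diffusible factor encoded elsewhere). A long-standing hypothesis holds that
cis-regulatory mutations accumulate preferentially over evolutionary time
because they are less pleiotropic — they disturb fewer other traits — and
therefore less costly. `pleionet` tests this at genome scale using
deletion-strain expression compendia of the kind produced for
*Saccharomyces cerevisiae*: deleting a gene is the most extreme
cis-regulatory mutation for that gene, and any other deletion that
significantly changes the gene's expression is a trans-regulatory mutation
for it.

The package is aimed at systems-biology and molecular-evolution
researchers who want to build the perturbation network from such a
compendium, quantify cis/trans pleiotropy, and test whether the contrast is
a wiring-specific feature or an emergent property of the network's degree
distribution (the "friendship paradox" of heavy-tailed networks).

## The model

From per-strain, per-gene log2 fold-changes *M* and FDR-adjusted p-values,
a binary directed adjacency is built:

    A[d, g] = 1  iff  |M[d, g]| >= log2(1.7)  and  p[d, g] <= 0.05

with an edge from each deleted gene *d* to every gene *g* it significantly
perturbs. A *focal gene* is a deletion that (i) is measured on the array,
(ii) significantly decreases its own expression, and (iii) is perturbed by
at least one other deletion. For each focal gene *f*:

- **cis pleiotropy** — |{g ≠ f : A[f, g] = 1}|, or the Euclidean distance
  √Σ M[f, g]² of the deletion profile from wild type (no cutoffs);
- **trans pleiotropy** of a regulator *t* (A[t, f] = 1) — the same count
  excluding *t* and *f*; the *parallel* variant further removes effects
  nested in the focal gene's own deletion (A[f, g] = 1);
- the **contrast** is median-over-regulators trans pleiotropy minus cis
  pleiotropy, tested with a one-sided one-sample t-test across focal genes.

Two permutation nulls probe the mechanism: shuffling each adjacency row
preserves every out-degree (scale-free topology intact); shuffling rows
then columns destroys the degree distribution while conserving the edge
count. The out-degree law is checked by least squares on log p(K) vs
log K, p(K) ~ K^-γ; fitness analyses regress competitive fitness *w* on
log10 pleiotropy and compare fitness costs 1 − *w* of cis vs trans
deletions per focal gene.

A synthetic-data module generates deleteome-dialect expression files with
a planted scale-free network, configurable false-positive/negative rates
and fitness anti-correlated with out-degree, so the entire analysis runs
and is testable with no external downloads.

## Worked example

Running the numbered drivers on the default synthetic dataset (seed 0):

```
$ python analysis/01_simulate_dataset.py
wrote results/synthetic/expression.tsv: 600 strains x 2000 genes, 46587 planted edges (gamma=0.75, k_max=300)

$ python analysis/02_build_network.py
46587 edges over 600 deletions x 2000 genes
focal filters removed 0 (no self-decrease), 0 (not on array), 0 (no trans-regulator); 600 focal genes remain

$ python analysis/03_cis_trans_contrast.py
[count] median per-focal difference (median trans - cis) = 120; one-sided t = 25.5 (df 599, p = 3.48e-98); cis greater for 103/600 focal genes (17.2%) and 2944/13756 pairs (21.4%)

$ python analysis/04_permutation_nulls.py --n-perm 100
[preserve_outdegree] 100 replicates: median differences in [112, 122], mean 117, 100% positive
[full_random] 100 replicates: median differences in [-0.75, 0.5], mean 0.0025, 6% positive
```

Read: on a planted scale-free network the typical trans-regulatory
deletion is far more pleiotropic than the cis deletion of the same focal
gene (median contrast +120 DE genes; only ~17% of focal genes go the other
way). The contrast survives every degree-preserving permutation but
vanishes under full randomization — it is a consequence of the heavy-tailed
out-degree distribution, not of the specific wiring.
`analysis/05_topology_and_fitness.py` then fits the degree law and shows
the trans deletions' greater fitness cost (cis cost greater in only ~36%
of pairs on the default synthetic data).

The same pipeline runs on real compendium files via the CLI, e.g.

```
pleionet run-all --expression deleteome.tsv --fitness fitness.tsv --outdir results/
```

with `--transformed-expression` accepting a growth-signature-corrected
expression file for the Euclidean re-analysis, and `--dialect` a YAML
column-mapping config if the file layout differs from the shipped default.

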