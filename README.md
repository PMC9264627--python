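# phyloconcord

Concordance of gene phylogenies with core-genome species phylogenies.

The 16S rRNA gene — the workhorse of bacterial phylogenetics and microbiome
profiling — is multi-copy, subject to recombination and horizontal transfer,
and dominated by invariant sites. How trustworthy is a phylogeny built from
it, or from any single gene, compared with a phylogeny built from the
concatenated single-copy core genome? `phyloconcord` provides the machinery
to answer that question quantitatively: a clade-based concordance metric,
majority-rule extended consensus trees, concordance-vs-SNP-count saturation
curves with cross-validated model selection, Shannon-entropy column masking,
16S hypervariable-region extraction, and a monophyly-based screen for
horizontal transfer of multi-copy loci — plus a seeded sequence-evolution
simulator that generates datasets with planted ground truth for validating
every stage.

## The metric

For a rooted reference tree *T_ref* (the species phylogeny, built from the
concatenation of single-copy core genes that passed recombination/HGT
screens) and a comparison tree *T* on the same *n* taxa,

```
concordance(T_ref, T) = | C(T_ref) ∩ C(T) | / | C(T_ref) |
```

where *C(·)* is the set of non-trivial clades (leaf sets subtended by
internal nodes, excluding single leaves and the full taxon set). For fully
binary trees |C(T_ref)| = n − 2 and the metric equals 1 − RF/(n − 2), a
reference-normalised Robinson–Foulds quantity. The reference always
denominates, so the metric stays well defined (and asymmetric) when the
reference contains polytomies.

The dependence of concordance on the number of segregating sites (SNPs) is
characterised by nested random subsampling of SNP columns and a least-squares
fit of either a logarithmic model *y = a + b·ln x* or ordinary logistic
regression *y = 1/(1 + e^−(a+bx))*, chosen by 5-fold cross-validation; the
fitted model is inverted for the SNP count required to reach a target
concordance (e.g. 80%).

## Worked example

Clade concordance between two eight-taxon trees differing by one nearest-
neighbor interchange:

```python
from phyloconcord import parse_newick, concordance

ref  = parse_newick("((((A,B),C),(D,E)),(F,(G,H)));")
gene = parse_newick("((((A,C),B),(D,E)),(F,(G,H)));")
r = concordance(ref, gene)
print(f"reference clades: {r.reference_clades}")   # 6
print(f"shared clades:    {r.shared}")             # 5
print(f"concordance:      {r.concordance:.3f} ({r.as_percent():.1f}%)")
```

```
reference clades: 6
shared clades:    5
concordance:      0.833 (83.3%)
```

The swap destroyed one of the reference's six clades ({A,B}), so 5/6 = 83.3%.

End-to-end on a 17-species synthetic dataset with one planted recombinant
gene and one planted operon copy transfer:

```python
from phyloconcord import run_pipeline, demo_config
result = run_pipeline(demo_config(17, seed=7), "out/")
```

The gene report ranks each gene by concordance with the species phylogeny
(dense ranks, ties shared; the planted recombinant `nr05` is excluded from
the concatenation and carries no rank):

```
 gene_id category  snp_count  concordance  rank  excluded
    cr03       CR        247     1.000000   1.0     False
    nr01       NR        821     1.000000   1.0     False
    ...
rrna_16S     rRNA        225     0.866667   3.0     False
    cr01       CR        191     0.800000   4.0     False
    nr05       NR        678     0.800000   NaN      True
```

The 16S-like locus sits below the coding genes, its hypervariable regions
lower still (V1 0.73, V3 0.67 here), and masking the 10% most entropic
columns cuts its SNP count from 225 to 70 and its concordance from 0.87 to
0.73 — trading away signal rather than recovering it. The fitted saturation
model for the core SNP pool on this run:

```json
{"family": "logarithmic", "a": 0.201, "b": 0.138, "x_at_80": 76.7}
```

i.e. on this small, clean 17-taxon dataset ~77 SNPs suffice for 80%
concordance; real datasets need far more because their SNP pools carry
conflicting histories.

The same stages are exposed on the command line:

```bash
phyloconcord all --n-species 17 --seed 7 --outdir out/
phyloconcord simulate --n-species 12 --seed 1 --out data/
phyloconcord hgt out/operon_tree.nwk --species-map out/inputs/operon.species_map.tsv --out hgt.json
```

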