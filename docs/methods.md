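# Methods

## Concordance metric

Trees are compared as rooted clade sets. A clade is the leaf set subtended by
an internal node; trivial clades (single leaves, the full taxon set) are
excluded. Concordance is the fraction of the reference tree's clades present
in the comparison tree. Design points:

- **Rooted comparison.** Gene trees estimated unrooted are midpoint-rooted
  before comparison (outgroup rooting available). For fully binary trees on
  n taxa the denominator is n − 2, which reproduces the familiar arithmetic
  of a one-rearrangement difference on 17 taxa being 14/15 = 93.3%.
- **Reference denominates.** The metric is deliberately asymmetric; a
  polytomous reference simply contributes fewer clades. A star reference has
  no clades and is rejected rather than reported as 0/0.
- **Errors are loud.** Leaf-set mismatches report the symmetric difference;
  trees with fewer than four leaves are rejected (no non-trivial comparison
  exists).

## Consensus trees

Majority-rule extended consensus over rooted clade sets: clades in more than
half of the input trees enter first (these are mutually compatible by
counting), then remaining clades are added greedily in order of decreasing
frequency whenever compatible (disjoint or nested) with everything accepted.
Frequency ties break deterministically: smaller clade first, then
lexicographic order of the sorted leaf list. The tie-break is arbitrary but
fixed — the classic consensus programs leave this case unspecified, and an
unspecified order would make consensus topologies run-dependent.

## Built-in tree estimator

Neighbor joining on Jukes–Cantor distances, midpoint-rooted. The estimator is
a plain callable `alignment -> rooted tree`, so an external ML program can be
substituted behind the same contract; NJ/JC is the self-consistent choice for
the bundled JC simulator and keeps the full pipeline inside a Python process.

- JC distance: d = −(3/4)·ln(1 − (4/3)p), p the mismatch proportion over
  columns where both sequences carry a called base. Saturated pairs
  (p ≥ 0.75) are capped at d = 5.0 substitutions/site to keep matrices
  finite. A pair sharing zero called columns is an error naming the pair.
- NJ determinism: taxa are sorted lexicographically and Q-matrix ties break
  to the lowest (row, column) pair, so the tree is invariant to input order.
  Negative branch-length estimates are clamped to zero.
- Midpoint rooting of a tree whose total length is zero (e.g. after masking
  removed all variation) is undefined; the tree is left rooted as built
  rather than passed to a library routine that misbehaves on that input.
- Bootstrap: columns resampled with replacement (seeded); node support is the
  percentage of replicate trees containing the node's clade; replicates on
  which estimation fails are dropped from the denominator.

## Alignment diagnostics

- **SNP**: a column with ≥ 2 distinct bases among A/C/G/T. Gap- or N-only
  variation does not count. This is the segregating-sites definition;
  counting gap variation would make indel regions dominate rRNA SNP counts.
- **Entropy**: Shannon entropy (base 2) of A/C/G/T frequencies per column,
  gaps/N excluded from the denominator; range [0, 2] bits.
- **Masking**: exactly ⌈fraction·L⌉ of the highest-entropy columns; ties at
  the threshold go to the lower column index. Default writes N (coordinates
  and region maps stay valid); deletion available by flag. Masking can only
  remove SNPs, never add them.
- **Hypervariable regions** are defined on the ungapped coordinate system of
  a reference sequence (1-based, inclusive); the packaged table carries the
  conventional E. coli-numbering V1–V9 boundaries plus V1-V2 and V3-V4. These
  defaults are a stand-in — studies differ in exact boundaries — and any
  table with the same three columns can be substituted.
- **SNP categories**: non-ribosomal (NR) and coding-ribosomal (CR) columns
  split by codon position (1–2 vs 3, frame-1 ORF convention — inputs are
  in-frame gene alignments), rRNA columns split into 16S and its stem/loop
  classes. Stem/loop columns count only when the structure call is consistent
  across all taxa. The 16S gene is recognised by "16S" in its gene id.

## Saturation curves and model selection

A single seeded permutation of the SNP columns defines nested subsets; the
size-s alignment is the first s columns. Nesting makes curves tend monotone
and reproducible, and the endpoint at the full column count equals the
full-matrix concordance by construction (independent per-size redraws are
available by flag). Sizes where tree estimation fails (e.g. one SNP leaving a
taxon pair with no shared called column) become recorded missing points and
are dropped from fitting.

Two families are fitted by least squares:

- logarithmic: y = a + b·ln x (closed-form linear fit);
- logistic: y = 1/(1 + e^−(a+bx)) — ordinary logistic regression, a linear
  predictor in the raw SNP count, fitted by Levenberg–Marquardt from a
  logit-scale linear start.

The logistic is deliberately *not* parameterised on ln x: a sigmoid in ln x
is a strictly more flexible saturating curve than the logarithm in the same
covariate and would win model selection on virtually any saturating data,
reducing the family contest to a tautology. With the raw-x form the two
families disagree in shape — concave-throughout vs sigmoid in x — and 5-fold
cross-validation (seeded permutation into near-equal folds, summed squared
held-out error, ties to the first-listed family, logarithmic by default)
genuinely discriminates. On simulated saturating curves the logarithmic model
is selected in the overwhelming majority of seeds, matching the behaviour the
framework is designed to measure.

Model inversion for a target concordance t: x = e^{(t−a)/b} (logarithmic) or
x = (logit t − a)/b (logistic); models with b ≤ 0 are not invertible toward
higher concordance and raise. Logistic predictions are bounded in (0, 1) by
construction; logarithmic predictions outside [0, 1] are reported as-is with
a warning — clamping would silently hide an extrapolation.

## HGT screen

For each species with ≥ 2 copies on a multi-copy gene tree, the minimal clade
(MRCA leaf set) containing all its copies is computed; the species is
monophyletic iff the clade contains no foreign leaves, otherwise the foreign
species are intruders and a (recipient, donor-candidates) event is flagged.
Any species — single-copy included — whose leaves fall strictly inside another
species' minimal clade is additionally reported nested in the tightest such
host. The minimal-clade operationalisation is the only deterministic reading
of "monophyletic grouping"; direction of transfer is reported as candidates
because a monophyly violation is symmetric evidence. No weak-signal guard is
applied beyond the availability of bootstrap supports on the gene tree.

## Synthetic data generator

Everything evolves under Jukes–Cantor along a simulated species tree, with a
seeded fraction of sites frozen invariant before evolution. JC (rather than
GTR+I+Γ) matches the built-in estimator's distance correction, keeping the
simulate–estimate loop self-consistent at desk scale.

Species trees: pure-birth (Yule, rate 1) conditioned on n tips, with an extra
exponential tip interval so terminal branches are positive — expected
root-to-tip depth (1/λ)Σ_{k=2..n} 1/k — or a unit-population Kingman
coalescent (expected depth 2(1 − 1/n)). Both are implemented directly (≈30
lines each) so these closed forms hold exactly for the process as coded and
are asserted in tests. An optional `min_branch` floor resamples until every
branch exceeds a threshold, expressing that recognised species are separated
by a minimum divergence; depth expectations hold only without the floor.

Default study conditions (one decision, not a dial):

| quantity | default | rationale |
|---|---|---|
| non-ribosomal genes | 20 × 928 bp, rate 0.15 | long genes, ~2/3 of sites segregating at intra-genus depths |
| coding-ribosomal genes | 8 × 434 bp, rate 0.10, 20% invariant | roughly half the NR length; slower, more constrained |
| rRNA locus | 1 × 1542 bp, rate 0.15, 83% invariant | 16S length; ~17% variable sites |
| per-gene jitter | length ±25% (codon-rounded), rate lognormal σ=0.35 | heterogeneity real core genomes show; the rRNA locus is not jittered (16S length is conserved and region coordinates assume it) |
| operon | copies uniform 1–8 per genome, copy divergence 0.005 subs/site | multi-copy with small intragenomic heterogeneity |

Planted events: an operon copy transfer overwrites a recipient copy with a
lightly perturbed donor copy (JC at 0.005 subs/site); segmental recombination
evolves columns beyond a breakpoint on an SPR-modified tree (one taxon
regrafted as sister to another). Every event is echoed in a JSON truth
record. Identical config + seed gives byte-identical FASTA/Newick/TSV output.

What the generator does not emulate: indels and alignment error, GTR-style
rate asymmetries, within-site rate variation beyond the invariant class,
gene-tree discordance from incomplete lineage sorting, and assembly artifacts
such as contig-truncated operons. Passing tests therefore demonstrate the
*machinery* is correct under a known substitution process, not that real 16S
data will show any particular concordance value.

## Validation design and problem sizes

- Clade machinery is checked against an independent brute-force oracle (a
  separate minimal newick-to-nested-tuple reader with recursive clade
  enumeration): exhaustively for all pairs of rooted binary topologies on
  ≤ 5 leaves (105² pairs), and on large seeded random samples for 6–7 leaves,
  where the full cross product (~10⁸ pairs) would buy no additional coverage
  per unit time.
- The curve-shape study runs at 30 taxa with five of twenty NR genes carrying
  planted breakpoints, so the SNP pool contains conflicting histories as real
  core genomes do, and sizes on a uniform grid up to ≈1.5× the SNP count at
  80% concordance — the same dynamic range as the curves being emulated
  (windows that extend far into the plateau measure the plateau, not the
  saturation law).
- The HGT screen's null/sensitivity study uses `min_branch = 0.1` and copy
  divergence 0.003 (≈10× separation margin). Without the floor, a Yule tree
  occasionally places two species closer than the operon's within-genome
  heterogeneity, and copy intermingling between such species is a property of
  the data, not a screen error.
- The end-to-end demo (17 species, ≈29 loci plus a multi-copy operon) runs in
  a few seconds and writes identical report hashes across reruns at a fixed
  seed; stage timings go to the log and stderr only.

## Known limitations

- NJ/JC is a consistent but noisy estimator; per-gene concordances at small
  alignment sizes carry estimator noise that an ML estimator would reduce.
  The estimator contract accepts any replacement.
- Recombination/HGT verdicts are inputs; the package ships no PHI/SBP-style
  detector. On synthetic data the generator's truth record plays that role.
- The exhaustive oracle stops at 5 leaves; 6–7-leaf coverage is sampled.
- GO-term aggregation assumes term maps and concordances are keyed
  consistently per dataset; terms missing from any dataset are silently
  non-universal rather than warned about.
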