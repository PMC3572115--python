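# Methods

## Model overview

The package tests, for each predefined gene set, the null hypothesis that
its genes are not collectively differentially expressed between two
phenotype groups, while weighting each gene by its functional centrality
within the set. Centrality is derived from a genome-scale functional
network built from GO semantic similarity, on the premise — borrowed from
the gene-network literature — that functional-linkage networks are
approximately scale-free, which drives the threshold selection below.

## Ontology handling

GO is treated as a DAG of `is_a` and `part_of` child→parent edges.
`part_of` traversal is a configuration flag, **default on**: semantic
similarity backends generally treat GO as a DAG without restricting
relations, and omitting `part_of` only disconnects ancestry, never
creates it. Obsolete terms are retained as metadata but never traversed.
Direct annotations are propagated to all ancestors (true-path rule)
before any term is counted.

Evidence filtering: `ND` (no biological data) records are always dropped
— they are non-configurable noise. `IEA` (electronic) exclusion is the
user's switch: including IEA gives a denser, noisier, higher-coverage
network; excluding it gives a sparse curated one. The default includes
IEA. Records with a `NOT` qualifier are excluded outright; records whose
term is unknown or obsolete are skipped with a counted report rather than
failing the run, because real GAF files routinely lag the ontology
release. Gene identifiers are matched exactly and case-sensitively; an
upper-casing normalization hook exists but is off by default, since
silent case-folding corrupts organisms with case-significant symbols.

## Information content and similarity

`IC(t) = −ln(n_t / n_total)` with natural logarithm; the base is
irrelevant after matrix normalization but is fixed for bit-for-bit
reproducibility. Terms with zero annotated genes have no defined IC and
are excluded rather than given infinite specificity. Term similarity is
the Resnik measure (max IC over common ancestors, a term being its own
ancestor); gene similarity uses max mixing over the genes' *direct* term
sets — propagation enters only through IC and ancestor queries, since
mixing over propagated sets would double-count ancestry.

The matrix is normalized by its maximal **off-diagonal** entry. The
diagonal never feeds edge decisions (self-edges are forbidden), and the
off-diagonal choice guarantees the threshold grid on [0, 1] is meaningful
(the off-diagonal maximum is exactly 1 whenever any positive similarity
exists). The diagonal may exceed 1 after normalization; it is never used.
Genes with no usable annotation are dropped from the matrix entirely —
they later receive the basic weight 1 — rather than being given
similarity 0, which would fabricate certainty about their unrelatedness.

## Network thresholding

Edges are `s_ij ≥ τ`, inclusive at the boundary so that τ = 1 keeps the
maximal pairs. The scale-free criterion uses equal-width bins over the
range of positive degrees (default 10 bins), excludes zero-degree nodes
before binning (their log-degree is undefined; the exclusion count is
reported), skips empty bins, and regresses `log10 p̂_b` on `log10 k̄_b` by
ordinary least squares. Log base 10 on both axes: R² is base-invariant
and the slope is then the (negated) power-law exponent estimate. The
default grid is 0.05–0.95 in steps of 0.05. Grid points whose network has
fewer than 3 nonempty bins (or no degree spread at all) are skipped with
a per-point diagnostic; ties in R² resolve to the lowest τ for
determinism. Bin count and grid are exposed in configuration because no
single choice suits all network sizes.

## Gene weighting

Under the null that gene *i* has no specific association with set *s*,
its in-set connectivity follows a hypergeometric distribution: the other
N − 1 network genes are the urn, its k_net neighbours the successes, the
other n_s − 1 set members the draws — the focal gene, being itself a
member, is excluded from both urn and draws, hence **n_s − 1** draws and
mean `E = k_net (n_s − 1)/(N − 1)`. Both n_s and N are counted over
network-present genes (units): a set member absent from the network
cannot be drawn from the urn and contributes nothing to in-set
connectivity.

The weight is `w = 1 + max(0, log2(k_path / E))`. The log transform tames
the right-skew of connectivity ratios; the clamp at zero keeps
below-expectation ("non-central") genes at weight 1 instead of
down-weighting them, so their expression still contributes to the set
statistic. **Log base 2** is the package's choice: each doubling of
in-set connectivity beyond expectation adds exactly 1 to the weight,
which makes weights directly interpretable. Degenerate cases (k_path = 0,
or E = 0) give weight exactly 1.

MSP correction: genes encoding subunits of one multi-subunit protein are
collapsed to a single unit before connectivity evaluation (units are
adjacent iff any cross-unit member pair is; intra-unit edges vanish).
A unit counts as inside a set iff at least one member gene is — a unit
straddling the set boundary is rare in practice and treating any-member
membership keeps the collapse monotone. Every member gene inherits its
unit's weight unchanged. Complex membership is user-supplied input; the
package does not attempt complex discovery.

Set-size filtering (default 15–500 genes) is applied to sets as loaded;
an option applies it after intersection with the measured genes instead,
for studies where platform coverage is the binding constraint.

## Set-level inference

Gene-level statistics are pooled-variance two-sample t statistics
(Welch by flag); zero-variance genes get d = 0. The set statistic is the
weighted mean absolute statistic, which reduces exactly to the
unweighted mean-absolute statistic at unit weights. Significance uses B
random label permutations — uniform over arrangements, sampled with
replacement across draws, weights held fixed — with the plain proportion
`p = #{T* ≥ T}/B`. No +1 smoothing by default: a statistic exceeding
every permuted value legitimately reports p = 0 at resolution 1/B (a
smoothing flag exists). A practical floor of 10,000 permutations is
recommended for stable p-values; the CLI default is 15,000, and tests use
far smaller B because they assert structural properties, not publication
p-values.

q-values are Benjamini–Hochberg step-up by default; a Storey-style
variant (π₀ estimated at λ = 0.5) is available. The normalized score
Z_s centers by the **median** (robust to the skew of permutation nulls)
and scales by the standard deviation of the set's **own** permuted
statistics. Per-set scope is the default because it is what makes Z
comparable across sets of different sizes; a pooled scope (all sets'
permuted values together) is implemented and surfaced in run metadata,
as the pooling convention varies in the literature. Ranking is by
descending Z with competition (minimum-rank) ties, so boundary claims
like "ranked above 80" are deterministic; the conservation rule keeps
sets with rank ≤ threshold (inclusive) in every dataset.

## Synthetic data

The generator emulates exactly the structure the inference assumes: a
two-group comparison with independent unit-variance Gaussian noise per
gene and sample, disjoint gene sets, and (optionally) a mean shift of
`effect_size` within-group standard deviations in the second group —
either uniformly over designated sets or confined to the hub (weight > 1)
genes of a supplied weight table. The default configuration is a
calibration-scale experiment: 20 genes in 5 disjoint sets of 4, 6 samples
per group, no effect. Permutation inference is distribution-free, so
Gaussian noise is the simplest adequate null; what the generator does
*not* emulate — gene–gene correlation, heavy-tailed intensities,
batch structure, realistic GO term/annotation counts — means passing
simulation tests demonstrates the machinery's correctness and calibration,
not performance on real microarray data.

The planted-similarity generator hides a configuration-model power-law
graph (degree exponent γ, default 2.5) at a chosen τ*: planted edges get
similarities in [τ*, τ* + 0.04], so one grid step higher the network
all but empties; non-edges get similarities uniform below τ*, so lower
thresholds bury the power law under Erdős–Rényi noise; one edge is
pinned at similarity 1 to satisfy the normalization contract. Threshold
recovery on these matrices is the package's own check that the selection
rule finds planted scale-free structure.

Packaged fixture tables transcribe only printed values from the
published p53, breast-cancer and asthma benchmarks (q-value columns, rank
triples, Z-score columns); no figure-derived numbers are included. They
feed the worked-example counting/ranking checks only.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` with caller
  seeds; identical seeds give bit-identical results.
- A similarity matrix whose off-diagonal is all zero is rejected
  ("degenerate similarity matrix") rather than normalized by zero.
- Sets with no measured genes are skipped with a warning; sets sharing no
  genes with the network get all weights 1 with a warning.
- Z is reported missing (NaN) for sets with zero permutation spread;
  such sets are left unranked.
- Evidence-filter changes do **not** generally yield nested networks at a
  fixed τ: removing annotations changes IC values and the normalization
  maximum, so edges can appear as well as disappear. What is guaranteed —
  and tested — is that the gene set with usable annotations shrinks.

## Problem sizes in the shipped checks

The calibration suite uses 1000 null datasets at the default
configuration with B = 200; the power check uses 500 replicates of a
50-gene star-network fixture; threshold recovery uses 20 matrices of 500
genes. These sizes give binomial standard errors small enough to resolve
the tested effects (e.g. ±0.003 on a 0.05 type-I rate) while keeping the
full suite fast enough to run on every change.

## Known limitations

- Cross-namespace similarity is undefined by design; analyses use one
  namespace (default Biological Process).
- No KS/GSEA-style enrichment statistic and no gene-label (competitive)
  permutation mode; the null is self-contained phenotype permutation.
- The scale-free criterion is unreliable on small or gene-biased
  networks; genome-wide input is assumed.
- Identifier mapping across naming systems is out of scope; inputs must
  share one gene vocabulary.
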