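# Methods

## The permutation ladder

A haplotype matrix is an `n_hap × width` binary array; columns `[0, n_seg)`
are segregating sites in genomic order, columns `[n_seg, width)` are
zero-padding added so that fixed-input-size models can consume the matrix.
Inter-site distance vectors, which some models take as a separate input
channel, are deliberately not modeled or permuted: the ladder interrogates
the matrix itself.

The five disruptions are defined on the non-padding region only:

1. **cols** — a uniform permutation of whole columns. Any statistic that is
   a function of the *multiset* of columns is untouched: the allele
   frequency spectrum (AFS), nucleotide diversity π, Tajima's D, the
   haplotype equality classes (hence Garud's H statistics), and the
   multiset of pairwise r² values. What is destroyed is the genomic
   position of each site, so the positions vector is dropped rather than
   carried along stale — this also holds for the trivial `n_seg ≤ 1` case,
   where the entries are returned unchanged.
2. **cols-within** — `cols` followed by an independent uniform shuffle of
   the entries within each column. Per-column sums are preserved (so AFS,
   π, D are unchanged), but the correlation between columns — linkage
   disequilibrium and haplotype identity — is destroyed: entries within a
   column become an exchangeable sample, and the expected r² between two
   columns collapses to its no-association value.
3. **all-entries** — a uniform permutation of all `n_hap · n_seg` cells.
   Only the grand total K of 1s survives. Each column's count becomes
   hypergeometric (drawing `n_hap` of `n_hap·n_seg` cells containing K
   ones), i.e. approximately binomial about the mean frequency
   `K/(n_hap·n_seg)` — the AFS is flattened onto that mean.
4. **group-keep-pad** — deterministic: the K ones are packed column-major
   against the padding boundary, filling columns from index `n_seg − 1`
   leftward, rows top-to-bottom. At most one column is mixed; all others
   are fixed at frequency 0 or 1, so the median allele frequency jumps to
   an extreme while the padding boundary stays visible.
5. **group-obscure-pad** — the same packing but from column 0 rightward;
   trailing data zeros become indistinguishable from padding, `n_seg` is
   reported as `width` and a `padding_obscured` flag is set. This
   additionally erases the implied number of segregating sites. When a
   matrix has no padding (`n_seg = width`) the two groupings produce
   mirror-image layouts with identical column multisets and are therefore
   functionally equivalent for column-order-invariant consumers.

**Grouping layout.** Nothing forces a particular placement of the grouped
1s; we pack column-major, top-to-bottom, against the padding boundary
(`keep-pad`) or against column 0 (`obscure-pad`). This is the minimal pair
that differs only in whether the boundary remains visible, and any fixed
fill order is equivalent for row-order-invariant models. The deterministic
layout also makes both groupings commute exactly with row reordering.

**Seeding.** Every stochastic operation takes an integer seed; batch
operations derive per-matrix seeds from `(base_seed, index)` through
`numpy.random.SeedSequence` spawn keys, a documented counter-based scheme
that is stable across platforms. Identical seeds give byte-identical
outputs end to end.

**Exactness.** "Preserved exactly" is meant at the bit level, which naive
floating-point accumulation would break (summing the same multiset in a
different order rounds differently). All statistic accumulations therefore
use `math.fsum`, whose result is the correctly rounded true sum and hence
order-independent, and the r² kernel is written symmetrically in its two
sites. The acceptance suite asserts bit equality, not closeness.

## Summary statistics

Statistics are computed over non-padding columns; after `group-obscure-pad`
the whole width is data by construction, so the same rule applies. Sites
monomorphic in the sample (which arise only post-permutation) are excluded
from S in Tajima's D and from r², and land in the 0/n classes of the AFS.
π is computed from column sums, `Σⱼ 2cⱼ(n−cⱼ)/(n(n−1))`, which equals the
mean pairwise Hamming distance; Tajima's D uses the standard normalizing
constants as functions of `n_hap`; r² uses gametic (phased-haplotype)
frequencies, not composite genotypic LD, since inputs are phased. Undefined
cases (D with S = 0, r² on a monomorphic column, AUC with one class,
Spearman's ρ on a constant vector) raise a dedicated
`StatisticUndefinedError`; the evaluation harness records them as explicit
NaN, never as 0.

## Synthetic data

The neutral generator is a Kingman coalescent **without recombination**
under a piecewise-constant demography, with infinite-sites mutations
dropped on branches as a Poisson process of rate θ/2 per unit branch
length. Time is in units of 2·N_ref generations; epoch sizes are scalars
relative to N_ref (coalescence rate `C(k,2)/s` in an epoch of size s, with
epoch boundaries handled by the memoryless restart); θ = 4·N_ref·μ·L for
the window. Under constant size s this gives the closed forms
E[S] = θ·s·a₁(n) and E[π] = θ·s used as simulator oracles, and the suite
cross-checks the mean S distribution against msprime at matched scaling.
Forgoing recombination keeps the simulator exact and fast; genealogical
correlation alone produces the LD-rich structure that makes `cols-within`
destructive. Site positions are drawn uniformly (stored as integer
coordinates on a 1 Mb window, ties permitted); when more sites arise than
the target width, the first `width` by position are kept, mirroring
fixed-input-size preprocessing.

Sweeps are **stylized distortions**, not structured-coalescent sweeps: a
seeded core haplotype is copied over `⌈f·n_hap⌉ − 1` other rows (raising
haplotype homozygosity) and a fraction of columns is deleted and re-padded
(lowering the minor-allele load). This produces class-separable data whose
separating features are known by construction — which is what the harness
needs — at the cost of physical realism; real sweep data additionally
perturb the AFS shape, local LD and flanking diversity in ways these
distortions do not. Passing degradation tests on these data therefore
demonstrates that the harness attributes performance to the intended
features, not that any particular published model behaves identically on
real data. Default conditions: classification uses 32 haplotypes × 64
columns at θ = 12 with tiers (f, thinning) = (0, 0), (0.5, 0.3),
(0.8, 0.6), 30 matrices per tier; regression uses 20 haplotypes × 96
columns at θ_ref = 8 with sizes drawn log-uniform on [0.3, 3] (a 10× span)
and epoch times uniform on [0.05, 0.45] and [0.5, 1.5]. These sizes keep
any single dataset under a second of generation time while leaving the
closed-form and degradation checks well-powered.

## Evaluation harness

`run_suite` permutes the test set at each level and seed, calls the model
once per (level, seed), and tabulates metrics: AUC (rank-based
Mann–Whitney form) and the confusion matrix for classification, Spearman's
ρ and RMSE per parameter for regression. Replication is over permutation
seeds on a *fixed* model — retraining is outside the harness's contract,
so instance-to-instance training variability is not captured. Multiclass
AUC is not computed; for multiclass classifiers the scalar
selection-intensity score is summarized as neutral-vs-rest AUC, and class
calls come from thresholds fixed once on the original data (threshold ties
resolve to the lower class index).

The three reference models are training-free and analytically
characterized: the **count** model scores by −(total 1s), a function of the
one quantity every level conserves, so its profile is flat by construction;
the **H1** model scores by Garud's H1, invariant under `cols`, destroyed by
`cols-within`, and driven toward the strongest class by the groupings
(which collapse haplotype diversity); the **AFS-moment** regressor
estimates epoch sizes from frequency-binned Fu-style estimators `i·ξᵢ`
(singletons → N0, mid-frequency → N1, high-frequency → N2, each scaled by
the reference θ) and reports prior midpoints for the epoch times. The
binned design is deliberate: a π-based estimator would partially survive
`all-entries` through the conserved grand total, whereas the bin estimators
depend on the AFS shape that `all-entries` genuinely destroys. Epoch times
carry little moment information at this scale, so their ρ is undefined
(constant estimate) and reported as NaN.

## Known limitations

* No recombination, migration, gene conversion or forward-time selection in
  the built-in simulator; externally simulated matrices can be supplied via
  the text dialect or VCF reader.
* Sweep labels come from stylized distortions (see above).
* The VCF reader requires fully phased, non-missing genotypes and skips
  multiallelic records and indels with a warning; no imputation.
* Only trailing padding is supported, and row-grouped multi-population
  matrices are out of scope.
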