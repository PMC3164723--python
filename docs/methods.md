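# Methods

## Problem setting

Given a genes × samples expression matrix with one class label per
sample (`K ≥ 2` classes), we want genes whose expression separates some
subset of classes from the rest. A *level-n* marker is highly expressed
in exactly `n` classes (the upper group) and lowly expressed in the
remaining `K − n` (the lower group). The package scores every gene at
every level `n ∈ 1..K−1`, selects stable candidates by resampling, and
attaches permutation significance.

## Preprocessing

Two dataset protocols are exposed:

- `leukemia-cns`: raw intensities are clipped to `[floor, ceiling]`
  (defaults 100 and 16000), log10-transformed, and each sample column is
  standardized to zero mean and unit variance across genes. The
  standardization uses the sample standard deviation (`ddof = 1`); this
  is a documented convention, chosen because it is the common default —
  any single consistent denominator would do, and the choice only
  rescales columns uniformly.
- `identity`: no change, for matrices that are already preprocessed.

Independently, the index always operates on per-gene min-max normalized
values: `x → (x − min)/(max − min)` over the samples present. A
constant gene maps to all zeros, which makes every one of its level
scores zero — a gene without variation has no discriminating power, and
this convention removes it without special-casing. Min-max normalization
makes `μ_Sep` values comparable across genes and leaves every rank
statistic unchanged.

During resampling, min-max normalization is **recomputed inside each
training split** rather than once globally. This keeps the GMI pipeline
and the template-based comparison on identical footing (the template
method is defined with per-training-set normalization) and means a
split's scores depend only on its own samples. The alternative — one
global normalization before splitting — is available via a flag
(`per_split_normalization=False` / `--global-normalization`); because
min-max is a positive affine map per gene and BCT is rank-based, the
difference only enters through `μ_Sep` and is small in practice.

## The index

For one gene at level `n` (class means sorted descending, ties broken
by ascending class id for determinism):

- `μ_Sep = μ_(n) − μ_(n+1)` ≥ 0, the gap between the *closest* pair of
  class means across the group boundary. Group means and pooled
  standard deviations are deliberately avoided: a signal-to-noise-style
  denominator lets one outlying sample shrink or inflate the score by an
  amount that depends on how far the outlier sits.
- `BCT`: sort the gene's values descending and count adjacent pairs
  whose upper/lower membership differs. Individual class identities
  inside a group are ignored (the grouping is binarized before
  counting). `BCT ∈ [1, 2·N_S]` whenever both groups are nonempty, and
  moving a single sample arbitrarily far changes it by at most 2.
- `OVL = BCT / N_S` with `N_S = min(N_up, N_low)`, a size-normalized
  overlap in `[1/N_S, 2]`.
- `GMI_n = μ_Sep / OVL`. When `BCT = 1` this equals `μ_Sep · N_S`
  exactly.

**Ties in the descending sort.** Equal expression values can change the
BCT count depending on how they are ordered. The default rule is
`stable` (tied samples keep their input order), which is deterministic
and, after continuous-valued normalization, essentially never exercised.
A `pessimistic` rule is available that orders every tied block to
*maximize* the transition count (computed exactly by a small dynamic
program over tie blocks, verified against exhaustive enumeration in the
tests); it gives a worst-case overlap for data with heavy value ties
(e.g. count data with many zeros).

## Stability selection

`R` times (default 100), a stratified training set is drawn with
`round(2/3 · n_k)` samples of each class `k` (round half-up, minimum 2;
a class with fewer than 2 samples is an error). Per split the matrix is
re-normalized, GMI is computed for every gene and level, and the top
`N1` genes per level are flagged. After `R` splits:

- `freq` = number of splits in which the gene was flagged (so per split
  and level the flags always sum to `min(N1, G)`);
- `ave_gmi` = mean of the gene's per-split GMI over **all** `R` splits,
  not only those in which it was selected — the average describes the
  gene, not the selection events;
- per level the `N2` genes with the highest `freq` are reported (ties
  by `ave_gmi` descending, then gene id); genes never flagged are
  excluded.

A selected gene's upper/lower groups can vary across splits; the
reported grouping is the modal class ordering over the splits in which
the gene was selected (ties broken lexicographically). Groups are
printed as concatenated class indices in descending-mean order
(`143` = classes 1, 4, 3).

Randomness: one master seed spawns an independent child seed per split
(`numpy` `SeedSequence.spawn`), so runs are reproducible, splits are
statistically independent, and two selection schemes given the same
master seed see *identical* training sets.

## Permutation significance

Class labels are permuted `B` times (default 200). Each permutation is
pushed through the identical `R`-split averaging code path, yielding
null averaged-GMI values for every gene and level. For observed value
`v` of gene `g` at level `n`:

- `p = #{null values at level n ≥ v} / (B·G)`, pooled over **all** genes
  — the null describes "any gene under no signal", so the smallest
  attainable nonzero p-value is `1/(B·G)` and a value exceeded by no
  null draw reports `p = 0`.
- `q` = empirical FDR: mean per-permutation count of null values `≥ v`,
  divided by the count of observed values `≥ v`, clamped to `[0, 1]`
  and monotonized by a running minimum from the least significant gene
  upward. The `≥` tail convention is used throughout, consistent with
  `p = 0` for untouched maxima. For a single gene `q` reduces to `p`.

## Template-based comparison

The baseline scores each gene by its best Pearson correlation with a
binary class template. At level `n` all `C(K, n)` size-`n` upper-group
subsets are enumerated (only positive templates: a down-regulated
pattern is the complementary subset at level `K − n`), totalling
`2^K − 2` templates per split across levels. The same split stream and
per-split top-`N1`/frequency aggregation are used as for GMI. Each gene
collapses to a single (combination, frequency) pair by argmax frequency,
ties by higher mean correlation; within a split, correlation ties pick
the lexicographically lowest combination. Genes constant within a split
have undefined correlation and are skipped for that split (logged).

**Class-imbalance bias.** For a fixed binary profile (1 on classes 1–2
with `n1`, `n2` samples) against the class-1 template, the Pearson
correlation has the closed form implemented in
`binary_template_correlation`; it increases monotonically in the size
`n3` of the unexpressed pool, approaching `sqrt(n1/(n1+n2))`, even
though no expression profile changes. With `n1=60, n2=15` it rises from
0.68 at `n3=20` to 0.85 at `n3=140`. The `(K+1)`-class variants (an
extra class of `n4` samples joins the template's expressed set, with the
gene uniformly expressed or unexpressed on it) are derived from the same
binary-overlap Pearson formula; both are cross-checked against
materialized 0/1 vectors to 1e-12, and the down-regulated variant sits
pointwise below the up-regulated one. This bias is what lets clean
level-3 genes outrank true small-class level-2 markers under template
ranking when one class is much larger than the rest, while the GMI
ranking — which looks at the boundary gap and rank overlap, not a
correlation over all samples — is unaffected.

## Single-gene evaluation

`loocv_nnc_accuracy` assesses one gene's power to separate a proposed
two-group split: each sample is assigned the group of its nearest other
sample by absolute difference on that gene alone (leave-one-out), ties
going to the lowest sample index (deterministic). Because the
nearest-neighbor rule is invariant under monotone transforms of a single
feature, normalized and raw values give identical accuracies.

## Synthetic data generator

`SyntheticSpec` defines the planted-marker simulations used throughout
testing: per planted gene, samples of the upper-group classes draw from
`N(upper_mean, sd)` and the rest from `N(lower_mean, sd)`, clipped to
`[0, 1]` so fixtures resemble post-min-max data; noise genes draw from a
single shared `N(0.5, 0.15)` clipped likewise. Defaults are a balanced
five-class design with ten samples per class and planted means 0.8/0.3
with sd 0.1 — a boundary separation of five noise standard deviations,
at which recovery should be (and is) certain. Outliers are implemented
as cross-group resampling — a fraction of a planted gene's samples is
redrawn from the opposite group's distribution — because that provably
raises BCT, whereas additive shifts may or may not cross the boundary.

What the generator does **not** emulate: probe-level effects,
intensity-dependent variance, correlated genes, batch structure, or
heavy-tailed noise. Passing tests therefore demonstrate correctness of
the algorithms and their documented statistical behavior under the
idealized model, not performance on any particular real platform.

## Problem sizes used in the test suite

The properties are exercised at sizes chosen to make the statistical
assertions sharp while keeping the suite quick: marker recovery at
`G = 500` genes, 60 samples, `R = 100` splits; null calibration on
exchangeable data at `G = 200`, `B = 100`, `R = 20` (the fraction of
genes with `p ≤ α` is required to sit within 3 binomial standard errors
of `α` at a fixed seed); the BCT oracle on 1000 random instances; the
permutation p-value against a brute-force double loop at `G = 50`,
`B = 20`.

## Known limitations

- The averaged GMI of a gene depends on all `R` splits, so frequencies
  and averages are only comparable between runs with the same `R`,
  `N1` and split fraction.
- Pooled permutation p-values assume genes are exchangeable under the
  null; strong inter-gene correlation makes the pooled null
  optimistic, a property shared by all gene-pooled permutation schemes.
- The q-value is an empirical-FDR estimate, not a Benjamini–Hochberg
  adjustment; with few permutations its granularity is coarse.
- `μ_Sep` compares single class means, so a level whose boundary classes
  have very few samples inherits the noise of those means; the
  resampling frequency is the guard against over-interpreting one split.
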