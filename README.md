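# gmi — Group Marker Index

Marker-gene selection for **multi-class** expression matrices (bulk
microarray or pseudo-bulked single-cell data). Most selection statistics
are built for two classes and can only find genes specific to a *single*
class; `gmi` finds, in one pass, genes specific to any *subset* of
classes — a gene highly expressed in exactly `n` of the `K` classes and
low in the rest is a **level-n marker** (level-1 = single-class specific,
level-n = multiple-class specific).

## The index

For a gene normalized to `[0, 1]` across samples, rank its `K` class
means in descending order; at level `n` the top `n` classes form the
*upper group* and the rest the *lower group*. Two quantities score the
split:

- `μ_Sep = μ_(n) − μ_(n+1)` — the gap between the *nearest* class means
  of the two groups (no pooled means or pooled standard deviations, so a
  single wild value cannot dominate the score);
- `BCT` — the **between-class-transition** count: sort the gene's values
  in descending order and count adjacent sample pairs whose group
  membership differs. A clean split has `BCT = 1`; each sample sandwiched
  inside the other group adds two. BCT is a rank statistic, so it
  depends on *how many* samples intrude, never on how far they sit.

With `N_S = min(N_up, N_low)` and `OVL = BCT / N_S`,

```
GMI_n = μ_Sep / OVL
```

is large exactly when the two groups are well separated with little
overlap. A `K`-class gene is scored at its `K − 1` levels, versus the
`2^K − 2` class subsets a template-matching method must enumerate.

Around the index the package provides:

- **stability selection** (`select_markers`): `R` stratified random
  splits (two thirds of each class), per-split top-`N1` bookkeeping,
  final ranking by selection frequency with averaged GMI;
- **permutation significance** (`build_null`, `p_values`, `q_values`):
  `B` label permutations re-run through the same split-averaging code,
  pooled over genes, giving empirical p-values and empirical-FDR
  q-values;
- **template-based method** (`rank_by_template`): the Pearson
  template-matching baseline run on identical splits, for head-to-head
  comparisons, plus the closed-form analysis of its class-imbalance bias
  (`binary_template_correlation`, `imbalance_curve`);
- **evaluation** (`loocv_nnc_accuracy`): single-gene leave-one-out
  nearest-neighbor accuracy of a proposed grouping;
- **synthetic data** (`generate`): planted-marker matrices with
  configurable class sizes, noise, and cross-group outliers, used by the
  whole test suite.

## Worked example

Plant one level-1 marker (high in class 3) and one level-2 marker (high
in classes 3 and 4) among 200 noise genes in a balanced 5-class design,
then select and test:

```python
from gmi import (PlantedMarker, SyntheticSpec, generate, select_markers,
                 average_gmi, build_null, attach_significance)

planted = (
    PlantedMarker(upper=(3,),   upper_mean=0.85, lower_mean=0.30, noise_sd=0.1),
    PlantedMarker(upper=(3, 4), upper_mean=0.80, lower_mean=0.25, noise_sd=0.1),
)
spec = SyntheticSpec(class_sizes=(10,) * 5, planted=planted,
                     n_noise_genes=200, seed=7)
data, truth = generate(spec)

records  = select_markers(data, R=100, N1=10, N2=5, seed=1)
observed = average_gmi(data, R=100, seed=1)
null     = build_null(data, R=100, B=50, seed=1)
records  = attach_significance(records, observed, null, data.gene_ids)
```

Top of the level-1 and level-2 tables:

```
level 1
  marker_0000  upper=3  freq=100  ave_gmi=4.42  p=0.00e+00  q=0.00e+00
  noise_0041   upper=1  freq=67   ave_gmi=0.18  p=1.49e-03  q=1.00e-01
level 2
  marker_0001  upper=34 freq=100  ave_gmi=8.22  p=0.00e+00  q=0.00e+00
  noise_0062   upper=21 freq=75   ave_gmi=0.19  p=5.94e-04  q=6.00e-02
```

Both planted genes are selected in all 100 splits (`freq=100`) at their
true level with their true upper group (`upper=34` means classes 3 and 4,
printed in descending-mean order), and their averaged GMI sits an order
of magnitude above the best noise gene; `p = q = 0` means no pooled
permutation value ever reached them. Noise genes picked up by chance
have small frequencies, tiny averaged GMI and non-trivial q-values.

The same pipeline is available from a shell:

```sh
gmi simulate --spec spec.yaml --out-matrix m.tsv --out-labels l.tsv --out-truth t.tsv
gmi select   --matrix m.tsv --labels l.tsv --R 100 --N1 10 --N2 10 --seed 1 --out markers.tsv
gmi permute  --matrix m.tsv --labels l.tsv --B 200 --R 100 --seed 1 --out markers_pq.tsv
gmi tbm      --matrix m.tsv --labels l.tsv --R 100 --seed 1 --out tbm.tsv
gmi evaluate imbalance --n1 60 --n2 15 --n3-range 20:300 --out curve.tsv
```

All result tables are tab-delimited with a commented provenance header
(seed and parameters), and identical configurations produce
byte-identical outputs.

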