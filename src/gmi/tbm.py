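"""Template-based marker selection (TBM), the comparison baseline.

For level ``n`` of a ``K``-class problem every size-``n`` subset of
classes defines a binary template: 1 for samples of the subset's classes,
0 elsewhere.  Each gene is scored by its best Pearson correlation over
the level's ``C(K, n)`` templates; across levels a split therefore
enumerates ``2**K - 2`` templates, against the ``K - 1`` evaluations GMI
needs.  The same repeated stratified splitting as the GMI selection is
applied — with an identical seed, both methods see identical training
sets — and (gene, template) pairs are accumulated by frequency of
appearance in the per-split top-``N1`` lists.

The method is known to be biased by class-size imbalance: the Pearson
correlation of a fixed binary profile with a fixed template grows as the
pool of unexpressed samples grows (see
:func:`gmi.evaluation.binary_template_correlation`), which can promote
genes whose expressed classes do not match the template level.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import LabeledExpressionMatrix
from .preprocess import minmax_rows
from .selection import DEFAULT_FRACTION, split_seeds, stratified_split

__all__ = ["TemplateRecord", "make_template", "rank_by_template", "n_templates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateRecord:
    """Best (template, frequency) pair for a gene at one level.

    ``best_combination`` is the upper-group class subset of the winning
    template (ascending class ids); ``best_correlation`` is the mean over
    the splits in which the pair was selected of the gene's correlation
    with that template.
    """

    gene_id: str
    level: int
    best_combination: tuple[int, ...]
    best_correlation: float
    freq: int


def make_template(labels: np.ndarray, upper: "tuple[int, ...] | set[int]") -> np.ndarray:
    """Binary template: 1 where the sample's class is in ``upper``.

    ``upper`` must be a nonempty proper subset of the classes present.
    """
    labels = np.asarray(labels, dtype=int)
    upper = frozenset(int(c) for c in upper)
    present = frozenset(int(c) for c in np.unique(labels))
    if not upper:
        raise ValueError("upper group must be nonempty")
    if upper >= present:
        raise ValueError("upper group must be a proper subset of the classes")
    if not upper <= present:
        raise ValueError(f"upper group {sorted(upper)} contains unknown classes")
    return np.isin(labels, sorted(upper)).astype(float)


def n_templates(K: int) -> int:
    """Number of templates enumerated per split across all levels."""
    return 2**K - 2


def _pearson_vs_templates(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of genes ``X (G,S)`` vs templates ``T (M,S)``.

    Constant gene rows yield NaN (correlation undefined).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    st = np.sqrt((Tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc @ Tc.T) / np.outer(sx, st)


def rank_by_template(
    data: LabeledExpressionMatrix,
    R: int = 100,
    N1: int = 10,
    N2: int = 10,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
) -> dict[int, list[TemplateRecord]]:
    """Frequency-ranked (gene, template) pairs per level over ``R`` splits.

    Per split and level, every gene's correlation with every size-``n``
    combination template is computed on the min-max re-normalized
    training values; the gene keeps its best combination (ties broken by
    the lexicographically lowest combination) and the top ``N1`` genes by
    that correlation enter the split's list.  Over ``R`` splits each
    gene's most frequent pair is retained (ties by higher mean
    correlation) and the top ``N2`` genes by frequency are returned.
    Genes constant within a split are skipped for that split.
    """
    if R < 1 or N1 < 1 or N2 < 1:
        raise ValueError("R, N1 and N2 must all be >= 1")
    G, K = data.n_genes, data.K
    if K < 2:
        raise ValueError("need at least 2 classes")
    # freq[(gene, level)][combination] = count; corr_sum for tie-breaking/reporting
    freq: dict[tuple[int, int], dict[tuple[int, ...], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    corr_sum: dict[tuple[int, int], dict[tuple[int, ...], float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for child in split_seeds(seed, R):
        idx = stratified_split(data, fraction=fraction, seed=child)
        sub = minmax_rows(data.values[:, idx])
        sub_labels = data.labels[idx]
        constant = sub.std(axis=1) == 0
        if constant.any():
            logger.info(
                "skipping %d constant gene(s) in a training split", int(constant.sum())
            )
        for n in range(1, K):
            combos = list(combinations(range(1, K + 1), n))
            T = np.stack([make_template(sub_labels, c) for c in combos])
            corr = _pearson_vs_templates(sub, T)  # (G, M)
            corr[constant] = -np.inf
            best_m = np.argmax(corr, axis=1)  # first max = lowest lexicographic combo
            best_c = corr[np.arange(G), best_m]
            usable = np.flatnonzero(np.isfinite(best_c))
            order = usable[np.argsort(-best_c[usable], kind="stable")][: min(N1, usable.size)]
            for g in order:
                combo = combos[best_m[g]]
                freq[(int(g), n)][combo] += 1
                corr_sum[(int(g), n)][combo] += float(best_c[g])
    out: dict[int, list[TemplateRecord]] = {}
    for n in range(1, K):
        rows = []
        for (g, level), combo_counts in freq.items():
            if level != n:
                continue
            best_combo = max(
                combo_counts,
                key=lambda c: (
                    combo_counts[c],
                    corr_sum[(g, n)][c] / combo_counts[c],
                    tuple(-x for x in c),
                ),
            )
            f = combo_counts[best_combo]
            rows.append(
                TemplateRecord(
                    gene_id=data.gene_ids[g],
                    level=n,
                    best_combination=best_combo,
                    best_correlation=corr_sum[(g, n)][best_combo] / f,
                    freq=f,
                )
            )
        rows.sort(key=lambda r: (-r.freq, -r.best_correlation, r.gene_id))
        out[n] = rows[:N2]
    return out
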