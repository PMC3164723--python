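"""Permutation significance for averaged GMI values.

Class labels are permuted ``B`` times; for each permutation the full
``R``-split averaging of :func:`gmi.selection.average_gmi` is re-run with
the permuted labels, giving a pooled null of ``B * G`` averaged GMI
values per discrimination level.  The p-value of a gene's observed
average is the fraction of that pooled null at least as large (so the
smallest attainable nonzero p-value is ``1 / (B * G)``, and a value
exceeded by no null draw reports ``p = 0``).  The q-value is the
empirical false-discovery-rate twin of the p-value: the mean number of
null exceedances per permutation divided by the number of observed
values at least as large, clamped to [0, 1] and made monotone
nonincreasing in the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import LabeledExpressionMatrix
from .selection import DEFAULT_FRACTION, average_gmi
from .selection import SelectionRecord

__all__ = ["PermutationNull", "build_null", "p_values", "q_values", "attach_significance"]


@dataclass(frozen=True)
class PermutationNull:
    """Null averaged-GMI values: array of shape ``(B, G, K-1)``."""

    values: np.ndarray
    B: int
    R: int
    seed: int

    def pooled(self, level: int) -> np.ndarray:
        """Flat pooled null for level ``n`` (1-based): ``B * G`` values."""
        return self.values[:, :, level - 1].ravel()


def build_null(
    data: LabeledExpressionMatrix,
    R: int = 100,
    B: int = 200,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
    tie_rule: str = "stable",
    per_split_normalization: bool = True,
) -> PermutationNull:
    """Averaged GMI under ``B`` independent label permutations.

    Each permutation reuses the selection module's split-averaging code
    path verbatim, so observed and null statistics are produced by the
    same computation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    G, K = data.n_genes, data.K
    null = np.empty((B, G, K - 1))
    for b, child in enumerate(np.random.SeedSequence(seed).spawn(B)):
        perm_seed, split_seed = child.spawn(2)
        rng = np.random.default_rng(perm_seed)
        permuted = LabeledExpressionMatrix(
            values=data.values,
            gene_ids=data.gene_ids,
            sample_ids=data.sample_ids,
            labels=rng.permutation(data.labels),
            class_names=data.class_names,
        )
        null[b] = average_gmi(
            permuted,
            R=R,
            seed=split_seed,
            fraction=fraction,
            tie_rule=tie_rule,
            per_split_normalization=per_split_normalization,
        )
    return PermutationNull(values=null, B=B, R=R, seed=seed)


def _exceedances(sorted_asc: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Count of entries in ``sorted_asc`` that are >= each of ``values``."""
    return sorted_asc.size - np.searchsorted(sorted_asc, values, side="left")


def p_values(observed: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Pooled permutation p-value per gene and level.

    ``observed`` has shape ``(G, K-1)`` (averaged GMI); the null for a
    level pools all genes of all ``B`` permutations at that level.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    out = np.empty_like(observed)
    for n in range(observed.shape[1]):
        pool = np.sort(null.pooled(n + 1))
        out[:, n] = _exceedances(pool, observed[:, n]) / pool.size
    return out


def q_values(observed: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Empirical-FDR q-value per gene and level.

    For gene ``g`` the raw estimate is the mean per-permutation count of
    null values >= its observed average, divided by the count of observed
    averages >= it.  Raw values are clamped to [0, 1] and monotonized by
    a running minimum from the least significant gene upward.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    out = np.empty_like(observed)
    for n in range(observed.shape[1]):
        col = observed[:, n]
        pool = np.sort(null.pooled(n + 1))
        obs_sorted = np.sort(col)
        numer = _exceedances(pool, col) / null.B
        denom = _exceedances(obs_sorted, col)  # >= includes the gene itself
        raw = np.clip(numer / denom, 0.0, 1.0)
        order = np.argsort(-col, kind="stable")
        monotone = np.minimum.accumulate(raw[order][::-1])[::-1]
        q = np.empty_like(raw)
        q[order] = monotone
        out[:, n] = q
    return out


def attach_significance(
    records: dict[int, list[SelectionRecord]],
    observed: np.ndarray,
    null: PermutationNull,
    gene_ids: "tuple[str, ...] | list[str]",
) -> dict[int, list[SelectionRecord]]:
    """Fill p/q-values into per-level selection records.

    ``observed`` is the full ``(G, K-1)`` averaged-GMI matrix over the
    same genes as ``gene_ids``; p/q are computed over all genes and the
    selected records receive their gene's values.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    p = p_values(observed, null)
    q = q_values(observed, null)
    out: dict[int, list[SelectionRecord]] = {}
    for level, recs in records.items():
        out[level] = [
            SelectionRecord(
                gene_id=r.gene_id,
                level=r.level,
                upper_group=r.upper_group,
                lower_group=r.lower_group,
                freq=r.freq,
                ave_gmi=r.ave_gmi,
                p_value=float(p[index[r.gene_id], level - 1]),
                q_value=float(q[index[r.gene_id], level - 1]),
            )
            for r in recs
        ]
    return out
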