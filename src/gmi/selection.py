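"""Stability selection of marker genes over repeated stratified splits.

A single split draws roughly two thirds of the samples from each class as
a training set.  In each of ``R`` splits the matrix is re-normalized on
the training samples, the level-wise GMI is computed for every gene, and
the top ``N1`` genes per level are flagged.  After ``R`` splits a gene's
*selection frequency* at a level is the number of splits in which it was
flagged, and its *averaged GMI* is the arithmetic mean of its per-split
GMI values over all ``R`` splits (selected or not).  Per level the ``N2``
most frequently selected genes are reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .index import gmi_statistics
from .matrix import LabeledExpressionMatrix
from .preprocess import minmax_rows

__all__ = [
    "SelectionRecord",
    "stratified_split",
    "split_seeds",
    "average_gmi",
    "select_markers",
]

DEFAULT_FRACTION = 2.0 / 3.0
MIN_PER_CLASS = 2


@dataclass(frozen=True)
class SelectionRecord:
    """One row of a per-level marker table.

    ``upper_group``/``lower_group`` are the modal class groupings over the
    splits in which the gene was selected, each ordered by descending
    class mean.  ``p_value``/``q_value`` stay ``None`` until the
    permutation test of :mod:`gmi.significance` fills them in.
    """

    gene_id: str
    level: int
    upper_group: tuple[int, ...]
    lower_group: tuple[int, ...]
    freq: int
    ave_gmi: float
    p_value: float | None = field(default=None)
    q_value: float | None = field(default=None)


def split_seeds(
    seed: "int | np.random.SeedSequence", R: int
) -> list[np.random.SeedSequence]:
    """Derive one independent child seed per split from a master seed.

    Exposed so that different selection schemes (GMI, template-based) can
    be run on *identical* training splits for a fair comparison.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return seed.spawn(R)


def stratified_split(
    data: LabeledExpressionMatrix,
    fraction: float = DEFAULT_FRACTION,
    seed: "int | np.random.SeedSequence | np.random.Generator" = 0,
) -> np.ndarray:
    """Sample a training subset with ``round(fraction * n_k)`` per class.

    Rounding is half-up, with a floor of ``2`` training samples per
    class.  Returns the sorted sample indices of the training set.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for k in range(1, data.K + 1):
        members = np.flatnonzero(data.labels == k)
        n_k = members.size
        take = max(int(np.floor(fraction * n_k + 0.5)), MIN_PER_CLASS)
        if n_k < MIN_PER_CLASS:
            raise ValueError(
                f"class {k} has only {n_k} sample(s); at least "
                f"{MIN_PER_CLASS} are required for splitting"
            )
        take = min(take, n_k)
        chosen.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def _run_splits(
    data: LabeledExpressionMatrix,
    R: int,
    seed: int,
    fraction: float,
    tie_rule: str,
    per_split_normalization: bool,
    track_selection: "int | None" = None,
):
    """Shared engine: per-split GMI with optional top-``N1`` bookkeeping.

    Returns ``(ave_gmi, freq, groups)`` where ``ave_gmi`` is the
    ``(G, K-1)`` mean over all ``R`` splits, and ``freq``/``groups`` are
    ``None`` unless ``track_selection`` (= ``N1``) is given.
    """
    G = data.n_genes
    K = data.K
    total = np.zeros((G, K - 1))
    freq = np.zeros((G, K - 1), dtype=int) if track_selection else None
    groups: "dict[tuple[int, int], Counter] | None" = (
        {} if track_selection else None
    )
    values = data.values
    if not per_split_normalization:
        values = minmax_rows(values)
    for child in split_seeds(seed, R):
        idx = stratified_split(data, fraction=fraction, seed=child)
        sub = values[:, idx]
        if per_split_normalization:
            sub = minmax_rows(sub)
        stats = gmi_statistics(sub, data.labels[idx], tie_rule=tie_rule)
        gmi = stats["gmi"]
        total += gmi
        if track_selection:
            n_top = min(track_selection, G)
            order = np.argsort(-gmi, axis=0, kind="stable")
            class_order = stats["class_order"]
            for n in range(K - 1):
                top = order[:n_top, n]
                freq[top, n] += 1
                for g in top:
                    key = (int(g), n)
                    groups.setdefault(key, Counter())[
                        tuple(int(c) for c in class_order[g])
                    ] += 1
    return total / R, freq, groups


def average_gmi(
    data: LabeledExpressionMatrix,
    R: int,
    seed: int,
    fraction: float = DEFAULT_FRACTION,
    tie_rule: str = "stable",
    per_split_normalization: bool = True,
) -> np.ndarray:
    """Mean level-wise GMI over ``R`` stratified training splits, ``(G, K-1)``."""
    ave, _, _ = _run_splits(
        data, R, seed, fraction, tie_rule, per_split_normalization, None
    )
    return ave


def select_markers(
    data: LabeledExpressionMatrix,
    R: int = 100,
    N1: int = 10,
    N2: int = 10,
    seed: int = 0,
    fraction: float = DEFAULT_FRACTION,
    tie_rule: str = "stable",
    per_split_normalization: bool = True,
) -> dict[int, list[SelectionRecord]]:
    """Frequency-ranked marker genes per discrimination level.

    Returns a mapping ``level -> records`` where each level's records are
    the up-to-``N2`` genes with the highest selection frequency (ties by
    averaged GMI descending, then gene id); genes never selected in any
    split are excluded.
    """
    if R < 1 or N1 < 1 or N2 < 1:
        raise ValueError("R, N1 and N2 must all be >= 1")
    ave, freq, groups = _run_splits(
        data, R, seed, fraction, tie_rule, per_split_normalization, N1
    )
    K = data.K
    out: dict[int, list[SelectionRecord]] = {}
    for n in range(K - 1):
        candidates = np.flatnonzero(freq[:, n] > 0)
        ranked = sorted(
            candidates,
            key=lambda g: (-freq[g, n], -ave[g, n], data.gene_ids[g]),
        )[:N2]
        records = []
        for g in ranked:
            counter = groups[(int(g), n)]
            top_count = max(counter.values())
            modal = min(k for k, v in counter.items() if v == top_count)
            records.append(
                SelectionRecord(
                    gene_id=data.gene_ids[g],
                    level=n + 1,
                    upper_group=modal[: n + 1],
                    lower_group=modal[n + 1 :],
                    freq=int(freq[g, n]),
                    ave_gmi=float(ave[g, n]),
                )
            )
        out[n + 1] = records
    return out
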