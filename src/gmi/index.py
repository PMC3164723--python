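"""The Group Marker Index (GMI) and its Between-Class-Transition statistic.

For a gene observed across ``S`` samples from ``K`` classes, sort the
expression values in descending order and count the adjacent pairs whose
group membership differs: the Between-Class-Transition (BCT) count.  BCT
is a rank statistic — it measures how interleaved two groups of samples
are, independently of how far any outlying value sits from its group.

A *level-n* marker is a gene highly expressed in exactly ``n`` of the
``K`` classes (the *upper group*) and lowly expressed in the rest (the
*lower group*).  For each level ``n`` in ``1..K-1`` the gene's classes
are ranked by mean expression; the top ``n`` form the upper group, and

    mu_sep = mu_(n) - mu_(n+1)          closest separation between groups
    OVL    = BCT / N_S,  N_S = min(N_up, N_low)
    GMI    = mu_sep / OVL

A large GMI means a wide gap between the nearest class means of the two
groups with few rank transitions between them.  Evaluating ``K-1`` levels
replaces the ``2**K - 2`` class-subset enumeration a template method
needs.

Inputs are expected to be min-max normalized per gene (see
:mod:`gmi.preprocess`); BCT itself is rank-based and unaffected, but
``mu_sep`` is only comparable across genes on the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import LabeledExpressionMatrix

__all__ = ["LevelProfile", "count_bct", "gmi_statistics", "level_profiles"]

TIE_RULES = ("stable", "pessimistic")


@dataclass(frozen=True)
class LevelProfile:
    """All level-``n`` quantities for one gene.

    ``class_order`` holds the class identifiers in descending order of
    their mean expression (ties broken by ascending class id); the first
    ``level`` entries are the upper group.
    """

    gene_id: str
    level: int
    sorted_class_means: tuple[float, ...]
    class_order: tuple[int, ...]
    upper_group: tuple[int, ...]
    lower_group: tuple[int, ...]
    mu_sep: float
    bct: int
    n_s: int
    ovl: float
    gmi: float


def _descending_order(values: np.ndarray) -> np.ndarray:
    # stable argsort of the negated values: descending, ties in input order
    return np.argsort(-values, axis=-1, kind="stable")


def count_bct(
    values: np.ndarray,
    group_flags: np.ndarray,
    tie_rule: str = "stable",
) -> int:
    """Count between-group transitions in the descending sort of ``values``.

    Parameters
    ----------
    values
        Expression values, one per sample.
    group_flags
        Boolean (or 0/1) group membership per sample; both groups must be
        nonempty.
    tie_rule
        How samples with exactly equal values are ordered: ``"stable"``
        keeps the original sample order, ``"pessimistic"`` orders every
        tied block so as to maximize the transition count (worst case).

    Returns
    -------
    int
        The BCT count, always in ``[1, 2 * min(group sizes)]``.
    """
    values = np.asarray(values, dtype=float).ravel()
    flags = np.asarray(group_flags).astype(bool).ravel()
    if values.shape != flags.shape:
        raise ValueError("values and group_flags must have the same length")
    if not flags.any():
        raise ValueError("upper group is empty")
    if flags.all():
        raise ValueError("lower group is empty")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    order = _descending_order(values)
    sorted_vals = values[order]
    sorted_flags = flags[order]
    if tie_rule == "stable":
        return int(np.count_nonzero(sorted_flags[1:] != sorted_flags[:-1]))
    return _pessimistic_bct(sorted_vals, sorted_flags)


def _pessimistic_bct(sorted_vals: np.ndarray, sorted_flags: np.ndarray) -> int:
    """Maximum BCT over all reorderings within blocks of tied values.

    Within a tied block holding ``a`` upper and ``b`` lower samples the
    achievable (first flag, last flag, internal transitions) triples are
    enumerated in closed form and combined across blocks by a two-state
    dynamic program on the trailing flag.
    """
    # block boundaries: indices where the value changes
    change = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [sorted_vals.size]))

    NEG = -(10**9)
    best = {True: NEG, False: NEG}
    first_block = True
    for s, e in zip(starts, ends):
        block = sorted_flags[s:e]
        a = int(block.sum())  # uppers
        b = block.size - a  # lowers
        options: list[tuple[bool, bool, int]] = []
        if b == 0:
            options.append((True, True, 0))
        elif a == 0:
            options.append((False, False, 0))
        elif a == b:
            options.append((True, False, 2 * a - 1))
            options.append((False, True, 2 * a - 1))
            options.append((True, True, 2 * a - 2))
            options.append((False, False, 2 * a - 2))
        else:
            # maj = majority flag, m = minority count
            maj = a > b
            m = min(a, b)
            options.append((maj, maj, 2 * m))
            options.append((maj, not maj, 2 * m - 1))
            options.append((not maj, maj, 2 * m - 1))
            if m >= 2:
                options.append((not maj, not maj, 2 * m - 2))
        new_best = {True: NEG, False: NEG}
        for first, last, internal in options:
            if first_block:
                cand = internal
            else:
                cand = max(
                    best[True] + (first is not True) + internal,
                    best[False] + (first is not False) + internal,
                )
            if cand > new_best[last]:
                new_best[last] = cand
        best = new_best
        first_block = False
    return int(max(best.values()))


def gmi_statistics(
    values: np.ndarray,
    labels: np.ndarray,
    tie_rule: str = "stable",
) -> dict[str, np.ndarray]:
    """Vectorized level-wise GMI for every gene of a matrix.

    Parameters
    ----------
    values
        ``(G, S)`` matrix, min-max normalized per gene.
    labels
        Integer class labels ``1..K``, one per sample; every class must
        be represented.

    Returns
    -------
    dict of arrays
        ``class_means (G, K)``, ``class_order (G, K)`` (1-based class
        ids, descending mean), ``sorted_means (G, K)``, and the
        ``(G, K-1)`` arrays ``mu_sep``, ``bct``, ``n_s``, ``ovl`` and
        ``gmi``; column ``n-1`` holds the level-``n`` quantities.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    G, S = values.shape
    K = int(labels.max())
    counts = np.bincount(labels, minlength=K + 1)[1:]
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValueError(f"class {empty} has no samples")
    if K < 2:
        raise ValueError("need at least 2 classes")

    class_means = np.empty((G, K))
    for k in range(K):
        class_means[:, k] = values[:, labels == k + 1].mean(axis=1)

    # descending means, ties by ascending class id (stable sort on -means)
    order0 = np.argsort(-class_means, axis=1, kind="stable")  # 0-based class index
    sorted_means = np.take_along_axis(class_means, order0, axis=1)
    rank = np.empty((G, K), dtype=int)  # rank[g, k] = position of class k+1
    np.put_along_axis(rank, order0, np.arange(K)[None, :], axis=1)

    mu_sep = sorted_means[:, :-1] - sorted_means[:, 1:]

    sample_order = _descending_order(values)
    labels_sorted = labels[sample_order]  # (G, S)
    ranks_sorted = np.take_along_axis(rank, labels_sorted - 1, axis=1)

    counts_sorted = counts[order0]  # (G, K)
    n_up = np.cumsum(counts_sorted, axis=1)[:, :-1]  # (G, K-1)
    n_s = np.minimum(n_up, S - n_up)

    bct = np.empty((G, K - 1), dtype=int)
    for n in range(1, K):
        flags = ranks_sorted < n
        bct[:, n - 1] = np.count_nonzero(flags[:, 1:] != flags[:, :-1], axis=1)
    if tie_rule == "pessimistic":
        # per-gene fallback only where ties exist
        svals = np.take_along_axis(values, sample_order, axis=1)
        has_tie = (np.diff(svals, axis=1) == 0).any(axis=1)
        for g in np.flatnonzero(has_tie):
            for n in range(1, K):
                flags = ranks_sorted[g] < n
                bct[g, n - 1] = _pessimistic_bct(svals[g], flags)
    elif tie_rule != "stable":
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")

    ovl = bct / n_s
    gmi = mu_sep / ovl
    return {
        "class_means": class_means,
        "class_order": order0 + 1,
        "sorted_means": sorted_means,
        "mu_sep": mu_sep,
        "bct": bct,
        "n_s": n_s,
        "ovl": ovl,
        "gmi": gmi,
    }


def level_profiles(
    data: LabeledExpressionMatrix,
    gene: "int | str",
    tie_rule: str = "stable",
) -> list[LevelProfile]:
    """All ``K-1`` level profiles for one gene of a normalized matrix.

    ``gene`` may be a row index or a gene id.  The matrix is expected to
    be min-max normalized per gene (values in [0, 1]).
    """
    if isinstance(gene, str):
        gene = data.gene_ids.index(gene)
    stats = gmi_statistics(data.values[gene : gene + 1], data.labels, tie_rule=tie_rule)
    K = data.K
    order = tuple(int(c) for c in stats["class_order"][0])
    profiles = []
    for n in range(1, K):
        profiles.append(
            LevelProfile(
                gene_id=data.gene_ids[gene],
                level=n,
                sorted_class_means=tuple(float(m) for m in stats["sorted_means"][0]),
                class_order=order,
                upper_group=order[:n],
                lower_group=order[n:],
                mu_sep=float(stats["mu_sep"][0, n - 1]),
                bct=int(stats["bct"][0, n - 1]),
                n_s=int(stats["n_s"][0, n - 1]),
                ovl=float(stats["ovl"][0, n - 1]),
                gmi=float(stats["gmi"][0, n - 1]),
            )
        )
    return profiles
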