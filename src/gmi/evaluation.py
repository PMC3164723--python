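"""Head-to-head assessment utilities.

Two independent ways to judge selected markers:

* :func:`loocv_nnc_accuracy` — how well a *single* gene separates two
  groups of samples, by leave-one-out nearest-neighbor classification on
  the gene's values alone.
* :func:`binary_template_correlation` and :func:`imbalance_curve` — the
  closed-form Pearson correlation between an idealized binary expression
  profile and a binary class template, as a function of the class sizes.
  The correlation grows monotonically with the size of the unexpressed
  pool even though no expression profile changes, which is the
  class-imbalance bias of template matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImbalanceScenario",
    "loocv_nnc_accuracy",
    "binary_template_correlation",
    "materialize_scenario",
    "imbalance_curve",
]


@dataclass(frozen=True)
class ImbalanceScenario:
    """Sample counts of the idealized template-matching scenario.

    A gene takes value 1 on all ``n1`` samples of class 1 and all ``n2``
    samples of class 2, and 0 on the pooled remaining ``n3`` samples.
    It is correlated with the ideal class-1 template (1 on class 1, 0
    elsewhere).  The optional extension adds one extra class of ``n4``
    samples that joins the template's expressed set and on which the
    gene is either uniformly expressed (``extra="up"``) or unexpressed
    (``extra="down"``).
    """

    n1: int
    n2: int
    n3: int
    n4: int = 0
    extra: str | None = None  # "up" | "down" when n4 > 0

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be >= 1")
        if min(self.n2, self.n3, self.n4) < 0:
            raise ValueError("sample counts must be nonnegative")
        if self.n1 + self.n2 + self.n3 < 2:
            raise ValueError("need at least 2 samples in total")
        if self.n4 > 0 and self.extra not in ("up", "down"):
            raise ValueError("extra must be 'up' or 'down' when n4 > 0")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4


def _binary_pearson(N: int, ones_x: int, ones_t: int, overlap: int) -> float:
    """Pearson correlation of two 0/1 vectors from their counts.

    ``ones_x``/``ones_t`` are the numbers of ones in each vector,
    ``overlap`` the number of positions where both are 1.
    """
    p = ones_x / N
    q = ones_t / N
    var = p * (1 - p) * q * (1 - q)
    if var <= 0:
        raise ValueError("both vectors must be non-constant (zero variance)")
    return (overlap / N - p * q) / np.sqrt(var)


def binary_template_correlation(scenario: ImbalanceScenario) -> float:
    """Closed-form Pearson correlation of the binary profile vs its template.

    For the base case (``n4 = 0``) with ``N = n1 + n2 + n3`` this is

        r = (n1/N - (n1+n2) n1 / N^2)
            / sqrt( (n1+n2)/N (1-(n1+n2)/N) * n1/N (1-n1/N) )

    whose limit as ``n3 -> inf`` is ``sqrt(n1 / (n1+n2))``: adding
    unexpressed samples inflates the correlation toward that ceiling.
    """
    s = scenario
    N = s.total
    if s.n4 == 0:
        return _binary_pearson(N, s.n1 + s.n2, s.n1, s.n1)
    if s.extra == "up":
        return _binary_pearson(N, s.n1 + s.n2 + s.n4, s.n1 + s.n4, s.n1 + s.n4)
    return _binary_pearson(N, s.n1 + s.n2, s.n1 + s.n4, s.n1)


def materialize_scenario(scenario: ImbalanceScenario) -> tuple[np.ndarray, np.ndarray]:
    """Explicit 0/1 profile and template vectors for a scenario.

    Sample order: class 1, class 2, pooled remainder, extra class.  Used
    as the empirical cross-check of the closed form.
    """
    s = scenario
    profile = np.concatenate(
        [
            np.ones(s.n1 + s.n2),
            np.zeros(s.n3),
            (np.ones if s.extra == "up" else np.zeros)(s.n4),
        ]
    )
    template = np.concatenate(
        [np.ones(s.n1), np.zeros(s.n2 + s.n3), np.ones(s.n4)]
    )
    return profile, template


def imbalance_curve(
    n1: int,
    n2: int,
    n3_grid: "np.ndarray | list[int]",
    extension: str = "none",
    n4: int = 5,
) -> np.ndarray:
    """Correlation as a function of the unexpressed-pool size ``n3``.

    ``extension`` is ``"none"`` for the base scenario or ``"up"``/
    ``"down"`` for the extra-class variants (extra class of ``n4``
    samples).  The base curve is monotone nondecreasing in ``n3`` and
    bounded above by ``sqrt(n1 / (n1+n2))``.
    """
    if extension not in ("none", "up", "down"):
        raise ValueError("extension must be 'none', 'up' or 'down'")
    out = np.empty(len(n3_grid))
    for i, n3 in enumerate(n3_grid):
        if extension == "none":
            s = ImbalanceScenario(n1, n2, int(n3))
        else:
            s = ImbalanceScenario(n1, n2, int(n3), n4=n4, extra=extension)
        out[i] = binary_template_correlation(s)
    return out


def loocv_nnc_accuracy(values: np.ndarray, group_flags: np.ndarray) -> float:
    """Leave-one-out nearest-neighbor accuracy of a single gene.

    Each sample is assigned the group of its nearest other sample by
    absolute difference of the gene's values; ties are broken in favor of
    the neighbor with the lowest sample index.  Returns the fraction of
    samples assigned their own group.
    """
    values = np.asarray(values, dtype=float).ravel()
    flags = np.asarray(group_flags).astype(bool).ravel()
    if values.shape != flags.shape:
        raise ValueError("values and group_flags must have the same length")
    S = values.size
    if S < 3:
        raise ValueError("need at least 3 samples")
    if flags.all() or not flags.any():
        raise ValueError("both groups must be nonempty")
    correct = 0
    for i in range(S):
        dist = np.abs(values - values[i])
        dist[i] = np.inf
        nearest = int(np.argmin(dist))  # argmin returns the lowest index on ties
        correct += flags[nearest] == flags[i]
    return correct / S
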