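"""Synthetic multi-class expression matrices with planted markers.

The generator emulates the structure the index is designed for: a
``K``-class matrix whose *planted* genes have a high Gaussian mean on a
chosen subset of classes (the upper group, defining the gene's true
level) and a low mean elsewhere, plus pure-noise genes drawn from one
shared distribution.  All values are clipped to [0, 1] so fixtures look
like per-gene min-max normalized data.  Outliers are implemented as
cross-group resampling — a fraction of a planted gene's samples is
redrawn from the opposite group's distribution — which provably raises
the gene's between-class-transition count, unlike additive shifts whose
effect depends on magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LabeledExpressionMatrix

__all__ = ["PlantedMarker", "SyntheticSpec", "generate"]


@dataclass(frozen=True)
class PlantedMarker:
    """A group of planted level-``len(upper)`` marker genes.

    Defaults place the upper-group mean 5 noise standard deviations above
    the lower-group mean, a separation at which recovery should be
    essentially certain.
    """

    upper: tuple[int, ...]
    upper_mean: float = 0.8
    lower_mean: float = 0.3
    noise_sd: float = 0.1
    count: int = 1

    @property
    def level(self) -> int:
        return len(self.upper)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-marker simulation.

    Defaults mirror a balanced five-class design with ten samples per
    class.  ``outlier_rate`` is the fraction of samples per planted gene
    redrawn from the opposite group's distribution.
    """

    class_sizes: tuple[int, ...] = (10, 10, 10, 10, 10)
    planted: tuple[PlantedMarker, ...] = field(default_factory=tuple)
    n_noise_genes: int = 0
    noise_mean: float = 0.5
    noise_sd: float = 0.15
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("every class must have at least one sample")
        K = len(self.class_sizes)
        for m in self.planted:
            if not m.upper or not set(m.upper) <= set(range(1, K + 1)):
                raise ValueError(f"planted upper group {m.upper} invalid for K={K}")
            if len(m.upper) >= K:
                raise ValueError("planted upper group must be a proper class subset")
            if m.noise_sd <= 0:
                raise ValueError("noise sd must be positive")
        if not (0.0 <= self.outlier_rate < 0.5):
            raise ValueError("outlier_rate must lie in [0, 0.5)")


def generate(spec: SyntheticSpec) -> tuple[LabeledExpressionMatrix, pd.DataFrame]:
    """Draw a labeled matrix and its ground-truth table.

    Returns the matrix (planted genes first, then noise genes) and a
    DataFrame with one row per planted gene: ``gene_id``, ``level``,
    ``upper_group`` (ascending class ids), ``upper_mean``,
    ``lower_mean``, ``noise_sd``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.class_sizes)
    labels = np.concatenate(
        [np.full(sz, k + 1, dtype=int) for k, sz in enumerate(spec.class_sizes)]
    )
    S = labels.size
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_rows: list[dict] = []
    g = 0
    for marker in spec.planted:
        in_upper = np.isin(labels, marker.upper)
        n_out = int(round(spec.outlier_rate * S))
        for _ in range(marker.count):
            means = np.where(in_upper, marker.upper_mean, marker.lower_mean)
            row = rng.normal(means, marker.noise_sd)
            if n_out:
                flip = rng.choice(S, size=n_out, replace=False)
                opposite = np.where(in_upper[flip], marker.lower_mean, marker.upper_mean)
                row[flip] = rng.normal(opposite, marker.noise_sd)
            rows.append(np.clip(row, 0.0, 1.0))
            gid = f"marker_{g:04d}"
            gene_ids.append(gid)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "level": marker.level,
                    "upper_group": ",".join(map(str, sorted(marker.upper))),
                    "upper_mean": marker.upper_mean,
                    "lower_mean": marker.lower_mean,
                    "noise_sd": marker.noise_sd,
                }
            )
            g += 1
    for i in range(spec.n_noise_genes):
        rows.append(np.clip(rng.normal(spec.noise_mean, spec.noise_sd, size=S), 0.0, 1.0))
        gene_ids.append(f"noise_{i:04d}")
    if not rows:
        raise ValueError("spec generates no genes")
    data = LabeledExpressionMatrix(
        values=np.vstack(rows),
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(f"s{j:03d}" for j in range(S)),
        labels=labels,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "level", "upper_group", "upper_mean", "lower_mean", "noise_sd"],
    )
    return data, truth
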