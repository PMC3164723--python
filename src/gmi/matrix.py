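"""Labeled gene-by-sample expression matrix.

The container used throughout the package: a dense genes x samples matrix
of expression values together with one class label per sample.  Class
labels are stored internally as integers ``1..K`` in the order the classes
first appear in the label source, which is also the convention used when
groups of classes are printed in result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["LabeledExpressionMatrix"]


@dataclass(frozen=True)
class LabeledExpressionMatrix:
    """Expression values for ``G`` genes across ``S`` labeled samples.

    Parameters
    ----------
    values
        ``(G, S)`` float array of expression values (any units).
    gene_ids
        Unique identifier per row.
    sample_ids
        Unique identifier per column.
    labels
        Integer class label per sample, taking every value in ``1..K``
        at least once.
    class_names
        Optional original class names, ``class_names[k-1]`` being the
        name mapped to integer label ``k``.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: np.ndarray
    class_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        G, S = values.shape
        if len(self.gene_ids) != G:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.sample_ids) != S:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {S} columns")
        if labels.shape != (S,):
            raise ValueError(
                f"number of labels ({labels.size}) must equal number of samples ({S})"
            )
        if len(set(self.gene_ids)) != G:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != S:
            raise ValueError("sample_ids must be unique")
        K = int(labels.max(initial=0))
        if labels.size and (labels.min() < 1 or set(np.unique(labels)) != set(range(1, K + 1))):
            raise ValueError("labels must cover every class in 1..K")
        if self.class_names is not None and len(self.class_names) != K:
            raise ValueError("class_names must have one entry per class")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        """Number of distinct classes."""
        return int(self.labels.max())

    def class_sizes(self) -> np.ndarray:
        """Sample count per class, index ``k-1`` for class ``k``."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    # ------------------------------------------------------------------
    def with_values(self, values: np.ndarray) -> "LabeledExpressionMatrix":
        """Return a copy with the same annotation but new values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_samples(self, indices: np.ndarray) -> "LabeledExpressionMatrix":
        """Restrict to a subset of sample columns (e.g. a training split)."""
        indices = np.asarray(indices, dtype=int)
        return LabeledExpressionMatrix(
            values=self.values[:, indices],
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in indices),
            labels=self.labels[indices],
            class_names=self.class_names,
        )

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        labels: "pd.Series | dict[str, object]",
    ) -> "LabeledExpressionMatrix":
        """Build from a genes x samples DataFrame and a sample -> class mapping.

        Classes are numbered ``1..K`` in order of first appearance over the
        matrix's sample columns.
        """
        if isinstance(labels, dict):
            labels = pd.Series(labels)
        missing = [s for s in frame.columns if s not in labels.index]
        if missing:
            raise ValueError(f"samples missing from labels: {missing}")
        raw = [labels[s] for s in frame.columns]
        names: list[object] = []
        for name in raw:
            if name not in names:
                names.append(name)
        codes = np.array([names.index(name) + 1 for name in raw], dtype=int)
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=tuple(map(str, frame.index)),
            sample_ids=tuple(map(str, frame.columns)),
            labels=codes,
            class_names=tuple(map(str, names)),
        )
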