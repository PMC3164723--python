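"""Scatter plot of one gene's normalized values, one symbol per class."""

from __future__ import annotations

import numpy as np

from .matrix import LabeledExpressionMatrix

__all__ = ["scatter_gene"]


def scatter_gene(
    data: LabeledExpressionMatrix,
    gene: "int | str",
    upper_group: "tuple[int, ...] | None" = None,
    ax=None,
):
    """Plot a gene's values against sample index, colored by class.

    If ``upper_group`` is given, upper-group samples are drawn filled and
    lower-group samples open.  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(gene, str):
        gene = data.gene_ids.index(gene)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(data.n_samples)
    y = data.values[gene]
    cmap = plt.get_cmap("tab10")
    for k in range(1, data.K + 1):
        mask = data.labels == k
        name = data.class_names[k - 1] if data.class_names else f"class {k}"
        filled = upper_group is None or k in upper_group
        ax.scatter(
            x[mask],
            y[mask],
            s=25,
            label=name,
            facecolors=cmap(k - 1) if filled else "none",
            edgecolors=cmap(k - 1),
        )
    ax.set_xlabel("sample index")
    ax.set_ylabel("normalized expression")
    ax.set_title(data.gene_ids[gene])
    ax.legend(fontsize="small", ncol=min(data.K, 5))
    return ax
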