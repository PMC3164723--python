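"""Dataset-level preprocessing and per-gene [0, 1] normalization.

Two protocols are provided, mirroring common microarray practice:

* ``leukemia-cns`` — clip raw intensities to a floor/ceiling (defaults 100
  and 16000), take base-10 logarithms, then standardize every sample
  (column) to zero mean and unit variance across genes.
* ``identity`` — leave the values untouched (for matrices that ship
  already preprocessed).

Independently of the protocol, the index computation always operates on
per-gene min-max normalized values in ``[0, 1]``; :func:`minmax_per_gene`
performs that mapping.
"""

from __future__ import annotations

import numpy as np

from .matrix import LabeledExpressionMatrix

__all__ = [
    "clip_log_standardize",
    "minmax_per_gene",
    "minmax_rows",
    "apply_protocol",
    "PROTOCOLS",
]

#: Column standardization uses the sample standard deviation (n-1 denominator).
STD_DDOF = 1


def clip_log_standardize(
    data: LabeledExpressionMatrix,
    floor: float = 100.0,
    ceiling: float = 16000.0,
) -> LabeledExpressionMatrix:
    """Clip to ``[floor, ceiling]``, log10-transform, standardize columns.

    Values below ``floor`` are raised to ``floor`` and values above
    ``ceiling`` lowered to ``ceiling`` before the logarithm, so the result
    is always finite for positive ``floor``.  Each sample column is then
    shifted and scaled to zero mean and unit variance across its genes
    (``ddof=1``).

    Raises
    ------
    ValueError
        If any input value is non-finite (reported with gene/sample
        coordinates) or a column is constant after clip+log (reported with
        the sample id).
    """
    if not (floor > 0):
        raise ValueError("floor must be positive (log10 is applied)")
    if not (ceiling > floor):
        raise ValueError("ceiling must exceed floor")
    values = data.values
    bad = ~np.isfinite(values)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite expression value at gene {data.gene_ids[g]!r}, "
            f"sample {data.sample_ids[s]!r}"
        )
    clipped = np.clip(values, floor, ceiling)
    logged = np.log10(clipped)
    sd = logged.std(axis=0, ddof=STD_DDOF)
    zero = np.flatnonzero(~(sd > 0))
    if zero.size:
        raise ValueError(
            f"sample {data.sample_ids[zero[0]]!r} has zero variance after "
            "clip+log; cannot standardize"
        )
    standardized = (logged - logged.mean(axis=0)) / sd
    return data.with_values(standardized)


def minmax_rows(values: np.ndarray) -> np.ndarray:
    """Min-max map each row of ``values`` to [0, 1]; constant rows map to 0."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    nonconst = (span > 0).ravel()
    out[nonconst] = (values[nonconst] - lo[nonconst]) / span[nonconst]
    return out


def minmax_per_gene(data: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """Normalize each gene row to [0, 1] across the samples present.

    A constant row is mapped to all zeros: a gene with no variation has no
    discriminating power and this convention gives it an index of zero at
    every level downstream.
    """
    if data.n_samples < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    return data.with_values(minmax_rows(data.values))


PROTOCOLS = ("leukemia-cns", "identity")


def apply_protocol(
    data: LabeledExpressionMatrix,
    protocol: str,
    floor: float = 100.0,
    ceiling: float = 16000.0,
) -> LabeledExpressionMatrix:
    """Apply a named dataset preprocessing protocol."""
    if protocol == "leukemia-cns":
        return clip_log_standardize(data, floor=floor, ceiling=ceiling)
    if protocol == "identity":
        return data
    raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
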