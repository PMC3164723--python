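"""Tab-delimited readers and writers.

Matrix files: genes in rows, samples in columns, first column gene ids,
header row sample ids.  Label files: two tab-delimited columns (sample
id, class name), order-independent, matched by sample id; classes are
numbered ``1..K`` in the order they first appear in the label file.

Result tables carry a commented provenance header (``# key: value``
lines) recording the seed and parameters of the run.  Class groups are
encoded as concatenated class indices in descending-mean order (e.g.
``143`` = classes 1, 4, 3); a ``-`` separator is used if any class index
has more than one digit.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .matrix import LabeledExpressionMatrix
from .selection import SelectionRecord
from .tbm import TemplateRecord

__all__ = [
    "read_expression",
    "write_expression",
    "write_labels",
    "encode_group",
    "decode_group",
    "write_records",
    "read_records",
    "write_template_records",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "Level",
    "Probe ID",
    "Gene Symbol",
    "Upper Group",
    "Lower Group",
    "Freq.",
    "Ave. GMI value",
    "p-value",
    "q-value",
]


def read_expression(matrix_path, labels_path) -> LabeledExpressionMatrix:
    """Read a gene x sample matrix and its sample labels.

    Duplicate gene ids are disambiguated by suffixing the row index (and
    logged); a sample present in the matrix but absent from the label
    file is an error.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        frame = frame.astype(float)
    except ValueError:
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                gene = frame.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at gene {gene!r}, sample {col!r} "
                    f"in {matrix_path}"
                ) from None
        raise
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        logger.warning("duplicate gene ids %s; suffixing row indices", dupes)
        frame.index = [
            f"{g}_{i}" if dup else str(g)
            for i, (g, dup) in enumerate(zip(frame.index, frame.index.duplicated(keep=False)))
        ]
    labels = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "class"], dtype=str,
        comment="#",
    ).set_index("sample")["class"]
    missing = [s for s in frame.columns if s not in labels.index]
    if missing:
        raise ValueError(f"label file is missing sample(s): {missing}")
    return LabeledExpressionMatrix.from_dataframe(frame, labels)


def write_expression(data: LabeledExpressionMatrix, path) -> None:
    data.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


def write_labels(data: LabeledExpressionMatrix, path) -> None:
    names = data.class_names or tuple(str(k) for k in range(1, data.K + 1))
    with open(path, "w") as fh:
        for sample, label in zip(data.sample_ids, data.labels):
            fh.write(f"{sample}\t{names[label - 1]}\n")


def encode_group(classes: Iterable[int]) -> str:
    """``(1, 4, 3) -> "143"`` (or ``"1-4-3"`` with double-digit classes)."""
    classes = [int(c) for c in classes]
    sep = "-" if any(c > 9 for c in classes) else ""
    return sep.join(str(c) for c in classes)


def decode_group(text: str) -> tuple[int, ...]:
    text = str(text)
    if "-" in text:
        return tuple(int(c) for c in text.split("-"))
    return tuple(int(c) for c in text)


def _provenance(fh, params: "Mapping | None") -> None:
    for key, value in (params or {}).items():
        fh.write(f"# {key}: {value}\n")


def write_records(
    records: "dict[int, list[SelectionRecord]] | list[SelectionRecord]",
    path,
    symbols: "Mapping[str, str] | None" = None,
    params: "Mapping | None" = None,
) -> None:
    """Write selection records as a TSV with the standard table columns."""
    if isinstance(records, dict):
        flat = [r for level in sorted(records) for r in records[level]]
    else:
        flat = list(records)
    symbols = symbols or {}

    def fmt(v):
        return "" if v is None else repr(float(v))

    with open(path, "w") as fh:
        _provenance(fh, params)
        fh.write("\t".join(RECORD_COLUMNS) + "\n")
        for r in flat:
            fh.write(
                "\t".join(
                    [
                        str(r.level),
                        r.gene_id,
                        symbols.get(r.gene_id, ""),
                        encode_group(r.upper_group),
                        encode_group(r.lower_group),
                        str(r.freq),
                        repr(float(r.ave_gmi)),
                        fmt(r.p_value),
                        fmt(r.q_value),
                    ]
                )
                + "\n"
            )


def read_records(path) -> list[SelectionRecord]:
    """Round-trip reader for :func:`write_records` output."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"Probe ID": str})
    out = []
    for _, row in frame.iterrows():
        out.append(
            SelectionRecord(
                gene_id=str(row["Probe ID"]),
                level=int(row["Level"]),
                upper_group=decode_group(row["Upper Group"]),
                lower_group=decode_group(row["Lower Group"]),
                freq=int(row["Freq."]),
                ave_gmi=float(row["Ave. GMI value"]),
                p_value=None if pd.isna(row["p-value"]) else float(row["p-value"]),
                q_value=None if pd.isna(row["q-value"]) else float(row["q-value"]),
            )
        )
    return out


def write_template_records(
    records: "dict[int, list[TemplateRecord]]",
    path,
    params: "Mapping | None" = None,
) -> None:
    """Write template-method records (rank, template, frequency) as TSV."""
    with open(path, "w") as fh:
        _provenance(fh, params)
        fh.write("Level\tTBM Rank\tProbe ID\tTBM Template\tTBM Corr.\tTBM Freq.\n")
        for level in sorted(records):
            for rank, r in enumerate(records[level], start=1):
                upper = encode_group(r.best_combination)
                fh.write(
                    f"{level}\t{rank}\t{r.gene_id}\t({upper})\t"
                    f"{r.best_correlation:.4f}\t{r.freq}\n"
                )
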