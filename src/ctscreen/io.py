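"""TSV readers/writers for the pipeline's tabular formats.

All files are UTF-8 tab-separated with '.' as the decimal separator.
Expression values are written with four decimal places so that repeated
write/read/write cycles are byte-stable across platforms.

Formats:

* expression matrix — header ``probeset_id<TAB>sample...``, one row per
  probeset;
* sample annotation — columns ``sample_id, group_id, category,
  matched_normal, label`` (``matched_normal`` empty unless the group is a
  cancer subtype);
* probeset annotation — columns ``probeset_id, gene_symbol`` (empty symbol
  = unmapped probeset).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputFormatError
from .model import ExpressionMatrix, ProbesetAnnotation, SampleAnnotation

FLOAT_FORMAT = "%.4f"

SAMPLE_COLUMNS = ["sample_id", "group_id", "category", "matched_normal", "label"]
PROBESET_COLUMNS = ["probeset_id", "gene_symbol"]


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except pd.errors.ParserError as exc:
        raise InputFormatError(f"{path}: malformed TSV: {exc}") from exc


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a log2 expression matrix; first column must be ``probeset_id``."""
    if not Path(path).exists():
        raise InputFormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # check the raw header: pandas would silently mangle duplicates
    dup_cols = pd.Index(header[1:])
    if dup_cols.has_duplicates:
        dups = dup_cols[dup_cols.duplicated()].unique().tolist()
        raise InputFormatError(f"{path}: duplicated sample header(s): {dups[:5]}")
    df = _read_tsv(path)
    if df.columns[0] != "probeset_id":
        raise InputFormatError(
            f"{path}: first column header must be 'probeset_id', got {df.columns[0]!r}"
        )
    df = df.set_index("probeset_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputFormatError(f"{path}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probeset_id", float_format=FLOAT_FORMAT)


def read_sample_annotation(path) -> SampleAnnotation:
    df = _read_tsv(path)
    missing = [c for c in SAMPLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    if "label" not in df.columns:
        df["label"] = ""
    samples = df.set_index("sample_id")[["group_id"]]
    groups = (
        df.drop_duplicates("group_id")
        .set_index("group_id")[["category", "matched_normal", "label"]]
    )
    # a group must not be annotated inconsistently across its samples
    chk = df.groupby("group_id")[["category", "matched_normal"]].nunique()
    bad = chk.index[(chk > 1).any(axis=1)].tolist()
    if bad:
        raise InputFormatError(f"{path}: inconsistent group annotation for {bad[:5]}")
    return SampleAnnotation(samples=samples, groups=groups)


def write_sample_annotation(annot: SampleAnnotation, path) -> None:
    df = annot.samples.reset_index()
    df.columns = ["sample_id", "group_id"]
    df = df.join(annot.groups, on="group_id")
    df[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probeset_annotation(path) -> ProbesetAnnotation:
    df = _read_tsv(path)
    missing = [c for c in PROBESET_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    return ProbesetAnnotation(df.set_index("probeset_id")["gene_symbol"])


def write_probeset_annotation(annot: ProbesetAnnotation, path) -> None:
    annot.mapping.rename_axis("probeset_id").reset_index().to_csv(path, sep="\t", index=False)
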