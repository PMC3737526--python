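"""Delimited-text readers and writers.

Expression matrices are genes x samples TSV (comma via ``delimiter``):
first column gene IDs, header row sample IDs.  Correlation-feature
matrices are square TSV with sample IDs on both axes.  Label files are
two columns (sample_id, label).  Writers prepend ``#``-prefixed comment
lines recording the tool version, the command and the seed; readers
skip them.  Values are written with 10 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import CorrelationFeatures, ExpressionMatrix
from .errors import DuplicateSampleID, ParseError


def _split_header(path: Path, delimiter: str) -> list[str]:
    """IDs from the first non-comment line of a delimited file."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return line.rstrip("\n").split(delimiter)[1:]
    raise ParseError(f"{path}: no header line found")


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples matrix.

    missing_policy: ``"error"`` rejects any empty or non-numeric cell;
    ``"drop"`` removes gene rows containing one.
    """
    path = Path(path)
    header_ids = _split_header(path, delimiter)
    dupes = sorted({s for s in header_ids if header_ids.count(s) > 1})
    if dupes:
        raise DuplicateSampleID(f"{path}: duplicate sample columns {dupes}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        if missing_policy == "drop":
            df = df.loc[~bad]
            if df.empty:
                raise ParseError(f"{path}: every gene row had missing values")
        else:
            rows = [str(g) for g in df.index[bad][:5]]
            raise ParseError(
                f"{path}: missing or non-numeric values in gene rows {rows}; "
                "use missing_policy='drop' to discard them"
            )
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=header_ids,
    )


def _metadata_header(metadata: Mapping[str, object] | None) -> str:
    lines = [f"# ipcc {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: Path, delimiter: str, metadata) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep=delimiter, float_format="%.10g")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        fh.write(buf.getvalue())


def write_expression(
    X: ExpressionMatrix,
    path: str | Path,
    delimiter: str = "\t",
    metadata: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    _write_frame(df, Path(path), delimiter, metadata)


def write_features(
    C: CorrelationFeatures,
    path: str | Path,
    delimiter: str = "\t",
    metadata: Mapping[str, object] | None = None,
) -> None:
    meta = {"order": C.order, **(metadata or {})}
    df = pd.DataFrame(C.values, index=C.sample_ids, columns=C.sample_ids)
    df.index.name = "sample_id"
    _write_frame(df, Path(path), delimiter, meta)


def read_features(path: str | Path, delimiter: str = "\t", order: int = 1) -> CorrelationFeatures:
    """Read a square correlation-feature matrix written by :func:`write_features`.

    The stored order is recovered from the ``# order:`` comment when
    present; ``order`` is the fallback.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.startswith("# order:"):
                order = int(line.split(":", 1)[1])
            elif not line.startswith("#"):
                break
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ParseError(f"{path}: feature matrix must be square, got {values.shape}")
    return CorrelationFeatures(values=values, order=order, sample_ids=[str(s) for s in df.index])


def read_labels(path: str | Path, delimiter: str = "\t", header: bool = True) -> dict[str, str]:
    """Two-column (sample_id, label) file as a mapping; order-independent."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        lines = [
            ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")
        ]
    if header:
        lines = lines[1:]
    if not lines:
        raise ParseError(f"{path}: no label rows found")
    for i, line in enumerate(lines, start=2 if header else 1):
        parts = line.split(delimiter)
        if len(parts) < 2:
            raise ParseError(f"{path}: line {i}: expected 2 columns, got {len(parts)}")
        mapping[parts[0]] = parts[1]
    return mapping


def write_labels(
    labels: Mapping[str, str],
    path: str | Path,
    delimiter: str = "\t",
    columns: tuple[str, str] = ("sample_id", "label"),
    metadata: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        fh.write(delimiter.join(columns) + "\n")
        for s, lab in labels.items():
            fh.write(f"{s}{delimiter}{lab}\n")


def reconcile_labels(
    labels: Mapping[str, str], sample_ids, strict: bool = True, warn=None
) -> dict[str, str]:
    """Join labels onto a matrix's samples.

    Extra labelled samples absent from the matrix are dropped (with a
    warning via ``warn`` when given).  Matrix samples without labels are
    an error when ``strict`` (supervised operations) and a warning
    otherwise.
    """
    from .errors import UnknownSample

    ids = list(sample_ids)
    extra = sorted(set(labels) - set(ids))
    missing = [s for s in ids if s not in labels]
    if extra and warn is not None:
        warn(f"dropping {len(extra)} labelled samples absent from the matrix: {extra[:5]}")
    if missing:
        if strict:
            raise UnknownSample(f"samples without labels: {missing[:5]}")
        if warn is not None:
            warn(f"{len(missing)} samples have no label: {missing[:5]}")
    return {s: labels[s] for s in ids if s in labels}
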