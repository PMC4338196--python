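"""Readers and writers for expression matrices, annotations and reports.

Formats are deliberately plain: tab-separated matrices with a ``probe_id``
first column and an optional ``# scale=linear|log2`` header line, a
GEO Series-Matrix-style dialect ("!"-prefixed metadata lines ignored),
annotation TSVs, CSV reports, and JSON discriminant models.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ClinicalGroup,
    DiscriminantModel,
    ExpressionMatrix,
    SampleAnnotation,
    check_unique_sample_ids,
    parse_group,
)

PathLike = Union[str, Path]

_SCALE_PREFIX = "# scale="


def _parse_float(token: str, line_no: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric cell {token!r} at line {line_no}, column {col + 1}"
        ) from None


def _read_table_lines(lines: Iterable[tuple[int, str]], sep: str = "\t"):
    """Parse (line_no, text) pairs into header + rows, checking raggedness."""
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    for line_no, text in lines:
        fields = text.rstrip("\n").split(sep)
        if header is None:
            header = fields
            continue
        if len(fields) != len(header):
            raise ValueError(
                f"ragged row at line {line_no}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        rows.append((line_no, fields))
    if header is None:
        raise ValueError("empty table")
    return header, rows


def read_expression_matrix(
    path: PathLike, dialect: str = "tsv", scale: str | None = None
) -> ExpressionMatrix:
    """Read a probe x sample expression matrix.

    Parameters
    ----------
    path
        TSV file: first column probe IDs, header row sample IDs.  A leading
        ``# scale=linear|log2`` line tags the storage scale.
    dialect
        ``"tsv"`` (default) or ``"series_matrix"``: the latter skips
        "!"-prefixed metadata lines and, when present, restricts parsing to
        the region between ``!series_matrix_table_begin`` and
        ``!series_matrix_table_end``.
    scale
        Override the scale when the file carries no tag (default log2).
    """
    if dialect not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw_lines = path.read_text().splitlines()

    file_scale: str | None = None
    numbered = list(enumerate(raw_lines, start=1))
    kept: list[tuple[int, str]] = []
    if dialect == "series_matrix":
        begin = [i for i, (_, t) in enumerate(numbered) if t.startswith("!series_matrix_table_begin")]
        end = [i for i, (_, t) in enumerate(numbered) if t.startswith("!series_matrix_table_end")]
        if begin and end:
            numbered = numbered[begin[0] + 1 : end[0]]
        numbered = [(n, t) for n, t in numbered if not t.startswith("!")]
    for line_no, text in numbered:
        if text.startswith(_SCALE_PREFIX):
            file_scale = text[len(_SCALE_PREFIX):].strip()
            continue
        if text.startswith("#") or not text.strip():
            continue
        kept.append((line_no, text))

    header, rows = _read_table_lines(kept)
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    probe_ids: list[str] = []
    data = np.empty((len(rows), len(sample_ids)), dtype=float)
    seen: set[str] = set()
    for r, (line_no, fields) in enumerate(rows):
        pid = fields[0].strip().strip('"')
        if pid in seen:
            raise ValueError(f"duplicate probe ID {pid!r} at line {line_no}")
        seen.add(pid)
        probe_ids.append(pid)
        for c, tok in enumerate(fields[1:]):
            data[r, c] = _parse_float(tok.strip().strip('"'), line_no, c + 1)

    resolved = file_scale or scale or "log2"
    values = pd.DataFrame(data, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(values=values, scale=resolved)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    """Write a matrix as TSV with its ``# scale=`` tag, 6 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_SCALE_PREFIX}{matrix.scale}\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in matrix.values.iterrows():
            fh.write(str(pid) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


_OPTIONAL_ANN_COLS = ("stage", "operable", "ca19_9", "cea", "d_bilirubin")


def read_annotations(path: PathLike) -> list[SampleAnnotation]:
    """Read a sample-annotation TSV (columns sample_id, group, optional
    stage/operable/ca19_9/cea/d_bilirubin); blank optional cells mean the
    covariate is unavailable."""
    path = Path(path)
    lines = [
        (n, t)
        for n, t in enumerate(path.read_text().splitlines(), start=1)
        if t.strip() and not t.startswith("#")
    ]
    header, rows = _read_table_lines(lines)
    cols = {name: i for i, name in enumerate(header)}
    for required in ("sample_id", "group"):
        if required not in cols:
            raise ValueError(f"annotation file lacks required column {required!r}")

    annotations: list[SampleAnnotation] = []
    for line_no, fields in rows:
        def opt(name: str) -> str | None:
            if name not in cols:
                return None
            v = fields[cols[name]].strip()
            return v or None

        operable_raw = opt("operable")
        operable = None
        if operable_raw is not None:
            if operable_raw.lower() in ("true", "1", "yes"):
                operable = True
            elif operable_raw.lower() in ("false", "0", "no"):
                operable = False
            else:
                raise ValueError(f"bad operable value {operable_raw!r} at line {line_no}")

        def num(name: str) -> float | None:
            v = opt(name)
            return None if v is None else _parse_float(v, line_no, cols[name])

        annotations.append(
            SampleAnnotation(
                sample_id=fields[cols["sample_id"]].strip(),
                group=parse_group(fields[cols["group"]]),
                stage=opt("stage"),
                operable=operable,
                ca19_9=num("ca19_9"),
                cea=num("cea"),
                d_bilirubin=num("d_bilirubin"),
            )
        )
    check_unique_sample_ids(annotations)
    return annotations


def write_annotations(annotations: Sequence[SampleAnnotation], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tgroup\t" + "\t".join(_OPTIONAL_ANN_COLS) + "\n")
        for ann in annotations:
            cells = [ann.sample_id, ann.group.value]
            for name in _OPTIONAL_ANN_COLS:
                v = getattr(ann, name)
                if v is None:
                    cells.append("")
                elif isinstance(v, bool):
                    cells.append("true" if v else "false")
                elif isinstance(v, float):
                    cells.append(f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def _record_to_row(obj, prefix: str = "") -> dict:
    from .performance import ConfusionCounts

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        row = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            key = f"{prefix}{f.name}"
            if isinstance(v, ClinicalGroup):
                v = v.value
            elif isinstance(v, DiscriminantModel):
                row[f"{key}_markers"] = ";".join(v.marker_ids)
                row[f"{key}_weights"] = ";".join(f"{w:.6g}" for w in v.weights)
                row[f"{key}_intercept"] = float(f"{v.intercept:.6g}")
                continue
            elif dataclasses.is_dataclass(v) and not isinstance(v, type):
                row.update(_record_to_row(v, prefix=f"{key}_"))
                if isinstance(v, ConfusionCounts):
                    row[f"{key}_sensitivity"] = v.sensitivity
                    row[f"{key}_specificity"] = v.specificity
                    row[f"{key}_accuracy"] = v.accuracy
                continue
            elif isinstance(v, np.ndarray):
                v = ";".join(f"{x:.6g}" for x in v)
            elif isinstance(v, (list, tuple, set, frozenset)):
                v = ";".join(str(x) for x in v)
            elif isinstance(v, dict):
                v = ";".join(f"{k}={x}" for k, x in v.items())
            row[key] = v
        return row
    if isinstance(obj, dict):
        return dict(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_results(objects, path: PathLike, columns: Sequence[str] | None = None) -> None:
    """Write a report (list of dataclass records, dicts, or a DataFrame) as
    CSV with deterministic column order and 6-significant-digit floats."""
    path = Path(path)
    if isinstance(objects, pd.DataFrame):
        df = objects
    else:
        rows = [_record_to_row(o) for o in objects]
        if not rows:
            df = pd.DataFrame(columns=list(columns) if columns else [])
        else:
            df = pd.DataFrame(rows)
    if columns:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False, float_format="%.6g")


def write_model(model: DiscriminantModel, path: PathLike) -> None:
    payload = {
        "marker_ids": model.marker_ids,
        "weights": [float(w) for w in model.weights],
        "intercept": float(model.intercept),
        "training_comparison": model.training_comparison,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: PathLike) -> DiscriminantModel:
    payload = json.loads(Path(path).read_text())
    return DiscriminantModel(
        marker_ids=list(payload["marker_ids"]),
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=float(payload["intercept"]),
        training_comparison=payload.get("training_comparison", ""),
    )
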