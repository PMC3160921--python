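"""CSV and YAML input/output.

Dataset CSV (UTF-8, header row), two dialects:

* single-cause: ``id,true_cause,predicted_cause``
* ranked: ``id,true_cause,cause_1,prob_1,cause_2,prob_2,...`` — trailing
  empty pairs are allowed for deaths with shorter ranked lists.

Matrix CSV: first row and first column are cause labels; the body is the
row-stochastic misclassification matrix.

Run configurations are YAML mappings of :class:`ResamplingConfig` fields.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .core import CauseList, DataError, DeathRecord, ValidationDataset
from .resampling import ResamplingConfig
from .simulate import MisclassificationMatrix

PathLike = Union[str, Path]


def _parse_single_row(row: dict, line: int) -> DeathRecord:
    return DeathRecord(
        id=row["id"], true_cause=row["true_cause"], prediction=row["predicted_cause"]
    )


def _parse_ranked_row(row: list[str], line: int) -> DeathRecord:
    rec_id, true_cause, *rest = row
    if len(rest) % 2:
        raise DataError(f"line {line}: ranked columns must come in (cause, prob) pairs")
    pairs = []
    for cause, prob in zip(rest[::2], rest[1::2]):
        if not cause.strip() and not prob.strip():
            continue
        try:
            pairs.append((cause, float(prob)))
        except ValueError:
            raise DataError(f"line {line}: probability {prob!r} is not a number") from None
    if not pairs:
        raise DataError(f"line {line}: no ranked causes given")
    return DeathRecord(id=rec_id, true_cause=true_cause, prediction=tuple(pairs))


def read_dataset_csv(path: PathLike, causes: CauseList | None = None) -> ValidationDataset:
    """Read a validation dataset, inferring the dialect from the header.

    If `causes` is omitted, the cause list is the sorted union of all
    true and predicted causes in the file.
    """
    path = Path(path)
    records: list[DeathRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if header[:2] != ["id", "true_cause"]:
            raise DataError(
                f"{path} line 1: header must start with 'id,true_cause', got {header[:2]}"
            )
        ranked = header[2:3] != ["predicted_cause"]
        for line, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise DataError(f"{path} line {line}: expected at least 3 columns")
            try:
                if ranked:
                    records.append(_parse_ranked_row(row, line))
                else:
                    records.append(
                        DeathRecord(id=row[0], true_cause=row[1], prediction=row[2])
                    )
            except DataError as exc:
                raise DataError(f"{path}: {exc}") from None
    if not records:
        raise DataError(f"{path}: no records")
    if causes is None:
        seen: set[str] = set()
        for rec in records:
            seen.add(rec.true_cause.strip())
            if isinstance(rec.prediction, str):
                seen.add(rec.prediction.strip())
            else:
                seen.update(c.strip() for c, _ in rec.prediction)
        causes = CauseList(tuple(sorted(seen)))
    return ValidationDataset(causes, tuple(records))


def write_dataset_csv(dataset: ValidationDataset, path: PathLike) -> None:
    path = Path(path)
    ranked = dataset.has_ranked
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if ranked:
            max_k = max(
                len(rec.prediction) if rec.is_ranked else 1 for rec in dataset.records
            )
            header = ["id", "true_cause"]
            for k in range(1, max_k + 1):
                header += [f"cause_{k}", f"prob_{k}"]
            writer.writerow(header)
            for rec in dataset.records:
                pairs = (
                    rec.prediction
                    if rec.is_ranked
                    else ((rec.prediction, 1.0),)
                )
                row = [rec.id, rec.true_cause]
                for cause, prob in pairs:
                    row += [cause, repr(prob)]
                row += [""] * (2 * max_k - 2 * len(pairs))
                writer.writerow(row)
        else:
            writer.writerow(["id", "true_cause", "predicted_cause"])
            for rec in dataset.records:
                writer.writerow([rec.id, rec.true_cause, rec.prediction])


def read_matrix_csv(path: PathLike) -> MisclassificationMatrix:
    """Read a misclassification matrix (labels in first row and column)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if any(cell.strip() for cell in r)]
    if len(rows) < 3:
        raise DataError(f"{path}: need at least two causes")
    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels = [r[0].strip() for r in rows[1:]]
    if col_labels != row_labels:
        raise DataError(
            f"{path}: row labels {row_labels} do not match column labels {col_labels}"
        )
    try:
        probs = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric matrix entry ({exc})") from None
    return MisclassificationMatrix(CauseList(tuple(col_labels)), probs)


def write_matrix_csv(matrix: MisclassificationMatrix, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(matrix.causes.labels))
        for label, row in zip(matrix.causes.labels, matrix.probs):
            writer.writerow([label] + [repr(float(x)) for x in row])


def read_config_yaml(path: PathLike) -> ResamplingConfig:
    """Read a resampling configuration from a YAML mapping."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise DataError(f"{path}: config must be a YAML mapping")
    known = set(ResamplingConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
    return ResamplingConfig(**data)
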