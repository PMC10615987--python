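"""Reading and writing response matrices, Q-matrices and result reports.

CSV conventions: comma-separated 0/1 cells, respondents (or items) as rows.
A single leading header row is auto-detected and skipped.  Parse errors name
the offending row and column.  Reports are written as full-precision JSON for
machines and 4-decimal CSV for tables.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .qmatrix import QMatrix, ValidationError
from .reliability import ReliabilityReport
from .simulate import ConditionSummary

__all__ = [
    "ParseError",
    "RunConfig",
    "read_response_csv",
    "read_qmatrix_csv",
    "write_matrix_csv",
    "write_report",
]


class ParseError(ValueError):
    """Raised when an input file is malformed; the message names the cell."""


@dataclasses.dataclass
class RunConfig:
    """Serializable record of one run's options; logged next to every output."""

    command: str
    options: dict

    def to_dict(self) -> dict:
        return {"command": self.command, "options": self.options}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(command=d["command"], options=dict(d["options"]))


def _read_binary_csv(path) -> np.ndarray:
    path = Path(path)
    rows: list[list[int]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for i, raw in enumerate(reader, start=1):
            cells = [c.strip() for c in raw]
            if not any(cells):
                continue
            if i == 1 and not all(c in ("0", "1") for c in cells):
                continue  # header row
            row = []
            for j, c in enumerate(cells, start=1):
                if c not in ("0", "1"):
                    raise ParseError(
                        f"{path}: non-binary value {c!r} at row {i}, column {j}"
                    )
                row.append(int(c))
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.array(rows, dtype=np.int8)


def read_response_csv(path) -> np.ndarray:
    """Load a persons × items binary response matrix."""
    return _read_binary_csv(path)


def read_qmatrix_csv(path) -> QMatrix:
    """Load and validate an items × attributes Q-matrix."""
    try:
        return QMatrix(_read_binary_csv(path))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_matrix_csv(matrix: np.ndarray, path, header: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(header)
        writer.writerows(np.asarray(matrix).tolist())


def _summary_dict(summary: ConditionSummary) -> dict:
    cond = dataclasses.asdict(summary.condition)
    return {
        "condition": cond,
        "mean_pcv": summary.mean_pcv,
        "mean_pca": list(summary.mean_pca),
        "mean_tau_em": summary.mean_tau_em,
        "mean_tau_mi": summary.mean_tau_mi,
        "mean_tau_k_em": list(summary.mean_tau_k_em),
        "mean_tau_k_mi": list(summary.mean_tau_k_mi),
        "rmse_tau_em": summary.rmse_tau_em,
        "rmse_tau_mi": summary.rmse_tau_mi,
        "rmse_tau_k_em": summary.rmse_tau_k_em,
        "rmse_tau_k_mi": summary.rmse_tau_k_mi,
        "mae_tau_em": summary.mae_tau_em,
        "mae_tau_mi": summary.mae_tau_mi,
        "n_failed": summary.n_failed,
        **summary.extra,
    }


def write_report(
    report: ReliabilityReport | ConditionSummary,
    path,
    config: RunConfig | None = None,
) -> None:
    """Write a report as JSON (full precision) and CSV (4 decimals).

    ``path`` is the JSON destination; the CSV goes next to it with the same
    stem.  ConditionSummary additionally gets a ``*_records.csv`` with the
    per-replication values.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(report, ReliabilityReport):
        doc = report.to_dict()
        csv_rows = [["index", "value"], ["tau", f"{report.tau:.4f}"]]
        csv_rows += [
            [f"tau_{k + 1}", f"{v:.4f}"] for k, v in enumerate(report.tau_k)
        ]
    elif isinstance(report, ConditionSummary):
        doc = _summary_dict(report)
        csv_rows = [["quantity", "value"]]
        for key, val in doc.items():
            if isinstance(val, float):
                csv_rows.append([key, f"{val:.4f}"])
        report.records.round(4).to_csv(
            path.with_name(path.stem + "_records.csv"), index=False
        )
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")
    if config is not None:
        doc["config"] = config.to_dict()
    with path.open("w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    with path.with_suffix(".csv").open("w", newline="") as fh:
        csv.writer(fh).writerows(csv_rows)
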