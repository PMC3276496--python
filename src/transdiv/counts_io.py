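"""Reading, validating and writing genes x conditions read-count tables.

The pipeline's sole real-world input is a tab-separated table of
non-negative integer tag counts: one row per gene (unigene, contig,
transcript), one column per sequencing library / experimental condition,
with one column designated as the untreated control.  Everything upstream
of the count table (base calling, assembly, read-to-unigene mapping) is
out of scope; everything downstream consumes the :class:`CountMatrix`
defined here.

File dialect: UTF-8 TSV, first header cell ``gene_id``, no quoting.
Lines starting with ``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ValidationReport",
    "read_count_table",
    "validate_counts",
    "write_count_table",
    "write_outputs",
]


class CountTableFormatError(ValueError):
    """Malformed count table (negative/non-integer cell, duplicate id...)."""


@dataclasses.dataclass
class CountMatrix:
    """Genes x conditions read counts with a designated control column.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids,
        columns = condition ids.
    control_id
        Label of the untreated control column; must be one of the columns.

    The constructor is permissive so that :func:`validate_counts` can
    report problems instead of raising; use :meth:`require_valid` (or
    :func:`read_count_table`, which validates) before analysis.
    """

    counts: pd.DataFrame
    control_id: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def treatment_ids(self) -> list[str]:
        """Condition ids excluding the control."""
        return [c for c in self.condition_ids if c != self.control_id]

    @property
    def depths(self) -> pd.Series:
        """Per-library read totals N_j."""
        return self.counts.sum(axis=0)

    def require_valid(self) -> "CountMatrix":
        report = validate_counts(self)
        errors = [msg for sev, msg in report.issues if sev == "error"]
        if errors:
            raise CountTableFormatError("; ".join(errors))
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.control_id == other.control_id and self.counts.equals(
            other.counts
        )


@dataclasses.dataclass
class ValidationReport:
    n_genes: int
    n_conditions: int
    column_totals: dict[str, int]
    issues: list[tuple[str, str]]

    @property
    def n_errors(self) -> int:
        return sum(1 for sev, _ in self.issues if sev == "error")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_genes": self.n_genes,
            "n_conditions": self.n_conditions,
            "column_totals": self.column_totals,
            "issues": [list(i) for i in self.issues],
            "ok": self.ok,
        }


def read_count_table(path: str | Path, control_id: str) -> CountMatrix:
    """Read a TSV count table and return a validated :class:`CountMatrix`.

    Row and column order are preserved from the file.  Raises
    ``FileNotFoundError`` for a missing file, :class:`CountTableFormatError`
    for malformed cells or duplicate gene ids (naming the offending row and
    column), and ``KeyError`` if ``control_id`` is not a column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    df = pd.read_csv(
        path, sep="\t", header=0, index_col=0, comment="#", dtype=str
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CountTableFormatError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise CountTableFormatError(f"duplicate condition id {dup!r} in {path}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed)) | (parsed < 0)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise CountTableFormatError(
                f"non-integer or negative count at gene {gene!r}, "
                f"condition {col!r} in {path}"
            )
        numeric[col] = parsed.astype(np.int64)
    if control_id not in numeric.columns:
        raise KeyError(
            f"control condition {control_id!r} not among columns "
            f"{list(numeric.columns)}"
        )
    empty = numeric.sum(axis=0) == 0
    if empty.any():
        raise CountTableFormatError(
            f"empty library (zero column total): {list(numeric.columns[empty])}"
        )
    return CountMatrix(counts=numeric, control_id=control_id)


def validate_counts(m: CountMatrix) -> ValidationReport:
    """Check every :class:`CountMatrix` invariant, reporting (not raising).

    Severity ``"error"`` issues are exactly the conditions under which
    :func:`read_count_table` would have rejected the file.
    """
    issues: list[tuple[str, str]] = []
    counts = m.counts
    if counts.index.has_duplicates:
        dups = sorted(set(counts.index[counts.index.duplicated()]))
        issues.append(("error", f"duplicate gene ids: {dups}"))
    if counts.columns.has_duplicates:
        dups = sorted(set(counts.columns[counts.columns.duplicated()]))
        issues.append(("error", f"duplicate condition ids: {dups}"))
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.floor(values)):
            issues.append(("error", "non-integer counts present"))
    if np.any(values < 0):
        issues.append(("error", "negative counts present"))
    totals = counts.sum(axis=0)
    for cond, total in totals.items():
        if total <= 0:
            issues.append(("error", f"empty library: column {cond!r} totals 0"))
    if m.control_id not in counts.columns:
        issues.append(
            ("error", f"control id {m.control_id!r} not among conditions")
        )
    all_zero = int((counts.sum(axis=1) == 0).sum())
    if all_zero:
        issues.append(
            ("info", f"{all_zero} genes have zero counts in every condition")
        )
    return ValidationReport(
        n_genes=counts.shape[0],
        n_conditions=counts.shape[1],
        column_totals={str(c): int(t) for c, t in totals.items()},
        issues=issues,
    )


def _provenance_line(config: dict | None = None) -> str:
    from . import __version__

    digest = ""
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        digest = " config=" + hashlib.sha256(blob).hexdigest()[:12]
    return f"# transdiv {__version__}{digest}"


def write_count_table(
    m: CountMatrix, path: str | Path, config: dict | None = None
) -> None:
    """Write a CountMatrix as TSV; read-back reproduces it exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_line(config) + "\n")
        fh.write("gene_id\t" + "\t".join(map(str, m.counts.columns)) + "\n")
        for gene, row in zip(m.counts.index, m.counts.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(map(str, row)) + "\n")


def write_outputs(obj: Any, path: str | Path, config: dict | None = None) -> None:
    """Write a pipeline result to disk (TSV for tables, JSON otherwise).

    Dispatches on type: CountMatrix and DataFrames become TSV with a
    provenance comment line; dicts, dataclasses and objects exposing
    ``to_dict`` become JSON.
    """
    path = Path(path)
    if isinstance(obj, CountMatrix):
        write_count_table(obj, path, config)
        return
    if isinstance(obj, pd.DataFrame):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_line(config) + "\n")
            obj.to_csv(fh, sep="\t")
        return
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = (
            obj.to_dict()
            if hasattr(obj, "to_dict")
            else dataclasses.asdict(obj)
        )
    elif hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif isinstance(obj, dict):
        payload = obj
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"_provenance": _provenance_line(config)[2:], **payload},
            fh,
            indent=2,
            default=_json_default,
        )
        fh.write("\n")


def _json_default(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return {str(k): v for k, v in o.items()}
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="index"))
    if isinstance(o, Iterable):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")
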