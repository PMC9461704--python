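"""Readers and writers between on-disk tables and :class:`QuantDataset`.

Two layouts are supported:

* A **wide export** in the style of a MetIDQ data-export sheet: sample
  metadata columns on the left, one column per metabolite, and two
  annotation header rows (metabolite class and LOD) between the column
  headers and the sample rows.  Measurement status flags come from a
  companion table of identical shape (a ``.status.csv`` sibling, or a
  ``status`` sheet in an XLSX workbook); when absent, statuses are inferred
  by comparing each concentration to the metabolite's LOD.
* A tidy **long table** (CSV only): one row per measurement joined to all
  annotations.  This is the canonical on-disk exchange format of the
  pipeline; writing then reading it is the identity on valid datasets.

Number parsing is locale-independent: decimal points only, thousands
separators rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    DEFAULT_STATUS_FLAGS,
    QuantDataset,
    Status,
    validate_dataset,
)

__all__ = [
    "WideDialect",
    "FormatError",
    "load_dialect",
    "read_wide_export",
    "write_wide_export",
    "write_long_table",
    "read_long_table",
    "LONG_COLUMNS",
]

LONG_COLUMNS = (
    "sample_id",
    "metabolite_id",
    "class",
    "concentration",
    "unit_basis",
    "status",
    "tissue",
    "protocol",
    "replicate_index",
    "lod_value",
)


class FormatError(ValueError):
    """The on-disk table does not match the expected layout."""


@dataclass
class WideDialect:
    """Configurable description of a wide-export sheet layout."""

    metadata_columns: tuple[str, ...] = (
        "sample_id",
        "tissue",
        "protocol",
        "replicate_index",
        "unit_basis",
    )
    class_row_marker: str = "class"
    lod_row_marker: str = "lod"
    status_sheet: str = "status"
    status_flags: Mapping[str, Status] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_FLAGS)
    )


def load_dialect(path: str) -> WideDialect:
    """Load a :class:`WideDialect` from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "metadata_columns" in raw:
        kwargs["metadata_columns"] = tuple(raw["metadata_columns"])
    for key in ("class_row_marker", "lod_row_marker", "status_sheet"):
        if key in raw:
            kwargs[key] = raw[key]
    if "status_flags" in raw:
        kwargs["status_flags"] = {k: Status(v) for k, v in raw["status_flags"].items()}
    return WideDialect(**kwargs)


def _parse_number(text, what: str) -> float:
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip()
    try:
        return float(s)  # rejects "1,000" and locale commas
    except ValueError:
        raise FormatError(f"cannot parse {what} value {text!r} as a number") from None


def _read_raw_table(path: str, sheet=0) -> pd.DataFrame:
    if str(path).lower().endswith((".xlsx", ".xlsm")):
        return pd.read_excel(path, sheet_name=sheet, header=None, dtype=object)
    return pd.read_csv(path, header=None, dtype=str, keep_default_na=False)


def read_wide_export(
    path: str,
    dialect: WideDialect | None = None,
    status_path: str | None = None,
    validate: bool = True,
) -> QuantDataset:
    """Parse a wide MetIDQ-style export (CSV or XLSX) into a dataset.

    Row/column order of the sheet is preserved in the sample and metabolite
    annotation tables, so a subsequent write round-trips faithfully.

    Raises
    ------
    FormatError
        On a missing class/LOD header row, zero metabolite columns,
        duplicate sample ids, or a status flag absent from the dialect map.
    """
    dialect = dialect or WideDialect()
    raw = _read_raw_table(path)
    if raw.shape[0] < 3:
        raise FormatError("wide export needs a header row plus class and lod rows")

    header = [str(x).strip() for x in raw.iloc[0]]
    n_meta = len(dialect.metadata_columns)
    if header[:n_meta] != list(dialect.metadata_columns):
        raise FormatError(
            f"expected metadata columns {list(dialect.metadata_columns)}, found {header[:n_meta]}"
        )
    metabolite_ids = [m for m in header[n_meta:] if m != ""]
    if not metabolite_ids:
        raise FormatError("wide export contains zero metabolite columns")
    if len(set(metabolite_ids)) != len(metabolite_ids):
        raise FormatError("duplicate metabolite columns in wide export")

    markers = [str(x).strip().lower() for x in raw.iloc[1:3, 0]]
    try:
        class_row = 1 + markers.index(dialect.class_row_marker.lower())
        lod_row = 1 + markers.index(dialect.lod_row_marker.lower())
    except ValueError:
        missing = dialect.class_row_marker if dialect.class_row_marker.lower() not in markers else dialect.lod_row_marker
        raise FormatError(f"missing required header row {missing!r}") from None

    classes = [str(x).strip() for x in raw.iloc[class_row, n_meta:][: len(metabolite_ids)]]
    lods = [
        _parse_number(x, "lod")
        for x in raw.iloc[lod_row, n_meta:][: len(metabolite_ids)]
    ]
    metabolites = pd.DataFrame(
        {"metabolite_id": metabolite_ids, "class": classes, "lod_value": lods}
    )

    body = raw.iloc[3:].reset_index(drop=True)
    samples = pd.DataFrame(
        {col: body.iloc[:, i].astype(str).str.strip() for i, col in enumerate(dialect.metadata_columns)}
    )
    samples["replicate_index"] = [
        int(_parse_number(x, "replicate_index")) for x in samples["replicate_index"]
    ]
    if samples["sample_id"].duplicated().any():
        dups = sorted(samples.loc[samples["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicate sample_id in wide export: {dups}")

    conc = np.array(
        [
            [_parse_number(x, "concentration") for x in body.iloc[i, n_meta : n_meta + len(metabolite_ids)]]
            for i in range(len(body))
        ],
        dtype=float,
    )

    status = _read_status(path, status_path, dialect, samples["sample_id"], metabolite_ids)
    if status is None:
        lod_arr = np.asarray(lods, dtype=float)
        status = np.where(conc > lod_arr[None, :], Status.VALID.value, Status.BELOW_LOD.value)

    records = pd.DataFrame(
        {
            "sample_id": np.repeat(samples["sample_id"].to_numpy(), len(metabolite_ids)),
            "metabolite_id": np.tile(np.asarray(metabolite_ids, dtype=object), len(samples)),
            "concentration": conc.ravel(),
            "status": np.asarray(status, dtype=object).ravel(),
        }
    )
    dataset = QuantDataset(records=records, metabolites=metabolites, samples=samples)
    if validate:
        problems = validate_dataset(dataset)
        if problems:
            raise FormatError(
                "wide export failed validation: " + "; ".join(str(p) for p in problems)
            )
    return dataset


def _read_status(path, status_path, dialect, sample_ids, metabolite_ids):
    """Locate and translate the companion status table, if any."""
    raw = None
    if str(path).lower().endswith((".xlsx", ".xlsm")):
        try:
            raw = _read_raw_table(path, sheet=dialect.status_sheet)
        except (ValueError, KeyError):
            raw = None
    else:
        candidate = status_path or _default_status_path(path)
        if candidate and os.path.exists(candidate):
            raw = _read_raw_table(candidate)
    if raw is None:
        return None
    body = raw.iloc[3:].reset_index(drop=True)
    n_meta = len(dialect.metadata_columns)
    flags = body.iloc[:, n_meta : n_meta + len(metabolite_ids)].astype(str).to_numpy()
    out = np.empty_like(flags, dtype=object)
    unknown: set[str] = set()
    for idx, flag in np.ndenumerate(flags):
        flag = flag.strip()
        mapped = dialect.status_flags.get(flag)
        if mapped is None:
            unknown.add(flag)
        else:
            out[idx] = mapped.value
    if unknown:
        raise FormatError(f"unknown status flags in export: {sorted(unknown)}")
    return out


def _default_status_path(path: str) -> str:
    stem, ext = os.path.splitext(path)
    return f"{stem}.status{ext}"


def write_wide_export(dataset: QuantDataset, path: str, dialect: WideDialect | None = None) -> None:
    """Write a dataset as a wide CSV plus a ``.status.csv`` companion."""
    dialect = dialect or WideDialect()
    met = dataset.metabolites
    sam = dataset.samples
    conc = dataset.records.pivot(index="sample_id", columns="metabolite_id", values="concentration")
    stat = dataset.records.pivot(index="sample_id", columns="metabolite_id", values="status")
    conc = conc.loc[sam["sample_id"], met["metabolite_id"]]
    stat = stat.loc[sam["sample_id"], met["metabolite_id"]]

    n_meta = len(dialect.metadata_columns)
    header = list(dialect.metadata_columns) + list(met["metabolite_id"])
    class_row = [dialect.class_row_marker] + [""] * (n_meta - 1) + list(met["class"])
    lod_row = [dialect.lod_row_marker] + [""] * (n_meta - 1) + [repr(float(x)) for x in met["lod_value"]]

    def rows(matrix: pd.DataFrame, fmt) -> list[list[str]]:
        out = []
        for _, srow in sam.iterrows():
            meta = [str(srow[c]) for c in dialect.metadata_columns]
            out.append(meta + [fmt(x) for x in matrix.loc[srow["sample_id"]]])
        return out

    def dump(file_path: str, body: list[list[str]]) -> None:
        lines = [",".join(r) for r in ([header, class_row, lod_row] + body)]
        with open(file_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")

    dump(path, rows(conc, lambda x: repr(float(x))))
    dump(_default_status_path(path), rows(stat, str))


def write_long_table(dataset: QuantDataset, path: str) -> None:
    """Write the dataset as a tidy long CSV, one row per measurement.

    Rows are ordered by (sample_id, metabolite_id) lexicographically so the
    output is deterministic regardless of in-memory ordering.
    """
    long = dataset.to_long()
    long = long[list(LONG_COLUMNS)].sort_values(["sample_id", "metabolite_id"])
    long.to_csv(path, index=False, lineterminator="\n")


def read_long_table(path: str, validate: bool = True) -> QuantDataset:
    """Read a tidy long CSV back into a validated :class:`QuantDataset`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "metabolite_id": str, "tissue": str,
                                  "protocol": str, "class": str, "status": str,
                                  "unit_basis": str})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"long table missing columns: {sorted(missing)}")
    records = df[["sample_id", "metabolite_id", "concentration", "status"]].copy()
    metabolites = (
        df[["metabolite_id", "class", "lod_value"]]
        .drop_duplicates(subset="metabolite_id")
        .reset_index(drop=True)
    )
    inconsistent = df.groupby("metabolite_id")["lod_value"].nunique()
    if (inconsistent > 1).any():
        bad = sorted(inconsistent[inconsistent > 1].index)
        raise FormatError(f"metabolites with conflicting LOD values: {bad}")
    samples = (
        df[["sample_id", "tissue", "protocol", "replicate_index", "unit_basis"]]
        .drop_duplicates(subset="sample_id")
        .reset_index(drop=True)
    )
    samples["replicate_index"] = samples["replicate_index"].astype(int)
    dataset = QuantDataset(records=records, metabolites=metabolites, samples=samples)
    if validate:
        problems = validate_dataset(dataset)
        if problems:
            raise FormatError(
                "long table failed validation: " + "; ".join(str(p) for p in problems)
            )
    return dataset
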