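"""File formats and provenance for the command-line surface.

Interchange is comma-delimited text.  Item banks are one row per item
(``item_id,a,b1,...``) or an equivalent JSON document; response matrices
are persons x items with a header row and an optional leading ``person_id``
column; category codes are 0-based by default with a switch for 1-based
input.  Result tables are CSV with leading ``#`` provenance comment lines
(package version and master seed) so that repeated runs with the same
inputs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grm import GRMItem, GRMItemBank, ResponseMatrix


def read_item_bank(path: str | Path) -> GRMItemBank:
    """Read an item bank from CSV (``item_id,a,b1..``) or JSON.

    Validation errors name the offending item.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        rows = [(item["id"], item["a"], item["b"]) for item in doc["items"]]
    else:
        frame = pd.read_csv(path, comment="#")
        cols = [c.strip() for c in frame.columns]
        frame.columns = cols
        if "item_id" not in cols or "a" not in cols:
            raise ValueError(f"{path}: header must contain item_id and a columns")
        b_cols = sorted(
            (c for c in cols if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not b_cols:
            raise ValueError(f"{path}: no threshold columns (b1, b2, ...)")
        rows = [
            (row["item_id"], row["a"], [row[c] for c in b_cols if pd.notna(row[c])])
            for _, row in frame.iterrows()
        ]
    items = []
    for item_id, a, b in rows:
        try:
            items.append(GRMItem(float(a), np.asarray(b, dtype=float)))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid item {item_id!r}: {exc}") from None
    return GRMItemBank(items)


def write_item_bank(bank: GRMItemBank, path: str | Path) -> None:
    """Write a bank as CSV or (for a .json path) JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "items": [
                {"id": f"item{j + 1}", "a": it.a, "b": list(it.b)}
                for j, it in enumerate(bank)
            ]
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    k = int(max(it.n_cat for it in bank)) - 1 if bank.J else 0
    cols = ["item_id", "a"] + [f"b{i + 1}" for i in range(k)]
    rows = []
    for j, it in enumerate(bank):
        rec = {"item_id": f"item{j + 1}", "a": repr(it.a)}
        for i, b in enumerate(it.b):
            rec[f"b{i + 1}"] = repr(float(b))
        rows.append(rec)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_responses(path: str | Path, base: int = 0) -> ResponseMatrix:
    """Read a persons x items response table (header row required).

    ``base=1`` accepts 1-based category codes and recodes them to the
    0-based internal convention.  A leading ``person_id`` column is used as
    row identifiers.
    """
    if base not in (0, 1):
        raise ValueError("base must be 0 or 1")
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.strip() for c in frame.columns]
    ids = None
    if frame.columns[0] == "person_id":
        ids = frame["person_id"].to_numpy()
        frame = frame.drop(columns=["person_id"])
    if frame.isna().any().any():
        i, j = np.argwhere(frame.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing or ragged entry at row {i}, column {j}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != values.astype(int)):
        raise ValueError(f"{path}: responses must be integers")
    values = values.astype(int) - base
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: category below {base} at row {i}, column {j} "
            f"(input is {base}-based)"
        )
    return ResponseMatrix(values, person_ids=ids)


def provenance_lines(seed: int | None = None) -> list[str]:
    lines = [f"# rcirt v{__version__}", "# categories: 0-based"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_results(table: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a results table as CSV with provenance comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        table.to_csv(fh, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
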