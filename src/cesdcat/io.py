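"""Readers and writers for response matrices and item banks.

All formats are delimited text with header rows.  A calibrated 17-item
CES-D graded-response item bank ships with the package and is exposed
through :func:`cesd_item_bank`.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GRMItem, ItemBank, ResponseMatrix

log = logging.getLogger(__name__)

__all__ = [
    "load_response_matrix",
    "write_response_matrix",
    "load_item_bank",
    "write_item_bank",
    "cesd_item_bank",
]


def load_response_matrix(
    path: str | Path,
    coding_offset: int = 1,
    n_categories: int = 4,
    item_prefix: str = "q",
    sep: str = ",",
) -> ResponseMatrix:
    """Read a persons x items CSV of Likert responses.

    Columns whose name starts with ``item_prefix`` are treated as items;
    any remaining columns (e.g. ``gender``, ``age``) become group covariates.
    On-disk categories are shifted by ``coding_offset`` so that internal
    coding is always ``0..n_categories-1``.  Rows containing a missing or
    out-of-range entry are dropped (listwise deletion) and the count logged.
    """
    if coding_offset not in (0, 1):
        raise ValueError("coding_offset must be 0 or 1")
    df = pd.read_csv(path, sep=sep)
    item_cols = [c for c in df.columns if c.startswith(item_prefix)]
    if not item_cols:
        raise ValueError(f"no item columns (prefix {item_prefix!r}) in {path}")
    raw = df[item_cols].apply(pd.to_numeric, errors="coerce")
    vals = raw.to_numpy(dtype=float) - coding_offset
    in_range = np.isfinite(vals) & (vals >= 0) & (vals <= n_categories - 1)
    # non-integer cells are invalid too
    in_range &= np.isclose(vals, np.round(vals), equal_nan=False)
    keep = in_range.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d rows with missing/out-of-range responses", n_dropped)
    if not keep.any():
        raise ValueError("all rows dropped: no complete in-range responses")
    other_cols = [c for c in df.columns if c not in item_cols]
    groups = df.loc[keep, other_cols].reset_index(drop=True) if other_cols else None
    return ResponseMatrix(
        np.round(vals[keep]).astype(np.int64),
        item_cols,
        groups=groups,
        coding_offset=coding_offset,
        n_categories=n_categories,
    )


def write_response_matrix(data: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix back to CSV in its on-disk coding."""
    data.to_dataframe().to_csv(path, index=False)


def load_item_bank(path: str | Path) -> ItemBank:
    """Read an item-parameter CSV (columns item_id, a, b1..bK[, se_*]).

    Raises on non-positive slopes or non-increasing thresholds.
    """
    df = pd.read_csv(path)
    b_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if "item_id" not in df.columns or "a" not in df.columns or not b_cols:
        raise ValueError("item bank needs columns item_id, a, b1..bK")
    se_b_cols = [f"se_{c}" for c in b_cols]
    have_se = "se_a" in df.columns and all(c in df.columns for c in se_b_cols)
    items = []
    for _, row in df.iterrows():
        items.append(
            GRMItem(
                item_id=str(row["item_id"]),
                a=float(row["a"]),
                b=row[b_cols].to_numpy(dtype=float),
                se_a=float(row["se_a"]) if have_se else None,
                se_b=row[se_b_cols].to_numpy(dtype=float) if have_se else None,
            )
        )
    return ItemBank(items)


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    rows = []
    for it in bank:
        row: dict[str, object] = {"item_id": it.item_id, "a": it.a}
        row.update({f"b{k + 1}": v for k, v in enumerate(it.b)})
        if it.se_a is not None and it.se_b is not None:
            row["se_a"] = it.se_a
            row.update({f"se_b{k + 1}": v for k, v in enumerate(it.se_b)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cesd_item_bank() -> ItemBank:
    """The packaged 17-item CES-D graded-response item bank.

    Slopes range from 1.13 (item 7) to 3.70 (item 6); thresholds are on the
    z-score scale.  Item ids keep the original 20-item numbering (items 2,
    11 and 15 were removed during scale evaluation).
    """
    with resources.as_file(
        resources.files("cesdcat").joinpath("data/cesd_grm_bank.csv")
    ) as p:
        return load_item_bank(p)
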