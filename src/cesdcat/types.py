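"""Shared domain types: response matrices, item banks and trait estimates.

Responses are coded 0..m-1 internally (m = 4 for the CES-D) regardless of
on-disk coding.  Item parameters live on the logistic metric with no 1.702
scaling constant; thetas are on a z-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "GRMItem", "ItemBank", "ThetaEstimate"]


@dataclass
class ResponseMatrix:
    """Persons x items integer category data with optional group covariates.

    Parameters
    ----------
    values : (n_persons, n_items) integer array, categories ``0..m-1``.
    item_ids : ordered item labels, e.g. ``["q1", ..., "q20"]``.
    groups : optional per-person covariates (gender, age group), aligned
        row-for-row with ``values``.
    coding_offset : the on-disk coding origin (0 or 1) recorded at load time.
    """

    values: np.ndarray
    item_ids: list[str]
    groups: pd.DataFrame | None = None
    coding_offset: int = 0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.item_ids = list(self.item_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D persons x items array")
        if self.values.shape[1] != len(self.item_ids):
            raise ValueError("item_ids length does not match number of columns")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 persons")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > self.n_categories - 1
        ):
            raise ValueError(
                f"responses must lie in 0..{self.n_categories - 1}"
            )
        if self.groups is not None and len(self.groups) != self.values.shape[0]:
            raise ValueError("groups must have one row per person")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def subset(self, item_ids: list[str]) -> "ResponseMatrix":
        """Return a matrix restricted to ``item_ids``, preserving groups."""
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            self.values[:, idx],
            [self.item_ids[i] for i in idx],
            groups=None if self.groups is None else self.groups.copy(),
            coding_offset=self.coding_offset,
            n_categories=self.n_categories,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values + self.coding_offset, columns=self.item_ids)
        if self.groups is not None:
            for c in self.groups.columns:
                df[c] = self.groups[c].to_numpy()
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return (
            self.item_ids == other.item_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class GRMItem:
    """A graded-response-model item: slope ``a`` and ordered thresholds ``b``.

    The slope is on the logistic metric (no scaling constant); thresholds are
    on the z-score theta scale.  ``b`` has m-1 entries for an m-category item.
    """

    item_id: str
    a: float
    b: np.ndarray
    se_a: float | None = None
    se_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.se_b is not None:
            self.se_b = np.asarray(self.se_b, dtype=float)
        if not self.a > 0:
            raise ValueError(f"{self.item_id}: slope must be positive, got {self.a}")
        if self.b.ndim != 1 or len(self.b) < 1:
            raise ValueError(f"{self.item_id}: need at least one threshold")
        if np.any(np.diff(self.b) <= 0):
            raise ValueError(
                f"{self.item_id}: thresholds must be strictly increasing, got {self.b}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1

    @property
    def loading(self) -> float:
        """Standardized factor loading, lambda = a*/sqrt(a*^2 + 1), a* = a/1.702."""
        a_star = self.a / 1.702
        return a_star / np.sqrt(a_star**2 + 1.0)


@dataclass
class ItemBank:
    """An ordered collection of calibrated GRM items.

    Items usually share one category count (4 for the CES-D); banks refit
    after testlet formation legitimately mix counts (a summed super-item
    has more categories than its parts).
    """

    items: list[GRMItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> GRMItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def slopes(self) -> np.ndarray:
        return np.array([it.a for it in self.items])

    def subset(self, item_ids: list[str]) -> "ItemBank":
        return ItemBank([self[i] for i in item_ids])


@dataclass
class ThetaEstimate:
    """A latent-trait point estimate with its standard error.

    ``se`` is 1/sqrt(information at theta); ``method`` records whether the
    estimate is the posterior mode under a normal prior (MAP) or maximum
    likelihood (ML); ``converged`` is False when the estimate was clamped to
    a bound (e.g. an all-floor or all-ceiling response pattern under ML).
    """

    theta: float
    se: float
    method: str  # "MAP" or "ML"
    converged: bool = True
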