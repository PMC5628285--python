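"""Synthetic Likert response data with the structure the analyses assume.

The generator emulates the study conditions the pipeline was built for:
roughly one thousand respondents per group (1018 evaluation / 1042
validation), a standard-normal latent trait, 4-category graded responses
from a calibrated item bank, and a two-thirds/one-third gender split.  On
top of that base it can inject the three violations the diagnostic stages
look for: off-dimension items (a second latent trait), locally dependent
item pairs (a shared residual shock), and DIF items (group-specific
threshold shifts and slope ratios).

Generation uses the ordinal-regression representation of the graded model:
a response propensity z_i = a_i (theta - .) + e_i with a standard logistic
error, categorized at the thresholds.  This makes the dependence and DIF
injections exact and keeps the null design bit-identical to plain GRM
sampling under the same stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import load_item_bank
from .types import ItemBank, ResponseMatrix

__all__ = [
    "SimulationDesign",
    "draw_thetas",
    "simulate_grm_responses",
    "make_study_dataset",
    "design_from_yaml",
]


def draw_thetas(n: int, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """n independent N(mean, sd) latent-trait draws, reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return np.random.default_rng(seed).normal(mean, sd, size=n)


def _categorize(bank: ItemBank, thetas: np.ndarray, errors: np.ndarray) -> np.ndarray:
    """Categorize logistic propensities: x = #{k : a(theta - b_k) + e > 0}."""
    X = np.zeros((len(thetas), len(bank)), dtype=np.int64)
    for j, it in enumerate(bank):
        z = it.a * (thetas[:, None] - it.b[None, :]) + errors[:, j, None]
        X[:, j] = (z > 0).sum(axis=1)
    return X


def simulate_grm_responses(
    bank: ItemBank, thetas: np.ndarray, seed: int = 0
) -> ResponseMatrix:
    """Sample one graded response per person-item from the model at theta."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise ValueError("thetas must be finite")
    rng = np.random.default_rng(seed)
    errors = rng.logistic(size=(len(thetas), len(bank)))
    X = _categorize(bank, thetas, errors)
    return ResponseMatrix(X, bank.item_ids, n_categories=bank.items[0].n_categories)


@dataclass
class SimulationDesign:
    """A full synthetic-study recipe.

    off_dimension_items : list of (item_id, secondary_loading) — the item is
        driven by sqrt(1 - lambda2^2)*theta + lambda2*theta2 with an
        independent second trait theta2, keeping total latent variance 1.
    dependent_pairs : list of (item_i, item_j, rho) — a shared N(0,1) shock,
        scaled so the two propensities' residual correlation is rho, is
        added before categorization.
    dif_items : list of (item_id, group_label, delta, kappa) — members of
        the named group answer the item with thresholds b + delta (uniform
        DIF) and slope a*kappa (non-uniform DIF when kappa != 1).
    """

    bank: ItemBank
    n_persons: int = 1018
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    off_dimension_items: list[tuple[str, float]] = field(default_factory=list)
    dependent_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dif_items: list[tuple[str, str, float, float]] = field(default_factory=list)
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"female": 0.66, "male": 0.34}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        for _, _, rho in self.dependent_pairs:
            if not -1 < rho < 1:
                raise ValueError("residual correlation must lie in (-1, 1)")
        for _, _, delta, kappa in self.dif_items:
            if not np.isfinite(delta):
                raise ValueError("threshold shift must be finite")
            if kappa <= 0:
                raise ValueError("slope ratio must be positive")
        known = set(self.bank.item_ids)
        referenced = (
            {i for i, _ in self.off_dimension_items}
            | {i for i, j, _ in self.dependent_pairs}
            | {j for i, j, _ in self.dependent_pairs}
            | {i for i, _, _, _ in self.dif_items}
        )
        missing = referenced - known
        if missing:
            raise ValueError(f"design references items not in bank: {sorted(missing)}")

    def child_seeds(self) -> tuple[int, int, int, int]:
        """(theta, group, response, injection) substream seeds."""
        return tuple(int(s) for s in np.random.SeedSequence(self.seed).generate_state(4))


def make_study_dataset(design: SimulationDesign) -> ResponseMatrix:
    """Generate a full synthetic study dataset from a design.

    With no injections the result is identical to
    ``simulate_grm_responses(bank, draw_thetas(n, ..., s_theta), s_resp)``
    where ``s_theta`` and ``s_resp`` come from ``design.child_seeds()``.
    """
    bank = design.bank
    n = design.n_persons
    s_theta, s_group, s_resp, s_inject = design.child_seeds()

    thetas = draw_thetas(n, design.theta_mean, design.theta_sd, s_theta)

    labels = list(design.group_fractions)
    probs = np.array([design.group_fractions[g] for g in labels])
    group = np.random.default_rng(s_group).choice(labels, size=n, p=probs)

    errors = np.random.default_rng(s_resp).logistic(size=(n, len(bank)))

    inj = np.random.default_rng(s_inject)
    # off-dimension items share ONE second trait, forming a second dimension
    theta_eff = np.tile(thetas[:, None], (1, len(bank)))
    if design.off_dimension_items:
        theta2 = inj.normal(size=n)
        for item_id, lam2 in design.off_dimension_items:
            j = bank.item_ids.index(item_id)
            theta_eff[:, j] = np.sqrt(max(0.0, 1 - lam2**2)) * thetas + lam2 * theta2

    # shared residual shocks for dependent pairs: corr(e'_i, e'_j) = rho
    sd_l = np.pi / np.sqrt(3.0)  # logistic sd
    for item_i, item_j, rho in design.dependent_pairs:
        shock = inj.normal(size=n)
        lam = sd_l * np.sqrt(abs(rho) / (1 - abs(rho)))
        for iid, sgn in ((item_i, 1.0), (item_j, np.sign(rho) or 1.0)):
            j = bank.item_ids.index(iid)
            errors[:, j] = errors[:, j] + sgn * lam * shock

    dif_by_item = {iid: (g, d, k) for iid, g, d, k in design.dif_items}
    X = np.zeros((n, len(bank)), dtype=np.int64)
    for j, it in enumerate(bank):
        a, b = it.a, it.b
        z = a * (theta_eff[:, j][:, None] - b[None, :]) + errors[:, j][:, None]
        if it.item_id in dif_by_item:
            g, delta, kappa = dif_by_item[it.item_id]
            mask = group == g
            z_g = (a * kappa) * (theta_eff[mask, j][:, None] - (b + delta)[None, :]) \
                + errors[mask, j][:, None]
            z[mask] = z_g
        X[:, j] = (z > 0).sum(axis=1)

    import pandas as pd

    return ResponseMatrix(
        X,
        bank.item_ids,
        groups=pd.DataFrame({"group": group}),
        n_categories=bank.items[0].n_categories,
    )


def design_from_yaml(path: str | Path) -> SimulationDesign:
    """Load a SimulationDesign from a YAML file.

    Expected keys mirror the dataclass fields; ``bank`` is a path to an
    item-parameter CSV (relative paths resolve against the YAML file).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    bank_path = Path(cfg.pop("bank"))
    if not bank_path.is_absolute():
        bank_path = path.parent / bank_path
    bank = load_item_bank(bank_path)
    for key in ("off_dimension_items", "dependent_pairs", "dif_items"):
        if key in cfg:
            cfg[key] = [tuple(entry) for entry in cfg[key]]
    return SimulationDesign(bank=bank, **cfg)
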