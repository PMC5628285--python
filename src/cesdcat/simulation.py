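"""Decile-stratified CAT performance studies.

Two study designs are provided.  Simulation I draws simulees from the
latent distribution, simulates their item responses on the fly and runs
the adaptive test against each; accuracy is measured against the known
true thetas.  Simulation II replays fixed full response vectors (post-hoc
CAT): the reference score is the full-bank estimate of the same vector,
and the headline statistic is the correlation between CAT and full-bank
scores.

Results are summarized per decile of the reference trait (D1 lowest to
D10 highest): mean theta, RMSE, mean bias, mean test length, mean SE and
simulee count, plus overall summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cat import CATConfig, CATResult, fixed_responder, run_cat, simulated_responder
from .grm import score_map, score_ml
from .types import ItemBank, ResponseMatrix

__all__ = [
    "DecileSummary",
    "simulation_one",
    "simulation_two",
    "length_by_theta_plot",
]


@dataclass
class DecileSummary:
    """Per-decile and overall CAT performance (the Tables 4/5 shape)."""

    per_decile: pd.DataFrame
    mean_test_length: float
    sd_test_length: float
    mean_rmse: float
    mean_bias: float
    score_correlation: float | None = None
    results: list[CATResult] | None = None
    reference_thetas: np.ndarray | None = None


def _decile_assignment(ref: np.ndarray) -> np.ndarray:
    """Deciles by rank of the reference theta, D1 lowest.

    Sizes are floor(n/10) with the remainder spread to the extreme deciles
    first (D1, D10, D2, D9, ...), so n=1042 gives 105 in D1 and D10.
    """
    n = len(ref)
    sizes = np.full(10, n // 10)
    order_extra = [0, 9, 1, 8, 2, 7, 3, 6, 4, 5]
    for k in range(n % 10):
        sizes[order_extra[k]] += 1
    dec = np.empty(n, dtype=int)
    rank = np.argsort(ref, kind="stable")
    pos = 0
    for d in range(10):
        dec[rank[pos:pos + sizes[d]]] = d
        pos += sizes[d]
    return dec


def _summarize(
    ref: np.ndarray,
    est: np.ndarray,
    lengths: np.ndarray,
    ses: np.ndarray,
    results: list[CATResult],
    score_correlation: float | None = None,
) -> DecileSummary:
    dec = _decile_assignment(ref)
    rows = []
    for d in range(10):
        mask = dec == d
        err = est[mask] - ref[mask]
        rows.append(
            {
                "decile": f"D{d + 1}",
                "mean_theta": float(ref[mask].mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mean_bias": float(err.mean()),
                "mean_test_length": float(lengths[mask].mean()),
                "mean_se": float(ses[mask].mean()),
                "n_simulees": int(mask.sum()),
            }
        )
    table = pd.DataFrame(rows)
    return DecileSummary(
        per_decile=table,
        mean_test_length=float(lengths.mean()),
        sd_test_length=float(lengths.std(ddof=1)),
        mean_rmse=float(table["rmse"].mean()),
        mean_bias=float((est - ref).mean()),
        score_correlation=score_correlation,
        results=results,
        reference_thetas=ref,
    )


def simulation_one(
    bank: ItemBank,
    n: int = 1042,
    config: CATConfig | None = None,
    seed: int = 0,
) -> DecileSummary:
    """CAT over n simulees drawn from N(0,1), scored against true theta.

    Each simulee gets an independent RNG substream, so results do not
    depend on processing order.
    """
    if n < 10:
        raise ValueError("need n >= 10 for decile summaries")
    config = config or CATConfig()
    root = np.random.SeedSequence(seed)
    theta_rng = np.random.default_rng(root.spawn(1)[0])
    true_thetas = theta_rng.normal(0.0, 1.0, size=n)
    person_seeds = root.spawn(n)

    results: list[CATResult] = []
    for i in range(n):
        rng = np.random.default_rng(person_seeds[i])
        results.append(run_cat(bank, simulated_responder(bank, true_thetas[i], rng), config))
    est = np.array([r.final.theta for r in results])
    lengths = np.array([r.n_items for r in results], dtype=float)
    ses = np.array([min(r.final.se, config.prior_sd * 4) for r in results])
    return _summarize(true_thetas, est, lengths, ses, results)


def simulation_two(
    bank: ItemBank,
    data: ResponseMatrix,
    config: CATConfig | None = None,
) -> DecileSummary:
    """Post-hoc CAT on fixed full response vectors.

    The reference score per person is the full-bank ML estimate (MAP when
    the pattern is all-floor/all-ceiling); the CAT replays the recorded
    responses and its final estimate is compared against the reference.
    ``score_correlation`` is the Pearson r between the two.
    """
    missing = [i for i in bank.item_ids if i not in data.item_ids]
    if missing:
        raise ValueError(f"data lacks bank items: {missing}")
    config = config or CATConfig()
    sub = data.subset(bank.item_ids)
    tops = np.array([it.n_categories - 1 for it in bank])

    ref = np.empty(sub.n_persons)
    for i, row in enumerate(sub.values):
        resp = dict(zip(sub.item_ids, row))
        if np.all(row == 0) or np.all(row == tops):
            ref[i] = score_map(bank, resp, config.prior_mean, config.prior_sd).theta
        else:
            ref[i] = score_ml(bank, resp).theta

    results = [
        run_cat(bank, fixed_responder(sub.item_ids, row), config)
        for row in sub.values
    ]
    est = np.array([r.final.theta for r in results])
    lengths = np.array([r.n_items for r in results], dtype=float)
    ses = np.array([min(r.final.se, config.prior_sd * 4) for r in results])
    r = float(np.corrcoef(est, ref)[0, 1])
    return _summarize(ref, est, lengths, ses, results, score_correlation=r)


def length_by_theta_plot(
    results: list[CATResult],
    reference_thetas: np.ndarray,
    out_png: str | Path,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Scatter of administered test length against theta, plus the table.

    Writes the figure to ``out_png`` and (optionally) the underlying table
    to ``out_csv``; returns the table (one row per result).
    """
    if not results:
        raise ValueError("no results to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thetas = np.asarray(reference_thetas, dtype=float)
    lengths = np.array([r.n_items for r in results])
    table = pd.DataFrame({"theta": thetas, "n_items": lengths})

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(thetas, lengths, s=8, alpha=0.4)
    if len(results) >= 20:
        bins = np.quantile(thetas, np.linspace(0, 1, 11))
        mids, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            mask = (thetas >= lo) & (thetas <= hi)
            if mask.any():
                mids.append(thetas[mask].mean())
                means.append(lengths[mask].mean())
        ax.plot(mids, means, color="C1", marker="o", label="decile mean")
        ax.legend()
    ax.set_xlabel(r"depressive-symptom severity $\theta$")
    ax.set_ylabel("items administered")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
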