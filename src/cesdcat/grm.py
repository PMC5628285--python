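"""Samejima's graded response model: probabilities, information, calibration,
scoring and local-dependence / item-fit diagnostics.

Model
-----
For an m-category item with slope ``a`` and ordered thresholds ``b_1 < ... <
b_{m-1}``, the boundary ("operating characteristic") curves are logistic,

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),   k = 1..m-1,

with P*_0 = 1 and P*_m = 0, and the category probabilities are
P_k = P*_k - P*_{k+1}.  No 1.702 scaling constant enters the model; the
constant appears only in the conversion of slopes to standardized factor
loadings, lambda = (a/1.702)/sqrt((a/1.702)^2 + 1).

Calibration is marginal maximum likelihood via EM with fixed quadrature on
[-5, 5] under a standard-normal latent density.  Scoring offers maximum
likelihood (bounded to [-4, 4]) and Bayesian modal (MAP) estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .types import GRMItem, ItemBank, ResponseMatrix, ThetaEstimate

log = logging.getLogger(__name__)

__all__ = [
    "category_probs",
    "item_information",
    "test_information",
    "info_curve",
    "fit_grm",
    "GRMFit",
    "score_ml",
    "score_map",
    "yen_q3",
    "Q3Result",
    "form_testlet",
    "item_fit",
]

THETA_BOUNDS = (-4.0, 4.0)
_TINY = 1e-300


# ---------------------------------------------------------------------------
# probabilities and information


def _boundary_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P*_k(theta) for k=0..m, shape (len(theta), m+1); P*_0=1, P*_m=0."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ps = expit(a * (theta[:, None] - b[None, :]))
    ones = np.ones((len(theta), 1))
    zeros = np.zeros((len(theta), 1))
    return np.concatenate([ones, ps, zeros], axis=1)


def category_probs(item: GRMItem, theta: float | np.ndarray) -> np.ndarray:
    """Category probabilities P_k(theta), k = 0..m-1.

    Returns shape ``(m,)`` for scalar theta, else ``(len(theta), m)``.
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    ps = _boundary_probs(item.a, item.b, theta)
    p = ps[:, :-1] - ps[:, 1:]
    return p[0] if scalar else p


def item_information(item: GRMItem, theta: float | np.ndarray) -> float | np.ndarray:
    """Samejima item information I(theta) = sum_k (P*'_k - P*'_{k+1})^2 / P_k.

    P*'_k = a P*_k (1 - P*_k) is the derivative of the boundary curve;
    this equals the expected (Fisher) information of the item at theta.
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    ps = _boundary_probs(item.a, item.b, theta)
    dps = item.a * ps * (1.0 - ps)
    p = np.clip(ps[:, :-1] - ps[:, 1:], _TINY, None)
    info = np.sum((dps[:, :-1] - dps[:, 1:]) ** 2 / p, axis=1)
    return float(info[0]) if scalar else info


def test_information(bank: ItemBank, theta: float | np.ndarray) -> float | np.ndarray:
    """Test information: the sum of item informations at theta."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    return sum(item_information(it, theta) for it in bank)


def info_curve(bank: ItemBank, grid: np.ndarray):
    """Tabulate (theta, information, SE) over a theta grid.

    SE = 1/sqrt(I); grid points with zero information get SE = inf.
    """
    import pandas as pd

    grid = np.asarray(grid, dtype=float)
    info = np.asarray(test_information(bank, grid), dtype=float)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(info)
    return pd.DataFrame({"theta": grid, "information": info, "se": se})


# ---------------------------------------------------------------------------
# scoring


def _log_likelihood(bank: ItemBank, responses: dict[str, int], theta: np.ndarray):
    """Sum of log category probabilities at each theta (vectorized)."""
    theta = np.atleast_1d(theta)
    ll = np.zeros(len(theta))
    for item_id, x in responses.items():
        it = bank[item_id]
        ps = _boundary_probs(it.a, it.b, theta)
        ll += np.log(np.clip(ps[:, x] - ps[:, x + 1], _TINY, None))
    return ll


def _as_response_dict(bank: ItemBank, responses) -> dict[str, int]:
    if isinstance(responses, dict):
        return {k: int(v) for k, v in responses.items()}
    # sequence aligned with the bank
    return {it.item_id: int(x) for it, x in zip(bank, responses)}


def score_ml(bank: ItemBank, responses) -> ThetaEstimate:
    """Maximum-likelihood trait estimate on [-4, 4].

    ``responses`` is either a dict ``{item_id: category}`` (partial patterns)
    or a sequence aligned with the bank.  All-floor / all-ceiling patterns
    have no interior maximum: the estimate is clamped to the bound and
    flagged ``converged=False``.  SE = 1/sqrt(I(theta_hat)) over the
    administered items.
    """
    resp = _as_response_dict(bank, responses)
    if not resp:
        raise ValueError("need at least one response")
    sub = bank.subset(list(resp))
    xs = np.array(list(resp.values()))
    tops = np.array([sub[i].n_categories - 1 for i in resp])
    lo, hi = THETA_BOUNDS
    if np.all(xs == 0):
        theta, converged = lo, False
    elif np.all(xs == tops):
        theta, converged = hi, False
    else:
        res = optimize.minimize_scalar(
            lambda t: -_log_likelihood(sub, resp, t)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        theta = float(res.x)
        converged = bool(res.success) and lo + 1e-4 < theta < hi - 1e-4
    info = test_information(sub, theta)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return ThetaEstimate(float(theta), float(se), "ML", converged)


def score_map(
    bank: ItemBank,
    responses=None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> ThetaEstimate:
    """Bayesian modal (MAP) estimate under a normal prior.

    With no responses the prior mode is returned (theta = prior_mean,
    SE = prior_sd).  SE = 1/sqrt(I(theta_hat) + 1/prior_sd^2): the prior
    contributes information, so the MAP SE is below the ML SE on the same
    responses.
    """
    resp = _as_response_dict(bank, responses) if responses else {}
    if not resp:
        return ThetaEstimate(prior_mean, prior_sd, "MAP", True)
    sub = bank.subset(list(resp))

    def neg_post(t):
        return -(
            _log_likelihood(sub, resp, t)[0]
            - 0.5 * ((t - prior_mean) / prior_sd) ** 2
        )

    res = optimize.minimize_scalar(
        neg_post, bounds=THETA_BOUNDS, method="bounded", options={"xatol": 1e-6}
    )
    theta = float(res.x)
    info = test_information(sub, theta) + 1.0 / prior_sd**2
    return ThetaEstimate(theta, float(1.0 / np.sqrt(info)), "MAP", bool(res.success))


# ---------------------------------------------------------------------------
# calibration (MML-EM)


@dataclass
class GRMFit:
    """Result of a marginal-maximum-likelihood GRM calibration."""

    bank: ItemBank
    loadings: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_trace: list[float] = field(default_factory=list)
    item_fit: "object | None" = None


def _quadrature(n_points: int = 41, bound: float = 5.0):
    """Fixed quadrature: equally spaced nodes weighted by the N(0,1) density."""
    nodes = np.linspace(-bound, bound, n_points)
    w = stats.norm.pdf(nodes)
    return nodes, w / w.sum()


def _item_log_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    ps = _boundary_probs(a, b, nodes)
    return np.log(np.clip(ps[:, :-1] - ps[:, 1:], _TINY, None))


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    return np.concatenate([[np.log(a), b[0]], np.log(np.diff(b))])


def _unpack(t: np.ndarray):
    a = np.exp(t[0])
    b = np.concatenate([[t[1]], t[1] + np.cumsum(np.exp(t[2:]))])
    return a, b


def _mstep_item(r: np.ndarray, nodes: np.ndarray, t0: np.ndarray) -> np.ndarray:
    """Maximize the expected complete-data log-likelihood for one item.

    ``r`` is the (n_quadrature, m) table of expected category counts.
    Thresholds stay ordered via a log-gap parametrization; the quasi-Newton
    step replaces per-item Newton iterations (same fixed point).
    """

    def neg(t):
        a, b = _unpack(t)
        return -float(np.sum(r * _item_log_prob_table(a, b, nodes)))

    res = optimize.minimize(neg, t0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
    res2 = optimize.minimize(neg, res.x, method="BFGS",
                             options={"gtol": 1e-7, "maxiter": 100})
    return res2.x if res2.fun <= res.fun else res.x


def fit_grm(
    data: ResponseMatrix,
    n_quadrature: int = 41,
    tol: float = 1e-4,
    max_iter: int = 500,
    fixed_items: dict[str, GRMItem] | None = None,
    compute_se: bool = True,
) -> GRMFit:
    """Calibrate a GRM by marginal maximum likelihood (EM).

    The latent density is standard normal, approximated by ``n_quadrature``
    equally spaced nodes on [-5, 5] weighted by the normal density.  The
    E-step computes each person's posterior over nodes; the M-step updates
    each item separately.  Convergence: max absolute parameter change < tol.

    ``fixed_items`` pins named items at given parameters (used for anchored
    recalibration in DIF adjustment).  Standard errors come from the
    empirical cross-product of per-person marginal score vectors.

    Items missing observed categories have those categories collapsed into
    the nearest lower category before fitting (logged); thresholds that
    collide during iteration are re-ordered with a small jitter.
    """
    X = data.values.copy()
    m = data.n_categories
    p = data.n_items
    n = data.n_persons
    fixed_items = fixed_items or {}

    # collapse unobserved categories (per item) so every threshold is
    # estimable; fixed items keep all categories (their parameters are given)
    collapse_maps = []
    for j in range(p):
        if data.item_ids[j] in fixed_items:
            collapse_maps.append(m)
            continue
        seen = np.unique(X[:, j])
        if len(seen) < 2:
            raise ValueError(f"item {data.item_ids[j]} is constant")
        remap = np.zeros(m, dtype=int)
        new = {int(c): k for k, c in enumerate(seen)}
        for c in range(m):
            lower = [s for s in seen if s <= c]
            remap[c] = new[int(lower[-1])] if lower else 0
        if len(seen) < m:
            log.info(
                "item %s: collapsing %d unobserved categories",
                data.item_ids[j], m - len(seen),
            )
            X[:, j] = remap[X[:, j]]
        collapse_maps.append(len(seen))

    nodes, w = _quadrature(n_quadrature)
    logw = np.log(w)

    # starting values: a=1, thresholds from marginal cumulative proportions
    params: list[tuple[float, np.ndarray]] = []
    for j in range(p):
        iid = data.item_ids[j]
        if iid in fixed_items:
            params.append((fixed_items[iid].a, fixed_items[iid].b.copy()))
            continue
        mj = collapse_maps[j]
        cum = np.array([(X[:, j] >= k).mean() for k in range(1, mj)])
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        b0 = -stats.norm.ppf(cum)
        b0 = np.sort(b0)
        for k in range(1, len(b0)):  # enforce strict order
            if b0[k] <= b0[k - 1]:
                b0[k] = b0[k - 1] + 1e-3
        params.append((1.0, b0))

    onehot = [
        np.eye(collapse_maps[j])[X[:, j]] for j in range(p)
    ]  # (n, m_j) per item

    ll_trace: list[float] = []
    converged = False
    it_count = 0
    for it_count in range(1, max_iter + 1):
        tables = [
            _item_log_prob_table(a, b, nodes) for a, b in params
        ]  # (q, m_j)
        logL = logw[None, :] + sum(
            onehot[j] @ tables[j].T for j in range(p)
        )  # (n, q)
        ll = float(logsumexp(logL, axis=1).sum())
        ll_trace.append(ll)
        W = np.exp(logL - logsumexp(logL, axis=1, keepdims=True))  # posteriors

        max_change = 0.0
        new_params = []
        for j in range(p):
            iid = data.item_ids[j]
            if iid in fixed_items:
                new_params.append(params[j])
                continue
            r = W.T @ onehot[j]  # (q, m_j) expected counts
            a0, b0 = params[j]
            t_new = _mstep_item(r, nodes, _pack(a0, b0))
            a1, b1 = _unpack(t_new)
            if np.any(np.diff(b1) < 1e-6):  # threshold collision
                log.warning("item %s: jittering colliding thresholds", iid)
                b1 = np.sort(b1) + np.arange(len(b1)) * 1e-4
            max_change = max(
                max_change, abs(a1 - a0), float(np.max(np.abs(b1 - b0)))
            )
            new_params.append((a1, b1))
        params = new_params
        if max_change < tol:
            converged = True
            break
    if not converged:
        log.warning("EM did not converge in %d iterations", max_iter)

    se = _empirical_se(X, params, onehot, nodes, logw, fixed_items, data.item_ids) \
        if compute_se else [None] * p

    items = []
    for j in range(p):
        a, b = params[j]
        se_j = se[j]
        items.append(
            GRMItem(
                data.item_ids[j], float(a), b,
                se_a=None if se_j is None else float(se_j[0]),
                se_b=None if se_j is None else np.asarray(se_j[1:]),
            )
        )
    bank = ItemBank(items)
    loadings = np.array([it.loading for it in bank])
    return GRMFit(bank, loadings, ll_trace[-1], converged, it_count, ll_trace)


def _empirical_se(X, params, onehot, nodes, logw, fixed_items, item_ids):
    """SEs from the empirical cross-product of per-person score vectors.

    Scores of the marginal log-likelihood are obtained by central finite
    differences on (a, b) directly; the information matrix is approximated
    by sum_p s_p s_p' over persons.
    """
    p = len(params)
    tables = [_item_log_prob_table(a, b, nodes) for a, b in params]
    base_terms = [onehot[j] @ tables[j].T for j in range(p)]  # (n, q) each
    total = logw[None, :] + sum(base_terms)
    free = [j for j in range(p) if item_ids[j] not in fixed_items]
    h = 1e-4
    scores = []
    for j in free:
        a, b = params[j]
        for k in range(1 + len(b)):
            cols = []
            for sgn in (+1, -1):
                aa, bb = a, b.copy()
                if k == 0:
                    aa = a + sgn * h
                else:
                    bb[k - 1] += sgn * h
                tab = _item_log_prob_table(aa, np.sort(bb), nodes)
                term = onehot[j] @ tab.T
                cols.append(logsumexp(total - base_terms[j] + term, axis=1))
            scores.append((cols[0] - cols[1]) / (2 * h))
    if not scores:
        return [None] * p
    S = np.column_stack(scores)  # (n, n_free_params)
    info = S.T @ S
    try:
        cov = np.linalg.pinv(info)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return [None] * p
    out: list = [None] * p
    pos = 0
    for j in free:
        npar = 1 + len(params[j][1])
        out[j] = ses[pos:pos + npar]
        pos += npar
    return out


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class Q3Result:
    """Yen's Q3 residual-correlation matrix with flagged item pairs."""

    item_ids: list[str]
    q3_matrix: np.ndarray
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float = 0.20


def yen_q3(data: ResponseMatrix, bank: ItemBank, threshold: float = 0.20) -> Q3Result:
    """Local-dependence check: correlations of item residuals given theta.

    Each person is scored by MAP on their full response vector (MAP rather
    than ML so extreme responders stay finite); the residual for item i is
    x_i - E[x_i | theta_hat] with E = sum_k k P_k.  |Q3| above the threshold
    (default 0.20) flags a locally dependent pair.
    """
    ids = data.item_ids
    sub = bank.subset(ids)
    thetas = np.array(
        [score_map(sub, dict(zip(ids, row))).theta for row in data.values]
    )
    resid = np.empty_like(data.values, dtype=float)
    for j, it in enumerate(sub):
        p = category_probs(it, thetas)  # (n, m)
        expected = p @ np.arange(it.n_categories)
        resid[:, j] = data.values[:, j] - expected
    if np.any(resid.std(axis=0) == 0):
        raise ValueError("zero residual variance for at least one item")
    q3 = np.corrcoef(resid, rowvar=False)
    flagged = [
        (ids[i], ids[j], float(q3[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if abs(q3[i, j]) > threshold
    ]
    return Q3Result(ids, q3, flagged, threshold)


def form_testlet(
    data: ResponseMatrix, item_ids: list[str], testlet_id: str | None = None
) -> ResponseMatrix:
    """Collapse locally dependent items into one summed polytomous super-item.

    The named items are removed and replaced (at the position of the first)
    by their per-person sum, a single item with sum(m_i - 1) + 1 ordered
    categories.
    """
    if len(item_ids) < 2:
        raise ValueError("a testlet needs at least 2 distinct items")
    if len(set(item_ids)) != len(item_ids):
        raise ValueError("duplicate items in testlet")
    missing = [i for i in item_ids if i not in data.item_ids]
    if missing:
        raise ValueError(f"items not in matrix: {missing}")
    idx = [data.item_ids.index(i) for i in item_ids]
    summed = data.values[:, idx].sum(axis=1)
    keep = [j for j in range(data.n_items) if j not in idx]
    pos = min(idx)
    new_ids, cols = [], []
    inserted = False
    for j in range(data.n_items):
        if j in idx:
            if not inserted:
                new_ids.append(testlet_id or "+".join(item_ids))
                cols.append(summed)
                inserted = True
            continue
        new_ids.append(data.item_ids[j])
        cols.append(data.values[:, j])
    m_new = len(idx) * (data.n_categories - 1) + 1
    return ResponseMatrix(
        np.column_stack(cols), new_ids,
        groups=None if data.groups is None else data.groups.copy(),
        coding_offset=data.coding_offset,
        n_categories=m_new,
    )


def item_fit(data: ResponseMatrix, fit: GRMFit, n_strata: int = 10):
    """Stratified Pearson chi-square item-fit check.

    For each item, persons are stratified into ``n_strata`` groups by their
    rest-score EAP theta (posterior excluding the item under test, so the
    item's own response cannot drive its stratum), and observed category
    counts are compared with model-expected counts.  Expectations average
    each person's category probabilities over their rest-score posterior
    (fixed quadrature under the standard-normal latent density), so
    trait-estimation error does not masquerade as misfit.  Expected cells
    below 5 are pooled into the neighbouring category; df = (used cells) -
    (strata) - (item parameter count), floored at 1.  Returns a DataFrame
    with columns item_id, statistic, df, p.
    """
    import pandas as pd

    bank = fit.bank.subset(data.item_ids)
    n = data.n_persons

    # per-item log-likelihood contributions over quadrature nodes
    nodes, w = _quadrature()
    logw = np.log(w)
    contribs = []
    for j, it in enumerate(bank):
        tab = _item_log_prob_table(it.a, it.b, nodes)  # (q, m_j)
        contribs.append(tab.T[data.values[:, j]])  # (n, q)
    logL_total = np.tile(logw, (n, 1)) + sum(contribs)

    n_strata = min(n_strata, max(n // (2 * data.n_categories), 1))

    rows = []
    for j, it in enumerate(bank):
        m = it.n_categories
        logL_rest = logL_total - contribs[j]
        W = np.exp(logL_rest - logsumexp(logL_rest, axis=1, keepdims=True))
        thetas = W @ nodes  # rest-score EAP
        order = np.argsort(thetas)
        sizes = np.full(n_strata, n // n_strata)
        sizes[: n % n_strata] += 1
        strata = np.empty(n, dtype=int)
        pos = 0
        for s, size in enumerate(sizes):
            strata[order[pos:pos + size]] = s
            pos += size

        probs_q = category_probs(it, nodes)  # (q, m)
        stat, used = 0.0, 0
        for s in range(len(sizes)):
            mask = strata == s
            obs = np.bincount(data.values[mask, j], minlength=m).astype(float)
            exp = (W[mask] @ probs_q).sum(axis=0)
            # pool low-expected cells into a neighbouring category
            while len(exp) > 1 and exp.min() < 5:
                small = int(np.argmin(exp))
                nb = small - 1 if small > 0 else 1
                exp[nb] += exp[small]
                obs[nb] += obs[small]
                exp = np.delete(exp, small)
                obs = np.delete(obs, small)
            stat += float(np.sum((obs - exp) ** 2 / np.clip(exp, 1e-12, None)))
            used += len(exp)
        n_par = 1 + len(it.b)
        df = max(used - len(sizes) - n_par, 1)
        rows.append(
            {
                "item_id": it.item_id,
                "statistic": stat,
                "df": df,
                "p": float(stats.chi2.sf(stat, df)),
            }
        )
    return pd.DataFrame(rows)
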