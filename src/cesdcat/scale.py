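"""Scale-level evaluation: internal consistency, one-factor CFA, Mokken
scalability with iterative item removal.

The CFA treats the Likert item scores as continuous and fits a single
common factor by maximum likelihood on the correlation matrix, with the
usual chi-square, CFI, TLI and RMSEA (90% CI) fit summary.  Mokken
scalability uses Loevinger's H: the ratio of observed item-pair covariance
to the maximum covariance attainable under the items' marginal category
distributions (the comonotone coupling).  Items and scales with H >= 0.30
are conventionally scalable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .types import ResponseMatrix

__all__ = [
    "cronbach_alpha",
    "CFAFit",
    "fit_one_factor_cfa",
    "MokkenResult",
    "mokken_scalability",
    "mokken_item_selection",
]


def cronbach_alpha(data: ResponseMatrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    X = data.values
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


# ---------------------------------------------------------------------------
# one-factor CFA


@dataclass
class CFAFit:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    n: int
    converged: bool
    heywood: bool


def _fml(S: np.ndarray, lam: np.ndarray, psi: np.ndarray) -> float:
    p = len(lam)
    Sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """Noncentral-chi-square inversion CI for RMSEA."""

    def bound(prob):
        # find nc with ncx2.cdf(chi2, df, nc) = prob
        if stats.ncx2.cdf(chi2, df, 0) < prob:
            return 0.0
        hi = max(chi2, df) * 2 + 10
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2
        return optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2, df, nc) - prob, 0, hi, xtol=1e-8
        )

    alpha = (1 - level) / 2
    nc_lo = bound(1 - alpha)
    nc_hi = bound(alpha)
    conv = df * (n - 1)
    return (np.sqrt(nc_lo / conv), np.sqrt(nc_hi / conv))


def fit_one_factor_cfa(data: ResponseMatrix) -> CFAFit:
    """Fit a single-common-factor model by maximum likelihood.

    Minimizes F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p over loadings
    and uniquenesses, on the correlation matrix (standardized variables),
    with analytic gradients.  chi^2 = (n-1) F_ML; CFI/TLI are computed
    against the independence baseline and truncated to [0, 1]; RMSEA with
    a 90% noncentral-chi-square CI.  Heywood cases are prevented by a small
    uniqueness floor (flagged when active).
    """
    X = data.values.astype(float)
    n, p = X.shape
    S = np.corrcoef(X, rowvar=False)
    if not np.all(np.linalg.eigvalsh(S) > 1e-10):
        raise ValueError("correlation matrix is not positive definite")

    floor = 0.005
    evals, evecs = np.linalg.eigh(S)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1] - 1.0, 0.1))
    lam0 = np.sign(lam0.sum() or 1.0) * lam0
    u0 = np.log(np.clip(1.0 - lam0**2, 0.05, None) - 0.0)

    def unpack(t):
        lam = t[:p]
        psi = floor + np.exp(t[p:])
        return lam, psi

    def obj_grad(t):
        lam, psi = unpack(t)
        Sigma = np.outer(lam, lam) + np.diag(psi)
        Sinv = np.linalg.inv(Sigma)
        f = _fml(S, lam, psi)
        G = Sinv - Sinv @ S @ Sinv  # dF/dSigma
        g_lam = 2.0 * G @ lam
        g_psi = np.diag(G) * (psi - floor)  # chain rule through exp
        return f, np.concatenate([g_lam, g_psi])

    res = optimize.minimize(
        obj_grad,
        np.concatenate([lam0, u0]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam, psi = unpack(res.x)
    if lam.sum() < 0:  # sign indeterminacy
        lam = -lam
    heywood = bool(np.any(psi <= floor + 1e-6))

    fmin = _fml(S, lam, psi)
    chi2 = (n - 1) * fmin
    df = p * (p + 1) // 2 - 2 * p
    # independence baseline: Sigma = I (correlation metric)
    _, logdet_s = np.linalg.slogdet(S)
    chi2_b = (n - 1) * float(-logdet_s)
    df_b = p * (p - 1) // 2

    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - d / max(d_b, d, 1e-12)
    if df > 0:
        denom = chi2_b / df_b - 1.0
        tli = (chi2_b / df_b - chi2 / df) / denom if denom > 0 else 1.0
        rmsea = float(np.sqrt(d / (df * (n - 1))))
        ci = _rmsea_ci(chi2, df, n)
    else:  # saturated model: perfect fit by construction
        tli, rmsea, ci = 1.0, 0.0, (0.0, 0.0)
    cfi = float(np.clip(cfi, 0.0, 1.0))
    tli = float(np.clip(tli, 0.0, 1.0))
    return CFAFit(
        loadings=lam,
        uniquenesses=psi,
        chi_square=float(chi2),
        df=df,
        chi_square_baseline=float(chi2_b),
        df_baseline=df_b,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        rmsea_ci=(float(ci[0]), float(ci[1])),
        n=n,
        converged=bool(res.success),
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# Mokken scalability


@dataclass
class MokkenResult:
    item_ids: list[str]
    item_H: np.ndarray
    item_H_se: np.ndarray
    scale_H: float
    pair_H: np.ndarray
    removed_items: list[str] = field(default_factory=list)


def _pair_cov_and_max(X: np.ndarray):
    """Observed covariances and their comonotone-coupling maxima.

    sigma_max for a pair is the covariance when both marginals are coupled
    comonotonically, i.e. the columns independently sorted and paired.
    """
    n, p = X.shape
    cov = np.cov(X, rowvar=False, ddof=1)
    Xs = np.sort(X, axis=0)
    mu = X.mean(axis=0)
    exy_max = (Xs.T @ Xs) / (n - 1)
    covmax = exy_max - np.outer(mu, mu) * n / (n - 1)
    return cov, covmax


def mokken_scalability(data: ResponseMatrix) -> MokkenResult:
    """Loevinger's H at pair, item and scale level.

    H_ij = sigma_ij / sigma_ij^max; H_i and scale H are the corresponding
    ratios of sums.  Item standard errors use a first-order (delta-method)
    approximation: the variance of the numerator sums via per-person
    influence values, denominators treated as fixed.
    """
    X = data.values.astype(float)
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 items")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant item (zero variance)")
    cov, covmax = _pair_cov_and_max(X)
    off = ~np.eye(p, dtype=bool)
    pair_H = np.full((p, p), np.nan)
    pair_H[off] = cov[off] / covmax[off]

    num_i = (cov * off).sum(axis=1)
    den_i = (covmax * off).sum(axis=1)
    item_H = num_i / den_i
    iu = np.triu_indices(p, 1)
    scale_H = float(cov[iu].sum() / covmax[iu].sum())

    # influence values for S_i = sum_{j != i} sigma_ij
    Xc = X - X.mean(axis=0)
    psi = Xc * (Xc.sum(axis=1, keepdims=True) - Xc) - num_i[None, :]
    var_S = psi.var(axis=0, ddof=1) / n
    item_H_se = np.sqrt(var_S) / den_i

    return MokkenResult(
        list(data.item_ids), item_H, item_H_se, scale_H, pair_H
    )


def mokken_item_selection(data: ResponseMatrix, h_min: float = 0.30) -> MokkenResult:
    """Iteratively drop the weakest item while its H_i falls below h_min.

    One item is removed per pass (the lowest H_i under the threshold) and
    all coefficients are recomputed, mirroring the repeat-until-clean
    strategy used in scale evaluation.  Stops with an error if fewer than
    3 items would remain.
    """
    current = data
    removed: list[str] = []
    while True:
        res = mokken_scalability(current)
        worst = int(np.argmin(res.item_H))
        if res.item_H[worst] >= h_min:
            res.removed_items = removed
            return res
        if current.n_items <= 3:
            raise ValueError("fewer than 3 items would remain")
        removed.append(res.item_ids[worst])
        keep = [i for i in current.item_ids if i != res.item_ids[worst]]
        current = current.subset(keep)
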