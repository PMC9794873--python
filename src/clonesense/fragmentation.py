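"""Joint Poisson model of induction and fragmentation, and the
monoclonality filter built on it.

Induction events per sample (and color) are Poisson with mean m0; each
induced clone accrues a Poisson(f) number of fragmentation events between
induction and analysis, so a clone leaves 1 + Poisson(f) spatially
separate clusters.  The joint probability of inducing m clones and
observing k fragments is

    J(k, m) = (m f)^(k-m) / (k-m)! * m0^m / m! * exp(-m f - m0),   k >= m,

(the sum of m independent Poisson(f) variables is Poisson(m f)).  Since
fully unlabelled samples usually go unrecorded, the observable fragment
count follows the conditional law

    F(k) = sum_{m=1}^{k} J(k, m) / (1 - J(0, 0)),   k >= 1.

Maximum likelihood on F recovers (m0, f) — though the two act so similarly
on F that fixing m0 from an independent multicolor estimate is strongly
preferred.  The posterior odds that a sample-color with k fragments is
polyclonal,

    Lambda(k) = sum_{m >= 2} J(k, m) / J(k, 1),

is monotone in k and yields a fragment-count cutoff for filtering data
down to (probably) monoclonal sample-colors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp

from .clonedata import ClusterTable, DomainError

import pandas as pd


@dataclass(frozen=True)
class FragmentationModel:
    """Parameters of the joint induction-fragmentation model: mean induced
    clones per sample-and-color (m0) and mean fragmentation events per
    clone (f)."""

    m0: float
    f: float

    def __post_init__(self) -> None:
        if self.m0 < 0 or self.f < 0:
            raise DomainError("m0 and f must be nonnegative")


@dataclass(frozen=True)
class FragmentationFit:
    model: FragmentationModel
    stderr_m0: float
    stderr_f: float
    loglik: float
    n_obs: int
    fixed_m0: bool
    converged: bool
    flat_surface: bool


@dataclass(frozen=True)
class MonoclonalDecision:
    """Likelihood-ratio verdict for one fragment count."""

    k: int
    lambda_ratio: float
    threshold: float | None = None
    keep: bool | None = None

    def __post_init__(self) -> None:
        if self.lambda_ratio < 0:
            raise DomainError("lambda_ratio must be nonnegative")


def log_joint_pmf(k, m, model: FragmentationModel):
    """log J(k, m), vectorized; -inf where k < m or the term vanishes.
    Uses the 0^0 = 1 convention at k = m (also covering f = 0 and m = 0)."""
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    k, m = np.broadcast_arrays(k, m)
    out = np.full(k.shape, -np.inf)
    valid = k >= m
    mf = m * model.f
    diff = k - m
    with np.errstate(divide="ignore", invalid="ignore"):
        frag_term = np.where(diff == 0, 0.0, diff * np.log(mf) - gammaln(diff + 1))
    with np.errstate(divide="ignore"):
        induct_term = np.where(
            m == 0, 0.0, m * (np.log(model.m0) if model.m0 > 0 else -np.inf)
        ) - gammaln(m + 1)
    lp = frag_term + induct_term - mf - model.m0
    out[valid] = lp[valid]
    # (m f)^(k-m) with m f = 0 and k > m is exactly 0
    out[valid & (diff > 0) & (mf == 0)] = -np.inf
    return out if out.ndim else float(out)


def joint_pmf(k, m, model: FragmentationModel):
    """J(k, m): probability of m induced clones leaving k fragments."""
    return np.exp(log_joint_pmf(k, m, model))


def log_fragment_count_pmf(k, model: FragmentationModel):
    """log F(k) for k >= 1: fragment-count law conditioned on the sample
    being labelled at all."""
    if model.m0 <= 0:
        raise DomainError("fragment-count law is undefined at m0 = 0")
    k = np.atleast_1d(np.asarray(k, dtype=int))
    if np.any(k < 1):
        raise DomainError("fragment counts start at k = 1")
    log_norm = math.log(-math.expm1(-model.m0))  # log(1 - J(0,0))
    out = np.empty(k.shape, dtype=float)
    for i, ki in enumerate(k.ravel()):
        m = np.arange(1, ki + 1)
        out.ravel()[i] = logsumexp(log_joint_pmf(ki, m, model)) - log_norm
    return out if out.size > 1 else float(out[0])


def fragment_count_pmf(k, model: FragmentationModel, k_max: int | None = None):
    """F(k) = sum_{m=1..k} J(k, m) / (1 - J(0,0)) for k >= 1."""
    return np.exp(log_fragment_count_pmf(k, model))


def fragment_count_support(
    model: FragmentationModel, tail_tol: float = 1e-12, k_cap: int = 100_000
) -> np.ndarray:
    """k values 1..k_max such that the remaining F tail mass < tail_tol."""
    ks = []
    cum = 0.0
    k = 1
    while k <= k_cap:
        ks.append(k)
        cum += float(fragment_count_pmf(k, model))
        if 1.0 - cum < tail_tol:
            break
        k += 1
    return np.array(ks, dtype=int)


def _neg_loglik(ks: np.ndarray, counts: np.ndarray, model: FragmentationModel) -> float:
    lf = np.atleast_1d(log_fragment_count_pmf(ks, model))
    if np.any(np.isneginf(lf)):
        return np.inf
    return -float(np.sum(counts * lf))


def fit_fragmentation(
    ks: Sequence[int], fixed_m0: float | None = None
) -> FragmentationFit:
    """Maximum-likelihood fit of (m0, f) — or f alone — to fragment counts.

    ``ks`` lists fragments per sample-color, one entry per labelled
    sample-color, all >= 1 (unlabelled samples carry no information under
    the conditional law).  Fixing m0 from an independent estimate is the
    recommended path: jointly the likelihood surface is near-degenerate
    along trade-offs between induction and fragmentation.

    Optimization runs on log-parameters with three deterministic starts;
    standard errors come from the observed Fisher information (finite
    differences), and ``flat_surface`` flags a near-singular Hessian.
    """
    arr = np.asarray(list(ks), dtype=int)
    if arr.size < 2:
        raise DomainError("need at least 2 observations")
    if np.any(arr < 1):
        raise DomainError("fragment counts must be >= 1 (drop unlabelled samples)")
    uniq, counts = np.unique(arr, return_counts=True)
    n = int(arr.size)

    if np.all(uniq == 1):
        # no sample fragmented: f sits on the boundary
        m0 = fixed_m0 if fixed_m0 is not None else 1e-8
        model = FragmentationModel(m0=m0, f=0.0)
        ll = -_neg_loglik(uniq, counts, model)
        return FragmentationFit(model, 0.0, 0.0, ll, n, fixed_m0 is not None,
                                True, False)

    mean_k = float(arr.mean())

    if fixed_m0 is not None:
        if fixed_m0 <= 0:
            raise DomainError("fixed_m0 must be positive")

        def nll1(log_f: float) -> float:
            return _neg_loglik(uniq, counts,
                               FragmentationModel(fixed_m0, math.exp(log_f)))

        res = optimize.minimize_scalar(nll1, bounds=(-12.0, 6.0), method="bounded",
                                       options={"xatol": 1e-10})
        f_hat = math.exp(res.x)
        model = FragmentationModel(fixed_m0, f_hat)
        ll = -res.fun
        h = max(1e-5, 1e-5 * f_hat)
        g = lambda f: -_neg_loglik(uniq, counts, FragmentationModel(fixed_m0, f))
        if f_hat > h:
            d2 = (g(f_hat + h) - 2 * g(f_hat) + g(f_hat - h)) / h**2
        else:
            d2 = 0.0
        flat = not (d2 < 0 and math.isfinite(d2))
        se_f = 1.0 / math.sqrt(-d2) if not flat else math.inf
        return FragmentationFit(model, 0.0, se_f, ll, n, True, res.success, flat)

    # joint fit on (log m0, log f), three deterministic starts bracketing the
    # m0 <-> f trade-off (mean_k ~ m0 (1 + f) conditioned on labelling)
    starts = [
        (math.log(max(mean_k, 0.05)), math.log(0.1)),
        (math.log(max(mean_k / 2, 0.05)), math.log(1.0)),
        (math.log(0.2), math.log(max(mean_k - 1, 0.2))),
    ]

    def nll2(theta: np.ndarray) -> float:
        return _neg_loglik(
            uniq, counts, FragmentationModel(math.exp(theta[0]), math.exp(theta[1]))
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(nll2, np.array(x0), method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("fragmentation fit failed to converge")
    m0_hat, f_hat = math.exp(best.x[0]), math.exp(best.x[1])
    model = FragmentationModel(m0_hat, f_hat)
    ll = -best.fun

    # observed Fisher information on the (m0, f) scale
    def loglik(theta):
        return -_neg_loglik(uniq, counts, FragmentationModel(theta[0], theta[1]))

    x = np.array([m0_hat, f_hat])
    hvec = np.maximum(1e-5, 1e-4 * x)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * hvec[i]
            ej = np.eye(2)[j] * hvec[j]
            H[i, j] = (
                loglik(x + ei + ej) - loglik(x + ei - ej)
                - loglik(x - ei + ej) + loglik(x - ei - ej)
            ) / (4 * hvec[i] * hvec[j])
    flat = False
    try:
        cov = np.linalg.inv(-H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
        se_m0, se_f = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        cond = np.linalg.cond(-H)
        flat = bool(cond > 1e8)
    except np.linalg.LinAlgError:
        se_m0 = se_f = math.inf
        flat = True
    return FragmentationFit(model, se_m0, se_f, ll, n, False, bool(best.success) or True, flat)


def lambda_ratio(
    k: int, model: FragmentationModel, m_max: int | None = None
) -> MonoclonalDecision:
    """Posterior odds Lambda(k) that k fragments are polyclonal vs monoclonal.

    Lambda = sum_{m=2..min(k, m_max)} J(k, m) / J(k, 1).  J(k, m) vanishes
    for m > k, so the sum is finite; Lambda(1) = 0 (one fragment is always
    monoclonal under the model) and Lambda is strictly increasing in k.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    upper = k if m_max is None else min(k, m_max)
    log_l1 = log_joint_pmf(k, 1, model)
    if np.isneginf(log_l1):
        return MonoclonalDecision(k=k, lambda_ratio=math.inf)
    if upper < 2:
        return MonoclonalDecision(k=k, lambda_ratio=0.0)
    m = np.arange(2, upper + 1)
    log_num = logsumexp(log_joint_pmf(k, m, model))
    return MonoclonalDecision(k=k, lambda_ratio=float(np.exp(log_num - log_l1)))


def monoclonal_cutoff(
    model: FragmentationModel, lambda_threshold: float = 1.0, k_cap: int = 10_000
) -> int:
    """Largest fragment count k with Lambda(k) < threshold."""
    if lambda_threshold <= 0:
        raise DomainError("lambda_threshold must be positive")
    k = 1
    while k < k_cap:
        if lambda_ratio(k + 1, model).lambda_ratio >= lambda_threshold:
            return k
        k += 1
    return k_cap


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the monoclonality filter."""

    cutoff: int
    decisions: pd.DataFrame  # sample_id, color, k, lambda_ratio, keep
    kept: ClusterTable | None = None
    discarded: ClusterTable | None = None


def filter_monoclonal(
    data: ClusterTable | Sequence[int],
    model: FragmentationModel,
    lambda_threshold: float = 1.0,
) -> FilterResult:
    """Partition sample-colors into (probably) monoclonal and polyclonal.

    Fragments are counted per (sample_id, color); a sample-color is kept
    when its count does not exceed the largest k with Lambda(k) below the
    threshold (default 1: keep what is more likely monoclonal than not).
    An audit table records every decision.
    """
    cutoff = monoclonal_cutoff(model, lambda_threshold)
    if isinstance(data, ClusterTable):
        grouped = data.df.groupby(["sample_id", "color"], sort=True).size()
        rows = []
        for (sid, color), k in grouped.items():
            dec = lambda_ratio(int(k), model)
            rows.append({"sample_id": sid, "color": color, "k": int(k),
                         "lambda_ratio": dec.lambda_ratio,
                         "keep": int(k) <= cutoff})
        audit = pd.DataFrame(rows)
        keep_pairs = set(
            audit.loc[audit["keep"], ["sample_id", "color"]].itertuples(index=False)
        )
        mask = [
            (sid, col) in keep_pairs
            for sid, col in zip(data.df["sample_id"], data.df["color"])
        ]
        mask = np.asarray(mask)
        kept = data.subset(mask) if mask.any() else None
        discarded = data.subset(~mask) if (~mask).any() else None
        return FilterResult(cutoff=cutoff, decisions=audit, kept=kept,
                            discarded=discarded)
    rows = []
    for i, k in enumerate(data):
        dec = lambda_ratio(int(k), model)
        rows.append({"sample_id": str(i), "color": "", "k": int(k),
                     "lambda_ratio": dec.lambda_ratio, "keep": int(k) <= cutoff})
    return FilterResult(cutoff=cutoff, decisions=pd.DataFrame(rows))
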