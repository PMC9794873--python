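"""Induction-frequency estimation from multicolor labelling statistics.

When labelling is stochastic, the number of distinct colors observed per
sample carries information about the mean number of induced cells.  With
statistically independent induction across n_C colors, the per-color number
of induced cells is Poisson with mean m0, so a sample is unlabelled in any
one color with probability J = exp(-m0), and the number of colors observed
follows Binomial(n_C, 1 - J).  Inverting the ratio of adjacent color-count
classes C_{n+1}/C_n, or maximizing the multinomial likelihood over all
classes, recovers m0.

Here m0 is *per color*: with equal color usage the expected total number of
induced cells per sample is n_C * m0.  Estimates expose both numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .clonedata import ClusterTable, ColorCountSummary, DomainError


@dataclass(frozen=True)
class InductionEstimate:
    """Estimated induction frequency.

    ``m0`` is the mean number of induced cells per sample *per color*;
    ``m0_total(n_colors)`` gives the expected total under equal color usage.
    """

    m0: float
    stderr: float
    method: str
    n_pairs_used: int

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise DomainError("m0 must be nonnegative")
        if self.stderr < 0:
            raise DomainError("stderr must be nonnegative")

    def m0_total(self, n_colors: int) -> float:
        return self.m0 * n_colors


def color_count_pmf(
    m0: float, n_colors: int, labelled_only: bool = False
) -> np.ndarray:
    """Probability vector over the number of distinct colors n = 0..n_colors.

    Binomial(n_colors, 1 - J) with J = exp(-m0).  With ``labelled_only`` the
    n = 0 class is dropped and the rest renormalized by 1 - J**n_colors,
    matching experiments where unlabelled samples are not recorded.
    """
    if m0 < 0:
        raise DomainError("m0 must be nonnegative")
    if n_colors < 1:
        raise DomainError("n_colors must be >= 1")
    if labelled_only and m0 == 0:
        raise DomainError(
            "labelled-only distribution is undefined at m0 = 0 (nothing is labelled)"
        )
    J = math.exp(-m0)
    n = np.arange(n_colors + 1)
    with np.errstate(divide="ignore"):
        log_binom = (
            gammaln(n_colors + 1) - gammaln(n + 1) - gammaln(n_colors - n + 1)
        )
        # (1-J)^n J^(n_C - n) in logs; handle J -> 0 / 1-J -> 0 endpoints
        log_p = log_binom
        if 1.0 - J > 0:
            log_p = log_p + n * math.log1p(-J)
        else:
            log_p = np.where(n == 0, log_binom, -np.inf)
        if J > 0:
            log_p = log_p + (n_colors - n) * (-m0)
        else:
            log_p = np.where(n == n_colors, log_p, -np.inf)
    p = np.exp(log_p)
    p /= p.sum()
    if labelled_only:
        p[0] = 0.0
        p /= p.sum()
    return p


def default_ratio_index(counts: ColorCountSummary, n_colors: int) -> int:
    """Pick n maximizing min(C_n, C_{n+1}): the ratio estimator's variance is
    dominated by the smaller of the two counts."""
    best_n, best_val = 0, -1
    for n in range(n_colors):
        val = min(counts[n], counts[n + 1])
        if val > best_val:
            best_n, best_val = n, val
    return best_n


def estimate_m0_ratio(
    counts: ColorCountSummary, n: int | None = None, *, n_colors: int
) -> InductionEstimate:
    """Invert the adjacent color-class ratio:

        m0 = log(1 + (n+1)/(n_C - n) * C_{n+1}/C_n)

    Standard error by the delta method treating C_n, C_{n+1} as independent
    Poisson counts (an approximation; the MLE stderr is preferred).
    """
    if n is None:
        n = default_ratio_index(counts, n_colors)
    if not (0 <= n < n_colors):
        raise DomainError(f"need 0 <= n < n_colors, got n={n}")
    c_n, c_n1 = counts[n], counts[n + 1]
    if c_n == 0:
        raise DomainError(
            f"C_{n} = 0: ratio estimator undefined; use estimate_m0_mle instead"
        )
    a = (n + 1) / (n_colors - n)
    ratio = c_n1 / c_n
    m0 = math.log1p(a * ratio)
    if c_n1 == 0:
        stderr = 0.0
    else:
        var_ratio = ratio**2 * (1.0 / c_n1 + 1.0 / c_n)
        stderr = a * math.sqrt(var_ratio) / (1.0 + a * ratio)
    return InductionEstimate(m0=m0, stderr=stderr, method="ratio", n_pairs_used=c_n + c_n1)


def _multinomial_loglik(m0: float, arr: np.ndarray, n_colors: int, labelled_only: bool) -> float:
    p = color_count_pmf(m0, n_colors, labelled_only)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    mask = arr > 0
    if np.any(np.isneginf(logp[mask])):
        return -np.inf
    return float(np.sum(arr[mask] * logp[mask]))


def estimate_m0_mle(
    counts: ColorCountSummary, n_colors: int, labelled_only: bool = False
) -> InductionEstimate:
    """Maximum-likelihood m0 from the full color-count histogram.

    Maximizes the multinomial log-likelihood of the observed C_n under
    :func:`color_count_pmf`; pools information across all classes and is
    usable when individual ratio classes are empty.  Standard error from
    observed Fisher information.  If all mass sits at n = n_colors the
    likelihood is unbounded and m0 = inf is returned.
    """
    arr = counts.as_array(n_colors)
    if labelled_only:
        arr[0] = 0.0
    total = arr.sum()
    if total <= 0:
        raise DomainError("need at least one nonzero count")
    if arr[n_colors] == total:
        return InductionEstimate(
            m0=math.inf, stderr=math.inf, method="mle", n_pairs_used=int(total)
        )
    if not labelled_only and arr[0] == total:
        return InductionEstimate(m0=0.0, stderr=0.0, method="mle", n_pairs_used=int(total))

    def nll(log_m0: float) -> float:
        return -_multinomial_loglik(math.exp(log_m0), arr, n_colors, labelled_only)

    res = optimize.minimize_scalar(nll, bounds=(-20.0, 8.0), method="bounded",
                                   options={"xatol": 1e-12})
    m0_hat = math.exp(res.x)
    # observed Fisher information by central second difference on m0
    h = max(1e-6, 1e-6 * m0_hat)
    ll = lambda m: _multinomial_loglik(m, arr, n_colors, labelled_only)
    if m0_hat > h:
        d2 = (ll(m0_hat + h) - 2 * ll(m0_hat) + ll(m0_hat - h)) / h**2
    else:
        d2 = -math.inf
    stderr = 1.0 / math.sqrt(-d2) if d2 < 0 and math.isfinite(d2) else 0.0
    return InductionEstimate(
        m0=m0_hat, stderr=stderr, method="mle", n_pairs_used=int(total)
    )


def partition_regions(
    table: ClusterTable, region_size: float, min_separation: float = 0.0
) -> list[ClusterTable]:
    """Tile the bounding box into equal regions, discarding buffer strips.

    Large tissues can stand in for independent samples: the bounding box is
    tiled with a period of ``region_size + min_separation`` per axis, and
    clusters falling in the leading ``region_size`` stretch of each cell are
    kept, so kept regions are separated by at least ``min_separation``.
    Each nonempty region becomes one pseudo-sample (sample_id is replaced by
    a region tag).
    """
    if region_size <= 0:
        raise DomainError("region_size must be positive")
    if min_separation < 0:
        raise DomainError("min_separation must be nonnegative")
    coords = table.coords()
    if len(coords) == 0:
        return []
    origin = coords.min(axis=0)
    period = region_size + min_separation
    offset = coords - origin
    cell_index = np.floor(offset / period).astype(int)
    within = offset - cell_index * period
    keep = np.all(within < region_size, axis=1)
    regions: list[ClusterTable] = []
    kept = table.df.loc[keep].copy()
    if kept.empty:
        return []
    tags = ["R" + "_".join(map(str, idx)) for idx in cell_index[keep]]
    kept["sample_id"] = tags
    for tag in sorted(set(tags)):
        regions.append(ClusterTable(kept.loc[kept["sample_id"] == tag]))
    return regions
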