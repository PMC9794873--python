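"""Binomial tests for multipotency against chance clonal mergers.

When two cell compartments (say basal and luminal) are both induced, a
same-color basal-luminal pair may reflect a genuine bipotent progenitor —
or a chance merger of two independently induced clones.  The null of
chance pairing makes the number of same-color (or labelled-contact) pairs
k* among N binomial with success probability nu, so the evidence for
multipotency is the exact upper tail

    p = sum_{k = k*}^{N} C(N, k) nu^k (1 - nu)^(N - k).

Two null models supply nu: the *pairwise* model (probability that a
labelled pair shares a color, from the two compartments' color
frequencies) and the *contact* model (probability that an induced cell
touches a labelled neighbour, from per-color induction probabilities and
the coordination-number distribution of the tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .clonedata import ColorScheme, CoordinationDistribution, DomainError


@dataclass(frozen=True)
class PairingModel:
    """Null pairing probability nu and how it was obtained."""

    nu: float
    variant: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu <= 1.0):
            raise DomainError(f"nu must be in [0, 1], got {self.nu}")


@dataclass(frozen=True)
class MultipotencyResult:
    k_star: int
    N: int
    p_value: float
    nu: PairingModel

    def __post_init__(self) -> None:
        if not (0 <= self.k_star <= self.N):
            raise DomainError("need 0 <= k_star <= N")
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p_value out of [0, 1]")


def nu_pairwise(scheme_a: ColorScheme, scheme_b: ColorScheme) -> PairingModel:
    """Probability that a labelled pair drawn from two compartments shares a
    color: nu = sum_C r_C^A r_C^B.  Color sets must match (order-free)."""
    if set(scheme_a.names) != set(scheme_b.names):
        raise DomainError("the two schemes must use the same color set")
    fa = scheme_a.as_dict()
    fb = scheme_b.as_dict()
    nu = float(sum(fa[c] * fb[c] for c in fa))
    return PairingModel(nu=nu, variant="pairwise",
                        inputs={"scheme_a": fa, "scheme_b": fb})


def nu_contact(
    lambdas: Mapping[str, float],
    coord: CoordinationDistribution,
    z_max: int | None = None,
) -> PairingModel:
    """Probability that an induced cell of one compartment touches a
    labelled cell of the other:

        nu = sum_C lambda_C sum_z z (1 - sum_C' lambda_C')^(z-1) F(z),

    with lambda_C the per-color induction probability of the second
    compartment and F(z) the coordination-number distribution."""
    lam = {str(c): float(v) for c, v in dict(lambdas).items()}
    if any(v < 0 for v in lam.values()):
        raise DomainError("induction probabilities must be nonnegative")
    lam_tot = sum(lam.values())
    if lam_tot > 1.0 + 1e-12:
        raise DomainError(f"sum of induction probabilities exceeds 1 ({lam_tot:.6g})")
    z = coord.support()
    f = coord.probs()
    if z_max is not None:
        keep = z <= z_max
        z, f = z[keep], f[keep]
    inner = float(np.sum(z * (1.0 - lam_tot) ** (z - 1) * f))
    nu = min(lam_tot * inner, 1.0)
    return PairingModel(nu=nu, variant="contact",
                        inputs={"lambdas": lam, "z_support": z.tolist()})


def nu_contact_approx(lambdas: Mapping[str, float], z_bar: float) -> PairingModel:
    """Small-induction approximation nu ~= z_bar * sum_C lambda_C, valid when
    coordination-number variation is small and total induction is low."""
    if z_bar < 1:
        raise DomainError("mean coordination number must be >= 1")
    lam = {str(c): float(v) for c, v in dict(lambdas).items()}
    if any(v < 0 for v in lam.values()):
        raise DomainError("induction probabilities must be nonnegative")
    nu = z_bar * sum(lam.values())
    inputs: dict = {"lambdas": lam, "z_bar": z_bar}
    if nu > 1.0:
        inputs["warnings"] = ["approximation exceeded 1 and was capped"]
        nu = 1.0
    return PairingModel(nu=nu, variant="contact_approx", inputs=inputs)


def binomial_tail(k_star: int, N: int, nu: float) -> float:
    """Exact upper-tail binomial probability P(K >= k_star), summed in
    log-space so it stays accurate for N up to ~10^6."""
    if not (0 <= k_star <= N):
        raise DomainError("need 0 <= k_star <= N")
    if k_star == 0:
        return 1.0
    if nu == 0.0:
        return 0.0
    if nu == 1.0:
        return 1.0
    def _tail_sum(ks: np.ndarray) -> float:
        log_terms = (
            gammaln(N + 1) - gammaln(ks + 1) - gammaln(N - ks + 1)
            + ks * math.log(nu) + (N - ks) * math.log1p(-nu)
        )
        # shifted exact summation (math.fsum): the sum itself contributes
        # no more error than the individual gammaln-based terms
        shift = float(log_terms.max())
        return math.exp(shift) * math.fsum(np.exp(log_terms - shift).tolist())

    # sum whichever tail is smaller; the relative error of the log-space
    # terms then translates into a tiny absolute error on the result
    if k_star <= N * nu:
        lower = _tail_sum(np.arange(0, k_star))
        return float(min(1.0, max(0.0, 1.0 - lower)))
    return float(min(1.0, _tail_sum(np.arange(k_star, N + 1))))


def binomial_multipotency_test(
    k_star: int, N: int, nu: PairingModel | float
) -> MultipotencyResult:
    """Test multipotency: p-value of observing at least k_star successes
    among N pairs under the chance-merger null Binomial(N, nu)."""
    if N < 1:
        raise DomainError("N must be >= 1")
    model = nu if isinstance(nu, PairingModel) else PairingModel(float(nu), "fixed")
    p = binomial_tail(k_star, N, model.nu)
    return MultipotencyResult(k_star=k_star, N=N, p_value=p, nu=model)
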