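"""Merging-probability estimators for multicolor and single-color tracing.

A cluster of labelled cells is *polyclonal* when two or more independently
induced clones of the same color have joined.  Multicolor constructs make
the merging rate directly observable: unicolor mergers are invisible, but
bicolor contacts are not, and under independent multinomial color
assignment the fraction of unicolor mergers for color c is

    G_unicolor(c) ~= (k_bicolor / k) * r_c / (1 - sum_c r_c^2),

where the denominator corrects the cluster count k for mergers hiding in
it.  Single-color experiments instead lean on a Poisson point-process
model of induction: the merging probability is the chance that the
nearest-neighbour centre distance falls below the sum of the two clone
radii, integrated over the clone-size distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .clonedata import (
    CloneSizeDistribution,
    ClusterTable,
    ColorScheme,
    DomainError,
)


@dataclass(frozen=True)
class MergeEstimate:
    """A merging-probability estimate with method diagnostics."""

    p_merge: float
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_merge <= 1.0):
            raise DomainError(f"p_merge must be in [0, 1], got {self.p_merge}")


def unit_ball_volume(d: int) -> float:
    """Volume of the unit ball in d dimensions: pi^(d/2) / Gamma(d/2 + 1)."""
    if d not in (1, 2, 3):
        raise DomainError("dimension must be 1, 2 or 3")
    return math.pi ** (d / 2) / math.exp(gammaln(d / 2 + 1))


def ball_volume(r, d: int):
    return unit_ball_volume(d) * np.asarray(r, dtype=float) ** d


def clone_radius(size, cell_volume: float, d: int):
    """Radius of a spherically compact clone of ``size`` cells, each of
    volume ``cell_volume``: V_d(r) = size * cell_volume."""
    if cell_volume <= 0:
        raise DomainError("cell_volume must be positive")
    s = np.asarray(size, dtype=float)
    return (s * cell_volume / unit_ball_volume(d)) ** (1.0 / d)


def correction_factor(scheme: ColorScheme) -> float:
    """The multicolor correction 1 - sum_c r_c^2.

    This is the probability that two independently colored clones differ in
    color; it deflates the observed cluster count for mergers already in it.
    A single color gives 0 (the multicolor estimator is inapplicable).
    """
    return 1.0 - float(sum(f * f for f in scheme.freq))


def unicolor_merger_fraction(
    k_bicolor: int, k: int, color: str, scheme: ColorScheme
) -> MergeEstimate:
    """Estimated fraction of color-``color`` clusters that are unicolor mergers.

    Scales the observed bicolor-contact fraction k_bicolor/k by the relative
    frequency r_c of the color and the multicolor correction factor.
    Standard error propagates the binomial noise on k_bicolor/k.
    """
    if k <= 0:
        raise DomainError("k must be positive")
    if not (0 <= k_bicolor <= k):
        raise DomainError("need 0 <= k_bicolor <= k")
    corr = correction_factor(scheme)
    if corr <= 0:
        raise DomainError(
            "correction factor is 0: multicolor estimator needs >= 2 colors in use"
        )
    r_c = scheme.frequency(color)
    frac = k_bicolor / k
    scale = r_c / corr
    p = frac * scale
    se = math.sqrt(frac * (1 - frac) / k) * scale
    details = {"correction_factor": corr, "r_c": r_c, "stderr": se,
               "k_bicolor": k_bicolor, "k": k}
    warnings = []
    if p > 1.0:
        warnings.append("estimate exceeded 1 and was clipped")
        p = 1.0
    if warnings:
        details["warnings"] = warnings
    return MergeEstimate(p_merge=p, method="multicolor", details=details)


def count_bicolor_contacts(
    table: ClusterTable, contact_radius: float
) -> dict[str, tuple[int, int]]:
    """Per color c: (k_bicolor, k) where k counts clusters of color c and
    k_bicolor those whose centroid lies within ``contact_radius`` of a
    differently colored cluster *in the same sample*."""
    if contact_radius <= 0:
        raise DomainError("contact_radius must be positive")
    colors = table.colors()
    out_k = {c: 0 for c in np.unique(colors)}
    out_kb = {c: 0 for c in out_k}
    df = table.df
    for _, group in df.groupby("sample_id", sort=False):
        pos = group[table.coord_columns].to_numpy(float)
        cols = group["color"].to_numpy()
        for c in cols:
            out_k[c] += 1
        if len(group) < 2:
            continue
        tree = cKDTree(pos)
        contact = np.zeros(len(group), dtype=bool)
        for i, j in tree.query_pairs(contact_radius):
            if cols[i] != cols[j]:
                contact[i] = contact[j] = True
        for c, hit in zip(cols, contact):
            if hit:
                out_kb[c] += 1
    return {c: (out_kb[c], out_k[c]) for c in out_k}


def merge_prob_area_fraction(labelled_area: float, total_area: float) -> MergeEstimate:
    """Heuristic single-color estimate: a randomly placed (point-like) clone
    lands on labelled tissue with probability equal to the labelled area
    fraction."""
    if total_area <= 0:
        raise DomainError("total_area must be positive")
    if not (0 <= labelled_area <= total_area):
        raise DomainError("need 0 <= labelled_area <= total_area")
    return MergeEstimate(
        p_merge=labelled_area / total_area,
        method="area_fraction",
        details={"labelled_area": labelled_area, "total_area": total_area},
    )


def merge_prob_1d(
    p: float, sizes: CloneSizeDistribution, s_max: int | None = None
) -> MergeEstimate:
    """One-dimensional merging probability.

    With per-cell induction probability ``p``, a clone of size s merges when
    the distance (in cells) to the next induced cell is below s:
    1 - (1-p)^s.  Averaging over the clone-size law P(s):

        p_merge = 1 - sum_s (1-p)^s P(s).
    """
    if not (0.0 <= p <= 1.0):
        raise DomainError("p must be in [0, 1]")
    support = sizes.support()
    probs = sizes.probs()
    if s_max is not None:
        keep = support <= s_max
        lost = float(probs[~keep].sum())
        support, probs = support[keep], probs[keep]
    else:
        lost = 0.0
    # truncated mass is treated as certain mergers: (1-p)^s -> 0 for large s
    pm = 1.0 - float(np.sum((1.0 - p) ** support * probs))
    pm = min(max(pm, 0.0), 1.0)
    details: dict = {"truncated_mass": lost}
    if lost > 1e-6:
        details["warnings"] = [
            f"{lost:.3g} probability mass beyond s_max={s_max} ignored"
        ]
    return MergeEstimate(p_merge=pm, method="1d", details=details)


def radius_sum_pmf(
    sizes: CloneSizeDistribution, cell_volume: float, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete distribution of the sum of two independent clone radii.

    Clones are spherically compact, so size s maps to radius r_s with
    V_d(r_s) = s * cell_volume; the pairwise convolution of the size law
    gives the exact (discrete) law of r1 + r2.
    """
    s = sizes.support()
    p = sizes.probs()
    radii = clone_radius(s, cell_volume, d)
    r_sum = (radii[:, None] + radii[None, :]).ravel()
    w = (p[:, None] * p[None, :]).ravel()
    order = np.argsort(r_sum)
    return r_sum[order], w[order]


def merge_prob_general(
    m0: float,
    volume: float,
    d: int,
    sizes: CloneSizeDistribution,
    cell_volume: float = 1.0,
    smoothing: float = 0.0,
) -> MergeEstimate:
    """Nearest-neighbour merging probability in d = 1, 2 or 3 dimensions.

        p_merge = int_0^inf (1 - exp(-rho V_d(r))) C(r) dr

    with clone density rho = m0 / volume and C(r) the density of the sum of
    two independent clone radii.  For a discrete size law C is a discrete
    sum, evaluated exactly by default; with ``smoothing`` > 0 the radius-sum
    pmf is Gaussian-kernel smoothed and integrated by adaptive quadrature
    (the quadrature error bound is reported in the diagnostics).

    Only pairwise (nearest-neighbour) mergers are counted; three-clone
    events are ignored, so at high density this tends to a lower bound.
    """
    if d not in (1, 2, 3):
        raise DomainError("dimension must be 1, 2 or 3")
    if m0 <= 0:
        raise DomainError("m0 must be positive")
    if volume <= 0:
        raise DomainError("volume must be positive")
    rho = m0 / volume
    r_sum, w = radius_sum_pmf(sizes, cell_volume, d)
    details: dict = {"rho": rho, "cell_volume": cell_volume}
    if smoothing <= 0:
        pm = float(np.sum(w * (1.0 - np.exp(-rho * ball_volume(r_sum, d)))))
        details["quadrature_error"] = 0.0
    else:
        def integrand(r: float) -> float:
            kern = np.exp(-0.5 * ((r - r_sum) / smoothing) ** 2)
            kern /= smoothing * math.sqrt(2 * math.pi)
            c_r = float(np.sum(w * kern))
            return (1.0 - math.exp(-rho * float(ball_volume(r, d)))) * c_r

        upper = float(r_sum.max() + 10 * smoothing)
        pm, err = integrate.quad(integrand, 0.0, upper, limit=200)
        details["quadrature_error"] = err
    pm = min(max(pm, 0.0), 1.0)
    return MergeEstimate(p_merge=pm, method="general_d", details=details)
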