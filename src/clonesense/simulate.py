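"""Spatially explicit Monte Carlo generator of multicolor lineage-tracing
data with ground truth.

Each sample is a d-dimensional box of the given volume.  Induction draws a
Poisson(m0) number of clones, placed uniformly and colored multinomially
from the scheme; clone sizes come from a configurable size law.  Each
clone then accrues Poisson(f) extra fragmentation events, its cells are
split into fragments by a uniform random composition, and fragment
centroids are displaced isotropically by the dispersal scale.  Boundaries
are periodic by default so nearest-neighbour statistics carry no edge
bias.

The emitted cluster table is exactly what the estimators consume; the
accompanying :class:`SimulationTruth` records the clonal origin of every
cluster and all geometric same-color contacts (realized merger pairs), so
every estimator in the toolkit can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .clonedata import (
    CloneSizeDistribution,
    ClusterTable,
    ColorScheme,
    DomainError,
    ValidationError,
)
from .merging import clone_radius


@dataclass(frozen=True)
class SizeModel:
    """Clone-size law at analysis time.

    kinds: ``fixed`` (all clones have ``param`` cells), ``geometric``
    (P(s) = (1-q) q^(s-1) with mean ``param``; the stationary, homeostatic
    regime), ``exponential`` (s = ceil(Exp(param)); an expansion-like law
    with mean ~ param).
    """

    kind: str
    param: float

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "geometric", "exponential"):
            raise ValidationError(f"unknown size model {self.kind!r}")
        if self.param < 1:
            raise ValidationError("size model parameter must be >= 1")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(self.param), dtype=int)
        if self.kind == "geometric":
            return rng.geometric(1.0 / self.param, size=n)
        return np.maximum(1, np.ceil(rng.exponential(self.param, size=n))).astype(int)

    def distribution(self, tail_tol: float = 1e-12) -> CloneSizeDistribution:
        if self.kind == "fixed":
            return CloneSizeDistribution.fixed(int(self.param))
        if self.kind == "geometric":
            return CloneSizeDistribution.geometric(self.param, tail_tol)
        # ceil(Exp(mean)) is geometric with q = exp(-1/mean)
        q = math.exp(-1.0 / self.param)
        return CloneSizeDistribution.geometric(1.0 / (1.0 - q), tail_tol)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int
    d: int = 2
    volume: float = 400.0
    m0: float = 2.0  # mean induced clones per sample (all colors together)
    scheme: ColorScheme = field(
        default_factory=lambda: ColorScheme(
            ("CFP", "RFP", "YFP", "GFP"), (0.3, 0.3, 0.3, 0.1)
        )
    )
    size_model: SizeModel = field(default_factory=lambda: SizeModel("fixed", 8))
    f: float = 0.0
    dispersal: float = 1.0
    n_samples: int = 100
    periodic: bool = True
    cell_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.d not in (1, 2, 3):
            raise ValidationError("dimension must be 1, 2 or 3")
        if min(self.volume, self.cell_volume) <= 0:
            raise ValidationError("volumes must be positive")
        if self.m0 < 0 or self.f < 0 or self.dispersal < 0:
            raise ValidationError("rates must be nonnegative")
        if self.n_samples < 1:
            raise ValidationError("need at least one sample")

    @property
    def side(self) -> float:
        return self.volume ** (1.0 / self.d)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth clonal partition of a simulated cluster table."""

    clones: pd.DataFrame  # sample_id, clone_id, color, coords..., size
    fragment_to_clone: dict[str, str]  # cluster_id -> clone_id
    merger_pairs: list[tuple[str, str]]  # same-color geometric contacts

    def true_partition(self, cluster_ids: Iterable[str]) -> list[str]:
        return [self.fragment_to_clone[c] for c in cluster_ids]


def _compositions(rng: np.random.Generator, size: int, parts: int) -> np.ndarray:
    """Uniform random composition of ``size`` into ``parts`` positive parts."""
    if parts == 1:
        return np.array([size])
    cuts = np.sort(rng.choice(size - 1, size=parts - 1, replace=False)) + 1
    return np.diff(np.concatenate(([0], cuts, [size])))


def _min_image(delta: np.ndarray, side: float, periodic: bool) -> np.ndarray:
    if periodic:
        delta = delta - side * np.round(delta / side)
    return delta


def simulate(config: SimConfig) -> tuple[ClusterTable, SimulationTruth]:
    """Run the generator: returns the observable cluster table and truth.

    Identical configs (including seed) give bit-identical outputs.  Each
    clone leaves min(1 + Poisson(f), size) fragments — a clone cannot split
    into more fragments than it has cells.  Fragments of an unsplit clone
    stay at the clone centre; fragments created by splitting are displaced
    by an isotropic Gaussian of scale ``dispersal``.
    """
    rng = np.random.default_rng(config.seed)
    d, L = config.d, config.side
    n_colors = config.scheme.n_colors

    m_per_sample = rng.poisson(config.m0, config.n_samples)
    M = int(m_per_sample.sum())
    clone_sample = np.repeat(np.arange(config.n_samples), m_per_sample)
    pos = rng.uniform(0.0, L, size=(M, d))
    color_idx = rng.choice(n_colors, size=M, p=np.asarray(config.scheme.freq))
    sizes = config.size_model.draw(rng, M)
    extra = rng.poisson(config.f, M)
    n_frag = np.minimum(1 + extra, sizes)

    # per-clone fragment sizes and displacements
    frag_clone = np.repeat(np.arange(M), n_frag)
    F = int(n_frag.sum())
    frag_sizes = np.empty(F, dtype=int)
    out = 0
    for j in range(M):
        nf = n_frag[j]
        frag_sizes[out:out + nf] = _compositions(rng, int(sizes[j]), int(nf))
        out += nf
    disp = np.zeros((F, d))
    split = n_frag[frag_clone] > 1
    if config.dispersal > 0 and split.any():
        disp[split] = rng.normal(0.0, config.dispersal, size=(int(split.sum()), d))
    frag_pos = pos[frag_clone] + disp
    if config.periodic:
        frag_pos = np.mod(frag_pos, L)
    else:
        frag_pos = np.clip(frag_pos, 0.0, L)

    sample_ids = np.array([f"S{i:05d}" for i in range(config.n_samples)])
    clone_ids = np.array(
        [f"{sample_ids[clone_sample[j]]}:K{j:06d}" for j in range(M)]
    )
    frag_local = np.concatenate([np.arange(nf) for nf in n_frag]) if F else np.array([], dtype=int)
    cluster_ids = np.array(
        [f"{clone_ids[frag_clone[i]]}:F{frag_local[i]}" for i in range(F)]
    )

    coord_cols = ["x", "y", "z"][:d]
    table_df = pd.DataFrame({
        "sample_id": sample_ids[clone_sample[frag_clone]],
        "cluster_id": cluster_ids,
        "color": np.asarray(config.scheme.names)[color_idx[frag_clone]],
    })
    for a, c in enumerate(coord_cols):
        table_df[c] = frag_pos[:, a]
    table_df["size"] = frag_sizes
    table = ClusterTable(table_df)

    clones_df = pd.DataFrame({
        "sample_id": sample_ids[clone_sample],
        "clone_id": clone_ids,
        "color": np.asarray(config.scheme.names)[color_idx],
    })
    for a, c in enumerate(coord_cols):
        clones_df[c] = pos[:, a]
    clones_df["size"] = sizes

    # realized mergers: same-sample same-color fragments whose compact-disk
    # radii overlap (minimum-image metric under periodic boundaries)
    radii = clone_radius(frag_sizes, config.cell_volume, d)
    merger_pairs: list[tuple[str, str]] = []
    frag_sample = clone_sample[frag_clone]
    # group fragment indices by sample
    by_sample: dict[int, list[int]] = {}
    for i in range(F):
        by_sample.setdefault(int(frag_sample[i]), []).append(i)
    frag_color = color_idx[frag_clone]
    for idxs in by_sample.values():
        if len(idxs) < 2:
            continue
        ii = np.array(idxs)
        for a_i in range(len(ii)):
            for b_i in range(a_i + 1, len(ii)):
                i, j = ii[a_i], ii[b_i]
                if frag_color[i] != frag_color[j]:
                    continue
                delta = _min_image(frag_pos[i] - frag_pos[j], L, config.periodic)
                if np.linalg.norm(delta) < radii[i] + radii[j]:
                    pair = tuple(sorted((cluster_ids[i], cluster_ids[j])))
                    merger_pairs.append(pair)
    merger_pairs.sort()

    truth = SimulationTruth(
        clones=clones_df,
        fragment_to_clone=dict(zip(cluster_ids, clone_ids[frag_clone])),
        merger_pairs=merger_pairs,
    )
    return table, truth


def fragment_counts_per_sample_color(table: ClusterTable) -> pd.Series:
    """Number of clusters per (sample_id, color) — the k entering the
    fragmentation model."""
    return table.df.groupby(["sample_id", "color"], sort=True).size()


def merging_inflation_experiment(config: SimConfig) -> dict:
    """Quantify how merging inflates apparent clone sizes.

    Requires f = 0 (merging isolated from fragmentation).  Same-color
    clones in geometric contact are fused into observed clusters; the
    report compares the realized polyclonal-cluster fraction with the
    relative inflation of the mean observed cluster size over the mean
    true clone size.  Larger clones merge more often, so the size
    inflation exceeds the merger fraction.
    """
    if config.f != 0:
        raise DomainError("set f = 0 to isolate merging")
    table, truth = simulate(config)
    ids = table.df["cluster_id"].tolist()
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in truth.merger_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    comp: dict[str, list[str]] = {}
    for i in ids:
        comp.setdefault(find(i), []).append(i)
    sizes = table.df.set_index("cluster_id")["size"]
    observed_sizes = np.array([sizes.loc[members].sum() for members in comp.values()])
    n_members = np.array([len(members) for members in comp.values()])
    mean_true = float(sizes.mean())  # f = 0: one fragment per clone
    mean_obs = float(observed_sizes.mean())
    p_merge_realized = float((n_members > 1).mean())
    return {
        "p_merge_realized": p_merge_realized,
        "mean_true_size": mean_true,
        "mean_observed_size": mean_obs,
        "mean_size_inflation": mean_obs / mean_true - 1.0,
        "n_observed_clusters": int(len(observed_sizes)),
        "n_true_clones": int(len(ids)),
    }


# ---------------------------------------------------------------------------
# flat YAML config loading for the CLI

def load_config(path: str | Path) -> SimConfig:
    """Read a flat key-value YAML file mirroring :class:`SimConfig`.

    Recognised keys: seed, d, volume, m0, colors, freqs, size_model,
    size_param, f, dispersal, n_samples, periodic, cell_volume.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValidationError("simulation config must set a seed")
    kwargs: dict = {"seed": int(raw["seed"])}
    if "colors" in raw:
        names = [str(c) for c in raw["colors"]]
        freqs = raw.get("freqs")
        if freqs is None:
            kwargs["scheme"] = ColorScheme.equal(names)
        else:
            kwargs["scheme"] = ColorScheme(tuple(names), tuple(float(f) for f in freqs))
    if "size_model" in raw:
        kwargs["size_model"] = SizeModel(str(raw["size_model"]),
                                         float(raw.get("size_param", 8)))
    for key in ("d", "n_samples"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("volume", "m0", "f", "dispersal", "cell_volume"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "periodic" in raw:
        kwargs["periodic"] = bool(raw["periodic"])
    return SimConfig(**kwargs)
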