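"""Shared domain types and delimited-text IO for lineage-tracing tables.

The observable unit throughout the toolkit is the labelled *cell cluster*:
a spatially contiguous group of same-color cells recorded with its sample,
color, centroid position and cell count.  Cluster tables are plain CSV/TSV
files with a header row; the schema is fixed as

    sample_id, cluster_id, color, x[, y[, z]], size

with one row per cluster.  Coordinates are real-valued centroids in
arbitrary but consistent length units; dimensionality (1-3) is inferred
from which coordinate columns are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table is missing required columns or has malformed structure."""


class ValidationError(ValueError):
    """A table or distribution violates a domain invariant."""


class DomainError(ValueError):
    """An operation was called outside its mathematical domain."""


COORD_COLUMNS = ("x", "y", "z")
REQUIRED_COLUMNS = ("sample_id", "cluster_id", "color", "size")

_NORM_TOL = 1e-9


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass(frozen=True)
class ColorScheme:
    """The label palette: color names and relative induction frequencies.

    ``freq[i]`` is r_c, the probability that a given labelled cell (or
    clone) carries color ``names[i]``; frequencies sum to one over
    labelled cells.
    """

    names: tuple[str, ...]
    freq: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "freq", tuple(float(f) for f in self.freq))
        if len(self.names) < 1:
            raise ValidationError("a color scheme needs at least one color")
        if len(self.names) != len(self.freq):
            raise ValidationError("names and freq must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("color names must be unique")
        if any(f < 0 or f > 1 for f in self.freq):
            raise ValidationError("color frequencies must lie in [0, 1]")
        if abs(sum(self.freq) - 1.0) > _NORM_TOL:
            raise ValidationError(
                f"color frequencies must sum to 1 (got {sum(self.freq):.12g})"
            )

    @property
    def n_colors(self) -> int:
        return len(self.names)

    def frequency(self, color: str) -> float:
        try:
            return self.freq[self.names.index(str(color))]
        except ValueError:
            raise ValidationError(f"unknown color {color!r}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.freq))

    @classmethod
    def equal(cls, names: Iterable[str]) -> "ColorScheme":
        names = tuple(names)
        return cls(names, tuple(1.0 / len(names) for _ in names))

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str | None = None) -> "ColorScheme":
        df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
        for col in ("color", "freq"):
            if col not in df.columns:
                raise SchemaError(f"color scheme file is missing column {col!r}")
        return cls(tuple(df["color"].astype(str)), tuple(df["freq"].astype(float)))

    def to_csv(self, path: str | Path, delimiter: str | None = None) -> None:
        pd.DataFrame({"color": self.names, "freq": self.freq}).to_csv(
            path, sep=_delimiter_for(path, delimiter), index=False
        )


class ClusterTable:
    """Validated table of labelled cell clusters.

    Wraps a :class:`pandas.DataFrame` with the fixed schema; rows are one
    cluster each.  Derived columns added by downstream operations are
    appended after ``size`` and survive round trips.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cluster table is missing column(s) {missing}")
        coord_cols = [c for c in COORD_COLUMNS if c in df.columns]
        # coordinate columns must be a prefix of (x, y, z)
        expected = list(COORD_COLUMNS[: len(coord_cols)])
        if coord_cols != expected:
            raise SchemaError(
                f"coordinate columns must be a prefix of {COORD_COLUMNS}, got {coord_cols}"
            )
        if not coord_cols:
            raise SchemaError("cluster table needs at least an 'x' coordinate column")
        df = df.copy()
        df["size"] = pd.to_numeric(df["size"])
        bad = df.index[(df["size"] < 1) | (df["size"] != df["size"].astype(int))]
        if len(bad):
            raise ValidationError(
                f"size must be an integer >= 1; first offending row index: {bad[0]}"
            )
        df["size"] = df["size"].astype(int)
        for c in coord_cols:
            df[c] = pd.to_numeric(df[c]).astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        df["cluster_id"] = df["cluster_id"].astype(str)
        df["color"] = df["color"].astype(str)
        if df["cluster_id"].duplicated().any():
            dup = df["cluster_id"][df["cluster_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate cluster_id {dup!r}")
        self._df = df.reset_index(drop=True)
        self._coord_cols = coord_cols

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ndim(self) -> int:
        return len(self._coord_cols)

    @property
    def coord_columns(self) -> list[str]:
        return list(self._coord_cols)

    def __len__(self) -> int:
        return len(self._df)

    def coords(self) -> np.ndarray:
        return self._df[self._coord_cols].to_numpy(float)

    def sizes(self) -> np.ndarray:
        return self._df["size"].to_numpy(int)

    def colors(self) -> np.ndarray:
        return self._df["color"].to_numpy()

    def sample_ids(self) -> np.ndarray:
        return self._df["sample_id"].to_numpy()

    def subset(self, mask) -> "ClusterTable":
        return ClusterTable(self._df.loc[mask])

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterTable) and self._df.equals(other._df)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def read(cls, path: str | Path, delimiter: str | None = None) -> "ClusterTable":
        df = pd.read_csv(path, sep=_delimiter_for(path, delimiter),
                         float_precision="round_trip")
        return cls(df)

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        self._df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def read_cluster_table(path: str | Path, delimiter: str | None = None) -> ClusterTable:
    """Read a cluster table from CSV/TSV (delimiter inferred from extension)."""
    return ClusterTable.read(path, delimiter)


def write_cluster_table(
    table: ClusterTable, path: str | Path, delimiter: str | None = None
) -> None:
    table.write(path, delimiter)


@dataclass(frozen=True)
class ColorCountSummary:
    """Per-sample counts of distinct colors: ``counts[n]`` is C_n, the
    number of samples labelled in exactly n distinct colors."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        counts = {int(n): int(c) for n, c in dict(self.counts).items()}
        if any(n < 0 for n in counts):
            raise ValidationError("color counts are indexed by n >= 0")
        if any(c < 0 for c in counts.values()):
            raise ValidationError("C_n must be nonnegative integers")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, n: int) -> int:
        return self.counts.get(int(n), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self, n_colors: int) -> np.ndarray:
        return np.array([self[n] for n in range(n_colors + 1)], dtype=float)


def _validated_pmf(pmf: Mapping[int, float], min_support: int, what: str) -> dict[int, float]:
    out = {int(k): float(v) for k, v in dict(pmf).items()}
    if not out:
        raise ValidationError(f"{what} pmf is empty")
    if any(k < min_support for k in out):
        raise ValidationError(f"{what} support starts at {min_support}")
    if any(v < 0 for v in out.values()):
        raise ValidationError(f"{what} pmf has negative mass")
    if abs(sum(out.values()) - 1.0) > _NORM_TOL:
        raise ValidationError(f"{what} pmf must sum to 1 (got {sum(out.values()):.12g})")
    return out


@dataclass(frozen=True)
class CloneSizeDistribution:
    """Probability mass P(s) over integer clone sizes s >= 1."""

    pmf: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pmf", _validated_pmf(self.pmf, 1, "clone size"))

    def support(self) -> np.ndarray:
        return np.array(sorted(self.pmf), dtype=int)

    def probs(self) -> np.ndarray:
        return np.array([self.pmf[s] for s in sorted(self.pmf)], dtype=float)

    def mean(self) -> float:
        return float(sum(s * p for s, p in self.pmf.items()))

    @classmethod
    def fixed(cls, s0: int) -> "CloneSizeDistribution":
        return cls({int(s0): 1.0})

    @classmethod
    def geometric(cls, mean: float, tail_tol: float = 1e-12) -> "CloneSizeDistribution":
        """Geometric law P(s) = (1-q) q^(s-1) on s >= 1 with the given mean,
        truncated where the tail mass drops below ``tail_tol`` and renormalized."""
        if mean < 1:
            raise DomainError("geometric clone-size mean must be >= 1")
        q = 1.0 - 1.0 / mean
        if q == 0.0:
            return cls.fixed(1)
        s_max = max(1, int(math.ceil(math.log(tail_tol) / math.log(q))) + 1)
        s = np.arange(1, s_max + 1)
        p = (1 - q) * q ** (s - 1)
        p /= p.sum()
        return cls(dict(zip(s.tolist(), p.tolist())))

    @classmethod
    def from_sizes(cls, sizes: Iterable[int]) -> "CloneSizeDistribution":
        vals, counts = np.unique(np.asarray(list(sizes), dtype=int), return_counts=True)
        p = counts / counts.sum()
        return cls(dict(zip(vals.tolist(), p.tolist())))


@dataclass(frozen=True)
class CoordinationDistribution:
    """Distribution F(z) of coordination numbers z >= 1 — the number of
    cells of a second compartment in contact with a given cell."""

    pmf: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pmf", _validated_pmf(self.pmf, 1, "coordination"))

    def support(self) -> np.ndarray:
        return np.array(sorted(self.pmf), dtype=int)

    def probs(self) -> np.ndarray:
        return np.array([self.pmf[z] for z in sorted(self.pmf)], dtype=float)

    def mean(self) -> float:
        return float(sum(z * p for z, p in self.pmf.items()))

    @classmethod
    def fixed(cls, z0: int) -> "CoordinationDistribution":
        return cls({int(z0): 1.0})


def summarize_colors(table: ClusterTable, scheme: ColorScheme) -> ColorCountSummary:
    """Count samples by the number of distinct colors they express.

    Returns C_n for n = 0..n_colors.  Samples with no rows in the table are
    *not* counted toward C_0 — unlabelled samples leave no clusters, so
    their count must be supplied separately by the caller where needed.
    """
    known = set(scheme.names)
    unknown = set(table.colors()) - known
    if unknown:
        raise ValidationError(f"colors not in scheme: {sorted(unknown)}")
    n_distinct = table.df.groupby("sample_id")["color"].nunique()
    counts = {n: 0 for n in range(scheme.n_colors + 1)}
    for n, c in n_distinct.value_counts().items():
        counts[int(n)] += int(c)
    return ColorCountSummary(counts)
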