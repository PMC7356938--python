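"""Binomial critical differences for proportion-correct speech scores.

A speech-recognition score is a proportion of correctly repeated items, so
two scores from the same listener differ by chance alone within limits set
by binomial measurement error at the tests' item counts.  The statistic used
here asks, for a candidate pair of true proportions ``(p1, n1)`` and
``(p2, n2)``: simulate one binomial score from each, take the absolute
difference of the observed proportions, repeat, and form

    z = mean(|d|) / sd(|d|)

over the repetitions.  Pairs whose z exceeds a critical value (1.96 for a
two-tailed 5% test under a normal approximation) are declared significantly
different; the set of p2 grid values compatible with a given p1 is the
*critical range*.  The construction generalises the classic binomial
critical-difference tables to unequal item counts, e.g. one 50-word list
against the average of three 50-word lists (n2 = 150).

Alongside the Monte-Carlo simulator this module provides an exact
enumeration oracle: for small n1*n2 the full joint distribution of the two
binomial counts can be enumerated, giving the exact mean and standard
deviation of |d| with no sampling error.  The oracle is used automatically
when cheap, and serves as the ground truth the simulator is verified
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ScoreObservation",
    "CritDiffConfig",
    "CritDiffResult",
    "CriticalRangeTable",
    "possible_scores",
    "simulate_abs_diff_z",
    "exact_abs_diff_z",
    "exact_z_grid",
    "compare_scores",
    "critical_range",
    "build_table",
    "EnumerationTooLargeError",
]

#: Grid-cell guard for the exact oracle: (n1+1)*(n2+1) outcome pairs at most.
MAX_ENUMERATION_CELLS = 1_000_000

_SD_EPS = 1e-12


class EnumerationTooLargeError(ValueError):
    """Exact enumeration refused because the outcome grid is too large."""


@dataclass(frozen=True)
class ScoreObservation:
    """A proportion-correct score with its effective number of scored items.

    ``p`` need not sit on the grid {0, 1/n, ..., 1}: a score averaged over
    several lists may fall between grid points, and the statistic is well
    defined for any p in [0, 1].
    """

    p: float
    n: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and not isinstance(self.n, bool)):
            raise TypeError(f"n must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class CritDiffConfig:
    """Parameters of the significance computation.

    iterations : Monte-Carlo repetitions (default 40,000).
    critical_z : significance cutoff (default 1.96, two-tailed 5%).
    seed       : seed for the simulator; None draws fresh entropy.
    use_exact  : True forces the enumeration oracle, False forces
                 simulation, None (default) picks the oracle whenever the
                 outcome grid fits under ``max_cells``.
    """

    iterations: int = 40_000
    critical_z: float = 1.96
    seed: int | None = None
    use_exact: bool | None = None
    max_cells: int = MAX_ENUMERATION_CELLS

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.critical_z <= 0:
            raise ValueError("critical_z must be > 0")


@dataclass(frozen=True)
class CritDiffResult:
    """Outcome of one pre/post comparison.

    ``significant`` is exactly ``z > critical_z``; ``direction`` refers to
    the second (post) score relative to the first and is ``"none"`` iff the
    two observed proportions are equal.
    """

    z: float
    significant: bool
    direction: str  # "lower" | "higher" | "none"
    used_exact: bool = False
    seed: int | None = None


def possible_scores(n: int) -> np.ndarray:
    """All proportions attainable with ``n`` scored items: {k/n, k=0..n}."""
    if not (isinstance(n, (int, np.integer)) and not isinstance(n, bool)):
        raise TypeError(f"n must be an integer, got {n!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return np.arange(n + 1) / n


def _ratio(mean: float, sd: float) -> float:
    # Degenerate-spread contract: identical certain scores are never
    # significant (z = 0); maximally distant certain ones always are (inf).
    if sd <= _SD_EPS:
        return 0.0 if mean <= _SD_EPS else math.inf
    return mean / sd


def _simulate_z(a: ScoreObservation, b: ScoreObservation, iterations: int,
                rng: np.random.Generator) -> float:
    x1 = rng.binomial(a.n, a.p, size=iterations) / a.n
    x2 = rng.binomial(b.n, b.p, size=iterations) / b.n
    d = np.abs(x1 - x2)
    return _ratio(float(d.mean()), float(d.std(ddof=1)))


def simulate_abs_diff_z(a: ScoreObservation, b: ScoreObservation,
                        cfg: CritDiffConfig = CritDiffConfig()) -> float:
    """Monte-Carlo z = mean|d| / sample-sd|d| over cfg.iterations draws."""
    if cfg.iterations < 2:
        raise ValueError("iterations must be >= 2 (sample sd undefined)")
    rng = np.random.default_rng(cfg.seed)
    return _simulate_z(a, b, cfg.iterations, rng)


def exact_abs_diff_z(a: ScoreObservation, b: ScoreObservation,
                     max_cells: int = MAX_ENUMERATION_CELLS) -> float:
    """Exact z by enumerating the joint binomial outcome distribution.

    Uses the population standard deviation — there is no sampling here.
    Refuses when (n1+1)*(n2+1) exceeds ``max_cells``.
    """
    cells = (a.n + 1) * (b.n + 1)
    if cells > max_cells:
        raise EnumerationTooLargeError(
            f"{cells} outcome pairs exceed the enumeration guard ({max_cells})")
    w1 = stats.binom.pmf(np.arange(a.n + 1), a.n, a.p)
    w2 = stats.binom.pmf(np.arange(b.n + 1), b.n, b.p)
    d = np.abs(possible_scores(a.n)[:, None] - possible_scores(b.n)[None, :])
    w = w1[:, None] * w2[None, :]
    mean = float(np.sum(w * d))
    var = float(np.sum(w * d * d)) - mean * mean
    sd = math.sqrt(max(var, 0.0))
    return _ratio(mean, sd)


def exact_z_grid(n1: int, n2: int,
                 max_cells: int = MAX_ENUMERATION_CELLS) -> np.ndarray:
    """Exact z for every grid pair: array of shape (n1+1, n2+1).

    ``Z[i, j]`` is ``exact_abs_diff_z((i/n1, n1), (j/n2, n2))``.  Computed
    with two matrix products over the shared |difference| grid, so building
    a full table costs a few dense (n+1)^2 multiplies rather than (n+1)^2
    separate enumerations.
    """
    if (n1 + 1) * (n2 + 1) > max_cells:
        raise EnumerationTooLargeError(
            f"{(n1 + 1) * (n2 + 1)} outcome pairs exceed the guard ({max_cells})")
    g1, g2 = possible_scores(n1), possible_scores(n2)
    k1, k2 = np.arange(n1 + 1), np.arange(n2 + 1)
    # A[i, k] = P(K1 = k | p1 = g1[i]); B[j, k] likewise for the second test.
    A = stats.binom.pmf(k1[None, :], n1, g1[:, None])
    B = stats.binom.pmf(k2[None, :], n2, g2[:, None])
    d = np.abs(g1[:, None] - g2[None, :])
    mean = A @ d @ B.T
    second = A @ (d * d) @ B.T
    var = np.maximum(second - mean * mean, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean / sd
    z[sd <= _SD_EPS] = np.where(mean[sd <= _SD_EPS] <= _SD_EPS, 0.0, np.inf)
    return z


def _z_for_pair(a: ScoreObservation, b: ScoreObservation,
                cfg: CritDiffConfig) -> tuple[float, bool]:
    """Route to the oracle or the simulator per cfg; returns (z, used_exact)."""
    cells = (a.n + 1) * (b.n + 1)
    exact_ok = cells <= cfg.max_cells
    if cfg.use_exact is True and not exact_ok:
        raise EnumerationTooLargeError(
            f"exact evaluation requested but {cells} cells exceed the guard")
    if cfg.use_exact is False or not exact_ok:
        return simulate_abs_diff_z(a, b, cfg), False
    return exact_abs_diff_z(a, b, cfg.max_cells), True


def compare_scores(pre: ScoreObservation, post: ScoreObservation,
                   cfg: CritDiffConfig = CritDiffConfig()) -> CritDiffResult:
    """Significance verdict and direction for a pre/post score pair."""
    z, used_exact = _z_for_pair(pre, post, cfg)
    if post.p < pre.p:
        direction = "lower"
    elif post.p > pre.p:
        direction = "higher"
    else:
        direction = "none"
    return CritDiffResult(z=z, significant=z > cfg.critical_z,
                          direction=direction, used_exact=used_exact,
                          seed=cfg.seed)


@dataclass(frozen=True)
class CriticalRangeTable:
    """Per-row sets of p2 grid values *not* significantly different from p1.

    Rows are the literal sets of non-significant grid values; contiguity is
    reported, not assumed (``row_contiguous``).
    """

    n1: int
    n2: int
    critical_z: float
    rows: Mapping[float, tuple[float, ...]] = field(repr=False)

    def row_contiguous(self, p1: float) -> bool:
        members = np.asarray(self.rows[p1])
        grid = possible_scores(self.n2)
        idx = np.searchsorted(grid, members)
        return bool(np.all(np.diff(idx) == 1)) if len(idx) > 1 else True

    def iter_rows(self) -> Iterator[tuple[float, tuple[float, ...]]]:
        return iter(self.rows.items())

    def to_frame(self, long: bool = False):
        """Tabular export: wide (p1, lower/upper non-significant bound,
        contiguity) or long (one row per non-significant p2)."""
        import pandas as pd

        if long:
            recs = [(p1, p2) for p1, row in self.rows.items() for p2 in row]
            return pd.DataFrame(recs, columns=["p1", "ns_p2"])
        recs = [(p1, row[0], row[-1], self.row_contiguous(p1))
                for p1, row in self.rows.items()]
        return pd.DataFrame(
            recs, columns=["p1", "lower_ns_p2", "upper_ns_p2", "contiguous"])


def critical_range(p1: float, n1: int, n2: int,
                   cfg: CritDiffConfig = CritDiffConfig()) -> tuple[float, ...]:
    """Grid values of p2 whose z against (p1, n1) stays at or below cutoff."""
    grid2 = possible_scores(n2)
    a = ScoreObservation(p=float(p1), n=n1)
    rng = np.random.default_rng(cfg.seed)
    out = []
    use_exact = cfg.use_exact
    if use_exact is None:
        use_exact = (n1 + 1) * (n2 + 1) <= cfg.max_cells
    for p2 in grid2:
        b = ScoreObservation(p=float(p2), n=n2)
        if use_exact:
            z = exact_abs_diff_z(a, b, cfg.max_cells)
        else:
            z = _simulate_z(a, b, cfg.iterations, rng)
        if z <= cfg.critical_z:
            out.append(float(p2))
    return tuple(out)


def build_table(n1: int, n2: int,
                cfg: CritDiffConfig = CritDiffConfig()) -> CriticalRangeTable:
    """Assemble the full critical-range table for tests of n1 and n2 items.

    One seeded generator serves the whole table when simulation is needed;
    when the grid fits the enumeration guard the exact oracle is used and
    the table is fully deterministic.
    """
    grid1, grid2 = possible_scores(n1), possible_scores(n2)
    use_exact = cfg.use_exact
    if use_exact is None:
        use_exact = (n1 + 1) * (n2 + 1) <= cfg.max_cells
    rows: dict[float, tuple[float, ...]] = {}
    if use_exact:
        Z = exact_z_grid(n1, n2, cfg.max_cells)
        for i, p1 in enumerate(grid1):
            keep = grid2[Z[i] <= cfg.critical_z]
            rows[float(p1)] = tuple(float(v) for v in keep)
    else:
        rng = np.random.default_rng(cfg.seed)
        for p1 in grid1:
            a = ScoreObservation(p=float(p1), n=n1)
            row = []
            for p2 in grid2:
                b = ScoreObservation(p=float(p2), n=n2)
                if _simulate_z(a, b, cfg.iterations, rng) <= cfg.critical_z:
                    row.append(float(p2))
            rows[float(p1)] = tuple(row)
    return CriticalRangeTable(n1=n1, n2=n2, critical_z=cfg.critical_z, rows=rows)
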