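"""Genealogies, classic skyline estimation and calibration arithmetic.

The classic skyline is the closed-form analogue of Bayesian skyline
reconstruction: each intercoalescent interval with i lineages and length
t_i yields the estimate N_hat = t_i * i * (i - 1) / 2 in haploid effective
individuals (times in generations, tips at 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genealogy",
    "SkylineEstimate",
    "CalibrationConfig",
    "classic_skyline",
    "generalized_skyline",
    "generations_to_years",
    "years_to_generations",
    "mean_rate_from_estimates",
    "detect_minimum",
    "median_skyline_trajectory",
]


@dataclass(frozen=True)
class Genealogy:
    """Rooted binary coalescent tree: tips at time 0, times in generations.

    Nodes 0..n-1 are tips; internal nodes are n..2n-2 with the root last
    when built by the simulator.  ``parent[root] == -1``.
    """

    n_tips: int
    parent: np.ndarray  # (2n-1,) int
    time: np.ndarray  # (2n-1,) float, generations before present
    tip_labels: tuple[str, ...] = ()

    def __post_init__(self):
        n = self.n_tips
        if n < 2:
            raise ValueError("genealogy needs >= 2 tips")
        parent = np.asarray(self.parent, dtype=int)
        time = np.asarray(self.time, dtype=float)
        if parent.shape != (2 * n - 1,) or time.shape != (2 * n - 1,):
            raise ValueError("parent/time arrays must have length 2n-1")
        if (parent == -1).sum() != 1:
            raise ValueError("exactly one root required")
        for v in range(2 * n - 1):
            if parent[v] >= 0 and time[parent[v]] <= time[v]:
                raise ValueError("parent must be strictly older than child")
        if not self.tip_labels:
            object.__setattr__(self, "tip_labels", tuple(f"t{i}" for i in range(n)))
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "time", time)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def coalescence_times(self) -> np.ndarray:
        """Internal-node times, ascending."""
        return np.sort(self.time[self.n_tips:])

    def branch_lengths(self) -> np.ndarray:
        """Branch length above each non-root node (0 for the root)."""
        b = np.zeros(2 * self.n_tips - 1)
        has_parent = self.parent >= 0
        b[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return b

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(2 * self.n_tips - 1)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch


@dataclass(frozen=True)
class SkylineEstimate:
    """Contiguous intercoalescent intervals tiling [0, TMRCA].

    Each interval carries its lineage count i and the estimate N_hat;
    zero-length intervals get N_hat = 0 and a flag.
    """

    starts: np.ndarray
    ends: np.ndarray
    lineages: np.ndarray
    n_hat: np.ndarray
    flags: tuple[str, ...] = ()

    def at(self, t: float) -> float:
        """N_hat of the interval containing time t (NaN beyond TMRCA)."""
        idx = np.searchsorted(self.ends, t, side="right")
        if idx >= len(self.n_hat):
            return float("nan")
        return float(self.n_hat[idx])


@dataclass(frozen=True)
class CalibrationConfig:
    """Mutation-rate and generation-time constants used for calibration.

    ``mt_rate`` is per site per year (the per-generation rate is
    mt_rate * generation_time); ``y_str_rate`` is per locus per generation.
    """

    generation_time_years: float = 25.0
    mt_rate: float = 1.546e-8
    mt_rate_sd: float = 3.675e-9
    y_str_rate: float = 8.2e-4
    y_str_rate_sd: float = 5.7e-4
    node_prior_mean_generations: float = 1411.0
    node_prior_sd_generations: float = 100.0

    def __post_init__(self):
        for name in ("generation_time_years", "mt_rate", "y_str_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def mt_rate_per_generation(self) -> float:
        return self.mt_rate * self.generation_time_years


def classic_skyline(g: Genealogy) -> SkylineEstimate:
    """Closed-form skyline: N_hat_i = t_i * i * (i - 1) / 2 per interval."""
    coal = g.coalescence_times()
    n = g.n_tips
    starts = np.concatenate([[0.0], coal[:-1]])
    ends = coal
    lineages = np.arange(n, 1, -1)
    lengths = ends - starts
    n_hat = lengths * lineages * (lineages - 1) / 2.0
    flags = tuple("zero-length" if L == 0 else "" for L in lengths)
    return SkylineEstimate(starts, ends, lineages, n_hat, flags)


def generalized_skyline(g: Genealogy, epsilon: float = 0.0) -> SkylineEstimate:
    """Generalized skyline: pool adjacent intervals shorter than epsilon.

    epsilon = 0 reduces to the classic skyline.  Pooled intervals share one
    estimate: (composite length x mean pairwise-rate factor) computed from
    the total coalescent intensity of the pooled stretch.
    """
    if epsilon <= 0:
        return classic_skyline(g)
    sk = classic_skyline(g)
    starts, ends, lineages = [], [], []
    n_hat = []
    i = 0
    m = len(sk.starts)
    while i < m:
        j = i
        length = sk.ends[j] - sk.starts[i]
        while length < epsilon and j + 1 < m:
            j += 1
            length = sk.ends[j] - sk.starts[i]
        # pooled estimate: total length divided by summed inverse-rate weights
        ls = sk.ends[i : j + 1] - sk.starts[i : j + 1]
        ks = sk.lineages[i : j + 1].astype(float)
        rate_units = np.sum(2.0 / (ks * (ks - 1)))  # expected time per unit N
        n_hat.append(float(length / rate_units) if rate_units > 0 else 0.0)
        starts.append(sk.starts[i])
        ends.append(sk.ends[j])
        lineages.append(int(sk.lineages[i]))
        i = j + 1
    return SkylineEstimate(
        np.array(starts), np.array(ends), np.array(lineages), np.array(n_hat)
    )


def generations_to_years(generations: float, generation_time: float = 25.0) -> float:
    if generations < 0 or generation_time <= 0:
        raise ValueError("inputs must be non-negative (generation time positive)")
    return generations * generation_time


def years_to_generations(years: float, generation_time: float = 25.0) -> float:
    if years < 0 or generation_time <= 0:
        raise ValueError("inputs must be non-negative (generation time positive)")
    return years / generation_time


def mean_rate_from_estimates(rates) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) SD of published rate estimates."""
    rates = np.asarray(list(rates), dtype=float)
    if len(rates) == 0:
        raise ValueError("no rates supplied")
    if (rates <= 0).any():
        raise ValueError("rates must be positive")
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return float(rates.mean()), sd


def detect_minimum(
    sk: SkylineEstimate, window: tuple[float, float]
) -> tuple[float, float, str]:
    """Locate the minimum-N_hat interval within a time window.

    Returns (midpoint time of the minimum interval, fractional decline
    1 - N_min / N_reference with the reference taken at the older window
    edge — the pre-decline level, since time runs backward from the
    present — and a flag).  Flat trajectories flag "flat" and return the
    earliest (oldest) qualifying interval.
    """
    if len(sk.n_hat) < 2:
        raise ValueError("need >= 2 intervals")
    lo, hi = window
    mask = (sk.ends > lo) & (sk.starts < hi)
    if not mask.any():
        raise ValueError("window contains no interval")
    idx = np.flatnonzero(mask)
    vals = sk.n_hat[idx]
    flat = np.allclose(vals, vals[0])
    j = idx[-1] if flat else idx[np.argmin(vals)]
    t_min = float((sk.starts[j] + sk.ends[j]) / 2.0)
    ref = sk.at(hi) if not np.isnan(sk.at(hi)) else float(sk.n_hat[idx[-1]])
    decline = 1.0 - float(sk.n_hat[j]) / ref if ref > 0 else 0.0
    return t_min, decline, ("flat" if flat else "")


def median_skyline_trajectory(
    skylines: list[SkylineEstimate], grid: np.ndarray
) -> np.ndarray:
    """Replicate-median N_hat evaluated on a time grid (NaN-aware)."""
    vals = np.array([[sk.at(t) for t in grid] for sk in skylines])
    return np.nanmedian(vals, axis=0)
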