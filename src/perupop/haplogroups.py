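"""Haplogroup frequency tables and the resampling test against reference frequencies.

The resampling test asks whether the haplogroup counts observed in a
subpopulation of size N could have arisen by chance from a larger
reference population: B multinomial draws of N haplotypes at the reference
frequencies give, per haplogroup, a null count distribution, a central 95%
acceptance interval and a two-sided empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PopulationMap

__all__ = [
    "HaplogroupCalls",
    "FrequencyTable",
    "ResamplingResult",
    "frequency_table",
    "non_native_fraction",
    "haplogroup_resampling_test",
    "central_interval_from_counts",
]

NATIVE_AMERICAN_MT = frozenset({"A2", "B2", "C1", "D"})
NATIVE_AMERICAN_Y = frozenset({"Q"})


@dataclass(frozen=True)
class HaplogroupCalls:
    """Macro-haplogroup call per sample, with an optional finer label."""

    macro: dict[str, str]
    sub: dict[str, str] | None = None

    def __post_init__(self):
        if any(not v for v in self.macro.values()):
            raise ValueError("empty haplogroup label")


@dataclass(frozen=True)
class FrequencyTable:
    """Absolute counts (population x haplogroup) with derived percentages."""

    populations: tuple[str, ...]
    haplogroups: tuple[str, ...]
    counts: np.ndarray  # (n_pops, n_haplogroups) int

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def percent(self, decimals: int = 1) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / self.totals[:, None]
        return np.round(pct, decimals)

    def row(self, population: str) -> dict[str, int]:
        i = self.populations.index(population)
        return dict(zip(self.haplogroups, self.counts[i].tolist()))


@dataclass(frozen=True)
class ResamplingResult:
    haplogroups: tuple[str, ...]
    observed: np.ndarray
    null_mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    p: np.ndarray
    flags: tuple[str, ...]  # "", "below", "above", "unreferenced"
    n: int
    draws: int
    seed: int

    def to_rows(self):
        for i, hg in enumerate(self.haplogroups):
            yield (hg, int(self.observed[i]), float(self.null_mean[i]),
                   int(self.lo[i]), int(self.hi[i]), float(self.p[i]), self.flags[i])


def frequency_table(
    calls: HaplogroupCalls, popmap: PopulationMap, level: str = "subgroup"
) -> FrequencyTable:
    """Tabulate absolute haplogroup counts per population at a hierarchy level."""
    missing = [s for s in calls.macro if s not in popmap]
    if missing:
        raise KeyError(f"samples missing from population map: {sorted(missing)}")
    pops = popmap.populations(level)
    haplogroups = tuple(sorted(set(calls.macro.values())))
    hg_index = {h: j for j, h in enumerate(haplogroups)}
    counts = np.zeros((len(pops), len(haplogroups)), dtype=int)
    pop_names = tuple(pops)
    for i, members in enumerate(pops.values()):
        for sid in members:
            if sid in calls.macro:
                counts[i, hg_index[calls.macro[sid]]] += 1
    return FrequencyTable(pop_names, haplogroups, counts)


def non_native_fraction(
    freq: FrequencyTable, native_set, decimals: int | None = 1
) -> dict[str, float | None]:
    """Percent of samples per population outside ``native_set``.

    ``decimals=None`` rounds to the nearest integer; empty populations are
    reported as None.
    """
    native_cols = [j for j, h in enumerate(freq.haplogroups) if h in native_set]
    out: dict[str, float | None] = {}
    for i, pop in enumerate(freq.populations):
        n = freq.counts[i].sum()
        if n == 0:
            out[pop] = None
            continue
        non_native = n - freq.counts[i, native_cols].sum()
        pct = 100.0 * non_native / n
        out[pop] = round(pct) if decimals is None else round(pct, decimals)
    return out


def central_interval_from_counts(counts: np.ndarray, mass: float = 0.95) -> tuple[int, int]:
    """Smallest central interval [lo, hi] holding >= ``mass`` of ``counts``.

    Among minimum-width intervals, ties go to the most symmetric split of
    the excluded tail mass.
    """
    x = np.sort(np.asarray(counts))
    B = len(x)
    m = int(np.ceil(mass * B))
    widths = x[m - 1:] - x[: B - m + 1]
    best_w = widths.min()
    candidates = np.flatnonzero(widths == best_w)
    # tail symmetry: left tail j draws, right tail B - (j + m)
    asym = np.abs(candidates - (B - (candidates + m)))
    j = candidates[np.argmin(asym)]
    return int(x[j]), int(x[j + m - 1])


def haplogroup_resampling_test(
    observed: dict[str, int],
    n: int,
    ref_freqs: dict[str, float],
    draws: int = 100_000,
    seed: int = 0,
) -> ResamplingResult:
    """Resample ``draws`` samples of size ``n`` from reference frequencies.

    Two-sided empirical p per haplogroup doubles the smaller tail
    probability (capped at 1).  Haplogroups observed but absent from the
    reference get the minimum attainable p of 1/(draws+1) and an
    ``unreferenced`` flag.
    """
    if n < 1 or draws < 1:
        raise ValueError("n and draws must be >= 1")
    freqs = np.array(list(ref_freqs.values()), dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("reference frequencies must sum to 1")
    labels = tuple(sorted(set(observed) | set(ref_freqs)))
    rng = np.random.default_rng(seed)
    table = rng.multinomial(n, freqs, size=draws)  # (draws, classes in ref order)
    col = {h: j for j, h in enumerate(ref_freqs)}

    obs = np.array([observed.get(h, 0) for h in labels])
    null_mean = np.empty(len(labels))
    lo = np.empty(len(labels), dtype=int)
    hi = np.empty(len(labels), dtype=int)
    p = np.empty(len(labels))
    flags = []
    for i, hg in enumerate(labels):
        if hg not in col:
            null_mean[i], lo[i], hi[i] = 0.0, 0, 0
            p[i] = 1.0 / (draws + 1)
            flags.append("unreferenced")
            continue
        draws_i = table[:, col[hg]]
        null_mean[i] = draws_i.mean()
        lo[i], hi[i] = central_interval_from_counts(draws_i)
        k = obs[i]
        p_le = np.mean(draws_i <= k)
        p_ge = np.mean(draws_i >= k)
        p[i] = min(1.0, 2.0 * min(p_le, p_ge))
        if k < lo[i]:
            flags.append("below")
        elif k > hi[i]:
            flags.append("above")
        else:
            flags.append("")
    return ResamplingResult(
        labels, obs, null_mean, lo, hi, p, tuple(flags), n, draws, seed
    )
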