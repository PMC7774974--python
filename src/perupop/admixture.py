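"""Post-processing of ancestry proportions and genotype QC screens.

Covers the 0-20 / 21-59 / 60-100 percent binning of one ancestry
component, construction of a synthetic "population" from high-component
individuals, a supervised maximum-likelihood ancestry estimator, and
Hardy-Weinberg / linkage-disequilibrium tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import GenotypeTable, QMatrix

__all__ = [
    "ComponentBinning",
    "SyntheticPopulation",
    "bin_by_component",
    "build_synthetic_population",
    "supervised_ancestry",
    "hwe_test",
    "ld_test",
    "LD_MULTIPLE_TESTING_P",
]

# fixed multiple-testing cutoff used for LD screens
LD_MULTIPLE_TESTING_P = 1e-4


@dataclass(frozen=True)
class ComponentBinning:
    """Assignment of samples to low/mid/high bins of one ancestry component.

    Boundary rule: an edge belongs to the lower bin, except the high bin is
    closed at its lower edge — with default edges (0.20, 0.60) the bins are
    low = [0, 0.20], mid = (0.20, 0.60) and high = [0.60, 1].
    """

    component: int
    edges: tuple[float, float]
    bins: dict[str, str]  # sample -> "low" | "mid" | "high"

    def counts(self) -> dict[str, int]:
        c = Counter(self.bins.values())
        return {b: c.get(b, 0) for b in ("low", "mid", "high")}


@dataclass(frozen=True)
class SyntheticPopulation:
    member_ids: tuple[str, ...]
    threshold: float
    component: int


def bin_by_component(
    q: QMatrix, component: int, edges: tuple[float, float] = (0.20, 0.60)
) -> ComponentBinning:
    """Bin samples by the proportion of one ancestry component."""
    if not 0 <= component < q.K:
        raise IndexError(f"component {component} out of range for K={q.K}")
    lo, hi = edges
    if not (0 < lo < hi < 1):
        raise ValueError("edges must be ascending within (0, 1)")
    bins = {}
    for sid, p in zip(q.sample_ids, q.proportions[:, component]):
        bins[sid] = "low" if p <= lo else ("high" if p >= hi else "mid")
    return ComponentBinning(component, edges, bins)


def build_synthetic_population(
    q: QMatrix, genotypes: GenotypeTable, component: int, threshold: float = 0.60
) -> tuple[SyntheticPopulation, GenotypeTable]:
    """Collect individuals with component proportion >= threshold.

    Returns the membership record plus the genotype subset, ready for
    downstream distance/AMOVA and ordination runs.
    """
    if not 0 <= component < q.K:
        raise IndexError(f"component {component} out of range for K={q.K}")
    members = tuple(
        sid for sid, p in zip(q.sample_ids, q.proportions[:, component]) if p >= threshold
    )
    if not members:
        raise ValueError(
            f"no individuals reach component proportion {threshold}; review the threshold"
        )
    missing = [m for m in members if m not in set(genotypes.sample_ids)]
    if missing:
        raise KeyError(f"members absent from genotype table: {missing}")
    return SyntheticPopulation(members, threshold, component), genotypes.subset(members)


def supervised_ancestry(
    genotypes: GenotypeTable,
    source_freqs: list[dict[str, dict[str, float]]],
    tol: float = 1e-8,
    max_iter: int = 2000,
    pseudo_freq: float = 1e-6,
) -> QMatrix:
    """Maximum-likelihood ancestry proportions given fixed source frequencies.

    Model: each observed allele is drawn from component k with probability
    q_k and then from that component's allele-frequency profile; the
    per-individual likelihood is maximized by EM from a uniform start, run
    until the relative log-likelihood change falls below ``tol``.  Alleles
    absent from every source are smoothed with ``pseudo_freq``.
    """
    K = len(source_freqs)
    if K < 2:
        raise ValueError("need at least 2 source components")
    loci = [l for l in genotypes.locus_names if all(l in f for f in source_freqs)]
    if not loci:
        raise ValueError("no loci shared between genotypes and all source profiles")
    locus_pos = {l: j for j, l in enumerate(genotypes.locus_names)}

    Q = np.zeros((genotypes.n_samples, K))
    for i in range(genotypes.n_samples):
        # per-allele K-vector of source frequencies
        fmat = []
        for locus in loci:
            g = genotypes.genotype(i, locus_pos[locus])
            if g is None:
                continue
            for allele in g:
                f = np.array([src[locus].get(allele, 0.0) for src in source_freqs])
                if (f <= 0).all():
                    f = np.full(K, pseudo_freq)
                fmat.append(f)
        if not fmat:
            Q[i] = 1.0 / K
            continue
        F = np.array(fmat)  # (n_alleles, K)
        q = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        for _ in range(max_iter):
            mix = F * q  # (n_alleles, K)
            denom = mix.sum(axis=1, keepdims=True)
            denom[denom == 0] = pseudo_freq
            ll = float(np.log(denom).sum())
            q = (mix / denom).mean(axis=0)
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                break
            prev_ll = ll
        Q[i] = q / q.sum()
    return QMatrix(genotypes.sample_ids, Q)


def _hwe_exact_p(n_het: int, n_a: int, n: int) -> float:
    """Exact conditional Hardy-Weinberg p for a biallelic locus.

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele counts that are no more probable than the observed one.
    """
    n_b = 2 * n - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((n_a - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_b - hs) / 2 + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hs == n_het][0]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def _genotype_log_prob(pairs: list[tuple]) -> float:
    """Log conditional probability (up to a constant) of a genotype sample
    given its allele counts: -sum log n_ij! + n_het log 2."""
    counts = Counter(tuple(sorted(p)) for p in pairs)
    het = sum(c for g, c in counts.items() if g[0] != g[1])
    return het * np.log(2.0) - sum(gammaln(c + 1) for c in counts.values())


def hwe_test(
    genotypes: list[tuple], permutations: int = 10_000, seed: int = 0
) -> float:
    """Hardy-Weinberg equilibrium test for one locus.

    ``genotypes`` is a list of allele pairs (missing entries excluded
    beforehand).  Biallelic loci use the exact conditional test;
    multi-allelic loci use a Monte-Carlo permutation of alleles among
    genotypes with the conditional sample probability as statistic.
    Monomorphic loci return p = 1.
    """
    pairs = [tuple(g) for g in genotypes if g is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 typed individuals")
    alleles = [a for g in pairs for a in g]
    distinct = sorted(set(alleles))
    if len(distinct) == 1:
        return 1.0
    if len(distinct) == 2:
        a = distinct[0]
        n_a = alleles.count(a)
        n_het = sum(1 for g in pairs if g[0] != g[1])
        return _hwe_exact_p(n_het, n_a, len(pairs))
    rng = np.random.default_rng(seed)
    obs = _genotype_log_prob(pairs)
    pool = np.array(alleles, dtype=object)
    hits = 0
    for _ in range(permutations):
        rng.shuffle(pool)
        perm_pairs = [(pool[2 * i], pool[2 * i + 1]) for i in range(len(pairs))]
        if _genotype_log_prob(perm_pairs) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)


def _g_statistic(x: list, y: list) -> float:
    table = Counter(zip(x, y))
    n = len(x)
    cx, cy = Counter(x), Counter(y)
    g = 0.0
    for (a, b), o in table.items():
        e = cx[a] * cy[b] / n
        g += o * np.log(o / e)
    return 2.0 * g


def ld_test(
    geno_a: list[tuple],
    geno_b: list[tuple],
    permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation test of linkage disequilibrium between two loci.

    Individuals typed at both loci contribute their genotype pair to a
    genotype-by-genotype contingency table scored with the G statistic;
    one locus's genotypes are shuffled across individuals, and
    p = (b+1)/(B+1).  Requires >= 10 doubly-typed individuals.
    """
    xs, ys = [], []
    for a, b in zip(geno_a, geno_b):
        if a is not None and b is not None:
            xs.append(tuple(sorted(a)))
            ys.append(tuple(sorted(b)))
    if len(xs) < 10:
        raise ValueError("fewer than 10 individuals typed at both loci")
    obs = _g_statistic(xs, ys)
    rng = np.random.default_rng(seed)
    ys_arr = np.empty(len(ys), dtype=object)  # 1-D array of genotype tuples
    ys_arr[:] = ys
    hits = 0
    for _ in range(permutations):
        rng.shuffle(ys_arr)
        if _g_statistic(xs, list(ys_arr)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)
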