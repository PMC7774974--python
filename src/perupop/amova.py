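"""Distance-based AMOVA: pairwise Phi-ST/F-ST matrices, hierarchical variance
components (F_CT, F_SC, F_ST) and the grouping-scheme search.

The decomposition follows the classical analysis of molecular variance:
total sums of squared inter-individual distances are partitioned into
among-group, among-population-within-group and within-population terms,
with the standard n-coefficient weighting for unequal sample sizes.
Negative variance components are reported as computed, not truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .diversity import sequence_diff_matrix, str_distance_matrix
from .io import GenotypeTable, PopulationMap, SequenceAlignment, StrHaplotypeTable

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "squared_distance_matrix",
    "amova_from_distances",
    "amova",
    "pairwise_distance_matrix",
    "grouping_search",
    "set_partitions",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    statistic: np.ndarray  # symmetric, zero diagonal
    p_values: np.ndarray
    kind: str  # phi_st_seq | phi_st_str | fst_autosomal

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.statistic[i, j]), float(self.p_values[i, j])


@dataclass(frozen=True)
class AmovaResult:
    grouping: dict[str, tuple[str, ...]]  # group -> populations
    df: tuple[int, int, int]  # among groups, among pops within, within pops
    ssd: tuple[float, float, float]
    components: tuple[float, float, float]  # sigma_a^2, sigma_b^2, sigma_c^2
    percentages: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float
    p_sc: float
    p_st: float
    permutations: int
    seed: int | None
    degenerate: bool = False


def squared_distance_matrix(data, str_metric: str = "squared") -> tuple[np.ndarray, tuple[str, ...]]:
    """Squared inter-individual distances for any supported marker system.

    Sequences: number of differing active sites.  STR haplotypes: sum of
    squared repeat differences by default (RST-like), or differing-locus
    count via ``str_metric='loci'``.  Autosomal genotypes: allele-sharing
    distance.
    """
    if isinstance(data, SequenceAlignment):
        D2 = sequence_diff_matrix(data)
    elif isinstance(data, StrHaplotypeTable):
        D2 = str_distance_matrix(data, metric=str_metric)
    elif isinstance(data, GenotypeTable):
        from .ordination import allele_sharing_distance_matrix

        D2 = allele_sharing_distance_matrix(data)
    else:
        raise TypeError(f"unsupported data type {type(data).__name__}")
    if np.isnan(D2).any():
        raise ValueError("incomparable individual pairs (no shared sites/loci)")
    return D2, tuple(data.sample_ids)


def _block_sums(D2: np.ndarray, labels: np.ndarray, n_blocks: int) -> np.ndarray:
    """Sum of D2 over each within-label block (both triangles + diagonal)."""
    Z = np.zeros((len(labels), n_blocks))
    Z[np.arange(len(labels)), labels] = 1.0
    return np.einsum("ip,ij,jp->p", Z, D2, Z)


def _components(
    D2: np.ndarray, pop_of_ind: np.ndarray, group_of_pop: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """SSD terms and variance components for one labelling.

    Returns (ssd[3], sigma[3], (df_a, df_b, df_c)); entries for an
    undefined level (single group / all-singleton groups) are NaN.
    """
    N = len(pop_of_ind)
    P = len(group_of_pop)
    G = int(group_of_pop.max()) + 1
    group_of_ind = group_of_pop[pop_of_ind]

    n_p = np.bincount(pop_of_ind, minlength=P).astype(float)
    N_g = np.bincount(group_of_ind, minlength=G).astype(float)

    ssd_total = D2.sum() / (2.0 * N)
    pop_blocks = _block_sums(D2, pop_of_ind, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_wp = float(np.sum(np.where(n_p > 0, pop_blocks / (2.0 * n_p), 0.0)))
    group_blocks = _block_sums(D2, group_of_ind, G)
    ssd_wg = float(np.sum(group_blocks / (2.0 * N_g)))  # within groups, all levels
    ssd_ap = ssd_wg - ssd_wp  # among populations within groups
    ssd_ag = ssd_total - ssd_wg  # among groups

    df_a, df_b, df_c = G - 1, P - G, N - P
    sum_np2_by_g = np.bincount(group_of_pop, weights=n_p**2, minlength=G)

    sigma_c = ssd_wp / df_c if df_c > 0 else np.nan
    if df_b > 0:
        n_coef = (N - np.sum(sum_np2_by_g / N_g)) / df_b
        sigma_b = (ssd_ap / df_b - sigma_c) / n_coef
    else:
        sigma_b = np.nan
    if df_a > 0:
        n_prime = (np.sum(sum_np2_by_g / N_g) - np.sum(n_p**2) / N) / df_a
        n_dprime = (N - np.sum(N_g**2) / N) / df_a
        sb = 0.0 if df_b <= 0 else sigma_b
        sigma_a = (ssd_ag / df_a - sigma_c - n_prime * sb) / n_dprime
    else:
        sigma_a = np.nan

    return (
        np.array([ssd_ag, ssd_ap, ssd_wp]),
        np.array([sigma_a, sigma_b, sigma_c]),
        (df_a, df_b, df_c),
    )


def _indices(sigma: np.ndarray) -> tuple[float, float, float]:
    sa, sb, sc = sigma
    a = 0.0 if np.isnan(sa) else sa
    b = 0.0 if np.isnan(sb) else sb
    total = a + b + sc
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ct = sa / total if not np.isnan(sa) else np.nan
        f_sc = sb / (sb + sc) if not np.isnan(sb) else np.nan
        f_st = (a + b) / total if total != 0 else np.nan
    return float(f_ct), float(f_sc), float(f_st)


def _encode(sample_ids, popmap: PopulationMap, level: str, grouping=None):
    """Integer population labels per individual and group label per population."""
    pops_members = popmap.populations(level)
    present = set(sample_ids)
    pop_names = [p for p, mem in pops_members.items() if sum(m in present for m in mem) > 0]
    kept, dropped = [], []
    for p in pop_names:
        n = sum(m in present for m in pops_members[p])
        (kept if n >= 2 else dropped).append(p)
    if dropped:
        warnings.warn(f"populations with n < 2 excluded: {dropped}", stacklevel=3)
    pop_index = {p: i for i, p in enumerate(kept)}
    rows, pop_of_ind = [], []
    for i, sid in enumerate(sample_ids):
        pop = popmap.label(sid, level)
        if pop in pop_index:
            rows.append(i)
            pop_of_ind.append(pop_index[pop])
    if grouping is None:
        grouping = {"all": tuple(kept)}
    group_names = list(grouping)
    group_of_pop = np.empty(len(kept), dtype=int)
    assigned = set()
    for gi, g in enumerate(group_names):
        for p in grouping[g]:
            if p in pop_index:
                group_of_pop[pop_index[p]] = gi
                assigned.add(p)
    unassigned = set(kept) - assigned
    if unassigned:
        raise ValueError(f"populations not assigned to any group: {sorted(unassigned)}")
    return np.array(rows), np.array(pop_of_ind), group_of_pop, kept, group_names


def amova_from_distances(
    D2: np.ndarray,
    pop_of_ind: np.ndarray,
    group_of_pop: np.ndarray,
    permutations: int = 10_000,
    seed: int | None = 0,
) -> tuple:
    """AMOVA on a precomputed squared-distance matrix with integer labels.

    Returns (ssd, sigma, df, indices, p_values).  Permutation schemes: whole
    populations among groups (F_CT), individuals among populations within
    groups (F_SC), individuals among all populations (F_ST); p-values use
    the (b+1)/(B+1) estimator.
    """
    ssd, sigma, df = _components(D2, pop_of_ind, group_of_pop)
    f_ct, f_sc, f_st = _indices(sigma)
    p_ct = p_sc = p_st = np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        G = int(group_of_pop.max()) + 1
        group_of_ind = group_of_pop[pop_of_ind]

        b_st = 0
        for _ in range(permutations):
            perm = rng.permutation(pop_of_ind)
            _, s, _ = _components(D2, perm, group_of_pop)
            if _indices(s)[2] >= f_st - 1e-12:
                b_st += 1
        p_st = (b_st + 1) / (permutations + 1)

        if not np.isnan(f_sc):
            b_sc = 0
            for _ in range(permutations):
                perm = pop_of_ind.copy()
                for g in range(G):
                    mask = group_of_ind == g
                    perm[mask] = rng.permutation(perm[mask])
                _, s, _ = _components(D2, perm, group_of_pop)
                if _indices(s)[1] >= f_sc - 1e-12:
                    b_sc += 1
            p_sc = (b_sc + 1) / (permutations + 1)

        if G > 1 and not np.isnan(f_ct):
            b_ct = 0
            for _ in range(permutations):
                gperm = rng.permutation(group_of_pop)
                _, s, _ = _components(D2, pop_of_ind, gperm)
                if _indices(s)[0] >= f_ct - 1e-12:
                    b_ct += 1
            p_ct = (b_ct + 1) / (permutations + 1)

    return ssd, sigma, df, (f_ct, f_sc, f_st), (p_ct, p_sc, p_st)


def amova(
    data,
    popmap: PopulationMap,
    grouping: dict | None = None,
    level: str = "subgroup",
    permutations: int = 10_000,
    seed: int | None = 0,
    str_metric: str = "squared",
) -> AmovaResult:
    """Hierarchical AMOVA for any marker system.

    ``grouping`` maps group label -> population labels; omit it for a
    two-level design (one implicit group, F_CT undefined).
    """
    D2_full, sample_ids = squared_distance_matrix(data, str_metric=str_metric)
    rows, pop_of_ind, group_of_pop, kept, group_names = _encode(
        sample_ids, popmap, level, grouping
    )
    if len(kept) < 2:
        raise ValueError("need at least two populations with n >= 2")
    D2 = D2_full[np.ix_(rows, rows)]
    ssd, sigma, df, idx, pvals = amova_from_distances(
        D2, pop_of_ind, group_of_pop, permutations, seed
    )
    degenerate = bool(np.allclose(ssd, 0.0))
    sigma_f = np.nan_to_num(sigma, nan=0.0)
    total = sigma_f.sum()
    pct = tuple(100.0 * sigma_f / total) if total > 0 else (0.0, 0.0, 0.0)
    grouping_out = {
        g: tuple(p for p in (grouping or {"all": kept})[g] if p in kept)
        for g in group_names
    }
    return AmovaResult(
        grouping_out, df, tuple(ssd), tuple(sigma), pct,
        idx[0] if not degenerate else 0.0,
        idx[1] if not degenerate else 0.0,
        idx[2] if not degenerate else 0.0,
        pvals[0], pvals[1], pvals[2],
        permutations, seed, degenerate,
    )


def pairwise_distance_matrix(
    data,
    popmap: PopulationMap,
    level: str = "subgroup",
    permutations: int = 10_000,
    seed: int | None = 0,
    str_metric: str = "squared",
) -> DistanceMatrix:
    """Pairwise Phi-ST/F-ST: two-level AMOVA fixation index per population pair.

    p = fraction of individual-label permutations with a statistic at least
    as large as observed, via the (b+1)/(B+1) estimator.  Negative
    statistics are reported as computed.
    """
    D2_full, sample_ids = squared_distance_matrix(data, str_metric=str_metric)
    rows, pop_of_ind, _, kept, _ = _encode(sample_ids, popmap, level, None)
    D2 = D2_full[np.ix_(rows, rows)]
    if isinstance(data, SequenceAlignment):
        kind = "phi_st_seq"
    elif isinstance(data, StrHaplotypeTable):
        kind = "phi_st_str"
    else:
        kind = "fst_autosomal"

    P = len(kept)
    stat = np.zeros((P, P))
    pmat = np.ones((P, P))
    rng = np.random.default_rng(seed)
    for a, b in combinations(range(P), 2):
        mask = (pop_of_ind == a) | (pop_of_ind == b)
        sub = D2[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
        labels = (pop_of_ind[mask] == b).astype(int)
        _, sigma, _ = _components(sub, labels, np.zeros(2, dtype=int))
        phi = _indices(sigma)[2]
        hits = 0
        for _ in range(permutations):
            _, s, _ = _components(sub, rng.permutation(labels), np.zeros(2, dtype=int))
            if _indices(s)[2] >= phi - 1e-12:
                hits += 1
        stat[a, b] = stat[b, a] = phi
        p = (hits + 1) / (permutations + 1) if permutations > 0 else np.nan
        pmat[a, b] = pmat[b, a] = p
    return DistanceMatrix(tuple(kept), stat, pmat, kind)


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def grouping_search(
    data,
    popmap: PopulationMap,
    candidate_groupings: list[dict] | None = None,
    level: str = "subgroup",
    permutations: int = 0,
    seed: int | None = 0,
    str_metric: str = "squared",
) -> list[AmovaResult]:
    """Rank grouping schemes by F_CT (descending) then F_SC (ascending).

    With no explicit candidates, all set partitions of the populations are
    enumerated (allowed for <= 8 populations).  Schemes whose F_CT is
    undefined (single group) rank last; ties are preserved in order.
    """
    if candidate_groupings is None:
        pops = [p for p, m in popmap.populations(level).items() if len(m) >= 2]
        if len(pops) > 8:
            raise ValueError("exhaustive partition enumeration limited to 8 populations")
        candidate_groupings = [
            {f"G{i + 1}": tuple(block) for i, block in enumerate(part)}
            for part in set_partitions(pops)
        ]
    results = [
        amova(data, popmap, grouping=g, level=level, permutations=permutations,
              seed=seed, str_metric=str_metric)
        for g in candidate_groupings
    ]

    def key(r: AmovaResult):
        f_ct = r.f_ct if len(r.grouping) > 1 else -np.inf
        f_sc = r.f_sc if not np.isnan(r.f_sc) else np.inf
        return (-f_ct, f_sc)

    return sorted(results, key=key)
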