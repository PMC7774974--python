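"""Coalescent synthetic data: genealogies under piecewise sex-specific
demographies, finite-sites mtDNA sequences, stepwise-mutation Y-STR
haplotypes and admixed autosomal genotypes.

Haploid scaling is used throughout for the uniparental markers (mtDNA and
the Y chromosome are haploid and uniparental): with constant size N the
expected pairwise coalescence time is N generations.  Diploid autosomal
genotypes are drawn from mixtures of component allele-frequency profiles,
not from a coalescent, since no autosomal sequence-level analysis is in
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import CalibrationConfig, Genealogy
from .io import (
    GenotypeTable,
    PopulationMap,
    QMatrix,
    SequenceAlignment,
    StrHaplotypeTable,
)

__all__ = [
    "Epoch",
    "DemographicModel",
    "SimConfig",
    "simulate_genealogy",
    "simulate_sequences",
    "simulate_str_haplotypes",
    "simulate_admixed_genotypes",
    "ScenarioBundle",
    "female_history",
    "male_history",
    "study_scenario",
]

BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass(frozen=True)
class Epoch:
    """One demographic epoch in backward time (generations before present).

    ``n_start`` is the size at ``start`` (the recent edge); exponential
    epochs interpolate log-linearly to ``n_end`` at the old edge.  The last
    epoch may be open-ended (end = inf) and must be constant.
    """

    start: float
    end: float
    n_start: float
    n_end: float | None = None
    kind: str = "constant"  # constant | exponential

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError("epoch must satisfy 0 <= start < end")
        if self.n_start <= 0:
            raise ValueError("N must be positive")
        if self.kind == "constant":
            object.__setattr__(self, "n_end", self.n_start)
        elif self.kind == "exponential":
            if self.n_end is None or self.n_end <= 0:
                raise ValueError("exponential epoch needs positive n_end")
            if math.isinf(self.end):
                raise ValueError("open-ended epoch must be constant")
        else:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")

    def size_at(self, t: float) -> float:
        if self.kind == "constant":
            return self.n_start
        g = math.log(self.n_end / self.n_start) / (self.end - self.start)
        return self.n_start * math.exp(g * (t - self.start))

    def intensity(self, t0: float, t1: float) -> float:
        """Integral of dt / N(t) over [t0, t1] within this epoch."""
        if self.kind == "constant":
            return (t1 - t0) / self.n_start
        g = math.log(self.n_end / self.n_start) / (self.end - self.start)
        if abs(g) < 1e-14:
            return (t1 - t0) / self.n_start
        # N(t) = n_start * exp(g (t - start))
        a0, a1 = t0 - self.start, t1 - self.start
        return (math.exp(-g * a0) - math.exp(-g * a1)) / (self.n_start * g)

    def time_for_intensity(self, t0: float, target: float) -> float:
        """Time t >= t0 in this epoch at which the intensity from t0 reaches
        ``target`` (may exceed the epoch end; caller clips)."""
        if self.kind == "constant":
            return t0 + target * self.n_start
        g = math.log(self.n_end / self.n_start) / (self.end - self.start)
        if abs(g) < 1e-14:
            return t0 + target * self.n_start
        a0 = t0 - self.start
        inner = math.exp(-g * a0) - target * self.n_start * g
        if inner <= 0:
            return math.inf
        return self.start - math.log(inner) / g


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise effective-size trajectory for one sex.

    Epochs must tile [0, inf) contiguously backward from the present.
    """

    epochs: tuple[Epoch, ...]
    label: str = "female"

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("at least one epoch required")
        if self.epochs[0].start != 0:
            raise ValueError("first epoch must start at 0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not math.isclose(a.end, b.start):
                raise ValueError("epochs must be contiguous")
        if not math.isinf(self.epochs[-1].end):
            raise ValueError("last epoch must be open-ended (end = inf)")

    def size_at(self, t: float) -> float:
        for ep in self.epochs:
            if ep.start <= t < ep.end:
                return ep.size_at(t)
        return self.epochs[-1].size_at(t)

    @classmethod
    def constant(cls, n: float, label: str = "female") -> "DemographicModel":
        return cls((Epoch(0.0, math.inf, n),), label)


@dataclass(frozen=True)
class SimConfig:
    """Bundle of simulation parameters; the seed is recorded in all outputs."""

    n_samples: int = 30
    sequence_length: int = 1000
    mu_site_per_generation: float = field(
        default_factory=lambda: CalibrationConfig().mt_rate_per_generation
    )
    n_str_loci: int = 17
    mu_locus_per_generation: float = 8.2e-4
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if min(self.n_samples, self.sequence_length, self.n_str_loci, self.replicates) <= 0:
            raise ValueError("sizes must be positive")
        if min(self.mu_site_per_generation, self.mu_locus_per_generation) < 0:
            raise ValueError("mutation rates must be non-negative")


def _first_passage(model: DemographicModel, t0: float, target: float) -> float:
    """Time at which cumulative single-pair coalescent intensity from t0
    reaches ``target`` under the piecewise trajectory."""
    t = t0
    acc = 0.0
    for ep in model.epochs:
        if ep.end <= t:
            continue
        seg_start = max(t, ep.start)
        seg_end = ep.end
        seg = ep.intensity(seg_start, seg_end) if not math.isinf(seg_end) else math.inf
        if acc + seg >= target:
            return ep.time_for_intensity(seg_start, target - acc)
        acc += seg
    raise RuntimeError("ran out of epochs (last epoch must be open-ended)")


def simulate_genealogy(
    model: DemographicModel,
    n: int,
    seed: int | np.random.Generator = 0,
    tip_labels=(),
) -> Genealogy:
    """Draw a coalescent genealogy of ``n`` tips under the model.

    With i lineages the instantaneous coalescent rate is i(i-1)/(2 N(t));
    waiting times are drawn by time-rescaling of unit-rate exponentials
    through the epochs; topology by uniform random pair merging.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    next_node = n
    for i in range(n, 1, -1):
        pairs = i * (i - 1) / 2.0
        target = rng.exponential(1.0) / pairs  # single-pair intensity units
        t = _first_passage(model, t, target)
        a, b = rng.choice(len(active), size=2, replace=False)
        u, v = active[a], active[b]
        parent[u] = parent[v] = next_node
        time[next_node] = t
        for idx in sorted((a, b), reverse=True):
            active.pop(idx)
        active.append(next_node)
        next_node += 1
    return Genealogy(n, parent, time, tuple(tip_labels))


def simulate_sequences(
    g: Genealogy,
    mu_site: float,
    length: int,
    seed: int | np.random.Generator = 0,
    coordinate_origin: int = 1,
) -> SequenceAlignment:
    """Finite-sites mutation along the genealogy.

    Mutations per branch ~ Poisson(mu_site * length * branch_length),
    placed at uniform sites; each substitutes one of the three other bases
    uniformly.  The root sequence is uniform random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = 2 * g.n_tips - 1
    seqs = np.empty((n_nodes, length), dtype="S1")
    root = g.root
    seqs[root] = BASES[rng.integers(0, 4, size=length)]
    blen = g.branch_lengths()
    children = g.children()
    order = np.argsort(g.time)[::-1]  # root first, tips last
    for v in order:
        for c in children[v]:
            seq = seqs[v].copy()
            k = rng.poisson(mu_site * length * blen[c])
            if k:
                sites = rng.integers(0, length, size=k)
                for s in sites:
                    current = seq[s]
                    choices = BASES[BASES != current]
                    seq[s] = choices[rng.integers(0, 3)]
            seqs[c] = seq
    tip_seqs = tuple(seqs[i].tobytes().decode("ascii") for i in range(g.n_tips))
    return SequenceAlignment(g.tip_labels, tip_seqs, coordinate_origin)


def simulate_str_haplotypes(
    g: Genealogy,
    n_loci: int,
    mu_locus: float,
    seed: int | np.random.Generator = 0,
    root_repeats: int = 12,
    locus_names=(),
) -> StrHaplotypeTable:
    """Stepwise mutation model along the genealogy.

    Per branch and locus, Poisson(mu_locus * branch_length) steps of +-1
    with equal probability, floored at 1 repeat (non-physical counts are
    clamped).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = 2 * g.n_tips - 1
    reps = np.empty((n_nodes, n_loci), dtype=int)
    root = g.root
    reps[root] = root_repeats
    blen = g.branch_lengths()
    children = g.children()
    order = np.argsort(g.time)[::-1]
    for v in order:
        for c in children[v]:
            k = rng.poisson(mu_locus * blen[c], size=n_loci)
            steps = np.array(
                [rng.choice([-1, 1], size=ki).sum() if ki else 0 for ki in k]
            )
            reps[c] = np.maximum(reps[v] + steps, 1)
    if not locus_names:
        locus_names = tuple(f"DYS{i + 1:03d}" for i in range(n_loci))
    return StrHaplotypeTable(g.tip_labels, tuple(locus_names), reps[: g.n_tips])


def simulate_admixed_genotypes(
    component_freqs: list[dict[str, dict[str, float]]],
    q: QMatrix,
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Diploid genotypes from K-component mixture allele frequencies.

    Each of the two alleles at a locus independently picks its source
    component with probability q_k, then its allele from that component's
    frequency profile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = len(component_freqs)
    if K != q.K:
        raise ValueError("component count mismatch between freqs and Q")
    loci = list(component_freqs[0])
    if any(list(f) != loci for f in component_freqs):
        raise ValueError("all components must share the same loci")
    allele_lists = {
        l: sorted({a for f in component_freqs for a in f[l]}) for l in loci
    }
    fmat = {
        l: np.array(
            [[f[l].get(a, 0.0) for a in allele_lists[l]] for f in component_freqs]
        )
        for l in loci
    }
    for l, m in fmat.items():
        fmat[l] = m / m.sum(axis=1, keepdims=True)
    n = len(q.sample_ids)
    alleles = np.empty((n, len(loci), 2), dtype=object)
    for i in range(n):
        qs = q.proportions[i]
        for j, l in enumerate(loci):
            for c in range(2):
                k = rng.choice(K, p=qs)
                a = rng.choice(len(allele_lists[l]), p=fmat[l][k])
                alleles[i, j, c] = allele_lists[l][a]
    return GenotypeTable(q.sample_ids, tuple(loci), alleles)


# ---------------------------------------------------------------------------
# Packaged study scenario


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything one analysis run needs, as generated data."""

    mt_alignment: SequenceAlignment
    mt_popmap: PopulationMap
    ystr_table: StrHaplotypeTable
    ystr_popmap: PopulationMap
    genotypes: GenotypeTable
    qmatrix: QMatrix
    genotype_popmap: PopulationMap
    female_model: DemographicModel
    male_model: DemographicModel
    seed: int


def female_history(n_plateau: float = 2000.0, n_ancient: float = 200.0) -> DemographicModel:
    """Female Ne trajectory: growth 625-250 generations ago to a plateau,
    then decline from 125 generations ago toward the present with no
    recent rebound (present size 40% of the plateau)."""
    return DemographicModel(
        (
            Epoch(0.0, 125.0, 0.4 * n_plateau, n_plateau, "exponential"),
            Epoch(125.0, 250.0, n_plateau),
            Epoch(250.0, 625.0, n_plateau, n_ancient, "exponential"),
            Epoch(625.0, math.inf, n_ancient),
        ),
        label="female",
    )


def male_history(n_plateau: float = 2000.0, n_ancient: float = 200.0) -> DemographicModel:
    """Male Ne trajectory: same ancient shape as the female one, but a
    steep decline reaching a 50% reduction 25 generations ago followed by
    a 20% rebound toward the present."""
    n_min = 0.5 * n_plateau
    return DemographicModel(
        (
            Epoch(0.0, 25.0, 1.2 * n_min, n_min, "exponential"),
            Epoch(25.0, 125.0, n_min, n_plateau, "exponential"),
            Epoch(125.0, 250.0, n_plateau),
            Epoch(250.0, 625.0, n_plateau, n_ancient, "exponential"),
            Epoch(625.0, math.inf, n_ancient),
        ),
        label="male",
    )


_SUBGROUPS = (
    "Pomacochas", "Chillao", "Corobamba", "RodriguezDeMendoza",
    "Chachapoya", "LaJalca", "Leymebamba",
)


def _population_layout(prefix: str, sizes: dict[str, int], rng) -> PopulationMap:
    """Build the four-population hierarchy; Chachapoyas-like samples are
    spread exchangeably over the seven subgroups (high-migration limit)."""
    assignments: dict[str, tuple[str, str, str]] = {}
    counter = 0
    n_cha = sizes["Chachapoyas"]
    subs = [_SUBGROUPS[i % len(_SUBGROUPS)] for i in range(n_cha)]
    rng.shuffle(subs)
    for s in subs:
        assignments[f"{prefix}{counter:03d}"] = (s, "Chachapoyas", "Andean")
        counter += 1
    for pop, macro in (("Jivaro", "Amazonian"), ("Huancas", "Andean"), ("Cajamarca", "Andean")):
        for _ in range(sizes[pop]):
            assignments[f"{prefix}{counter:03d}"] = (pop, pop, macro)
            counter += 1
    return PopulationMap(assignments)


def study_scenario(
    seed: int = 0,
    sizes: dict[str, int] | None = None,
    n_plateau: float = 2000.0,
    sequence_length: int = 2000,
    n_str_loci: int = 17,
    n_auto_loci: int = 100,
    calibration: CalibrationConfig | None = None,
) -> ScenarioBundle:
    """Generate the packaged default scenario.

    Four populations (Chachapoyas-like with seven exchangeable subgroups,
    Jivaro-like, Huancas-like, Cajamarca-like); mtDNA sequences under the
    female trajectory, Y-STR haplotypes under the male trajectory, and
    K=3 admixed autosomal genotypes with a third component concentrated in
    the Chachapoyas- and Jivaro-like samples.  Each main population gets
    its own genealogy (strong between-population structure); subgroup
    labels within Chachapoyas are exchangeable, emulating migration high
    enough to homogenize the subgroups.
    """
    rng = np.random.default_rng(seed)
    calibration = calibration or CalibrationConfig()
    sizes = sizes or {"Chachapoyas": 42, "Jivaro": 18, "Huancas": 8, "Cajamarca": 12}
    fem = female_history(n_plateau=n_plateau)
    mal = male_history(n_plateau=n_plateau)

    mt_popmap = _population_layout("F", sizes, rng)
    mu_site = calibration.mt_rate_per_generation
    mt_parts: dict[str, SequenceAlignment] = {}
    for pop, members in mt_popmap.populations("region").items():
        g = simulate_genealogy(fem, len(members), rng, tip_labels=members)
        mt_parts[pop] = simulate_sequences(g, mu_site, sequence_length, rng)
    all_ids = tuple(s for p in mt_parts.values() for s in p.sample_ids)
    all_seqs = tuple(s for p in mt_parts.values() for s in p.sequences)
    mt_alignment = SequenceAlignment(all_ids, all_seqs, coordinate_origin=577)

    ystr_popmap = _population_layout("M", sizes, rng)
    ystr_parts = []
    for pop, members in ystr_popmap.populations("region").items():
        g = simulate_genealogy(mal, len(members), rng, tip_labels=members)
        # distinct founder repeat counts per population preserve structure
        root = int(rng.integers(10, 18))
        ystr_parts.append(
            simulate_str_haplotypes(
                g, n_str_loci, calibration.y_str_rate, rng, root_repeats=root
            )
        )
    ystr_table = StrHaplotypeTable(
        tuple(s for p in ystr_parts for s in p.sample_ids),
        ystr_parts[0].locus_names,
        np.vstack([p.repeat_counts for p in ystr_parts]),
    )

    geno_popmap = _population_layout("A", sizes, rng)
    # emulate the forensic panel's mix: ~27% STR-like multi-allelic loci,
    # the rest SNP-like biallelic
    n_str_like = max(1, round(0.27 * n_auto_loci))
    allele_counts = [6] * n_str_like + [2] * (n_auto_loci - n_str_like)
    loci = [f"L{j + 1:03d}" for j in range(n_auto_loci)]
    component_freqs = []
    for _ in range(3):
        freqs = {}
        for l, n_all in zip(loci, allele_counts):
            p = rng.dirichlet([0.5] * n_all)
            freqs[l] = {str(a + 1): float(p[a]) for a in range(n_all)}
        component_freqs.append(freqs)
    # component means: Native American, European, third unknown component
    dirichlet_by_pop = {
        "Chachapoyas": (5.0, 2.5, 2.5),
        "Jivaro": (5.0, 1.0, 4.0),
        "Huancas": (8.0, 1.5, 0.5),
        "Cajamarca": (6.0, 3.0, 1.0),
    }
    ids, qrows = [], []
    for pop, members in geno_popmap.populations("region").items():
        alpha = dirichlet_by_pop[pop]
        for sid in members:
            ids.append(sid)
            qrows.append(rng.dirichlet(alpha))
    qmatrix = QMatrix(tuple(ids), np.array(qrows))
    genotypes = simulate_admixed_genotypes(component_freqs, qmatrix, rng)

    return ScenarioBundle(
        mt_alignment, mt_popmap, ystr_table, ystr_popmap,
        genotypes, qmatrix, geno_popmap, fem, mal, seed,
    )
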