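import numpy as np
import pytest

from perupop.amova import (
    amova,
    grouping_search,
    pairwise_distance_matrix,
    set_partitions,
    squared_distance_matrix,
)
from perupop.io import PopulationMap, SequenceAlignment


def brute_force_amova(D2, pop_of_ind, group_of_pop):
    """Independent oracle: variance components assembled directly from the
    distance matrix and group sums, scalar arithmetic only."""
    N = len(pop_of_ind)
    P = len(group_of_pop)
    G = max(group_of_pop) + 1
    grp_of_ind = [group_of_pop[p] for p in pop_of_ind]
    n_p = [pop_of_ind.count(p) for p in range(P)]
    N_g = [grp_of_ind.count(g) for g in range(G)]

    def block(members):
        return sum(D2[i][j] for i in members for j in members)

    sst = block(range(N)) / (2 * N)
    ssw = sum(
        block([i for i in range(N) if pop_of_ind[i] == p]) / (2 * n_p[p])
        for p in range(P)
    )
    sswg = sum(
        block([i for i in range(N) if grp_of_ind[i] == g]) / (2 * N_g[g])
        for g in range(G)
    )
    ssd_ap, ssd_ag = sswg - ssw, sst - sswg
    sum_np2_g = [
        sum(n_p[p] ** 2 for p in range(P) if group_of_pop[p] == g) for g in range(G)
    ]
    sc = ssw / (N - P)
    if P - G > 0:
        n_c = (N - sum(s / N_g[g] for g, s in enumerate(sum_np2_g))) / (P - G)
        sb = (ssd_ap / (P - G) - sc) / n_c
    else:
        sb = float("nan")
    if G > 1:
        n_pr = (
            sum(s / N_g[g] for g, s in enumerate(sum_np2_g))
            - sum(x**2 for x in n_p) / N
        ) / (G - 1)
        n_dpr = (N - sum(x**2 for x in N_g) / N) / (G - 1)
        sa = (ssd_ag / (G - 1) - sc - n_pr * (0 if np.isnan(sb) else sb)) / n_dpr
    else:
        sa = float("nan")
    return (ssd_ag, ssd_ap, ssw), (sa, sb, sc)


def random_alignment(rng, pops, n_per, L=15, div=0.15):
    ids, seqs, assign = [], [], {}
    bases = np.array(list("ACGT"))
    for p in pops:
        anc = rng.choice(bases, size=L)
        for i in range(n_per):
            s = anc.copy()
            mut = rng.random(L) < div
            s[mut] = rng.choice(bases, size=mut.sum())
            sid = f"{p}_{i}"
            ids.append(sid)
            seqs.append("".join(s))
            assign[sid] = (p, p, "M")
    return SequenceAlignment(tuple(ids), tuple(seqs)), PopulationMap(assign)


class TestPairwisePhiST:
    def test_identical_multisets_phi_near_zero(self):
        seqs = ("AAAA", "AATT", "AAAA", "AATT")
        pm = PopulationMap(
            {f"s{i}": (("P1", "P2")[i // 2], ("P1", "P2")[i // 2], "M") for i in range(4)}
        )
        aln = SequenceAlignment(tuple(f"s{i}" for i in range(4)), seqs)
        dm = pairwise_distance_matrix(aln, pm, permutations=200, seed=0)
        phi, p = dm.pair("P1", "P2")
        assert phi <= 1e-9
        assert p > 0.5

    def test_fixed_distinct_haplotypes_phi_one(self):
        seqs = ("AAAA", "AAAA", "TTTT", "TTTT")
        pm = PopulationMap(
            {f"s{i}": (("P1", "P2")[i // 2], ("P1", "P2")[i // 2], "M") for i in range(4)}
        )
        aln = SequenceAlignment(tuple(f"s{i}" for i in range(4)), seqs)
        dm = pairwise_distance_matrix(aln, pm, permutations=0, seed=0)
        assert dm.pair("P1", "P2")[0] == pytest.approx(1.0)

    def test_matches_two_level_amova(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2"], 6, L=20)
        dm = pairwise_distance_matrix(aln, pm, permutations=0, seed=0)
        res = amova(aln, pm, permutations=0)
        assert dm.pair("P1", "P2")[0] == pytest.approx(res.f_st, abs=1e-12)

    def test_small_population_excluded_with_warning(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2"], 3)
        pm2 = PopulationMap({**pm.assignments, "solo": ("P3", "P3", "M")})
        aln2 = SequenceAlignment(
            aln.sample_ids + ("solo",), aln.sequences + (aln.sequences[0],)
        )
        with pytest.warns(UserWarning, match="P3"):
            dm = pairwise_distance_matrix(aln2, pm2, permutations=0, seed=0)
        assert "P3" not in dm.labels


class TestAmova:
    def test_all_identical_degenerate(self):
        seqs = ("ACGT",) * 6
        pm = PopulationMap(
            {f"s{i}": (("A", "B")[i // 3], ("A", "B")[i // 3], "M") for i in range(6)}
        )
        aln = SequenceAlignment(tuple(f"s{i}" for i in range(6)), seqs)
        res = amova(aln, pm, permutations=0)
        assert res.degenerate
        assert res.f_st == 0.0
        assert all(s == 0 for s in res.ssd)

    def test_matches_brute_force_oracle(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2", "P3"], 4)
        grouping = {"G1": ("P1", "P2"), "G2": ("P3",)}
        res = amova(aln, pm, grouping=grouping, permutations=0)
        D2, ids = squared_distance_matrix(aln)
        pop_of = [0] * 4 + [1] * 4 + [2] * 4
        ssd_o, sigma_o = brute_force_amova(D2.tolist(), pop_of, [0, 0, 1])
        np.testing.assert_allclose(res.ssd, ssd_o, atol=1e-9)
        np.testing.assert_allclose(res.components, sigma_o, atol=1e-9)

    def test_unequal_sizes_match_oracle(self, rng):
        ids, seqs, assign = [], [], {}
        bases = np.array(list("ACGT"))
        sizes = {"P1": 3, "P2": 5, "P3": 4}
        for p, n in sizes.items():
            anc = rng.choice(bases, size=12)
            for i in range(n):
                s = anc.copy()
                mut = rng.random(12) < 0.2
                s[mut] = rng.choice(bases, size=mut.sum())
                ids.append(f"{p}_{i}")
                seqs.append("".join(s))
                assign[f"{p}_{i}"] = (p, p, "M")
        aln = SequenceAlignment(tuple(ids), tuple(seqs))
        pm = PopulationMap(assign)
        res = amova(aln, pm, grouping={"G1": ("P1",), "G2": ("P2", "P3")}, permutations=0)
        D2, _ = squared_distance_matrix(aln)
        pop_of = [0] * 3 + [1] * 5 + [2] * 4
        ssd_o, sigma_o = brute_force_amova(D2.tolist(), pop_of, [0, 1, 1])
        np.testing.assert_allclose(res.ssd, ssd_o, atol=1e-9)
        np.testing.assert_allclose(res.components, sigma_o, atol=1e-9)

    def test_ssd_conservation(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2", "P3", "P4"], 4)
        res = amova(
            aln, pm, grouping={"G1": ("P1", "P2"), "G2": ("P3", "P4")}, permutations=0
        )
        D2, _ = squared_distance_matrix(aln)
        total = D2.sum() / (2 * 16)
        assert sum(res.ssd) == pytest.approx(total, abs=1e-9)

    def test_percentages_sum_to_hundred(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2", "P3"], 4)
        res = amova(aln, pm, grouping={"G1": ("P1",), "G2": ("P2", "P3")}, permutations=0)
        assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)

    def test_index_definitions(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2", "P3"], 4)
        res = amova(aln, pm, grouping={"G1": ("P1", "P2"), "G2": ("P3",)}, permutations=0)
        sa, sb, sc = res.components
        assert res.f_ct == pytest.approx(sa / (sa + sb + sc), abs=1e-12)
        assert res.f_sc == pytest.approx(sb / (sb + sc), abs=1e-12)

    def test_split_population_phi_centers_on_zero(self, rng):
        """Randomly splitting one panmictic sample yields Phi-ST near 0."""
        phis = []
        bases = np.array(list("ACGT"))
        for _ in range(40):
            anc = rng.choice(bases, size=30)
            seqs, assign = [], {}
            for i in range(12):
                s = anc.copy()
                mut = rng.random(30) < 0.1
                s[mut] = rng.choice(bases, size=mut.sum())
                seqs.append("".join(s))
                assign[f"s{i}"] = (("H1", "H2")[i % 2], ("H1", "H2")[i % 2], "M")
            aln = SequenceAlignment(tuple(f"s{i}" for i in range(12)), tuple(seqs))
            dm = pairwise_distance_matrix(aln, PopulationMap(assign), permutations=0, seed=0)
            phis.append(dm.pair("H1", "H2")[0])
        assert abs(np.mean(phis)) < 0.03


class TestGroupingSearch:
    def test_partition_count_is_bell_number(self):
        assert len(list(set_partitions([1, 2, 3, 4]))) == 15

    def test_single_candidate_returned(self, rng):
        aln, pm = random_alignment(rng, ["P1", "P2"], 4)
        results = grouping_search(
            aln, pm, candidate_groupings=[{"G1": ("P1",), "G2": ("P2",)}]
        )
        assert len(results) == 1

    def test_true_partition_recovered(self, rng):
        """Two clusters of two populations each: the 2+2 partition wins."""
        bases = np.array(list("ACGT"))
        wins = 0
        n_rep = 12
        for _ in range(n_rep):
            ids, seqs, assign = [], [], {}
            for g, pops in enumerate((("P1", "P2"), ("P3", "P4"))):
                anc = rng.choice(bases, size=40)
                for p in pops:
                    for i in range(4):
                        s = anc.copy()
                        mut = rng.random(40) < 0.05
                        s[mut] = rng.choice(bases, size=mut.sum())
                        ids.append(f"{p}_{i}")
                        seqs.append("".join(s))
                        assign[f"{p}_{i}"] = (p, p, "M")
            aln = SequenceAlignment(tuple(ids), tuple(seqs))
            ranked = grouping_search(aln, PopulationMap(assign), permutations=0)
            top = {frozenset(v) for v in ranked[0].grouping.values()}
            if top == {frozenset({"P1", "P2"}), frozenset({"P3", "P4"})}:
                wins += 1
        assert wins >= round(0.9 * n_rep) - 1
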