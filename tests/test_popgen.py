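"""FST, permutation significance, merging, linearization, MDS, composition."""

import itertools

import numpy as np
import pytest

from mtphylo.popgen import (
    MdsResult,
    PopgenError,
    PopulationSample,
    bonferroni,
    classify_lineage,
    fst_matrix,
    haplogroup_composition,
    mds,
    merge_nonsignificant,
    pairwise_fst,
    permutation_pvalue,
    slatkin_linearize,
)
from mtphylo.sequence_io import Haplotype, Variant
from mtphylo.synthetic import SimConfig, simulate_island_pair

from conftest import sub

FR = (16090, 16365)


def _hap(sid, variants, pop="p"):
    return Haplotype(sid, pop, "other", frozenset(variants), FR)


H1 = [sub(16111)]
H2 = [sub(16222, "C", "T")]


def _pop(name, hap_lists):
    return PopulationSample(name, [_hap(f"{name}{i}", v, pop=name) for i, v in enumerate(hap_lists)])


def brute_force_amova_fst(members_a, members_b, mode="haplotype_identity"):
    """Independent loop-based AMOVA oracle (explicit sums of squares)."""
    def key(h):
        return frozenset((v.position, v.derived_base) for v in h.variants)

    def dist(h, g):
        if mode == "haplotype_identity":
            return 0.0 if key(h) == key(g) else 1.0
        return float(len(key(h) ^ key(g)))

    everyone = list(members_a) + list(members_b)
    N = len(everyone)
    ssd_total = 0.0
    for i in range(N):
        for j in range(N):
            ssd_total += dist(everyone[i], everyone[j])
    ssd_total /= 2 * N
    ssd_within = 0.0
    for group in (members_a, members_b):
        s = 0.0
        for h in group:
            for g in group:
                s += dist(h, g)
        ssd_within += s / (2 * len(group))
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (N - 2)
    n_prime = (N - (len(members_a) ** 2 + len(members_b) ** 2) / N) / 1
    sigma_a = (ssd_among / 1 - ms_within) / n_prime
    denom = sigma_a + ms_within
    return 0.0 if denom == 0 else sigma_a / denom


class TestPairwiseFst:
    def test_identical_fixed_populations_give_zero(self):
        assert pairwise_fst(_pop("A", [H1] * 5), _pop("B", [H1] * 5)) == 0.0

    def test_distinct_fixed_populations_give_one(self):
        assert pairwise_fst(_pop("A", [H1] * 10), _pop("B", [H2] * 10)) == pytest.approx(1.0)

    def test_matches_brute_force_amova_on_mixed_fixture(self):
        a = _pop("A", [H1, H1, H1, H2])
        b = _pop("B", [H1, H2, H2, H2])
        got = pairwise_fst(a, b)
        want = brute_force_amova_fst(a.members, b.members)
        assert got == pytest.approx(want, abs=1e-12)

    def test_pairwise_differences_mode_matches_oracle(self):
        a = _pop("A", [H1, H1, H1 + H2, H2])
        b = _pop("B", [H2, H2, [], H1])
        got = pairwise_fst(a, b, "pairwise_differences")
        want = brute_force_amova_fst(a.members, b.members, "pairwise_differences")
        assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_arguments(self):
        a = _pop("A", [H1, H1, H2])
        b = _pop("B", [H2, H2, H1])
        assert pairwise_fst(a, b) == pytest.approx(pairwise_fst(b, a), abs=1e-14)

    def test_self_comparison_shows_no_differentiation(self):
        # unbiased variance components can go negative for identical samples;
        # the estimate must never be positive and linearizes to exactly 0
        a = _pop("A", [H1, H2, H1, []])
        f = pairwise_fst(a, _pop("B", [H1, H2, H1, []]))
        assert f <= 1e-12
        assert slatkin_linearize(f) == 0.0

    def test_mismatched_fragments_error(self):
        a = _pop("A", [H1])
        other = PopulationSample("B", [Haplotype("x", "B", "other", frozenset(), (16090, 16300))])
        with pytest.raises(PopgenError):
            pairwise_fst(a, other)


class TestPermutationPvalue:
    def test_identical_monomorphic_populations_give_p_one(self):
        p = permutation_pvalue(_pop("A", [H1] * 5), _pop("B", [H1] * 5), 99, seed=0)
        assert p == 1.0

    def test_fixed_different_haplotypes_are_significant(self):
        p = permutation_pvalue(_pop("A", [H1] * 10), _pop("B", [H2] * 10), 999, seed=0)
        assert p < 0.05

    def test_same_seed_reproduces_p_exactly(self):
        a, b = simulate_island_pair(SimConfig.island_scenario(seed=3, divergence=0.3))
        p1 = permutation_pvalue(a, b, 199, seed=42)
        p2 = permutation_pvalue(a, b, 199, seed=42)
        assert p1 == p2


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals,alpha,expected",
        [
            ([0.04], 0.05, [True]),
            ([0.01] + [0.5] * 9, 0.05, [False] + [False] * 9),
            ([0.004] + [0.5] * 9, 0.05, [True] + [False] * 9),
        ],
    )
    def test_threshold_is_alpha_over_m(self, pvals, alpha, expected):
        assert list(bonferroni(pvals, alpha)) == expected


class TestMergeNonsignificant:
    def test_same_population_samples_are_merged(self):
        a, b = simulate_island_pair(SimConfig.island_scenario(seed=7, divergence=0.0))
        merged = merge_nonsignificant([a, b], [["island_A", "island_B"]],
                                      n_permutations=999, seed=7)
        assert len(merged) == 1
        assert merged[0].name == "island_A+island_B"
        assert len(merged[0]) == len(a) + len(b)

    def test_fixed_different_populations_not_merged(self):
        a = _pop("A", [H1] * 20)
        b = _pop("B", [H2] * 20)
        merged = merge_nonsignificant([a, b], [["A", "B"]], n_permutations=999, seed=0)
        assert [p.name for p in merged] == ["A", "B"]

    def test_empty_candidate_list_is_identity(self):
        a = _pop("A", [H1])
        b = _pop("B", [H2])
        assert merge_nonsignificant([a, b], [], seed=0) == [a, b]


class TestSlatkin:
    @pytest.mark.parametrize("fst,expected", [(0.0, 0.0), (0.5, 1.0), (0.2, 0.25)])
    def test_linearization(self, fst, expected):
        assert slatkin_linearize(fst) == pytest.approx(expected)

    def test_negative_estimates_floored_at_zero(self):
        assert slatkin_linearize(-0.03) == 0.0

    def test_fst_one_errors(self):
        with pytest.raises(PopgenError):
            slatkin_linearize(1.0)


class TestMds:
    def test_planted_configuration_recovered(self, rng):
        X = rng.normal(size=(6, 2))
        X -= X.mean(axis=0)
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        res = mds(D, k=2)
        assert res.s_stress < 1e-8
        # Procrustes: optimal rotation via SVD
        Y = res.coordinates
        U, _, Vt = np.linalg.svd(Y.T @ X)
        R = U @ Vt
        rmse = np.sqrt(((Y @ R - X) ** 2).mean())
        assert rmse < 1e-6

    def test_zero_distances_give_coincident_points(self):
        res = mds(np.zeros((4, 4)), k=2)
        assert np.allclose(res.coordinates, 0.0)
        assert res.s_stress == 0.0

    def test_two_points_one_dimension_separated_by_distance(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = mds(D, k=1)
        assert abs(res.coordinates[0, 0] - res.coordinates[1, 0]) == pytest.approx(3.0)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0)

    def test_full_rank_embedding_achieves_tiny_stress(self, rng):
        X = rng.normal(size=(5, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        res = mds(D, k=4)
        assert res.s_stress < 1e-6

    def test_k_too_large_errors(self):
        with pytest.raises(PopgenError):
            mds(np.zeros((3, 3)), k=3)


class TestFstMatrix:
    def test_matrices_symmetric_and_linearized_consistent(self):
        pops = [_pop("A", [H1] * 4), _pop("B", [H2] * 4), _pop("C", [H1, H1, H2, H2])]
        dm = fst_matrix(pops, n_permutations=99, seed=0)
        f = dm.fst.to_numpy()
        assert np.allclose(f, f.T) and np.allclose(np.diag(f), 0)
        lin = dm.linearized.to_numpy()
        capped = np.clip(f, 0, 1 - 1e-12)
        assert np.allclose(lin, capped / (1 - capped))


CLASSIFIER = {
    "L2": ["16223T", "16278T"],
    "L2a": ["16223T", "16278T", "16294T"],
    "L0": ["16129A", "16148T"],
}


def _motif(*keys):
    out = []
    for k in keys:
        pos, base = int(k[:-1]), k[-1]
        ref = "A" if base != "A" else "C"
        out.append(Variant(pos, ref, base, "substitution"))
    return out


class TestHaplogroupComposition:
    def test_single_label_population_has_frequency_one(self):
        pop = _pop("A", [_motif("16223T", "16278T", "16294T")] * 4)
        table = haplogroup_composition([pop], CLASSIFIER)
        assert table.loc["A", "L2a"] == 1.0

    def test_l2_without_subclade_motif_falls_back_to_l2_star(self):
        hap = _hap("x", _motif("16223T", "16278T"))
        assert classify_lineage(hap, CLASSIFIER) == "L2*"

    def test_planted_mixture_recovered_and_rows_sum_to_one(self):
        members = [_motif("16223T", "16278T", "16294T")] * 3 + [
            _motif("16129A", "16148T")
        ] * 7
        table = haplogroup_composition([_pop("A", members)], CLASSIFIER)
        assert table.loc["A", "L2a"] == pytest.approx(0.3)
        assert table.loc["A", "L0"] == pytest.approx(0.7)
        assert table.sum(axis=1).to_numpy() == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_top_level_match_errors(self):
        hap = _hap("x", _motif("16223T", "16278T", "16129A", "16148T"))
        with pytest.raises(PopgenError):
            classify_lineage(hap, CLASSIFIER)

    def test_unmatched_lineage_counted_as_other(self):
        table = haplogroup_composition([_pop("A", [[sub(16100)]])], CLASSIFIER)
        assert table.loc["A", "other"] == 1.0
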