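import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvwatch import selection as sel
from cnvwatch import simulate as sim


def brute_force_ehh(H, positions, rows, region, direction):
    """All-pairs prefix comparison oracle for EHH."""
    left, right = region
    if direction == "left":
        order = [i for i in range(len(positions)) if positions[i] < left][::-1]
        dists = [left - positions[i] for i in order]
    else:
        order = [i for i in range(len(positions)) if positions[i] > right]
        dists = [positions[i] - right for i in order]
    pairs = list(itertools.combinations(rows, 2))
    out = [(0.0, 1.0)]
    for k in range(1, len(order) + 1):
        cols = order[:k]
        same = sum(1 for a, b in pairs if np.array_equal(H[a, cols], H[b, cols]))
        out.append((float(dists[k - 1]), same / len(pairs)))
    return out


def brute_force_shared(H, positions, a, b, region):
    """Per-pair shared length oracle: distance to last concordant variant."""
    left, right = region
    total = 0.0
    for direction in ("left", "right"):
        if direction == "left":
            order = [i for i in range(len(positions)) if positions[i] < left][::-1]
            dists = [left - positions[i] for i in order]
        else:
            order = [i for i in range(len(positions)) if positions[i] > right]
            dists = [positions[i] - right for i in order]
        length = 0.0
        for i, d in zip(order, dists):
            if H[a, i] != H[b, i]:
                break
            length = d
        total += length
    return total


def random_hap(seed, n=30, m=50, span=100_000):
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(span, m, replace=False))
    H = rng.integers(0, 2, (n, m)).astype(np.uint8)
    return sel.HaplotypeMatrix(haplotypes=H, positions=positions)


REGION = (45_000, 55_000)


class TestEHH:
    def test_identical_carriers_give_unit_ehh(self):
        H = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.uint8), (4, 1))
        hap = sel.HaplotypeMatrix(H, np.array([10, 20, 60, 70, 80]),
                                  core=np.array(["A"] * 4, dtype=object))
        curves = sel.compute_ehh(hap, "A", (30, 50))
        assert np.all(curves["left"].ehh == 1.0)
        assert np.all(curves["right"].ehh == 1.0)

    def test_hand_enumerable_case(self):
        # 4 haplotypes, 5 right-side SNPs at known distances
        H = np.array([[0, 0, 0, 0, 0],
                      [0, 0, 1, 0, 0],
                      [0, 0, 0, 1, 1],
                      [0, 0, 0, 1, 0]], dtype=np.uint8)
        pos = np.array([60, 70, 80, 90, 100])
        hap = sel.HaplotypeMatrix(H, pos, core=np.array(["A"] * 4, dtype=object))
        curve = sel.compute_ehh(hap, "A", (0, 50))["right"]
        # 6 pairs; SNPs 1-2: all identical -> 1; SNP3 isolates h1 -> 3/6
        # ({0,2,3}); SNP4 splits {0} | {2,3} -> 1/6; SNP5 splits {2},{3} -> 0
        np.testing.assert_allclose(curve.distances, [0, 10, 20, 30, 40, 50])
        np.testing.assert_allclose(curve.ehh, [1, 1, 1, 3 / 6, 1 / 6, 0])

    def test_matches_brute_force_on_random_matrices(self):
        for seed in range(8):
            hap = random_hap(seed)
            hap.core = np.array(["A"] * 10 + ["WT"] * 20, dtype=object)
            for direction in ("left", "right"):
                curve = sel.compute_ehh(hap, "A", REGION)[direction]
                expected = brute_force_ehh(hap.haplotypes, hap.positions,
                                           list(range(10)), REGION, direction)
                got = list(zip(curve.distances, curve.ehh))
                assert len(got) == len(expected)
                for (d1, e1), (d2, e2) in zip(got, expected):
                    assert d1 == d2 and e1 == pytest.approx(e2)

    def test_region_variants_are_masked(self):
        H = np.zeros((3, 3), dtype=np.uint8)
        H[0, 1] = 1  # inside-region variant differs; must be ignored
        hap = sel.HaplotypeMatrix(H, np.array([10, 50, 90]),
                                  core=np.array(["A"] * 3, dtype=object))
        curves = sel.compute_ehh(hap, "A", (40, 60))
        assert np.all(curves["left"].ehh == 1.0)
        assert np.all(curves["right"].ehh == 1.0)

    def test_requires_two_carriers(self):
        hap = random_hap(1)
        hap.core = np.array(["A"] + ["WT"] * 29, dtype=object)
        with pytest.raises(ValueError):
            sel.compute_ehh(hap, "A", REGION)


class TestSharedLengths:
    def test_identical_pair_spans_full_surveyed_length(self):
        H = np.zeros((2, 6), dtype=np.uint8)
        pos = np.array([1000, 2000, 4000, 6000, 8000, 9000])
        hap = sel.HaplotypeMatrix(H, pos, core=np.array(["A", "A"], dtype=object))
        d = sel.shared_haplotype_lengths(hap, "A", (4500, 5500), n_boot=10)
        # left: 4500-1000; right: 9000-5500
        assert d.lengths[0] == (4500 - 1000) + (9000 - 5500)

    def test_first_variant_discordant_gives_zero(self):
        H = np.zeros((2, 4), dtype=np.uint8)
        H[1, 1] = 1  # nearest left variant
        H[1, 2] = 1  # nearest right variant
        pos = np.array([1000, 4000, 6000, 9000])
        hap = sel.HaplotypeMatrix(H, pos, core=np.array(["A", "A"], dtype=object))
        d = sel.shared_haplotype_lengths(hap, "A", (4500, 5500), n_boot=10)
        assert d.lengths[0] == 0.0

    def test_matches_brute_force_oracle(self):
        hap = random_hap(3, n=20)
        hap.core = np.array(["A"] * 20, dtype=object)
        d = sel.shared_haplotype_lengths(hap, "A", REGION, n_boot=10)
        expected = [brute_force_shared(hap.haplotypes, hap.positions, a, b, REGION)
                    for a, b in itertools.combinations(range(20), 2)]
        np.testing.assert_allclose(np.sort(d.lengths), np.sort(expected))

    def test_ci_contains_median(self):
        hap = random_hap(4, n=15)
        hap.core = np.array(["A"] * 15, dtype=object)
        d = sel.shared_haplotype_lengths(hap, "A", REGION, n_boot=300, seed=1)
        assert d.ci_low <= d.median <= d.ci_high


class TestClustering:
    def test_two_clean_groups(self):
        a = np.zeros(50, dtype=np.uint8)
        b = a.copy()
        b[:5] = 1  # 10% divergent
        H = np.vstack([np.tile(a, (6, 1)), np.tile(b, (4, 1))])
        hap = sel.HaplotypeMatrix(H, np.arange(50) * 100 + 1)
        labels = sel.cluster_haplotypes(hap, n_variants=50, cutoff=0.001)
        assert len(np.unique(labels)) == 2
        assert (labels[:6] == 1).all()  # largest cluster labelled 1
        assert (labels[6:] == 2).all()

    def test_all_identical_single_cluster(self):
        H = np.ones((5, 30), dtype=np.uint8)
        hap = sel.HaplotypeMatrix(H, np.arange(30) + 1)
        assert (sel.cluster_haplotypes(hap, n_variants=30) == 1).all()

    def test_distance_matrix_matches_accessible_hamming_oracle(self):
        rng = np.random.default_rng(5)
        H = rng.integers(0, 2, (12, 40)).astype(np.uint8)
        accessible = rng.random(40) < 0.7
        hap = sel.HaplotypeMatrix(H, np.arange(40) * 10 + 1, accessible=accessible)
        from scipy.spatial.distance import pdist
        got = pdist(H[:, accessible[:40]], metric="hamming")
        cols = np.flatnonzero(accessible)
        expected = [np.mean(H[a, cols] != H[b, cols])
                    for a, b in itertools.combinations(range(12), 2)]
        np.testing.assert_allclose(got, expected)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 2, (3, 60)).astype(np.uint8)
        H = np.vstack([np.tile(base[0], (5, 1)), np.tile(base[1], (3, 1)),
                       np.tile(base[2], (2, 1))])
        hap = sel.HaplotypeMatrix(H, np.arange(60) * 7 + 1)
        labels = sel.cluster_haplotypes(hap, n_variants=60)
        perm = rng.permutation(10)
        hap2 = sel.HaplotypeMatrix(H[perm], np.arange(60) * 7 + 1)
        labels2 = sel.cluster_haplotypes(hap2, n_variants=60)
        # same partition up to the permutation
        for i in range(10):
            for j in range(10):
                assert (labels[perm[i]] == labels[perm[j]]) == \
                    (labels2[i] == labels2[j])


class TestAssociation:
    def test_perfect_triplication_linkage(self):
        # copy number = 2 x cluster count: rho = 1, slope 0.5 cluster/copy
        counts = {f"f{i}": c for i, c in enumerate([0, 0, 1, 1, 2, 2, 1, 0])}
        copies = {s: 2 * c for s, c in counts.items()}
        sexes = {s: "F" for s in counts}
        rep = sel.associate_cluster_with_cnv(counts, copies, sexes)
        assert rep.female_rho == pytest.approx(1.0)
        assert rep.female_slope == pytest.approx(0.5)

    def test_male_fisher_equals_hypergeometric_closed_form(self):
        counts = {f"m{i}": (1 if i < 10 else 0) for i in range(20)}
        copies = {f"m{i}": (1 if i < 10 else 0) for i in range(20)}
        sexes = {s: "M" for s in counts}
        rep = sel.associate_cluster_with_cnv(counts, copies, sexes)
        # table ((10,0),(0,10)): two-sided p = 2 / C(20,10)
        p_exact = 2 * stats.hypergeom.pmf(10, 20, 10, 10)
        assert rep.male_p == pytest.approx(p_exact)

    def test_null_calibration_of_female_correlation(self):
        rng = np.random.default_rng(7)
        reps, rejections = 600, 0
        for _ in range(reps):
            counts = {f"f{i}": int(c) for i, c in enumerate(rng.integers(0, 3, 50))}
            copies = {f"f{i}": int(c) for i, c in enumerate(rng.integers(0, 3, 50))}
            sexes = {s: "F" for s in counts}
            rep = sel.associate_cluster_with_cnv(counts, copies, sexes)
            rejections += rep.female_p < 0.05
        assert 0.02 < rejections / reps < 0.09


class TestParameterRecovery:
    def test_sweep_frequency_recovered_by_largest_cluster(self):
        hap, carriers = sim.simulate_swept_haplotypes(
            200, 1500, 0.3, core_identity_length=None, mutation_rate=0.0002,
            seed=11)
        # cluster on the SNPs immediately left of the CNV region
        left = np.flatnonzero(hap.positions < 485_000)[-1000:]
        sub = sel.HaplotypeMatrix(hap.haplotypes[:, left],
                                  hap.positions[left])
        labels = sel.cluster_haplotypes(sub, n_variants=1000, cutoff=0.001)
        freq = (labels == 1).mean()
        assert abs(freq - 0.3) <= 0.05
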