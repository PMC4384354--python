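"""Fragment-pair RMSD, greedy clustering, library construction, coverage."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import annotated_dimer, own_pairs
from ifplib.fixtures import make_planted_pair_dataset
from ifplib.fragments import InterfaceFragmentPair
from ifplib.library import (Cluster, build_library, coverage, cutoff_scan,
                            greedy_cluster, pair_rmsd, pair_rmsd_matrix,
                            read_library, select_representative,
                            stability_runs, write_library)


def random_pair(rng, gap=8.0):
    a = np.cumsum(rng.normal(0, 1, (9, 3)) + [3.0, 0, 0], axis=0)
    b = np.cumsum(rng.normal(0, 1, (9, 3)) + [3.0, 0, 0], axis=0)
    b = b + [0, gap, 0]
    return InterfaceFragmentPair("rnd", 4, 4, a, b, "H", "H")


def brute_force_joint_rmsd(p, q):
    """Independent oracle: quaternion superposition of the 18-point joint
    blocks, minimum over the two block pairings."""
    best = np.inf
    P = np.vstack([p.coords_a, p.coords_b])
    for blocks in ((q.coords_a, q.coords_b), (q.coords_b, q.coords_a)):
        Q = np.vstack(blocks)
        pc, qc = P.mean(axis=0), Q.mean(axis=0)
        rot, _ = Rotation.align_vectors(Q - qc, P - pc)
        moved = rot.apply(P - pc)
        best = min(best, float(np.sqrt(((moved - (Q - qc)) ** 2)
                                       .sum(axis=1).mean())))
    return best


def test_pair_rmsd_identity_and_block_swap():
    rng = np.random.default_rng(0)
    p = random_pair(rng)
    assert pair_rmsd(p, p) == pytest.approx(0.0, abs=1e-6)
    swapped = InterfaceFragmentPair("s", p.center_j, p.center_i,
                                    p.coords_b, p.coords_a, p.ss_b, p.ss_a)
    assert pair_rmsd(p, swapped) == pytest.approx(0.0, abs=1e-6)


def test_pair_rmsd_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        p = random_pair(rng)
        q = InterfaceFragmentPair("q", 4, 4,
                                  p.coords_a + rng.normal(0, 0.3, (9, 3)),
                                  p.coords_b + rng.normal(0, 0.3, (9, 3)),
                                  "H", "H")
        assert pair_rmsd(p, q) == pytest.approx(brute_force_joint_rmsd(p, q),
                                                abs=1e-9)


def test_pair_rmsd_symmetric_nonnegative():
    rng = np.random.default_rng(2)
    p, q = random_pair(rng), random_pair(rng)
    assert pair_rmsd(p, q) >= 0.0
    assert pair_rmsd(p, q) == pytest.approx(pair_rmsd(q, p), abs=1e-9)


def test_rmsd_matrix_consistent_with_pairwise_calls():
    rng = np.random.default_rng(3)
    pairs = [random_pair(rng) for _ in range(8)]
    dm = pair_rmsd_matrix(pairs)
    assert dm.shape == (8, 8)
    assert np.allclose(dm, dm.T, atol=1e-12)
    assert np.allclose(np.diag(dm), 0.0)
    for i in (0, 3):
        for j in (5, 7):
            assert dm[i, j] == pytest.approx(pair_rmsd(pairs[i], pairs[j]),
                                             abs=1e-9)


def test_all_far_pairs_become_singletons(planted_300):
    pairs, _ = make_planted_pair_dataset(K=6, members_per=1, noise_sigma=0.0,
                                         seed=2)
    clusters = greedy_cluster(pairs, cutoff=4.0, order_seed=0)
    assert len(clusters) == 6
    assert all(c.size == 1 for c in clusters)


def test_all_close_pairs_one_cluster():
    rng = np.random.default_rng(4)
    base = random_pair(rng)
    pairs = [InterfaceFragmentPair("c", 4, 4,
                                   base.coords_a + rng.normal(0, 0.1, (9, 3)),
                                   base.coords_b + rng.normal(0, 0.1, (9, 3)),
                                   "H", "H") for _ in range(20)]
    clusters = greedy_cluster(pairs, cutoff=4.0, order_seed=1)
    assert len(clusters) == 1 and clusters[0].size == 20


def test_planted_clusters_recovered_for_any_seed(planted_300):
    pairs, labels = planted_300
    dmat = pair_rmsd_matrix(pairs)
    for seed in range(5):
        clusters = greedy_cluster(pairs, cutoff=4.0, order_seed=seed,
                                  dmat=dmat)
        assert len(clusters) == 10
        for c in clusters:
            assert len({labels[m] for m in c.member_ids}) == 1


def test_partition_property(planted_300):
    pairs, _ = planted_300
    clusters = greedy_cluster(pairs, cutoff=4.0, order_seed=3)
    seen = sorted(m for c in clusters for m in c.member_ids)
    assert seen == list(range(len(pairs)))
    assert sum(c.size for c in clusters) == len(pairs)


def test_representative_of_chain_cluster_is_middle():
    """In a 3-member chain A-B-C where only B is within the cutoff of
    both ends, B has the most neighbors and is the representative."""
    dmat = np.array([[0.0, 3.0, 6.0],
                     [3.0, 0.0, 3.0],
                     [6.0, 3.0, 0.0]])
    assert select_representative([0, 1, 2], dmat, cutoff=4.0) == 1


def test_representative_tie_breaks_to_lowest_id():
    dmat = np.full((3, 3), 2.0) - 2.0 * np.eye(3)
    assert select_representative([0, 1, 2], dmat, cutoff=4.0) == 0
    assert select_representative([2, 1], dmat, cutoff=4.0) == 1


def test_singleton_representative_is_sole_member():
    assert select_representative([7], np.zeros((8, 8)), 4.0) == 7


def test_min_members_is_strict():
    """Cluster sizes 25, 21, 20, 5 with the >20 rule keep exactly two."""
    rng = np.random.default_rng(5)
    pairs = []
    clusters = []
    for size in (25, 21, 20, 5):
        base = random_pair(rng)
        start = len(pairs)
        pairs.extend(InterfaceFragmentPair("m", 4, 4, base.coords_a,
                                           base.coords_b, "H", "H")
                     for _ in range(size))
        clusters.append(Cluster(list(range(start, start + size)), start))
    lib = build_library(clusters, pairs, min_members=20)
    assert len(lib) == 2
    assert [e.member_count for e in lib.entries] == [25, 21]
    with pytest.warns(UserWarning):
        assert len(build_library(clusters, pairs, min_members=30)) == 0
    assert len(build_library(clusters, pairs, min_members=0)) == 4


def test_abundant_clusters_cover_planted_majority():
    big, _ = make_planted_pair_dataset(K=9, members_per=30, noise_sigma=0.3,
                                       seed=5)
    single, _ = make_planted_pair_dataset(K=30, members_per=1,
                                          noise_sigma=0.0, seed=6,
                                          min_separation=4.5, avoid=big,
                                          avoid_separation=6.0)
    allp = big + single
    lib = build_library(greedy_cluster(allp, 4.0, 0), allp, min_members=20)
    frac, min_rmsd = coverage(allp, lib, cutoff=4.0)
    assert frac >= 0.9
    assert len(min_rmsd) == len(allp)


def test_coverage_trivial_cases(planted_300):
    pairs, _ = planted_300
    lib = build_library(greedy_cluster(pairs, 4.0, 0), pairs, min_members=20)
    frac_self, _ = coverage([e.pair for e in lib.entries], lib, 4.0)
    assert frac_self == 1.0
    far, _ = make_planted_pair_dataset(K=3, members_per=1, noise_sigma=0.0,
                                       seed=9, min_separation=4.5,
                                       avoid=[e.pair for e in lib.entries],
                                       avoid_separation=6.0)
    frac_far, _ = coverage(far, lib, 4.0)
    assert frac_far == 0.0
    with pytest.raises(ValueError):
        coverage([], lib, 4.0)


def test_coverage_monotone_in_cutoff(planted_300):
    pairs, _ = planted_300
    lib = build_library(greedy_cluster(pairs, 4.0, 0), pairs, min_members=20)
    fracs = [coverage(pairs, lib, c)[0] for c in (0.5, 2.0, 4.0, 10.0)]
    assert fracs == sorted(fracs)


def test_cutoff_scan_counts(planted_300):
    pairs, _ = planted_300
    table = cutoff_scan(pairs, [0.1, 4.0, 100.0], order_seed=0)
    assert [n for _, n in table] == [300, 10, 1]
    counts = [n for _, n in table]
    assert counts == sorted(counts, reverse=True)
    with pytest.raises(ValueError):
        cutoff_scan(pairs, [4.0], order_seed=0)


def test_stability_runs_on_separated_data(planted_300):
    pairs, _ = planted_300
    runs = stability_runs(pairs, cutoff=4.0, n_runs=5,
                          seeds=[0, 1, 2, 3, 4], min_members=20)
    assert len(runs) == 5
    assert len({r["n_clusters"] for r in runs}) == 1
    assert len({tuple(r["ranked_sizes"]) for r in runs}) == 1
    assert all(r["n_abundant"] == 10 for r in runs)


def test_stability_runs_argument_errors(planted_300):
    pairs, _ = planted_300
    with pytest.raises(ValueError):
        stability_runs(pairs, 4.0, n_runs=5, seeds=[0, 1])
    with pytest.raises(ValueError):
        stability_runs(pairs, 4.0, n_runs=1)


def test_identical_copies_always_one_cluster():
    rng = np.random.default_rng(6)
    base = random_pair(rng)
    pairs = [InterfaceFragmentPair("c", 4, 4, base.coords_a, base.coords_b,
                                   "L", "L") for _ in range(12)]
    for r in stability_runs(pairs, 4.0, n_runs=3, seeds=[5, 6, 7]):
        assert r["n_clusters"] == 1


def test_library_json_roundtrip_and_determinism(tmp_path):
    dom_i, dom_j, _ = annotated_dimer("SS-antiparallel", seed=0)
    pairs = own_pairs(dom_i, dom_j)
    lib = build_library(greedy_cluster(pairs, 4.0, 0), pairs, min_members=0,
                        params={"cutoff_A": 4.0, "min_members": 0, "seed": 0})
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_library(lib, p1)
    write_library(lib, p2)
    assert p1.read_bytes() == p2.read_bytes()
    back = read_library(p1)
    assert len(back) == len(lib)
    for a, b in zip(lib.entries, back.entries):
        assert (a.entry_id, a.motif, a.member_count) == \
            (b.entry_id, b.motif, b.member_count)
        assert np.allclose(a.pair.coords_a, b.pair.coords_a, atol=1e-5)
    assert back.params["cutoff_A"] == 4.0


def test_entries_sorted_by_descending_count(planted_300):
    pairs, _ = planted_300
    lib = build_library(greedy_cluster(pairs, 4.0, 0), pairs, min_members=0)
    counts = [e.member_count for e in lib.entries]
    assert counts == sorted(counts, reverse=True)
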