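"""Window enumeration, matching, placement, clash filtering, evaluation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import annotated_dimer, own_pairs, random_rigid_transform
from ifplib.assembly import (ComplexModel, assemble, clash_filter,
                             complex_rmsd, enumerate_window_pairs,
                             evaluate_ensemble, match_and_build, model_ca,
                             surface_mask, write_ensemble_pdb)
from ifplib.config import RunConfig
from ifplib.fixtures import backbone_to_domain, ideal_helix, \
    make_planted_pair_dataset
from ifplib.geometry import RigidTransform, apply_transform
from ifplib.library import FragmentPairLibrary, LibraryEntry, build_library, \
    greedy_cluster


def helix_domain_of(n):
    return backbone_to_domain(ideal_helix(n), dom_id=f"h{n}")


def own_library(dom_i, dom_j):
    pairs = own_pairs(dom_i, dom_j)
    return build_library(greedy_cluster(pairs, 4.0, 0), pairs, min_members=0)


# ---------------------------------------------------------------------------
# enumeration and surface

def test_window_pair_count_follows_formula():
    combos = list(enumerate_window_pairs(helix_domain_of(50),
                                         helix_domain_of(40)))
    assert len(combos) == 42 * 32 == 1344
    assert len(set(combos)) == 1344


def test_minimal_domains_give_single_combination():
    assert len(list(enumerate_window_pairs(helix_domain_of(9),
                                           helix_domain_of(9)))) == 1


def test_domain_shorter_than_window_errors():
    with pytest.raises(ValueError):
        list(enumerate_window_pairs(helix_domain_of(8), helix_domain_of(9)))


def test_surface_mask_boundary_is_strict():
    dom = helix_domain_of(9)
    dom.sasa = np.array([10.1, 9.9, 10.0, 50.0, 0.0, 11.0, 10.1, 9.9, 20.0])
    mask = surface_mask(dom, threshold=10.0)
    assert mask.tolist() == [True, False, False, True, False, True, True,
                             False, True]


def test_isolated_peptide_fully_on_surface():
    dom = helix_domain_of(9)
    assert surface_mask(dom).all()


# ---------------------------------------------------------------------------
# matching and placement

def test_identity_entry_recovers_native_pose(hh_dimer):
    dom_i, dom_j, native = hh_dimer
    pairs = own_pairs(dom_i, dom_j)
    p = pairs[0]
    entry = LibraryEntry(0, p, 1, "HH")
    models = match_and_build(dom_i, dom_j, p.center_i - 4, p.center_j - 4,
                             entry, align_cutoff=2.0)
    assert models
    m = models[0]
    assert m.orientation == 1
    assert m.rmsd_a == pytest.approx(0.0, abs=1e-6)
    assert m.rmsd_b == pytest.approx(0.0, abs=1e-6)
    assert complex_rmsd(model_ca(m, dom_i, dom_j), native) < 1e-6


def test_distant_entry_yields_nothing(hh_dimer):
    dom_i, dom_j, _ = hh_dimer
    far, _ = make_planted_pair_dataset(K=1, members_per=1, noise_sigma=0.0,
                                       seed=30, min_separation=0.0,
                                       avoid=own_pairs(dom_i, dom_j),
                                       avoid_separation=8.0)
    entry = LibraryEntry(0, far[0], 1, "??")
    out = match_and_build(dom_i, dom_j, 4, 4, entry, align_cutoff=2.0)
    assert out == []


def test_symmetric_entry_emits_both_orientations(hh_dimer):
    dom_i, dom_j, _ = hh_dimer
    p = own_pairs(dom_i, dom_j)[0]
    from ifplib.fragments import InterfaceFragmentPair
    sym = InterfaceFragmentPair("sym", p.center_i, p.center_j,
                                p.coords_a, p.coords_a + [0.0, 0.0, 40.0],
                                "H", "H")
    entry = LibraryEntry(0, sym, 1, "HH")
    models = match_and_build(dom_i, dom_i, p.center_i - 4, p.center_i - 4,
                             entry, align_cutoff=2.0)
    assert {m.orientation for m in models} == {1, 2}


def test_alignment_cutoff_boundary():
    """An entry calibrated to sit at 1.99 A from the window matches; the
    same entry scaled to 2.01 A does not."""
    from ifplib.fragments import InterfaceFragmentPair
    from ifplib.geometry import kabsch_fit

    dom = helix_domain_of(17)
    w = dom.ca_coords()[4:13]
    rng = np.random.default_rng(0)
    direction = rng.normal(size=(9, 3))

    def block_at(target):
        lo, hi = 0.0, 3.0
        for _ in range(60):
            mid = (lo + hi) / 2
            r = kabsch_fit(w, w + mid * direction)[1]
            if r < target:
                lo = mid
            else:
                hi = mid
        return w + ((lo + hi) / 2) * direction

    for target, expected in ((1.99, True), (2.01, False)):
        blk = block_at(target)
        entry = LibraryEntry(0, InterfaceFragmentPair(
            "b", 8, 8, blk, w + [0.0, 50.0, 0.0], "H", "H"), 1, "HH")
        models = match_and_build(dom, dom, 4, 4, entry, align_cutoff=2.0)
        assert bool(models) is expected, target
        assert all(max(m.rmsd_a, m.rmsd_b) < 2.0 for m in models)


# ---------------------------------------------------------------------------
# clash filter

def place_apart(dx):
    dom_i = helix_domain_of(12)
    dom_j = helix_domain_of(12)
    ca_i = dom_i.ca_coords()
    ca_j = dom_j.ca_coords()
    # translation along x by (current gap + dx) puts min CA-CA at dx
    t = RigidTransform(np.eye(3), np.zeros(3))
    best = np.inf
    # solve offset so the minimum inter-domain CA distance equals dx
    lo, hi = 0.0, 60.0
    for _ in range(80):
        mid = (lo + hi) / 2
        d = np.sqrt(((ca_i[:, None] - (ca_j + [mid, 0, 0])[None, :]) ** 2)
                    .sum(-1)).min()
        if d < dx:
            lo = mid
        else:
            hi = mid
    off = (lo + hi) / 2
    model = ComplexModel(t, RigidTransform(np.eye(3), np.array([off, 0, 0])),
                         0, 0, 0, 1, 0.0, 0.0)
    return model, dom_i, dom_j


@pytest.mark.parametrize("gap,expected", [(3.4, True), (3.6, False),
                                          (50.0, False), (0.05, True)])
def test_clash_boundary(gap, expected):
    model, dom_i, dom_j = place_apart(gap)
    assert clash_filter(model, dom_i, dom_j, ca_cutoff=3.5) is expected


def test_heavy_atom_clash_mode():
    model, dom_i, dom_j = place_apart(0.5)
    assert clash_filter(model, dom_i, dom_j, mode="heavy")
    far, dom_i, dom_j = place_apart(50.0)
    assert not clash_filter(far, dom_i, dom_j, mode="heavy")


# ---------------------------------------------------------------------------
# complex RMSD

def test_complex_rmsd_native_and_rigid_copy(hh_dimer):
    _, _, native = hh_dimer
    assert complex_rmsd(native, native) == pytest.approx(0.0, abs=1e-6)
    rng = np.random.default_rng(1)
    moved = apply_transform(random_rigid_transform(rng), native)
    assert complex_rmsd(moved, native) == pytest.approx(0.0, abs=1e-6)


def test_complex_rmsd_matches_quaternion_oracle(hh_dimer):
    _, _, native = hh_dimer
    rng = np.random.default_rng(2)
    model = native + rng.normal(0, 1.0, native.shape)
    pc, qc = model.mean(axis=0), native.mean(axis=0)
    rot, _ = Rotation.align_vectors(native - qc, model - pc)
    oracle = float(np.sqrt(((rot.apply(model - pc) - (native - qc)) ** 2)
                           .sum(axis=1).mean()))
    assert complex_rmsd(model, native) == pytest.approx(oracle, abs=1e-9)


def test_ligand_mode_measures_unfitted_offset(hh_dimer):
    dom_i, _, native = hh_dimer
    n_rec = len(dom_i)
    model = native.copy()
    model[n_rec:] += [0.0, 0.0, 2.5]  # translate the ligand only
    r = complex_rmsd(model, native, mode="ligand", n_receptor=n_rec)
    assert r == pytest.approx(2.5, abs=1e-9)


def test_complex_rmsd_shape_mismatch_errors(hh_dimer):
    _, _, native = hh_dimer
    with pytest.raises(ValueError):
        complex_rmsd(native[:-1], native)


# ---------------------------------------------------------------------------
# full assembly

def test_assembly_with_own_library_recovers_native(hh_dimer):
    dom_i, dom_j, native = hh_dimer
    lib = own_library(dom_i, dom_j)
    ens = assemble(dom_i, dom_j, lib, RunConfig())
    lowest, n, rmsds = evaluate_ensemble(ens, dom_i, dom_j, native)
    assert n > 0 and len(rmsds) == n
    assert lowest < 0.1
    assert all(not m.clash for m in ens.models)


def test_assembly_stage_counts_consistent(hh_dimer):
    dom_i, dom_j, _ = hh_dimer
    ens = assemble(dom_i, dom_j, own_library(dom_i, dom_j), RunConfig())
    sc = ens.stage_counts
    assert sc["window_pairs"] == (len(dom_i) - 8) * (len(dom_j) - 8)
    assert sc["models"] == len(ens.models)
    assert sc["models"] + sc["clash_eliminated"] + sc["deduplicated"] \
        == sc["aligned_candidates"]
    assert sum(ens.models_per_entry.values()) == len(ens.models)


def test_no_matching_entry_gives_valid_empty_ensemble(hh_dimer):
    dom_i, dom_j, native = hh_dimer
    far, _ = make_planted_pair_dataset(K=1, members_per=1, noise_sigma=0.0,
                                       seed=31, min_separation=0.0,
                                       avoid=own_pairs(dom_i, dom_j),
                                       avoid_separation=8.0)
    lib = FragmentPairLibrary([LibraryEntry(0, far[0], 1, "??")], {})
    ens = assemble(dom_i, dom_j, lib, RunConfig())
    assert len(ens) == 0
    assert evaluate_ensemble(ens, dom_i, dom_j, native) == \
        (None, 0, pytest.approx(np.zeros(0)))


def test_model_count_monotone_in_filters(hh_dimer):
    dom_i, dom_j, _ = hh_dimer
    lib = own_library(dom_i, dom_j)
    base = len(assemble(dom_i, dom_j, lib, RunConfig()))
    tighter_align = len(assemble(dom_i, dom_j, lib,
                                 RunConfig(align_cutoff=0.5)))
    bigger_clash = len(assemble(dom_i, dom_j, lib,
                                RunConfig(clash_cutoff=8.0)))
    higher_surface = len(assemble(dom_i, dom_j, lib,
                                  RunConfig(sasa_threshold=60.0)))
    assert tighter_align <= base
    assert bigger_clash <= base
    assert higher_surface <= base


def test_deduplication_never_increases_and_keeps_best(hh_dimer):
    dom_i, dom_j, native = hh_dimer
    lib = own_library(dom_i, dom_j)
    raw = assemble(dom_i, dom_j, lib, RunConfig())
    dedup = assemble(dom_i, dom_j, lib, RunConfig(dedup=True))
    assert 0 < len(dedup) <= len(raw)
    lo_raw, _, _ = evaluate_ensemble(raw, dom_i, dom_j, native)
    lo_dedup, _, _ = evaluate_ensemble(dedup, dom_i, dom_j, native)
    assert lo_dedup <= lo_raw + RunConfig().dedup_cutoff


def test_domain_exchange_symmetry(hh_dimer):
    """assemble(I, J) and assemble(J, I) give the same pose set up to
    global superposition."""
    dom_i, dom_j, _ = hh_dimer
    lib = own_library(dom_i, dom_j)
    fwd = assemble(dom_i, dom_j, lib, RunConfig())
    rev = assemble(dom_j, dom_i, lib, RunConfig())
    assert len(fwd) == len(rev)
    rev_cas = [np.vstack([apply_transform(m.transform_j, dom_i.ca_coords()),
                          apply_transform(m.transform_i, dom_j.ca_coords())])
               for m in rev.models]  # reorder to (I, J)
    used = set()
    for m in fwd.models:
        ca = model_ca(m, dom_i, dom_j)
        hit = next(k for k, rc in enumerate(rev_cas)
                   if k not in used and complex_rmsd(ca, rc) < 1e-6)
        used.add(hit)
    assert len(used) == len(fwd)


def test_ensemble_pdb_deterministic_and_readable(tmp_path, hh_dimer):
    import gemmi

    dom_i, dom_j, _ = hh_dimer
    lib = own_library(dom_i, dom_j)
    ens = assemble(dom_i, dom_j, lib, RunConfig(dedup=True))
    p1, p2 = tmp_path / "e1.pdb", tmp_path / "e2.pdb"
    write_ensemble_pdb(ens, dom_i, dom_j, p1)
    write_ensemble_pdb(assemble(dom_i, dom_j, lib, RunConfig(dedup=True)),
                       dom_i, dom_j, p2)
    assert p1.read_bytes() == p2.read_bytes()
    st = gemmi.read_structure(str(p1))
    assert len(st) == len(ens)
    assert "ENTRY=" in p1.read_text()
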