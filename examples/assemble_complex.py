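"""Reassemble a dimer from its monomers, guided by a fragment library.

Builds a helix-helix toy dimer, derives a library from its own interface
fragment pairs, then enumerates every (N_I-8) x (N_J-8) window pair
against every entry in both orientations, keeps candidates whose two
9-point alignments are under 2 A, places the rigid domains, and drops
clashed poses (inter-domain CA-CA < 3.5 A). Because the library contains
the dimer's own interface geometry, the native pose must reappear in the
ensemble with RMSD ~ 0 — the identity-recovery check of the method.
"""

from ifplib import (RunConfig, assemble, assign_ss3, build_library,
                    evaluate_ensemble, extract_fragment_pairs,
                    greedy_cluster, interface_residue_pairs, make_toy_dimer,
                    write_ensemble_pdb)
from ifplib.fixtures import ToyDimerSpec

dom_i, dom_j, native_ca = make_toy_dimer(ToyDimerSpec(motif="HH", seed=0))
dom_i.ss3 = assign_ss3(dom_i)
dom_j.ss3 = assign_ss3(dom_j)

pairs = extract_fragment_pairs(dom_i, dom_j,
                               interface_residue_pairs(dom_i, dom_j))
lib = build_library(greedy_cluster(pairs, 4.0, order_seed=0), pairs,
                    min_members=0)
ens = assemble(dom_i, dom_j, lib, RunConfig(dedup=True))
lowest, n_models, rmsds = evaluate_ensemble(ens, dom_i, dom_j, native_ca)

print("filter stages:", ens.stage_counts)
print(f"{n_models} candidate poses; lowest RMSD to native = {lowest:.3f} A")
print("(a value near zero means the native binding mode is inside the "
      "enumerated ensemble)")
write_ensemble_pdb(ens, dom_i, dom_j, "hh_ensemble.pdb", max_models=25)
print("first 25 poses written to hh_ensemble.pdb (REMARK lines carry "
      "entry/window provenance)")
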