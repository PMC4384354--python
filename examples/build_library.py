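"""Build a fragment pair library from a panel of synthetic dimers.

Generates toy dimers spanning all seven secondary-structure packing
motifs, extracts their interface fragment pairs (5 A side-chain contact
rule, 9-residue windows), clusters the pairs at 4 A RMSD and keeps every
cluster as a library entry (min_members=0: the panel is tiny, so the
abundance filter is switched off here).
"""

from ifplib import (RunConfig, assign_ss3, build_library,
                    extract_fragment_pairs, greedy_cluster,
                    interface_residue_pairs, make_toy_dimer, write_library)
from ifplib.fixtures import DIMER_MOTIFS, ToyDimerSpec

cfg = RunConfig()
all_pairs = []
for motif in DIMER_MOTIFS:
    dom_i, dom_j, _ = make_toy_dimer(ToyDimerSpec(motif=motif, seed=0))
    dom_i.ss3 = assign_ss3(dom_i)
    dom_j.ss3 = assign_ss3(dom_j)
    contacts = interface_residue_pairs(dom_i, dom_j, cfg.contact_cutoff)
    pairs = extract_fragment_pairs(dom_i, dom_j, contacts, cfg.window)
    print(f"{motif:16s} {len(contacts):2d} contacts -> "
          f"{len(pairs):2d} fragment pairs")
    all_pairs.extend(pairs)

clusters = greedy_cluster(all_pairs, cutoff=cfg.cluster_cutoff, order_seed=0)
lib = build_library(clusters, all_pairs, min_members=0,
                    params={"cutoff_A": cfg.cluster_cutoff,
                            "min_members": 0, "seed": 0})
write_library(lib, "toy_library.json")

print(f"\n{len(all_pairs)} pairs -> {len(clusters)} clusters "
      f"-> {len(lib)} library entries (toy_library.json)")
print("entry  motif  members   (each entry is the cluster member with the "
      "most sub-cutoff neighbors)")
for e in lib.entries[:8]:
    print(f"{e.entry_id:5d}  {e.motif:5s}  {e.member_count:7d}")
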