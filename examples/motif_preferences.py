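"""Secondary-structure motif statistics of interface fragment pairs.

Classifies fragment pairs into the six motifs (HH, SS, LL, HL, HS, SL)
by the 3-state type of their center residues and computes the preference
score ln(P(XY) / (P(X) P(Y))). The first block uses a mixed panel of toy
dimers; the second block shows the null behavior under purely random
pairing: homogeneous motifs score ~0 while heterogeneous motifs sit at
ln 2 ~ 0.69, the combinatorial offset inherent in the printed form of
the score.
"""

import math

from ifplib import motif_stats
from ifplib.fixtures import (DIMER_MOTIFS, ToyDimerSpec, make_random_type_pairs,
                             make_toy_dimer)
from ifplib.fragments import extract_fragment_pairs, interface_residue_pairs
from ifplib.motifs import MOTIFS
from ifplib.structures import assign_ss3

panel = []
for motif in DIMER_MOTIFS:
    for seed in (0, 1):
        dom_i, dom_j, _ = make_toy_dimer(ToyDimerSpec(motif=motif, seed=seed))
        dom_i.ss3 = assign_ss3(dom_i)
        dom_j.ss3 = assign_ss3(dom_j)
        panel.extend(extract_fragment_pairs(
            dom_i, dom_j, interface_residue_pairs(dom_i, dom_j)))

stats = motif_stats(panel)
print(f"{len(panel)} fragment pairs from the toy-dimer panel")
print("motif  count  P(motif)  preference")
for m in MOTIFS:
    print(f"{m:5s}  {stats.motif_counts[m]:5d}  {stats.motif_probs[m]:8.3f}"
          f"  {stats.preference[m]:+10.3f}")

null = motif_stats(make_random_type_pairs(100000, seed=0))
print("\nrandom-pairing null at N=100000 (types at interface-typical "
      "frequencies 0.432/0.286/0.282):")
for m in MOTIFS:
    print(f"{m:5s}  score {null.preference[m]:+.4f}")
print(f"heterogeneous motifs approach ln 2 = {math.log(2):.4f} under this "
      "null; homogeneous motifs approach 0")
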