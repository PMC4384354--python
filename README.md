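# ifplib — interface fragment pair libraries

`ifplib` decomposes protein–protein binding interfaces into **interface
fragment pairs**: two 9-residue backbone fragments, one from each binding
partner, whose central residues make at least one side-chain contact
(closest side-chain heavy-atom distance < 5 Å). Recorded as paired Cα
coordinate blocks, these local geometries can be clustered into a small
library of recurrent packing motifs, characterized by the secondary
structure of their centers, and used to enumerate candidate quaternary
structures of two given domains. The package is for structural
bioinformaticians studying the degeneracy of protein quaternary-structure
space and for anyone who wants a fragment-guided, enumeration-style
baseline for rigid-body complex modeling.

## The method

1. **Extraction.** For domains I and J, every residue pair (i ∈ I, j ∈ J)
   with a side-chain contact under 5 Å becomes an interface residue pair;
   a 9-residue window centered on each side turns it into a fragment pair
   (a center touching two partner residues is recorded once per partner).
2. **Clustering.** The distance between two fragment pairs is the RMSD of
   a joint Kabsch superposition over all 18 Cα atoms, minimized over the
   two block pairings. Entries are visited in random order; each joins
   the cluster of its nearest previously-visited entry if that RMSD
   < 4 Å, else founds a new cluster. The member with the most co-members
   within the cutoff represents the cluster, and clusters with more than
   `min_members` (default 20) members form the library.
3. **Motif statistics.** Each fragment is typed H/S/L by the DSSP-style
   3-state secondary structure of its center residue; a pair falls into
   one of six unordered motifs with preference score
   `ln(P(XY) / (P(X)·P(Y)))`.
4. **Assembly.** For two monomers, all `(N_I − 8) × (N_J − 8)` window
   combinations are compared against every library entry in both
   orientations. If both window centers are surface residues (monomer
   SASA > 10 Å², 1.4 Å probe) and both 9-point alignments are < 2 Å RMSD,
   the whole domains are carried into the entry frame, yielding one
   candidate pose; poses with any inter-domain Cα–Cα distance < 3.5 Å are
   discarded as clashes. The ensemble samples binding modes; no scoring
   or ranking is attempted.

A deterministic fixture generator (ideal helices, hydrogen-bonded
two-strand sheets, self-avoiding coils, toy dimers with planted
interfaces, planted clustering datasets) makes the whole pipeline testable
without downloading any structure database.

## Worked example

`python examples/assemble_complex.py` builds a helix–helix toy dimer,
derives a library from the dimer's own interface fragment pairs, and
reassembles the monomers:

```
filter stages: {'window_pairs': 81, 'surface_window_pairs': 81,
 'aligned_candidates': 162, 'clash_eliminated': 0, 'deduplicated': 90,
 'models': 72}
72 candidate poses; lowest RMSD to native = 0.000 A
```

81 window combinations (two 17-residue helices: 9 × 9) all pass the
surface filter, 162 window/entry alignments fall under 2 Å, none clash,
and near-duplicate poses collapse to 72. The lowest RMSD of 0.000 Å means
the native binding mode was recovered exactly — the identity-recovery
property that anchors the whole pipeline. The other examples print the
cutoff scan (300 → 10 → 1 clusters at 0.1/4/100 Å on planted data),
clustering stability across shuffled runs, 0.90 library coverage with 90%
of pairs planted in abundant clusters, and motif preference scores with
their random-pairing null.

Equivalent shell pipeline:

```sh
ifplib simulate --motif HH --seed 0 --out dimer.pdb
ifplib extract --pdb-i dimer.pdb --chain-i A --pdb-j dimer.pdb --chain-j B --out pairs.tsv
ifplib cluster --pairs pairs.tsv --out clusters.tsv
ifplib build-lib --pairs pairs.tsv --clusters clusters.tsv --min-members 0 --out lib.json
ifplib assemble --pdb-i dimer.pdb --chain-i A --pdb-j dimer.pdb --chain-j B \
    --library lib.json --out ensemble.pdb
ifplib evaluate --ensemble ensemble.pdb --native dimer.pdb --out eval.tsv
```

## Scope

`ifplib` targets desk-scale inputs (thousands of fragment pairs; the
clustering is an O(N²) RMSD loop). It does not rank or score poses,
predict binding sites, use sequence profiles, or handle backbone
flexibility.
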