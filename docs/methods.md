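# Methods

## Model and assumptions

The package treats a protein–protein interface as a bag of local,
pairwise backbone geometries. The unit is the interface fragment pair:
two 9-residue Cα fragments, one per partner, centered on residues whose
side chains approach within the contact cutoff. Two assumptions follow
from this representation and bound what the method can claim:

- **Locality.** Similarity between interfaces is judged purely on the
  relative geometry of 9+9 Cα atoms after optimal superposition. Global
  interface shape, side-chain packing and chemistry are not compared.
- **Rigidity.** Assembly moves whole domains by the rigid transform of a
  single 9-residue window fit. There is no refinement, no flexibility,
  and the quality of a pose degrades linearly with the lever arm between
  the matched window and the rest of the domain.

## Parameters

All tunables live in `ifplib.config.RunConfig`; defaults are the
method's published operating point.

| parameter | default | meaning |
|---|---|---|
| `contact_cutoff` | 5.0 Å | side-chain heavy-atom distance defining an interface residue pair (strict `<`) |
| `window` | 9 | fragment length; centers need 4 flanking residues on each side |
| `cluster_cutoff` | 4.0 Å | joint 18-point RMSD below which an entry joins its nearest visited neighbor |
| `min_members` | 20 | clusters must be strictly larger to enter the library |
| `align_cutoff` | 2.0 Å | both 9-point window-to-entry alignments must be strictly below it |
| `sasa_threshold` | 10.0 Å² | residues strictly above are surface; applied to window centers only |
| `probe_radius` / `sasa_points` | 1.4 Å / 960 | Shrake–Rupley probe and sphere sampling |
| `clash_cutoff` | 3.5 Å | minimum allowed inter-domain Cα–Cα distance in a pose |
| `dedup` / `dedup_cutoff` | off / 1.0 Å | optional greedy pose collapse (keep-first) |

Every boundary in the pipeline is strict, and the boundary suite pins
each one (4.9/5.1, 9.9/10.1, 1.99/2.01, 20/21, 3.4/3.6).

Side chain means Cβ and beyond. Glycine contributes its Cα as a
side-chain surrogate — skipping glycine would silently delete real
interface centers. Alanine's side chain is {Cβ}.

## Design choices where the design was open

- **Contact atoms.** Only side-chain atoms count toward the 5 Å rule;
  main-chain atoms are excluded. This is the narrowest reading of a
  side-chain contact rule; it makes loop–loop interfaces somewhat
  sparser than a any-atom rule would.
- **Block order in the pair RMSD.** The joint RMSD is minimized over the
  two ways of matching blocks (a→a/b→b vs a→b/b→a) so homodimer pairs
  and relabeled domains compare as identical. Fragment N→C direction is
  never reversed: reversing would align chains backwards.
- **Clustering variant.** Each entry is compared to every
  previously-visited *entry* (nearest neighbor), not to cluster
  representatives. The visiting order is a seeded shuffle recorded in
  the library metadata, making runs exactly reproducible.
- **Representative ties** break by lowest mean RMSD to co-members, then
  lowest member id — a total, deterministic order.
- **SASA on the monomer.** The surface filter uses the isolated monomer:
  at assembly time the partner is by definition unknown. Computed with
  biotite's Shrake–Rupley on a fixed Bondi element-radius table
  (C 1.70, N 1.55, O 1.52, S 1.80 …, fallback 1.70 Å) rather than
  residue-template radii, so non-standard fixtures are handled uniformly.
- **Clash definition.** A pose clashes when any inter-domain Cα–Cα
  distance is under 3.5 Å — Cα-level for consistency with the Cα-only
  library; an optional heavy-atom mode (< 2.5 Å) is stricter.
- **RMSD to native.** Default is one optimal superposition over all Cα
  atoms of both domains ("complex" mode). A receptor-fit/ligand-measure
  mode is available (`mode="ligand"`), since conventions differ between
  docking evaluations.
- **Deduplication** defaults to off: raw enumeration over overlapping
  windows of regular elements produces many near-identical poses, but
  collapsing them is a presentation choice, not part of the method.

## Secondary structure

The internal assigner implements the Kabsch–Sander hydrogen-bond
electrostatic energy (27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN), bond
if < −0.5 kcal/mol, amide H placed 1 Å from N along the previous C=O
direction) with 4-turn α-helices, 3-turn 3₁₀ helices and parallel/
antiparallel bridge patterns; 8-state codes map H,G,I→H; E,B→S; rest→L.
Exact parity with a full DSSP implementation is not promised — π-helices,
bends and some edge ladder logic are omitted; the fixture tests use
geometries where the assignment is unambiguous and cross-check against an
independent DSSP implementation. For bit-compatible labels, an external
DSSP output file can be supplied and takes precedence.

## The synthetic-data generators

The fixtures emulate idealized versions of the geometries the method is
about: helices built from canonical (φ, ψ) = (−57°, −47°) internal
coordinates; extended strands at (−135°, 135°); two-strand sheets whose
partner-strand offset is solved per strand length by maximizing the
Kabsch–Sander inter-strand bond ladder (so sheet residues genuinely
label S); self-avoiding polyproline-II-like coils for loops; toy dimers
that pack two such elements at a motif-specific angle, with the
separation solved so the closest side-chain gap lands at 4.2 Å while the
native pose stays clear of the clash threshold; and planted clustering
datasets of K seed fragment-pair geometries (mutually > 8 Å apart by
rejection) replicated with iid Gaussian noise. The random-pairing motif
null samples fragment types at interface-typical frequencies
(H 0.432, S 0.286, L 0.282).

What the fixtures do **not** emulate: real side chains (a pseudo-Cβ at
ideal tetrahedral geometry stands in), crystallographic disorder,
numbering gaps and altlocs beyond what the parser tests construct,
irregular secondary structure, or interfaces whose contact is mediated
by main-chain atoms. Passing tests therefore demonstrate correctness of
the pipeline's geometry, counting and filtering logic under clean
conditions — not performance on experimental structures, where fragment
diversity, disorder and contact chemistry are all harsher.

Problem sizes used by the test suite and the acceptance script — 300-pair
planted datasets, a 20-dimer assembly panel of 17–19-residue domains, a
10⁵-record motif null — were chosen as the smallest sizes at which the
studied properties are unambiguous (cluster separation ≫ noise, every
motif class represented, simulation error ≪ the tested tolerance).

## Numerical notes

- Superposition is Kabsch via SVD in double precision, with the sign of
  the smallest singular value corrected so det(R) = +1 always: mirror
  solutions are never produced, even for degenerate (collinear) inputs.
  RMSD uses the singular-value identity with clipping at zero, so
  reported zeros can carry ~1e−7 Å of square-root round-off.
- All-vs-all distance matrices batch the 3×3 SVDs (`numpy.linalg.svd`
  on stacked covariance matrices); the O(N²) loop is accepted as the
  method targets desk-scale N.
- Windows require 9 consecutive residues with finite Cα and every
  consecutive Cα–Cα distance < 4.5 Å (chain-break guard) and consecutive
  author numbering; fixture sheets rely on this guard to reject windows
  spanning the inter-strand register gap.
- Altloc resolution: highest occupancy, ties to altloc 'A', then
  alphabetical. Hydrogens, waters and non-amino-acid residues are always
  dropped; only the first model of multi-model files is read.
- The ensemble writer emits fixed-width ATOM records at PDB precision
  (3 decimals) by direct formatting, making identical runs byte-identical.

## The heterogeneous-motif null

The preference score is implemented exactly in its printed form,
`ln(P(XY)/(P(X)P(Y)))`, including for heterogeneous motifs. Because the
six motif probabilities are unordered frequencies that sum to 1, an
unordered heterogeneous motif XY occurs under independent random pairing
with probability 2·P(X)·P(Y); its score therefore converges to ln 2 ≈
0.693 rather than 0, while homogeneous motifs converge to 0. This
combinatorial offset is a property of the printed formula and is
deliberately documented rather than corrected; comparisons *between*
heterogeneous motifs (or between homogeneous ones) are unaffected, but
comparing a heterogeneous score against a homogeneous one carries the
ln 2 bias.

## Known limitations

- No pose scoring or ranking: the native-like model is in the ensemble
  but not identified.
- Bound-backbone assumption: monomers are used as-is.
- The greedy clustering is order-dependent in principle; stability runs
  quantify this rather than eliminate it (a hierarchical variant would
  be the next step).
- The internal secondary-structure assigner is a subset of full DSSP
  (see above).
- Performance: clustering is quadratic in the number of pairs; tens of
  thousands of pairs are practical, millions are not.
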