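"""Protein domain structures: parsing, secondary structure, surface area.

A :class:`DomainStructure` is one protein domain — an ordered list of
residues with heavy-atom coordinates — decorated with a C-alpha trace,
3-state secondary structure (H = helix, S = strand, L = loop/other) and
per-residue solvent-accessible surface area. Everything downstream
(fragment extraction, library construction, assembly) consumes this type.

Readers accept PDB and mmCIF via gemmi; hydrogens are always dropped and
alternate locations are resolved to the highest-occupancy conformer.
Secondary structure comes either from an internal Kabsch–Sander
hydrogen-bond assigner or from an external DSSP output file, which takes
precedence when supplied. SASA is Shrake–Rupley on the isolated monomer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import VDW_DEFAULT, VDW_RADII

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Residue", "DomainStructure",
    "read_domain", "write_pdb", "assign_ss3", "compute_sasa",
    "read_dssp_ss3",
]

#: 8-state DSSP code -> 3-state class
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "S", "B": "S",
    "T": "L", "S": "L", "P": "L", "-": "L", " ": "L", "C": "L",
}

# Kabsch-Sander hydrogen-bond energy: E = 27.888 * (1/rON + 1/rCH - 1/rOH - 1/rCN)
_KS_Q = 27.888          # 0.084 e^2 * 332 kcal*A/mol
_KS_CUTOFF = -0.5       # kcal/mol
_PEPTIDE_BOND_MAX = 2.5  # A; C(i)-N(i+1) beyond this is a chain break


@dataclass
class Atom:
    """A heavy atom: PDB atom label, element symbol, coordinates in A."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")
        self.coords = c
        self.element = self.element.upper()


@dataclass
class Residue:
    """One residue: author numbering retained for reporting, internal
    ``index`` is the 0-based sequential position within the domain."""

    chain_id: str
    author_number: int
    icode: str
    name: str
    atoms: list[Atom]
    index: int = -1

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def side_chain_atoms(self) -> list[Atom]:
        """Side-chain heavy atoms under the contact rule: CB and beyond.

        Glycine has no CB; its CA serves as the side-chain surrogate so
        glycine interface centers are not silently lost.
        """
        side = [a for a in self.atoms
                if a.name not in ("N", "CA", "C", "O", "OXT")]
        if not side:
            ca = self.ca
            return [ca] if ca is not None else []
        return side


@dataclass
class DomainStructure:
    """An ordered protein domain with optional SS and SASA annotations."""

    id: str
    residues: list[Residue]
    ss3: list[str] | None = None
    sasa: np.ndarray | None = None

    def __post_init__(self) -> None:
        for i, r in enumerate(self.residues):
            r.index = i
        if self.ss3 is not None and len(self.ss3) != len(self.residues):
            raise ValueError("ss3 length != residue count")
        if self.sasa is not None and len(self.sasa) != len(self.residues):
            raise ValueError("sasa length != residue count")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) C-alpha coordinates; rows are NaN where CA is missing."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca
            if ca is not None:
                out[i] = ca.coords
        return out

    def backbone(self) -> dict[str, np.ndarray]:
        """(n, 3) arrays for N, CA, C, O with NaN for missing atoms."""
        out = {k: np.full((len(self.residues), 3), np.nan)
               for k in ("N", "CA", "C", "O")}
        for i, r in enumerate(self.residues):
            for k in out:
                a = r.atom(k)
                if a is not None:
                    out[k][i] = a.coords
        return out

    def all_coords(self) -> np.ndarray:
        return np.array([a.coords for r in self.residues for a in r.atoms])

    def transformed(self, transform) -> "DomainStructure":
        """A deep copy with every atom moved by a RigidTransform."""
        from .geometry import apply_transform
        new_res = []
        for r in self.residues:
            atoms = [Atom(a.name, a.element,
                          apply_transform(transform, a.coords[None])[0])
                     for a in r.atoms]
            new_res.append(Residue(r.chain_id, r.author_number, r.icode,
                                   r.name, atoms, r.index))
        return DomainStructure(self.id, new_res,
                               list(self.ss3) if self.ss3 is not None else None,
                               None if self.sasa is None else self.sasa.copy())


# ---------------------------------------------------------------------------
# reading / writing

def _resolve_altlocs(raw_atoms: list[tuple[str, str, str, float, np.ndarray]]
                     ) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    altloc 'A' first then alphabetically."""
    by_name: dict[str, list[tuple[str, str, str, float, np.ndarray]]] = {}
    for rec in raw_atoms:
        by_name.setdefault(rec[0], []).append(rec)
    out = []
    for name, recs in by_name.items():
        def rank(rec):
            altloc = rec[2]
            return (-rec[3], altloc != "A", altloc)
        best = sorted(recs, key=rank)[0]
        out.append(Atom(best[0], best[1], best[4]))
    return out


def read_domain(path: str | Path, chain: str,
                res_range: tuple[int, int] | None = None) -> DomainStructure:
    """Read one chain (optionally an author-numbered residue span) from a
    PDB or mmCIF file.

    Heavy atoms only: hydrogens and deuteriums are dropped, waters and
    ligands skipped, the highest-occupancy altloc kept, and only the first
    model of multi-model files is used.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ValueError(f"{path}: chain {chain!r} not found")
    residues: list[Residue] = []
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and (info.is_water() or not info.is_amino_acid()):
            continue
        num = res.seqid.num
        icode = (res.seqid.icode or "").strip()
        if res_range is not None and not (res_range[0] <= num <= res_range[1]):
            continue
        raw = []
        for atom in res:
            el = atom.element.name.upper()
            if el in ("H", "D"):
                continue
            raw.append((atom.name, el, (atom.altloc or "").strip(),
                        float(atom.occ),
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
        if not raw:
            continue
        residues.append(Residue(chain, num, icode, res.name,
                                _resolve_altlocs(raw)))
    if not residues:
        raise ValueError(f"{path}: chain {chain!r} has no residues"
                         + (f" in range {res_range}" if res_range else ""))
    residues.sort(key=lambda r: (r.author_number, r.icode))
    rng = f"_{res_range[0]}-{res_range[1]}" if res_range else ""
    dom_id = f"{Path(path).stem}_{chain}{rng}"
    return DomainStructure(dom_id, residues)


def write_pdb(domains: DomainStructure | list[DomainStructure],
              path: str | Path) -> None:
    """Write one or more domains (one chain each) to a PDB file."""
    import gemmi

    if isinstance(domains, DomainStructure):
        domains = [domains]
    st = gemmi.Structure()
    st.name = "ifplib"
    model = gemmi.Model(1)
    for dom in domains:
        chain = gemmi.Chain(dom.residues[0].chain_id if dom.residues else "A")
        for r in dom.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.author_number, r.icode or " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# secondary structure

def _ks_hbond_matrix(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Boolean (n, n) matrix: entry [i, j] is True when the C=O of residue
    i accepts a hydrogen bond from the N-H of residue j, by the
    Kabsch-Sander electrostatic criterion (E < -0.5 kcal/mol)."""
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]
    n = len(N)
    # amide H: on N, one unit along the previous C=O direction
    H = np.full((n, 3), np.nan)
    prev_co = C[:-1] - O[:-1]
    norm = np.linalg.norm(prev_co, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        H[1:] = N[1:] + prev_co / norm
    # chain-break guard: no donor H right after a break
    pept = np.linalg.norm(N[1:] - C[:-1], axis=1)
    H[1:][~(pept < _PEPTIDE_BOND_MAX)] = np.nan

    def dist(A, B):
        return np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        # acceptor i (C=O), donor j (N-H)
        e = _KS_Q * (1.0 / dist(O, N) + 1.0 / dist(C, H)
                     - 1.0 / dist(O, H) - 1.0 / dist(C, N))
    bonded = np.where(np.isfinite(e), e < _KS_CUTOFF, False)
    # exclude self and sequence neighbors
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    bonded[near] = False
    return bonded


def _ks_assign(bb: dict[str, np.ndarray]) -> list[str]:
    """3-state Kabsch-Sander assignment: 4-turn helices -> H, 3-turn
    (3_10) helices -> H (via G), beta bridges/ladders -> S, else L."""
    hb = _ks_hbond_matrix(bb)
    n = hb.shape[0]
    ss = np.array(["L"] * n, dtype="U1")

    def turn(k):
        t = np.zeros(n, dtype=bool)
        if n > k:
            t[: n - k] = hb[np.arange(n - k), np.arange(k, n)]
        return t

    t3, t4 = turn(3), turn(4)
    # bridges: parallel / antiparallel, Kabsch-Sander patterns
    is_bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        js = np.arange(1, n - 1)
        js = js[np.abs(js - i) >= 3]
        if js.size == 0:
            continue
        par = (hb[i - 1, js] & hb[js, i + 1]) | (hb[js - 1, i] & hb[i, js + 1])
        anti = (hb[i, js] & hb[js, i]) | (hb[i - 1, js + 1] & hb[js - 1, i + 1])
        if np.any(par | anti):
            is_bridge[i] = True
    ss[is_bridge] = "S"
    # 3_10 helix: two consecutive 3-turns
    for i in range(n - 1):
        if t3[i] and t3[i + 1]:
            ss[i + 1: i + 4] = "H"
    # alpha helix: two consecutive 4-turns (takes precedence)
    for i in range(n - 1):
        if t4[i] and t4[i + 1]:
            ss[i + 1: i + 5] = "H"
    return list(ss)


def read_dssp_ss3(path: str | Path, chain: str) -> dict[tuple[int, str], str]:
    """Parse a classic DSSP output file into a map
    (author_number, icode) -> 3-state label, for one chain."""
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, _ = make_dssp_dict(str(path))
    out: dict[tuple[int, str], str] = {}
    for (ch, res_id), values in dssp_dict.items():
        if ch != chain:
            continue
        _, num, icode = res_id
        out[(num, icode.strip())] = SS8_TO_SS3.get(values[1], "L")
    if not out:
        raise ValueError(f"{path}: DSSP file has no residues for chain {chain!r}")
    return out


def assign_ss3(domain: DomainStructure,
               external: str | Path | None = None) -> list[str]:
    """Per-residue 3-state secondary structure for a domain.

    With ``external`` given, labels are read from that DSSP output file
    (8-state codes mapped H,G,I->H; E,B->S; rest->L) and take precedence.
    Otherwise the internal Kabsch-Sander hydrogen-bond assigner runs on
    the backbone N/CA/C/O geometry. Residues with incomplete backbones are
    labeled L.
    """
    if external is not None:
        chain_ids = {r.chain_id for r in domain.residues}
        if len(chain_ids) != 1:
            raise ValueError("domain spans multiple chain ids")
        mapping = read_dssp_ss3(external, chain_ids.pop())
        labels = []
        missing = []
        for r in domain.residues:
            key = (r.author_number, r.icode)
            if key not in mapping:
                missing.append(key)
                labels.append("L")
            else:
                labels.append(mapping[key])
        if len(missing) == len(domain.residues):
            raise ValueError("external DSSP file covers none of the domain")
        if missing:
            logger.warning("DSSP file missing %d residues; labeled L",
                           len(missing))
        return labels
    return _ks_assign(domain.backbone())


# ---------------------------------------------------------------------------
# solvent accessible surface area

def compute_sasa(domain: DomainStructure, probe: float = 1.4,
                 n_points: int = 960,
                 radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-residue Shrake-Rupley SASA (A^2) of the isolated domain.

    The numerical rollout is delegated to biotite's Shrake-Rupley
    implementation; atom radii come from the package's Bondi table so the
    radius set is fixed and documented rather than residue-template based.
    """
    import biotite.structure as struc

    table = radii if radii is not None else VDW_RADII
    atoms = [(i, a) for i, r in enumerate(domain.residues) for a in r.atoms]
    n_res = len(domain.residues)
    if not atoms:
        warnings.warn("domain has no atoms; SASA all zero")
        return np.zeros(n_res)
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for _, a in atoms], dtype=np.float32)
    arr.chain_id = np.array(["A"] * len(atoms))
    arr.res_id = np.array([i + 1 for i, _ in atoms])
    arr.res_name = np.array([domain.residues[i].name for i, _ in atoms])
    arr.atom_name = np.array([a.name for _, a in atoms])
    arr.element = np.array([a.element for _, a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    per_atom_radii = np.array([table.get(a.element, VDW_DEFAULT)
                               for _, a in atoms])
    per_atom = struc.sasa(arr, probe_radius=probe, point_number=n_points,
                          vdw_radii=per_atom_radii)
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    out = np.zeros(n_res)
    for (i, _), area in zip(atoms, per_atom):
        out[i] += area
    empties = [i for i in range(n_res) if not domain.residues[i].atoms]
    if empties:
        warnings.warn(f"{len(empties)} residues without atoms: SASA 0")
    return out
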