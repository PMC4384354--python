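"""Interface residue pairs and 9-residue interface fragment pairs.

Two residues across a domain-domain interface form an interface residue
pair when any of their side-chain heavy atoms (CB and beyond; CA as the
glycine surrogate) come closer than the contact cutoff, 5 A by default.
Around each such pair, one window of 9 residues per side — centered on
the contacting residues — gives an interface fragment pair, recorded as
the two 9-point CA coordinate blocks. A center contacting two partner
residues is recorded once per partner (so interactions are deliberately
recorded multiple times, once per contacting center combination).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structures import DomainStructure

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceResiduePair", "InterfaceFragmentPair",
    "interface_residue_pairs", "extract_fragment_pairs",
    "write_pair_table", "read_pair_table",
]

#: consecutive CA-CA beyond this is treated as a chain break
CHAIN_BREAK_CA = 4.5


@dataclass(frozen=True)
class InterfaceResiduePair:
    """Residue i of domain I and residue j of domain J in side-chain
    contact; ``min_dist`` is the closest side-chain heavy-atom distance."""

    i: int
    j: int
    min_dist: float


@dataclass
class InterfaceFragmentPair:
    """Two 9-residue CA fragments, one per binding partner.

    ``coords_a``/``coords_b`` are (window, 3) CA blocks; ``center_i`` and
    ``center_j`` are the residue indices of the contacting centers in
    their source domains; ``ss_a``/``ss_b`` the 3-state secondary
    structure of those center residues (None when unassigned).
    """

    source: str
    center_i: int
    center_j: int
    coords_a: np.ndarray
    coords_b: np.ndarray
    ss_a: str | None = None
    ss_b: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.coords_a, dtype=float)
        b = np.asarray(self.coords_b, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("coordinate blocks must both be (window, 3)")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("fragment coordinates must be finite")
        self.coords_a = a
        self.coords_b = b

    @property
    def window(self) -> int:
        return self.coords_a.shape[0]

    def joint(self, swapped: bool = False) -> np.ndarray:
        """The concatenated (2*window, 3) coordinate block, optionally
        with the a/b blocks exchanged."""
        if swapped:
            return np.vstack([self.coords_b, self.coords_a])
        return np.vstack([self.coords_a, self.coords_b])

    def is_continuous(self, max_gap: float = CHAIN_BREAK_CA) -> bool:
        """True when both blocks look like unbroken chain (every
        consecutive CA-CA distance below ``max_gap``)."""
        for block in (self.coords_a, self.coords_b):
            steps = np.linalg.norm(np.diff(block, axis=0), axis=1)
            if np.any(steps >= max_gap):
                return False
        return True


def _side_chain_catalog(dom: DomainStructure
                        ) -> tuple[np.ndarray, np.ndarray]:
    """All side-chain heavy atoms of a domain as a coordinate array plus
    the residue index of each atom."""
    coords, owner = [], []
    for r in dom.residues:
        for a in r.side_chain_atoms():
            coords.append(a.coords)
            owner.append(r.index)
    if not coords:
        return np.zeros((0, 3)), np.zeros(0, dtype=int)
    return np.asarray(coords), np.asarray(owner, dtype=int)


def interface_residue_pairs(I: DomainStructure, J: DomainStructure,
                            cutoff: float = 5.0) -> list[InterfaceResiduePair]:
    """All residue pairs (i from I, j from J) whose closest side-chain
    heavy-atom distance is strictly below ``cutoff`` (A).

    Side chain means CB and beyond; glycine contributes its CA as a
    surrogate. Pairs are sorted by (i, j).
    """
    ca_i, own_i = _side_chain_catalog(I)
    ca_j, own_j = _side_chain_catalog(J)
    if len(ca_i) == 0 or len(ca_j) == 0:
        warnings.warn("empty side-chain atom set; no interface pairs")
        return []
    tree_i = cKDTree(ca_i)
    tree_j = cKDTree(ca_j)
    sparse = tree_i.sparse_distance_matrix(tree_j, cutoff, output_type="coo_matrix")
    best: dict[tuple[int, int], float] = {}
    for ai, aj, d in zip(sparse.row, sparse.col, sparse.data):
        if d >= cutoff:  # strict inequality at the boundary
            continue
        key = (int(own_i[ai]), int(own_j[aj]))
        if d < best.get(key, np.inf):
            best[key] = float(d)
    return [InterfaceResiduePair(i, j, d)
            for (i, j), d in sorted(best.items())]


def _window_block(dom: DomainStructure, ca: np.ndarray, center: int,
                  half: int) -> np.ndarray | None:
    """The (window, 3) CA block centered at ``center``; None when the
    window runs off a terminus, hits a missing CA, a numbering gap, or a
    chain break."""
    lo, hi = center - half, center + half
    if lo < 0 or hi >= len(dom.residues):
        return None
    for k in range(lo, hi):
        if dom.residues[k + 1].author_number - dom.residues[k].author_number > 1:
            return None  # numbering gap
    block = ca[lo:hi + 1]
    if not np.all(np.isfinite(block)):
        return None
    steps = np.linalg.norm(np.diff(block, axis=0), axis=1)
    if np.any(steps >= CHAIN_BREAK_CA):
        return None
    return block.copy()


def extract_fragment_pairs(I: DomainStructure, J: DomainStructure,
                           pairs: list[InterfaceResiduePair],
                           window: int = 9,
                           return_skips: bool = False):
    """One interface fragment pair per interface residue pair.

    Each record takes the ``window`` CA coordinates centered on the two
    contacting residues. A center contacting several partner residues
    yields one record per partner (deliberate multiple recording). Pairs
    whose window would cross a terminus, a missing CA, or a chain break
    (consecutive CA-CA >= 4.5 A) are skipped and logged.

    With ``return_skips`` the list of skipped residue pairs is returned
    alongside, so callers can verify record + skip counts add up.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    half = (window - 1) // 2
    ca_i = I.ca_coords()
    ca_j = J.ca_coords()
    records: list[InterfaceFragmentPair] = []
    skips: list[InterfaceResiduePair] = []
    for p in pairs:
        block_a = _window_block(I, ca_i, p.i, half)
        block_b = _window_block(J, ca_j, p.j, half)
        if block_a is None or block_b is None:
            skips.append(p)
            continue
        ss_a = I.ss3[p.i] if I.ss3 is not None else None
        ss_b = J.ss3[p.j] if J.ss3 is not None else None
        records.append(InterfaceFragmentPair(
            source=f"{I.id}|{J.id}", center_i=p.i, center_j=p.j,
            coords_a=block_a, coords_b=block_b, ss_a=ss_a, ss_b=ss_b))
    if skips:
        logger.info("extract_fragment_pairs: %d records, %d skipped "
                    "(incomplete windows)", len(records), len(skips))
    if return_skips:
        return records, skips
    return records


# ---------------------------------------------------------------------------
# fragment-pair tables: TSV with provenance columns + JSON coordinates

_COLUMNS = ["id", "source", "center_i", "center_j", "ss_a", "ss_b",
            "coords_a", "coords_b"]


def write_pair_table(pairs: list[InterfaceFragmentPair],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for k, p in enumerate(pairs):
            row = [str(k), p.source, str(p.center_i), str(p.center_j),
                   p.ss_a or ".", p.ss_b or ".",
                   json.dumps(np.round(p.coords_a, 6).tolist()),
                   json.dumps(np.round(p.coords_b, 6).tolist())]
            fh.write("\t".join(row) + "\n")


def read_pair_table(path: str | Path) -> list[InterfaceFragmentPair]:
    out: list[InterfaceFragmentPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected pair-table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(InterfaceFragmentPair(
                source=f[1], center_i=int(f[2]), center_j=int(f[3]),
                coords_a=np.array(json.loads(f[6])),
                coords_b=np.array(json.loads(f[7])),
                ss_a=None if f[4] == "." else f[4],
                ss_b=None if f[5] == "." else f[5]))
    return out
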