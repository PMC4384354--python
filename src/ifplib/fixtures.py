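"""Deterministic synthetic structures for testing and simulation.

Everything here is a pure function of its arguments and seed: ideal
helices and strands built from canonical backbone internal coordinates,
self-avoiding random coils, two-stranded beta sheets with proper
hydrogen-bond registry, toy dimers with planted interface geometries, and
planted fragment-pair datasets with known cluster labels.

These generators let interface detection, fragment extraction, clustering,
library construction and complex assembly all be exercised without any
structure download. They emulate idealized secondary-structure packing —
not side-chain rotamers, crystallographic disorder, or relaxed physical
geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structures import Atom, DomainStructure, Residue

__all__ = [
    "ToyDimerSpec", "ideal_helix", "ideal_strand", "random_loop",
    "ideal_sheet", "backbone_to_domain", "make_toy_dimer",
    "make_planted_pair_dataset", "DIMER_MOTIFS",
]

# canonical backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# dihedral pairs for the ideal elements
_HELIX_PHI_PSI = (-57.0, -47.0)
_STRAND_PHI_PSI = (-135.0, 135.0)

#: toy dimer motif vocabulary
DIMER_MOTIFS = ("HH", "SS-parallel", "SS-antiparallel", "LL", "HL", "HS", "SL")

# inter-strand x offsets (A) of the two-strand sheets; the z register
# offset depends on strand length and is solved per length by maximizing
# the Kabsch-Sander inter-strand hydrogen-bond ladder
_SHEET_ANTI_DX = 4.85
_SHEET_PAR_DX = 4.2
_SHEET_PAR_SPIN = 90.0  # pleat alignment of the translated parallel partner


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Next atom D from the chain A-B-C with bond length r = |C-D|, angle
    theta = B-C-D and dihedral phi = A-B-C-D (natural extension reference
    frame construction)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = (-r * math.cos(theta)) * bc \
        + (r * math.sin(theta) * math.cos(phi)) * m \
        + (r * math.sin(theta) * math.sin(phi)) * n
    return c + d


def _pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N, CA, C (L-configuration)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _build_backbone(phi_psi: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O/CB coordinates from a per-residue (phi, psi) list
    with trans peptide bonds."""
    n_res = len(phi_psi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # first residue in a canonical local frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi_psi[i][0])
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        psi = phi_psi[i][1]
        O[i] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi - 180.0)
    CB = np.array([_pseudo_cb(N[i], CA[i], C[i]) for i in range(n_res)])
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _principal_axis_frame(bb: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Re-express a backbone with its CA centroid at the origin and its CA
    principal axis along +z (sign fixed so the chain runs N->C in +z)."""
    ca = bb["CA"]
    center = ca.mean(axis=0)
    u, _, _ = np.linalg.svd((ca - center).T @ (ca - center))
    z = u[:, 0]
    if np.dot(ca[-1] - ca[0], z) < 0:
        z = -z
    # complete a right-handed frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, z)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - np.dot(ref, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # world -> frame
    return {k: (v - center) @ R.T for k, v in bb.items()}


def ideal_helix(n: int) -> dict[str, np.ndarray]:
    """Canonical alpha helix (phi -57, psi -47): about 1.5 A rise and 100
    degrees of twist per residue, consecutive CA-CA near 3.8 A. Axis along
    +z, centroid at origin. Includes a pseudo-CB on every residue."""
    if n < 4:
        raise ValueError("helix needs n >= 4")
    return _principal_axis_frame(_build_backbone([_HELIX_PHI_PSI] * n))


def ideal_strand(n: int) -> dict[str, np.ndarray]:
    """Extended beta geometry (phi -135, psi +135), axis along +z."""
    if n < 3:
        raise ValueError("strand needs n >= 3")
    return _principal_axis_frame(_build_backbone([_STRAND_PHI_PSI] * n))


def random_loop(n: int, seed: int, max_tries: int = 200) -> dict[str, np.ndarray]:
    """Self-avoiding random coil. Dihedrals are drawn from a broad
    polyproline-II-like band (phi -75 +/- 35, psi +145 +/- 35) that forms
    no helical or sheet hydrogen bonds; conformers with any non-adjacent
    CA-CA distance below 4 A are rejected and redrawn."""
    if n < 3:
        raise ValueError("loop needs n >= 3")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pp = [(-75.0 + rng.uniform(-35, 35), 145.0 + rng.uniform(-35, 35))
              for _ in range(n)]
        bb = _build_backbone(pp)
        ca = bb["CA"]
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        iu = np.triu_indices(n, k=2)
        if np.all(d[iu] > 4.0):
            return _principal_axis_frame(bb)
    raise RuntimeError("could not generate a self-avoiding loop")


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _transform_bb(bb: dict[str, np.ndarray], R: np.ndarray,
                  t: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v @ R.T + np.asarray(t, float) for k, v in bb.items()}


@lru_cache(maxsize=None)
def _sheet_register_dz(n_per_strand: int, parallel: bool) -> float:
    """z offset of the partner strand that maximizes the inter-strand
    hydrogen-bond ladder (deterministic grid solve, cached per length)."""
    from .structures import assign_ss3

    s1 = _principal_axis_frame(_build_backbone([_STRAND_PHI_PSI] * n_per_strand))
    if parallel:
        R, dx = _rot("z", _SHEET_PAR_SPIN), _SHEET_PAR_DX
    else:
        R, dx = _rot("x", 180.0), _SHEET_ANTI_DX
    best = (-1, 0.0)
    for dz in np.arange(-2.5, 2.51, 0.1):
        s2 = _transform_bb(s1, R, np.array([dx, 0.0, float(dz)]))
        bb = {k: np.vstack([s1[k], s2[k]]) for k in s1}
        labels = assign_ss3(backbone_to_domain(bb))
        score = labels.count("S")
        if score > best[0]:
            best = (score, float(dz))
    return best[1]


def ideal_sheet(n_per_strand: int, parallel: bool = False
                ) -> tuple[dict[str, np.ndarray], int]:
    """Two-stranded beta sheet as one chain with a register gap.

    Strand one lies along +z; strand two is a rigid copy at the
    calibrated inter-strand offset — rotated 180 degrees about x for the
    antiparallel sheet (chain direction reversed), or spun about z and
    translated for the parallel one. The z register offset is solved per
    strand length so the Kabsch-Sander hydrogen-bond ladder forms.
    Returns the concatenated backbone dict and the index at which strand
    two starts. The two strands are sequence-discontinuous (no connecting
    turn); windows spanning the gap are rejected by the chain-break guard
    downstream.
    """
    s1 = _principal_axis_frame(_build_backbone([_STRAND_PHI_PSI] * n_per_strand))
    dz = _sheet_register_dz(n_per_strand, parallel)
    if parallel:
        R, dx = _rot("z", _SHEET_PAR_SPIN), _SHEET_PAR_DX
    else:
        R, dx = _rot("x", 180.0), _SHEET_ANTI_DX
    s2 = _transform_bb(s1, R, np.array([dx, 0.0, dz]))
    bb = {k: np.vstack([s1[k], s2[k]]) for k in s1}
    return bb, n_per_strand


def backbone_to_domain(bb: dict[str, np.ndarray], chain_id: str = "A",
                       dom_id: str = "fixture", start_number: int = 1,
                       res_name: str = "ALA",
                       noise_sigma: float = 0.0,
                       rng: np.random.Generator | None = None
                       ) -> DomainStructure:
    """Wrap a backbone dict into a DomainStructure of ALA residues (the
    pseudo-CB is the single side-chain atom). Optional iid Gaussian noise
    (A) on every atom."""
    n = bb["CA"].shape[0]
    noisy = {k: v.copy() for k, v in bb.items()}
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        for k in noisy:
            noisy[k] = noisy[k] + rng.normal(0.0, noise_sigma, noisy[k].shape)
    residues = []
    atom_names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
    for i in range(n):
        atoms = [Atom(name, el, noisy[name][i]) for name, el in atom_names
                 if name in noisy]
        residues.append(Residue(chain_id, start_number + i, "", res_name, atoms))
    return DomainStructure(dom_id, residues)


def helix_bundle(n_ring: int = 6, radius: float = 8.0,
                 length: int = 15) -> DomainStructure:
    """A central helix surrounded by a ring of parallel helices — the
    central residues are solvent-inaccessible, giving a fixture with a
    genuinely buried core for surface-filter tests."""
    bbs = [ideal_helix(length)]
    for k in range(n_ring):
        ang = math.radians(360.0 * k / n_ring)
        off = np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        bbs.append(_transform_bb(ideal_helix(length), np.eye(3), off))
    residues = []
    num = 1
    for bb in bbs:
        dom = backbone_to_domain(bb, start_number=num)
        residues.extend(dom.residues)
        num += len(dom.residues) + 10  # numbering gap between helices
    return DomainStructure("bundle", [
        Residue(r.chain_id, r.author_number, r.icode, r.name, r.atoms)
        for r in residues])


# ---------------------------------------------------------------------------
# toy dimers

@dataclass(frozen=True)
class ToyDimerSpec:
    """Recipe for a synthetic two-domain complex with a planted interface.

    ``motif`` picks the secondary-structure class of each domain's
    interface element (sheet motifs additionally fix the relative strand
    direction). ``lengths`` is the residue count of the interface element
    per domain; strand domains get a second, equally long support strand
    so the interface strand has genuine sheet hydrogen bonds and is
    labeled S by the assigner. ``separation`` is the distance (A) between
    element axes along x, ``angle_deg`` the rotation of domain J's element
    about the packing (x) axis, ``noise_sigma`` the iid Gaussian
    coordinate noise (A) on all atoms. Every random choice is fixed by
    ``seed``.
    """

    motif: str = "HH"
    lengths: tuple[int, int] = (17, 17)
    separation: float | None = None
    angle_deg: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in DIMER_MOTIFS:
            raise ValueError(f"motif must be one of {DIMER_MOTIFS}")
        if any(n < 9 for n in self.lengths):
            raise ValueError("domain element lengths must be >= 9")
        if self.separation is not None and self.separation <= 0:
            raise ValueError("separation must be positive")


# default packing angle (deg, rotation of element J about the packing
# axis) per motif; the separation is solved per spec so the closest
# side-chain gap lands at _CONTACT_TARGET
_PACKING_ANGLE: dict[str, float] = {
    "HH": 160.0,
    "SS-parallel": 0.0,
    "SS-antiparallel": 180.0,
    "LL": 90.0,
    "HL": 90.0,
    "HS": 20.0,
    "SL": 90.0,
}
_CONTACT_TARGET = 4.2   # A; aimed-for closest side-chain gap
_NATIVE_CA_MIN = 3.6    # A; native pose must clear the clash threshold


def _element_letters(motif: str) -> tuple[str, str]:
    if motif.startswith("SS"):
        return "S", "S"
    return motif[0], motif[1]


def _build_element(letter: str, n: int, seed: int
                   ) -> tuple[dict[str, np.ndarray], int, int]:
    """Build one domain's backbone; returns (backbone, interface element
    start index, interface element length)."""
    if letter == "H":
        return ideal_helix(n), 0, n
    if letter == "L":
        return random_loop(n, seed), 0, n
    bb, start2 = ideal_sheet(n, parallel=False)
    # strand 2 (at larger x) is the interface strand, facing the partner
    return bb, start2, n


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a[:, None] - b[None, :]) ** 2).sum(-1).min()))


def _solve_separation(bb_i: dict[str, np.ndarray],
                      bb_j: dict[str, np.ndarray]) -> float:
    """Distance along +x at which the closest CB-CB gap between the two
    oriented elements reaches the contact target, nudged outward until
    the native CA trace clears the clash threshold."""
    sep = 30.0
    for _ in range(80):
        off = np.array([sep, 0.0, 0.0])
        gap = _min_dist(bb_i["CB"], bb_j["CB"] + off)
        if abs(gap - _CONTACT_TARGET) < 0.02:
            break
        sep -= 0.8 * (gap - _CONTACT_TARGET)
    while _min_dist(bb_i["CA"], bb_j["CA"] + np.array([sep, 0, 0])) < _NATIVE_CA_MIN:
        sep += 0.1
    return sep


def make_toy_dimer(spec: ToyDimerSpec
                   ) -> tuple[DomainStructure, DomainStructure, np.ndarray]:
    """Build a two-domain complex with the planted interface geometry.

    Returns domains I and J in their native (bound) placement plus the
    native CA trace of the whole complex, ``(N_I + N_J, 3)``. Domain I's
    interface element faces +x; domain J sits ``separation`` A away along
    x with its element rotated by ``angle_deg`` about x. Raises if the
    spec produces no side-chain contact under the 5 A rule or if the
    native pose itself would be flagged as a clash.
    """
    from .fragments import interface_residue_pairs

    la, lb = _element_letters(spec.motif)
    ang = _PACKING_ANGLE[spec.motif] if spec.angle_deg is None else spec.angle_deg
    rng = np.random.default_rng(spec.seed)

    bb_i, _, _ = _build_element(la, spec.lengths[0], spec.seed * 2 + 1)
    bb_j, _, _ = _build_element(lb, spec.lengths[1], spec.seed * 2 + 2)

    # sheets are re-centered so the interface strand faces the partner
    shift = np.array([_SHEET_ANTI_DX / 2.0, 0.0, 0.0])
    if la == "S":
        bb_i = _transform_bb(bb_i, np.eye(3), -shift)
    if lb == "S":
        bb_j = _transform_bb(bb_j, np.eye(3), -shift)

    # domain J: rotate about its own z so its interface face points -x,
    # then rotate by the packing angle about x; the separation along x is
    # either given or solved so the closest side-chain gap lands at the
    # contact target without a native CA clash
    Rj = _rot("x", ang) @ _rot("z", 180.0)
    bb_j = _transform_bb(bb_j, Rj, np.zeros(3))
    sep = spec.separation
    if sep is None:
        sep = _solve_separation(bb_i, bb_j)
    bb_j = _transform_bb(bb_j, np.eye(3), np.array([sep, 0.0, 0.0]))

    dom_i = backbone_to_domain(bb_i, "A", f"toy_{spec.motif}_I_s{spec.seed}",
                               noise_sigma=spec.noise_sigma, rng=rng)
    dom_j = backbone_to_domain(bb_j, "B", f"toy_{spec.motif}_J_s{spec.seed}",
                               noise_sigma=spec.noise_sigma, rng=rng)

    pairs = interface_residue_pairs(dom_i, dom_j, cutoff=5.0)
    if not pairs:
        raise ValueError(f"spec {spec} yields no interface contact")
    ca_i, ca_j = dom_i.ca_coords(), dom_j.ca_coords()
    dmin = np.linalg.norm(ca_i[:, None] - ca_j[None, :], axis=-1).min()
    if dmin < 3.5:
        raise ValueError(f"spec {spec} places native CA atoms at clash "
                         f"distance ({dmin:.2f} A)")
    native = np.vstack([ca_i, ca_j])
    return dom_i, dom_j, native


# ---------------------------------------------------------------------------
# planted fragment-pair datasets

def _random_fragment_block(rng: np.random.Generator, n: int = 9,
                           step: float = 3.8,
                           bend: float | None = None) -> np.ndarray:
    """A smooth random CA fragment: fixed bond length, bounded turns.

    ``bend`` controls the turn magnitude per step (drawn in [0.1, 1.0]
    when None); low values give near-straight fragments, high values
    tight curls, which spreads planted geometries far apart in RMSD.
    """
    if bend is None:
        bend = rng.uniform(0.1, 1.0)
    pts = [np.zeros(3)]
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for _ in range(n - 1):
        pts.append(pts[-1] + step * d)
        t = rng.normal(size=3)
        t /= np.linalg.norm(t)
        d = d + bend * t
        d /= np.linalg.norm(d)
    return np.array(pts)


_CENTER_TYPES = [("H", "H"), ("S", "S"), ("L", "L"),
                 ("H", "L"), ("H", "S"), ("S", "L")]

#: fragment-type frequencies typical of domain interfaces (H, S, L)
DEFAULT_TYPE_FREQS = {"H": 0.432, "S": 0.286, "L": 0.282}


def make_random_type_pairs(n: int, seed: int,
                           type_freqs: dict[str, float] | None = None):
    """n fragment pairs whose center types are drawn independently from
    ``type_freqs`` (defaults to interface-typical H/S/L frequencies) and
    paired at random — the null model under which every motif preference
    score tends to zero. Coordinates are placeholders; only the types
    carry information."""
    from .fragments import InterfaceFragmentPair

    freqs = type_freqs or DEFAULT_TYPE_FREQS
    types = sorted(freqs)
    p = np.array([freqs[t] for t in types])
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(types), size=(n, 2), p=p)
    block = np.zeros((9, 3))
    block[:, 0] = np.arange(9) * 3.8  # straight placeholder trace
    out = []
    for k in range(n):
        out.append(InterfaceFragmentPair(
            source=f"null_{k}", center_i=4, center_j=4,
            coords_a=block, coords_b=block + np.array([0.0, 5.0, 0.0]),
            ss_a=types[draws[k, 0]], ss_b=types[draws[k, 1]]))
    return out


def make_planted_pair_dataset(K: int, members_per: int, noise_sigma: float,
                              seed: int, min_separation: float = 8.0,
                              avoid: list | None = None,
                              avoid_separation: float | None = None,
                              max_tries: int = 500):
    """K well-separated seed fragment-pair geometries, each replicated
    ``members_per`` times with iid Gaussian noise of ``noise_sigma`` A.

    Seed geometries are redrawn until every inter-seed order-insensitive
    superposition RMSD exceeds ``min_separation`` (default twice the 4 A
    clustering cutoff), and additionally stays ``avoid_separation``
    (default: ``min_separation``) away from every fragment pair in
    ``avoid`` — used to plant guaranteed-uncovered outliers around an
    existing dataset. Returns ``(pairs, labels)`` where ``labels[k]`` is
    the planted cluster index of ``pairs[k]``. Deterministic given seed.
    """
    from .fragments import InterfaceFragmentPair
    from .library import pair_rmsd

    if K < 1 or members_per < 1:
        raise ValueError("K and members_per must be >= 1")
    avoid = avoid or []
    if avoid_separation is None:
        avoid_separation = min_separation
    rng = np.random.default_rng(seed)

    def make_seed_pair(g: int) -> "InterfaceFragmentPair":
        a = _random_fragment_block(rng)
        b = _random_fragment_block(rng)
        offset = rng.normal(size=3)
        offset = offset / np.linalg.norm(offset) * rng.uniform(5.0, 40.0)
        b = b - b.mean(axis=0) + a.mean(axis=0) + offset
        ss = _CENTER_TYPES[g % len(_CENTER_TYPES)]
        return InterfaceFragmentPair(source=f"planted_g{g}", center_i=4,
                                     center_j=4, coords_a=a, coords_b=b,
                                     ss_a=ss[0], ss_b=ss[1])

    seeds: list = []
    for g in range(K):
        for _ in range(max_tries):
            cand = make_seed_pair(g)
            if all(pair_rmsd(cand, s) > min_separation for s in seeds) and \
                    all(pair_rmsd(cand, a) > avoid_separation for a in avoid):
                seeds.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not plant {K} geometries separated by "
                f"{min_separation} A in {max_tries} tries")

    pairs, labels = [], []
    for g, s in enumerate(seeds):
        for m in range(members_per):
            a = s.coords_a + rng.normal(0.0, noise_sigma, (9, 3))
            b = s.coords_b + rng.normal(0.0, noise_sigma, (9, 3))
            pairs.append(type(s)(source=f"planted_g{g}_m{m}", center_i=4,
                                 center_j=4, coords_a=a, coords_b=b,
                                 ss_a=s.ss_a, ss_b=s.ss_b))
            labels.append(g)
    return pairs, np.array(labels)
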