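"""Shared fixtures: synthetic domains, dimers, planted datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ifplib.fixtures import (ToyDimerSpec, backbone_to_domain, ideal_helix,
                             make_planted_pair_dataset, make_toy_dimer)
from ifplib.fragments import extract_fragment_pairs, interface_residue_pairs
from ifplib.structures import assign_ss3


def annotated_dimer(motif: str, seed: int = 0, noise: float = 0.0):
    """A toy dimer with secondary structure assigned on both domains."""
    spec = ToyDimerSpec(motif=motif, seed=seed, noise_sigma=noise)
    dom_i, dom_j, native = make_toy_dimer(spec)
    dom_i.ss3 = assign_ss3(dom_i)
    dom_j.ss3 = assign_ss3(dom_j)
    return dom_i, dom_j, native


def own_pairs(dom_i, dom_j, cutoff: float = 5.0):
    return extract_fragment_pairs(
        dom_i, dom_j, interface_residue_pairs(dom_i, dom_j, cutoff))


@pytest.fixture(scope="session")
def helix_domain():
    return backbone_to_domain(ideal_helix(25), dom_id="helix25")


@pytest.fixture(scope="session")
def hh_dimer():
    return annotated_dimer("HH", seed=0)


@pytest.fixture(scope="session")
def planted_300():
    """K=10 planted geometries x 30 noisy members (sigma 0.3 A)."""
    return make_planted_pair_dataset(K=10, members_per=30, noise_sigma=0.3,
                                     seed=11)


def write_dssp_stub(path, records):
    """Minimal classic-format DSSP file: records are
    (author_number, chain, aa_letter, ss8_code) tuples."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====\n",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA\n",
    ]
    for k, (num, ch, aa, ss) in enumerate(records, start=1):
        line = [" "] * 120
        line[0:5] = list(f"{k:5d}")
        line[5:10] = list(f"{num:5d}")
        line[11] = ch
        line[13] = aa
        line[16] = ss
        line[34:38] = list(f"{50:4d}")
        line[38:45] = list(f"{0:7d}")
        line[46:50] = list(f"{0.0:4.1f}")
        line[50:56] = list(f"{0:6d}")
        line[57:61] = list(f"{0.0:4.1f}")
        line[61:67] = list(f"{0:6d}")
        line[68:72] = list(f"{0.0:4.1f}")
        line[72:78] = list(f"{0:6d}")
        line[79:83] = list(f"{0.0:4.1f}")
        line[103:109] = list(f"{-60.0:6.1f}")
        line[109:115] = list(f"{-40.0:6.1f}")
        lines.append("".join(line).rstrip() + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation
    from ifplib.geometry import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return RigidTransform(R, t)
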