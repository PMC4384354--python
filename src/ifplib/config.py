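"""Run configuration: every tunable of the pipeline in one place.

Defaults are the published operating point of the interface fragment pair
method: a 5 A side-chain contact cutoff defines interface residue pairs, a
9-residue window defines fragments, pairs are clustered at 4.0 A RMSD,
clusters with more than 20 members enter the library, window-to-entry
alignments must be below 2 A, surface residues have SASA above 10 A^2
(1.4 A probe), and assembled models with any inter-domain CA-CA distance
below 3.5 A are discarded as clashes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


#: Bondi van der Waals radii (A), by element symbol. Used for SASA.
#: Elements not listed fall back to ``VDW_DEFAULT``.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
VDW_DEFAULT: float = 1.70


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their default values.

    Attributes
    ----------
    contact_cutoff : float
        Side-chain heavy-atom distance (A) below which two residues across
        the interface count as an interface residue pair.
    window : int
        Fragment length in residues; must be odd (a center plus flanks).
    cluster_cutoff : float
        Fragment-pair RMSD (A) below which an entry joins the cluster of
        its nearest previously-visited entry.
    min_members : int
        Clusters must have strictly more members than this to enter the
        library.
    align_cutoff : float
        Both 9-point window-to-entry alignment RMSDs (A) must be strictly
        below this for a model to be built.
    sasa_threshold : float
        Residues with SASA strictly above this (A^2) are surface residues.
    probe_radius : float
        Solvent probe radius (A) for Shrake-Rupley SASA.
    sasa_points : int
        Sphere sample points per atom for SASA.
    clash_cutoff : float
        Minimum allowed inter-domain CA-CA distance (A) in a model.
    seed : int
        Seed for every stochastic step (clustering visit order, fixtures).
    dedup : bool
        If true, near-duplicate poses (complex RMSD below ``dedup_cutoff``)
        are collapsed greedily, keeping the first.
    dedup_cutoff : float
        Pose RMSD (A) under which two models count as duplicates.
    """

    contact_cutoff: float = 5.0
    window: int = 9
    cluster_cutoff: float = 4.0
    min_members: int = 20
    align_cutoff: float = 2.0
    sasa_threshold: float = 10.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    clash_cutoff: float = 3.5
    seed: int = 0
    dedup: bool = False
    dedup_cutoff: float = 1.0
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        for name in ("contact_cutoff", "cluster_cutoff", "align_cutoff",
                     "probe_radius", "clash_cutoff", "dedup_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
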