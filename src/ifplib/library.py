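"""Clustering interface fragment pairs into a library of binding motifs.

The structural distance between two fragment pairs is the RMSD of a joint
Kabsch superposition over all CA atoms of both fragments (18 points for
the default 9-residue window), minimized over the two ways of matching
blocks — (a, b) onto (a, b) or onto (b, a) — so the comparison does not
depend on which partner was called "a". Fragment N-to-C direction is
never reversed.

Entries are visited in a seeded random order; each joins the cluster of
its nearest previously-visited entry when that RMSD is under the cutoff
(4.0 A default), otherwise it founds a new cluster. The cluster member
with the most co-members within the cutoff becomes its representative,
and clusters with strictly more than ``min_members`` members (20 default)
enter the library.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import InterfaceFragmentPair
from .geometry import batch_rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster", "LibraryEntry", "FragmentPairLibrary",
    "pair_rmsd", "pair_rmsd_matrix", "greedy_cluster",
    "select_representative", "build_library", "coverage",
    "cutoff_scan", "stability_runs",
    "write_library", "read_library",
]


@dataclass
class Cluster:
    member_ids: list[int]
    representative_id: int

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster cannot be empty")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class LibraryEntry:
    """One library entry: the representative fragment pair of an abundant
    cluster, its motif label, and how many pairs it stands for."""

    entry_id: int
    pair: InterfaceFragmentPair
    member_count: int
    motif: str


@dataclass
class FragmentPairLibrary:
    entries: list[LibraryEntry]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def pair_rmsd(p: InterfaceFragmentPair, q: InterfaceFragmentPair) -> float:
    """Order-insensitive joint superposition RMSD (A) between two
    fragment pairs: min over matching q's blocks directly or swapped."""
    P = p.joint()[None]
    direct = batch_rmsd(P, q.joint()[None])[0]
    swapped = batch_rmsd(P, q.joint(swapped=True)[None])[0]
    return float(min(direct, swapped))


def pair_rmsd_matrix(pairs: list[InterfaceFragmentPair],
                     others: list[InterfaceFragmentPair] | None = None
                     ) -> np.ndarray:
    """Dense matrix of order-insensitive pair RMSDs.

    With ``others`` given, the result is (len(pairs), len(others));
    otherwise the symmetric all-vs-all matrix with a zero diagonal. The
    O(N^2) cost is accepted: the method targets desk-scale inputs.
    """
    A = np.stack([p.joint() for p in pairs])
    if others is None:
        B, Bs = A, np.stack([p.joint(swapped=True) for p in pairs])
        n, m = len(pairs), len(pairs)
        iu = np.triu_indices(n, k=1)
        P = A[iu[0]]
        d = np.minimum(batch_rmsd(P, B[iu[1]]), batch_rmsd(P, Bs[iu[1]]))
        out = np.zeros((n, m))
        out[iu] = d
        out[(iu[1], iu[0])] = d
        return out
    B = np.stack([q.joint() for q in others])
    Bs = np.stack([q.joint(swapped=True) for q in others])
    n, m = len(pairs), len(others)
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    d = np.minimum(batch_rmsd(A[ii], B[jj]), batch_rmsd(A[ii], Bs[jj]))
    return d.reshape(n, m)


def select_representative(member_ids: list[int], dmat: np.ndarray,
                          cutoff: float) -> int:
    """The member with the most co-members within ``cutoff`` RMSD; ties
    broken by lowest mean RMSD to co-members, then lowest member id."""
    ids = np.asarray(member_ids)
    if ids.size == 1:
        return int(ids[0])
    sub = dmat[np.ix_(ids, ids)]
    neighbor_counts = (sub < cutoff).sum(axis=1) - 1  # exclude self
    mean_rmsd = sub.sum(axis=1) / (ids.size - 1)
    order = sorted(range(ids.size),
                   key=lambda k: (-neighbor_counts[k], mean_rmsd[k], ids[k]))
    return int(ids[order[0]])


def greedy_cluster(pairs: list[InterfaceFragmentPair], cutoff: float = 4.0,
                   order_seed: int = 0,
                   dmat: np.ndarray | None = None) -> list[Cluster]:
    """Greedy nearest-neighbor clustering in a seed-shuffled visit order.

    The first visited entry founds the first cluster. Each later entry
    joins the cluster of its nearest previously-visited entry when that
    RMSD is strictly below ``cutoff``, else it founds a new cluster.
    Deterministic given ``order_seed``; cluster sizes always sum to N.
    """
    n = len(pairs)
    if n == 0:
        raise ValueError("no pairs to cluster")
    if dmat is None:
        dmat = pair_rmsd_matrix(pairs)
    order = np.random.default_rng(order_seed).permutation(n)
    assignment = np.full(n, -1, dtype=int)
    members: list[list[int]] = []
    for step, idx in enumerate(order):
        if step == 0:
            assignment[idx] = 0
            members.append([int(idx)])
            continue
        prev = order[:step]
        d = dmat[idx, prev]
        k = int(np.argmin(d))
        if d[k] < cutoff:
            cid = assignment[prev[k]]
            assignment[idx] = cid
            members[cid].append(int(idx))
        else:
            assignment[idx] = len(members)
            members.append([int(idx)])
    clusters = [Cluster(sorted(m), select_representative(sorted(m), dmat, cutoff))
                for m in members]
    return clusters


def build_library(clusters: list[Cluster],
                  pairs: list[InterfaceFragmentPair],
                  min_members: int = 20,
                  params: dict | None = None) -> FragmentPairLibrary:
    """Library of representatives of the abundant clusters.

    Keeps clusters with strictly more than ``min_members`` members (the
    published rule is "larger than 20"). Entries are sorted by descending
    member count, ties by representative id.
    """
    from .motifs import classify_pair_motif

    kept = [c for c in clusters if c.size > min_members]
    kept.sort(key=lambda c: (-c.size, c.representative_id))
    entries = []
    for k, c in enumerate(kept):
        rep = pairs[c.representative_id]
        try:
            motif = classify_pair_motif(rep)
        except ValueError:
            motif = "??"
        entries.append(LibraryEntry(k, rep, c.size, motif))
    if not entries:
        warnings.warn("no cluster exceeds min_members; library is empty")
    p = dict(params or {})
    p.setdefault("min_members", min_members)
    return FragmentPairLibrary(entries, p)


def coverage(queries: list[InterfaceFragmentPair],
             lib: FragmentPairLibrary,
             cutoff: float = 4.0) -> tuple[float, np.ndarray]:
    """Fraction of query pairs within ``cutoff`` RMSD of some library
    entry, plus each query's minimum RMSD over entries (the histogram
    behind library-coverage plots)."""
    if not queries:
        raise ValueError("empty query list")
    if not lib.entries:
        raise ValueError("empty library")
    dm = pair_rmsd_matrix(queries, [e.pair for e in lib.entries])
    min_rmsd = dm.min(axis=1)
    return float(np.mean(min_rmsd < cutoff)), min_rmsd


def cutoff_scan(pairs: list[InterfaceFragmentPair],
                cutoffs: list[float],
                order_seed: int = 0) -> list[tuple[float, int]]:
    """Cluster counts over a range of RMSD cutoffs with one shared
    visiting order (and one shared distance matrix)."""
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoff values")
    dmat = pair_rmsd_matrix(pairs)
    out = []
    for c in cutoffs:
        clusters = greedy_cluster(pairs, cutoff=c, order_seed=order_seed,
                                  dmat=dmat)
        out.append((float(c), len(clusters)))
    return out


def stability_runs(pairs: list[InterfaceFragmentPair], cutoff: float = 4.0,
                   n_runs: int = 5, seeds: list[int] | None = None,
                   min_members: int = 20) -> list[dict]:
    """Independent clustering runs over shuffled visit orders.

    Returns one record per run: total clusters, number of abundant
    clusters (size strictly greater than ``min_members``), and the
    rank-ordered size profile — the stability diagnostics of the
    clustering procedure.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) < n_runs:
        raise ValueError("seeds list shorter than n_runs")
    dmat = pair_rmsd_matrix(pairs)
    out = []
    for r in range(n_runs):
        clusters = greedy_cluster(pairs, cutoff=cutoff, order_seed=seeds[r],
                                  dmat=dmat)
        sizes = sorted((c.size for c in clusters), reverse=True)
        out.append({"seed": seeds[r], "n_clusters": len(clusters),
                    "n_abundant": sum(s > min_members for s in sizes),
                    "ranked_sizes": sizes})
    return out


# ---------------------------------------------------------------------------
# library JSON

def write_library(lib: FragmentPairLibrary, path: str | Path) -> None:
    doc = {
        "params": lib.params,
        "entries": [
            {
                "id": e.entry_id,
                "motif": e.motif,
                "member_count": e.member_count,
                "source": e.pair.source,
                "center_i": e.pair.center_i,
                "center_j": e.pair.center_j,
                "ss_a": e.pair.ss_a,
                "ss_b": e.pair.ss_b,
                "coords_a": np.round(e.pair.coords_a, 6).tolist(),
                "coords_b": np.round(e.pair.coords_b, 6).tolist(),
            }
            for e in lib.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_library(path: str | Path) -> FragmentPairLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    if "entries" not in doc or "params" not in doc:
        raise ValueError(f"{path}: not a fragment-pair library file")
    entries = []
    for rec in doc["entries"]:
        pair = InterfaceFragmentPair(
            source=rec["source"], center_i=rec["center_i"],
            center_j=rec["center_j"],
            coords_a=np.array(rec["coords_a"]),
            coords_b=np.array(rec["coords_b"]),
            ss_a=rec.get("ss_a"), ss_b=rec.get("ss_b"))
        entries.append(LibraryEntry(rec["id"], pair, rec["member_count"],
                                    rec["motif"]))
    return FragmentPairLibrary(entries, doc["params"])
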