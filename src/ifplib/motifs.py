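"""Secondary-structure motifs of interface fragment pairs.

Each fragment is typed H (helix), S (strand) or L (loop) by the 3-state
secondary structure of its center residue, so a fragment pair falls into
one of six unordered motifs: HH, SS, LL, HL, HS, SL. The preference score
of a motif XY is

    score(XY) = ln( P(XY) / (P(X) * P(Y)) )

where P(XY) is the motif's frequency among pair records and P(X) the
frequency of type X among individual fragments (two per record). The
null model is implemented exactly in this printed form — no 2 P(X) P(Y)
combinatorial factor for heterogeneous motifs; a positive score marks a
packing that occurs more often than independent pairing of fragment
types would produce.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from .fragments import InterfaceFragmentPair

__all__ = ["MOTIFS", "MotifStats", "classify_pair_motif",
           "fragment_type_probs", "preference_scores", "motif_stats",
           "write_motif_report"]

_TYPE_ORDER = {"H": 0, "S": 1, "L": 2}
MOTIFS = ("HH", "SS", "LL", "HL", "HS", "SL")


def classify_pair_motif(p: InterfaceFragmentPair) -> str:
    """Unordered motif label from the two center-residue types: (S, H)
    and (H, S) both map to HS."""
    if p.ss_a not in _TYPE_ORDER or p.ss_b not in _TYPE_ORDER:
        raise ValueError(f"fragment pair lacks center secondary structure "
                         f"(ss_a={p.ss_a!r}, ss_b={p.ss_b!r})")
    a, b = sorted((p.ss_a, p.ss_b), key=_TYPE_ORDER.get)
    return a + b


@dataclass
class MotifStats:
    """Counts, probabilities and preference scores of the six motifs."""

    motif_counts: dict[str, int]
    type_probs: dict[str, float]
    motif_probs: dict[str, float]
    preference: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.type_probs.values()) - 1.0) > 1e-9:
            raise ValueError("type probabilities must sum to 1")
        if abs(sum(self.motif_probs.values()) - 1.0) > 1e-9:
            raise ValueError("motif probabilities must sum to 1")
        if any(c < 0 for c in self.motif_counts.values()):
            raise ValueError("negative motif count")


def fragment_type_probs(pairs: list[InterfaceFragmentPair]) -> dict[str, float]:
    """Frequency of H, S and L among individual fragments; every pair
    record contributes two fragments."""
    if not pairs:
        raise ValueError("no pairs")
    counts = {"H": 0, "S": 0, "L": 0}
    for p in pairs:
        for ss in (p.ss_a, p.ss_b):
            if ss not in counts:
                raise ValueError(f"fragment without valid type: {ss!r}")
            counts[ss] += 1
    total = 2 * len(pairs)
    return {t: counts[t] / total for t in counts}


def preference_scores(type_probs: dict[str, float],
                      motif_probs: dict[str, float]) -> dict[str, float]:
    """ln(P(XY) / (P(X) P(Y))) per motif; motifs never observed score
    -inf (flagged, not an error). A zero type probability is an error
    naming the type, since the null is then undefined."""
    for t, pt in type_probs.items():
        if pt <= 0.0:
            raise ValueError(f"type probability of {t!r} is zero; "
                             f"preference scores undefined")
    out = {}
    for m in MOTIFS:
        pm = motif_probs.get(m, 0.0)
        null = type_probs[m[0]] * type_probs[m[1]]
        out[m] = math.log(pm / null) if pm > 0.0 else -math.inf
    return out


def motif_stats(pairs: list[InterfaceFragmentPair]) -> MotifStats:
    """Full motif statistics of a set of fragment pairs.

    When some fragment type never occurs the preference scores are
    undefined; they are reported as NaN with a warning rather than
    failing the whole report.
    """
    counts = {m: 0 for m in MOTIFS}
    for p in pairs:
        counts[classify_pair_motif(p)] += 1
    n = len(pairs)
    motif_probs = {m: c / n for m, c in counts.items()}
    type_probs = fragment_type_probs(pairs)
    try:
        pref = preference_scores(type_probs, motif_probs)
    except ValueError as exc:
        warnings.warn(str(exc))
        pref = {m: math.nan for m in MOTIFS}
    return MotifStats(counts, type_probs, motif_probs, pref)


def write_motif_report(stats: MotifStats, path: str | Path) -> None:
    """TSV: motif, count, probability, preference score."""
    with open(path, "w") as fh:
        fh.write("motif\tcount\tprobability\tpreference\n")
        for m in MOTIFS:
            fh.write(f"{m}\t{stats.motif_counts[m]}\t"
                     f"{stats.motif_probs[m]:.6f}\t"
                     f"{stats.preference[m]:.6f}\n")
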