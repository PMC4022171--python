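"""Accessory-motif scanners: short linear motifs on proteins, W-box on DNA.

Protein motifs:

* ``LXXLL`` — nuclear-receptor-style coactivator motif (L, any, any, L, L);
* ``LXLXLX`` — EAR-like active-repressor motif (L alternating with any
  residue over a 6-window, i.e. L at window offsets 0, 2 and 4);
* ``HARF`` — the literal ``RTGHARFRR(A/G)P`` block characteristic of
  group IId WRKY proteins;
* a leucine-zipper heuristic: maximal heptad runs with Leu at every
  seventh position (labelled ``LZ-heuristic`` — it is a periodicity
  check, not a coiled-coil predictor).

DNA: the W-box element ``(C/T)TGAC(T/C)`` that WRKY domains bind, on one
or both strands.  All scanners are exhaustive over window positions and
report every overlapping occurrence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .domain_scan import _check_alphabet

__all__ = [
    "MotifHit",
    "LeucineZipperRegion",
    "PROTEIN_MOTIFS",
    "WBOX_PATTERN",
    "find_protein_motif",
    "find_wbox",
    "predict_leucine_zipper",
]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int
    matched: str
    strand: str = "+"


@dataclass(frozen=True)
class LeucineZipperRegion:
    sequence_id: str
    start: int
    end: int
    n_heptads: int
    motif: str = "LZ-heuristic"


#: window predicates per protein motif (window length, residue test)
PROTEIN_MOTIFS = {
    "LXXLL": re.compile(r"L..LL"),
    "LXLXLX": re.compile(r"L.L.L."),
    "HARF": re.compile(r"RTGHARFRR[AG]P"),
}

WBOX_PATTERN = re.compile(r"[CT]TGAC[TC]")

_DNA = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def find_protein_motif(seq: str, motif: str, *, sequence_id: str = "") -> list[MotifHit]:
    """All overlapping occurrences of a named protein motif, sorted by start."""
    if motif not in PROTEIN_MOTIFS:
        raise ValueError(f"unknown protein motif {motif!r}; choose from {sorted(PROTEIN_MOTIFS)}")
    up = _check_alphabet(seq)
    pattern = PROTEIN_MOTIFS[motif]
    hits = []
    pos = 0
    while True:
        m = pattern.search(up, pos)
        if m is None:
            break
        hits.append(MotifHit(sequence_id=sequence_id, motif=motif, start=m.start(), matched=m.group()))
        pos = m.start() + 1  # overlapping occurrences
    return hits


def reverse_complement(dna: str) -> str:
    return dna.upper().translate(_COMPLEMENT)[::-1]


def find_wbox(dna: str, *, both_strands: bool = True, sequence_id: str = "") -> list[MotifHit]:
    """W-box occurrences; minus-strand hits in plus-strand start coordinates.

    ``N`` never matches.  Invalid bases raise with the position named.
    """
    up = dna.upper()
    for i, ch in enumerate(up):
        if ch not in _DNA:
            raise ValueError(f"invalid DNA base {ch!r} at position {i}")
    hits = []
    pos = 0
    while True:
        m = WBOX_PATTERN.search(up, pos)
        if m is None:
            break
        hits.append(MotifHit(sequence_id=sequence_id, motif="WBOX", start=m.start(), matched=m.group()))
        pos = m.start() + 1
    if both_strands:
        rc = reverse_complement(up)
        n = len(up)
        pos = 0
        while True:
            m = WBOX_PATTERN.search(rc, pos)
            if m is None:
                break
            plus_start = n - m.start() - 6
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    motif="WBOX",
                    start=plus_start,
                    matched=m.group(),
                    strand="-",
                )
            )
            pos = m.start() + 1
    return sorted(hits, key=lambda h: (h.start, h.strand))


def predict_leucine_zipper(
    seq: str,
    min_heptads: int = 4,
    *,
    allow_ile: bool = False,
    sequence_id: str = "",
) -> list[LeucineZipperRegion]:
    """Maximal heptad runs with Leu (optionally Ile) every 7th residue.

    A run starting at ``i`` spans positions ``i, i+7, …``; it is maximal
    when position ``i-7`` does not extend it.  Runs shorter than
    ``min_heptads`` periods are suppressed.
    """
    up = _check_alphabet(seq)
    accepted = {"L", "I"} if allow_ile else {"L"}
    n = len(up)
    regions = []
    for i in range(n):
        if up[i] not in accepted:
            continue
        if i >= 7 and up[i - 7] in accepted:
            continue  # not maximal: extendable to the left
        k = 1
        while i + 7 * k < n and up[i + 7 * k] in accepted:
            k += 1
        if k >= min_heptads:
            regions.append(
                LeucineZipperRegion(
                    sequence_id=sequence_id,
                    start=i,
                    end=min(i + 7 * k, n),
                    n_heptads=k,
                )
            )
    return regions
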