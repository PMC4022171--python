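"""Rule-based detection of WRKY DNA-binding domains in protein sequences.

A WRKY domain is recognised here by two features, applied in order:

1. the near-invariant heptapeptide ``WRKYGQK`` (natural variants such as
   ``WRKYGKK`` differ by a single residue), and
2. a downstream zinc-chelating motif whose four ligands are spaced
   ``C-X(a)-C-X(b)-H-X(c)-[H|C]``; a terminal His gives the C2H2 finger
   class (groups I/II), a terminal Cys gives C2HC (group III).

Spacer ranges are expressed as a :class:`FingerGrammar` and default to the
permissive union observed across the grape family catalog:
``a`` in [4, 8], ``b`` in [22, 28], ``c`` in [1, 2].

Detection is deliberately grammar-based: there is no profile scoring and
no E-value.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "CANONICAL_HEPTAPEPTIDE",
    "AMINO_ACIDS",
    "FingerGrammar",
    "HeptapeptideHit",
    "ZincFingerSpec",
    "WRKYDomain",
    "PatternError",
    "scan_heptapeptide",
    "find_zinc_finger",
    "scan_domains",
    "parse_pattern",
    "format_pattern",
]

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"

#: the 20 proteinogenic residues; ``X`` is additionally accepted on input
#: and always counts as a mismatch.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_VALID_PROTEIN = AMINO_ACIDS | {"X"}


class PatternError(ValueError):
    """A zinc-finger pattern string does not follow the spacing grammar."""


@dataclass(frozen=True)
class FingerGrammar:
    """Configurable spacing grammar for the zinc-finger motif.

    ``linker_window`` bounds how far downstream of the heptapeptide the
    first Cys ligand may start; ``max_domain_span`` bounds the whole
    domain (heptapeptide start to one past the terminal ligand).
    """

    spacer1: tuple[int, int] = (4, 8)
    spacer2: tuple[int, int] = (22, 28)
    spacer3: tuple[int, int] = (1, 2)
    linker_window: int = 30
    max_domain_span: int = 80
    max_mismatch: int = 1
    require_invariant_w: bool = True


DEFAULT_GRAMMAR = FingerGrammar()


@dataclass(frozen=True)
class HeptapeptideHit:
    start: int
    observed: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + 7


@dataclass(frozen=True)
class ZincFingerSpec:
    """Spacing of the four zinc ligands, as in a catalog pattern string.

    ``observed_intervening`` holds the residues between the His and the
    terminal ligand; the placeholder ``X`` (repeated ``spacer3`` times)
    means "unspecified", which is how C2H2 patterns are printed.
    """

    spacer1: int
    spacer2: int
    spacer3: int
    terminal_ligand: str  # "H" or "C"
    observed_intervening: str = ""

    def __post_init__(self):
        if self.terminal_ligand not in ("H", "C"):
            raise ValueError(f"terminal ligand must be H or C, got {self.terminal_ligand!r}")
        inter = self.observed_intervening or "X" * self.spacer3
        object.__setattr__(self, "observed_intervening", inter)
        if len(inter) != self.spacer3:
            raise ValueError(
                f"intervening residues {inter!r} inconsistent with spacer3={self.spacer3}"
            )

    @property
    def finger_class(self) -> str:
        return "C2HC" if self.terminal_ligand == "C" else "C2H2"

    def within(self, grammar: FingerGrammar = DEFAULT_GRAMMAR) -> bool:
        return (
            grammar.spacer1[0] <= self.spacer1 <= grammar.spacer1[1]
            and grammar.spacer2[0] <= self.spacer2 <= grammar.spacer2[1]
            and grammar.spacer3[0] <= self.spacer3 <= grammar.spacer3[1]
        )


@dataclass(frozen=True)
class WRKYDomain:
    """A detected domain: heptapeptide hit plus downstream zinc finger."""

    protein_id: str
    hepta: HeptapeptideHit
    finger: ZincFingerSpec
    ligand_positions: tuple[int, int, int, int]
    start: int
    end: int

    def __post_init__(self):
        c1, c2, h, t = self.ligand_positions
        if not (c1 < c2 < h < t):
            raise ValueError("ligand positions must be strictly increasing")

    @property
    def pattern(self) -> str:
        return format_pattern(self.finger)


def _check_alphabet(seq: str, *, extra: str = "") -> str:
    """Return the upper-cased sequence, rejecting non-amino-acid letters."""
    up = seq.upper()
    allowed = _VALID_PROTEIN | set(extra)
    for i, ch in enumerate(up):
        if ch not in allowed:
            raise ValueError(f"invalid amino-acid character {ch!r} at position {i}")
    return up


def scan_heptapeptide(
    seq: str,
    max_mismatch: int = 1,
    *,
    require_invariant_w: bool = True,
) -> list[HeptapeptideHit]:
    """Report every 7-mer window within ``max_mismatch`` of WRKYGQK.

    ``X`` counts as a mismatch at any position.  By default the leading
    Trp must be invariant, since no natural heptapeptide variant alters
    it; pass ``require_invariant_w=False`` to allow mismatches there too.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    up = _check_alphabet(seq)
    hits: list[HeptapeptideHit] = []
    for i in range(len(up) - 6):
        window = up[i : i + 7]
        if require_invariant_w and window[0] != "W":
            continue
        d = sum(a != b for a, b in zip(window, CANONICAL_HEPTAPEPTIDE))
        if d <= max_mismatch:
            hits.append(HeptapeptideHit(start=i, observed=window, mismatches=d))
    return hits


def find_zinc_finger(
    seq: str,
    from_pos: int,
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
) -> tuple[ZincFingerSpec, tuple[int, int, int, int]] | None:
    """Leftmost zinc-finger match starting at or after ``from_pos``.

    The first Cys must lie within ``grammar.linker_window`` residues of
    ``from_pos``.  Among overlapping candidates the smallest first-Cys
    position wins, then the smallest spacer1, spacer2 and spacer3.
    Returns ``(spec, (c1, c2, h, terminal))`` or ``None``.
    """
    up = _check_alphabet(seq)
    n = len(up)
    if not (0 <= from_pos <= n):
        raise ValueError(f"from_pos {from_pos} outside sequence of length {n}")
    lo1, hi1 = grammar.spacer1
    lo2, hi2 = grammar.spacer2
    lo3, hi3 = grammar.spacer3
    c1_limit = min(n, from_pos + grammar.linker_window)
    for c1 in range(from_pos, c1_limit):
        if up[c1] != "C":
            continue
        for s1 in range(lo1, hi1 + 1):
            c2 = c1 + 1 + s1
            if c2 >= n or up[c2] != "C":
                continue
            for s2 in range(lo2, hi2 + 1):
                h = c2 + 1 + s2
                if h >= n or up[h] != "H":
                    continue
                for s3 in range(lo3, hi3 + 1):
                    t = h + 1 + s3
                    if t >= n or up[t] not in ("H", "C"):
                        continue
                    spec = ZincFingerSpec(
                        spacer1=s1,
                        spacer2=s2,
                        spacer3=s3,
                        terminal_ligand=up[t],
                        observed_intervening=up[h + 1 : t],
                    )
                    return spec, (c1, c2, h, t)
    return None


def scan_domains(
    seq: str,
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
    *,
    protein_id: str = "",
) -> list[WRKYDomain]:
    """Detect WRKY domains: heptapeptide hits paired with downstream fingers.

    Every heptapeptide hit is greedily paired with the leftmost finger
    downstream of it; hits with no finger (or a pairing exceeding
    ``max_domain_span``) are dropped, and domains fully nested inside
    another are removed.  Results are ordered N-terminus to C-terminus.
    """
    hits = scan_heptapeptide(
        seq, grammar.max_mismatch, require_invariant_w=grammar.require_invariant_w
    )
    domains: list[WRKYDomain] = []
    for hit in hits:
        found = find_zinc_finger(seq, hit.end, grammar)
        if found is None:
            continue
        spec, positions = found
        end = positions[3] + 1
        if end - hit.start > grammar.max_domain_span:
            continue
        domains.append(
            WRKYDomain(
                protein_id=protein_id,
                hepta=hit,
                finger=spec,
                ligand_positions=positions,
                start=hit.start,
                end=end,
            )
        )
    # drop domains strictly nested inside another (shared finger, shifted heptapeptide)
    kept = [
        d
        for d in domains
        if not any(
            e is not d
            and e.start <= d.start
            and d.end <= e.end
            and (e.start < d.start or d.end < e.end)
            for e in domains
        )
    ]
    return sorted(kept, key=lambda d: d.start)


_SPACER_RE = re.compile(r"^X(\d+)$")
_TAIL_RE = re.compile(r"^H([A-Z]{1,2})([HC])$")


def parse_pattern(s: str) -> ZincFingerSpec:
    """Parse a catalog pattern string such as ``C-X4-C-X23-HXH``.

    Underscores and whitespace (subscript markup in print) are stripped
    first.  The trailing token encodes the His plus terminal ligand:
    ``HXH`` is a C2H2 finger with one unspecified intervening residue,
    ``HTC`` a C2HC finger with observed intervening ``T``.
    """
    if not s or not s.strip():
        raise PatternError("empty pattern string")
    cleaned = re.sub(r"[_\s]", "", s).upper()
    tokens = cleaned.split("-")
    if len(tokens) == 7:
        # long form C-Xa-C-Xb-H-Xc-H: fold the tail back into one token
        tokens = tokens[:4] + [tokens[4] + _expand_tail(tokens[5]) + tokens[6]]
    if len(tokens) != 5:
        raise PatternError(f"pattern {s!r} does not have form C-Xa-C-Xb-<tail>")
    if tokens[0] != "C":
        raise PatternError(f"expected leading 'C', got {tokens[0]!r} in {s!r}")
    if tokens[2] != "C":
        raise PatternError(f"expected second 'C', got {tokens[2]!r} in {s!r}")
    spacers = []
    for tok in (tokens[1], tokens[3]):
        m = _SPACER_RE.match(tok)
        if not m:
            raise PatternError(f"bad spacer token {tok!r} in {s!r}")
        spacers.append(int(m.group(1)))
    m = _TAIL_RE.match(tokens[4])
    if not m:
        raise PatternError(f"bad tail token {tokens[4]!r} in {s!r}")
    inter, terminal = m.group(1), m.group(2)
    return ZincFingerSpec(
        spacer1=spacers[0],
        spacer2=spacers[1],
        spacer3=len(inter),
        terminal_ligand=terminal,
        observed_intervening=inter,
    )


def _expand_tail(token: str) -> str:
    m = _SPACER_RE.match(token)
    if m:
        return "X" * int(m.group(1))
    if token and all(c in AMINO_ACIDS or c == "X" for c in token):
        return token
    raise PatternError(f"bad intervening token {token!r}")


def format_pattern(f: ZincFingerSpec) -> str:
    """Canonical pattern string for a finger spec.

    C2H2 fingers print unspecified intervening residues (``HXH`` style),
    matching the catalog convention; C2HC fingers interpolate the
    observed intervening residues (``HTC`` style).
    """
    if f.terminal_ligand == "H":
        tail = "H" + "X" * f.spacer3 + "H"
    else:
        tail = "H" + f.observed_intervening + "C"
    return f"C-X{f.spacer1}-C-X{f.spacer2}-{tail}"


def canonical_spec(f: ZincFingerSpec) -> ZincFingerSpec:
    """The spec as a pattern string represents it (C2H2 intervening erased)."""
    if f.terminal_ligand == "H":
        return replace(f, observed_intervening="X" * f.spacer3)
    return f
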