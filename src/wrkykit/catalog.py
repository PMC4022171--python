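"""Machine-readable catalog of the grape WRKY transcription-factor family.

The packaged fixture ``data/grape_wrky_catalog.tsv`` transcribes the
published family survey: 80 proteins across five *Vitis* species, each
with identity, chromosome, physical properties, group/subgroup and the
zinc-finger spacing pattern of every WRKY domain.  Two-domain (group I)
proteins occupy two rows — one per domain (N-terminal then C-terminal) —
and collapse into a single :class:`CatalogEntry` on load.

Printed anomalies of the source table (a duplicated row label, swapped
N/C domain labels, an implausible molecular weight) are preserved
verbatim and flagged in the ``anomaly`` column rather than corrected.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .domain_scan import parse_pattern

__all__ = [
    "GROUPS",
    "CatalogEntry",
    "DomainRecord",
    "CatalogSummary",
    "load_catalog",
    "save_catalog",
    "summarize",
    "count_entries",
    "EF1G_FORWARD_PRIMER",
    "EF1G_REVERSE_PRIMER",
    "EF1G_ACCESSION",
]

GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: qRT-PCR reference-gene primers (elongation factor 1 gamma), stored as
#: metadata only; nothing in the package amplifies anything with them.
EF1G_FORWARD_PRIMER = "GCGGGCAAGAGATACCTCAA"
EF1G_REVERSE_PRIMER = "TCAATCTGTCTAGGAAAGGAAG"
EF1G_ACCESSION = "AF176496"

COLUMNS = (
    "name",
    "source_label",
    "gi",
    "chromosome",
    "length_aa",
    "pi",
    "mw_kda",
    "species",
    "group",
    "role",
    "domain_label",
    "pattern_string",
    "anomaly",
)


@dataclass(frozen=True)
class DomainRecord:
    """One WRKY domain line of a catalog entry."""

    label: str
    pattern_string: str
    role: str  # NTWD | CTWD | single

    def __post_init__(self):
        if self.role not in ("NTWD", "CTWD", "single"):
            raise ValueError(f"bad domain role {self.role!r}")


@dataclass(frozen=True)
class CatalogEntry:
    """One protein of the family catalog (one or two domain records)."""

    name: str
    source_label: str
    gi: str
    chromosome: int | str  # 1..19 or "unknown"
    length_aa: int
    pi: float
    mw_kda: float
    species: str
    group: str
    terminal_domains: tuple[DomainRecord, ...]
    anomalies: tuple[str, ...] = ()

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        roles = tuple(d.role for d in self.terminal_domains)
        if self.group == "I":
            if roles != ("NTWD", "CTWD"):
                raise ValueError(
                    f"{self.name}: group I needs one NTWD and one CTWD record, got {roles}"
                )
        elif roles != ("single",):
            raise ValueError(
                f"{self.name}: group {self.group} needs exactly one single-domain record"
            )
        if self.length_aa <= 0:
            raise ValueError(f"{self.name}: nonpositive length")

    @property
    def finger_classes(self) -> tuple[str, ...]:
        return tuple(parse_pattern(d.pattern_string).finger_class for d in self.terminal_domains)


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    per_group: dict[str, int]
    per_chromosome: dict[str, int]
    per_species: dict[str, int]
    length_min: int | None
    length_max: int | None
    pi_min: float | None
    pi_max: float | None


def _packaged_fixture() -> Path:
    return resources.files("wrkykit").joinpath("data/grape_wrky_catalog.tsv")


def _parse_chromosome(raw: str):
    if raw in ("unknown", "*", "∗", ""):
        return "unknown"
    chrom = int(raw)
    if not 1 <= chrom <= 19:
        raise ValueError(f"chromosome {chrom} outside 1..19")
    return chrom


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load catalog entries from a TSV file (default: the packaged fixture).

    One line per domain; consecutive group-I lines sharing a protein name
    collapse into one two-domain entry.  Malformed pattern strings and
    duplicate protein names raise with the offending row named; an empty
    file raises rather than yielding a partial catalog.
    """
    if path is None:
        text = _packaged_fixture().read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty catalog file: missing header") from None
    if tuple(header) != COLUMNS:
        raise ValueError(f"unexpected catalog header {header!r}; expected {list(COLUMNS)}")

    rows = [r for r in reader if r and any(f.strip() for f in r)]
    if not rows:
        raise ValueError("catalog file has a header but no rows")

    grouped: dict[str, list[tuple[int, dict]]] = {}
    order: list[str] = []
    for lineno, row in enumerate(rows, start=2):
        if len(row) < len(COLUMNS) - 1:  # anomaly column may be absent
            raise ValueError(f"row {lineno}: expected {len(COLUMNS)} columns, got {len(row)}")
        rec = dict(zip(COLUMNS, row + [""] * (len(COLUMNS) - len(row))))
        try:
            parse_pattern(rec["pattern_string"])
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({rec['name']}): {exc}") from exc
        if rec["name"] not in grouped:
            order.append(rec["name"])
        grouped.setdefault(rec["name"], []).append((lineno, rec))

    entries: list[CatalogEntry] = []
    for name in order:
        recs = grouped[name]
        first = recs[0][1]
        if first["group"] != "I" and len(recs) > 1:
            raise ValueError(f"duplicate catalog name {name!r} (rows {[ln for ln, _ in recs]})")
        for ln, rec in recs[1:]:
            for col in ("source_label", "gi", "group", "length_aa"):
                if rec[col] != first[col]:
                    raise ValueError(f"row {ln}: {name} domain lines disagree on {col}")
        domains = tuple(
            DomainRecord(label=r["domain_label"], pattern_string=r["pattern_string"], role=r["role"])
            for _, r in recs
        )
        anomalies = tuple(sorted({r["anomaly"] for _, r in recs if r["anomaly"]}))
        lineno = recs[0][0]
        try:
            entry = CatalogEntry(
                name=name,
                source_label=first["source_label"],
                gi=first["gi"],
                chromosome=_parse_chromosome(first["chromosome"]),
                length_aa=int(first["length_aa"]),
                pi=float(first["pi"]),
                mw_kda=float(first["mw_kda"]),
                species=first["species"],
                group=first["group"],
                terminal_domains=domains,
                anomalies=anomalies,
            )
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({name}): {exc}") from exc
        entries.append(entry)
    return entries


def save_catalog(entries: list[CatalogEntry], path: str | Path) -> None:
    """Write entries back to TSV (one line per domain; load round-trips)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(COLUMNS)
        for e in entries:
            for d in e.terminal_domains:
                writer.writerow(
                    [
                        e.name,
                        e.source_label,
                        e.gi,
                        str(e.chromosome),
                        str(e.length_aa),
                        _fmt_num(e.pi),
                        _fmt_num(e.mw_kda),
                        e.species,
                        e.group,
                        d.role,
                        d.label,
                        d.pattern_string,
                        ";".join(e.anomalies),
                    ]
                )


def _fmt_num(x: float) -> str:
    s = f"{x:g}"
    return s


def summarize(entries: list[CatalogEntry]) -> CatalogSummary:
    """Counts and ranges over the catalog; empty input yields a zero summary."""
    if not entries:
        return CatalogSummary(0, {}, {}, {}, None, None, None, None)
    per_group = Counter(e.group for e in entries)
    per_chromosome = Counter(str(e.chromosome) for e in entries)
    per_species = Counter(e.species for e in entries)
    lengths = [e.length_aa for e in entries]
    pis = [e.pi for e in entries]
    return CatalogSummary(
        n_total=len(entries),
        per_group=dict(per_group),
        per_chromosome=dict(per_chromosome),
        per_species=dict(per_species),
        length_min=min(lengths),
        length_max=max(lengths),
        pi_min=min(pis),
        pi_max=max(pis),
    )


def count_entries(
    entries: list[CatalogEntry],
    *,
    finger_class: str | None = None,
    name_prefix: str | None = None,
    group: str | None = None,
) -> int:
    """Count entries matching optional filters.

    ``finger_class`` matches entries having at least one domain of that
    class (C2H2 or C2HC); ``name_prefix`` filters on the normalized name.
    """
    n = 0
    for e in entries:
        if name_prefix is not None and not e.name.startswith(name_prefix):
            continue
        if group is not None and e.group != group:
            continue
        if finger_class is not None and finger_class not in e.finger_classes:
            continue
        n += 1
    return n
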