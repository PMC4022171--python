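"""Group and subgroup assignment for scanned WRKY proteins.

Group assignment follows the family's structural definition directly:
two or more WRKY domains -> group I (N-most domain labelled NTWD, C-most
CTWD); a single domain with a C2HC finger (terminal Cys) -> group III;
a single C2H2 domain -> group II; no domain -> unclassified.

Group II subgrouping is phylogenetic in origin, so for subgroups a
transparent surrogate is used and the evidence records which path fired:

1. rule layer — a first spacer of 4 residues is diagnostic of IIc
   (every IIc catalog pattern is ``C-X4-…``); the HARF block anywhere in
   the full protein overrides to IId;
2. otherwise 1-nearest-neighbour by global-alignment identity against a
   labelled reference set of subgroup domain sequences, ties breaking to
   the lexicographically smallest reference label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain_scan import WRKYDomain
from .motif_scan import find_protein_motif
from .phylo import pairwise_align

__all__ = ["GroupCall", "Evidence", "ReferenceSet", "assign_group", "assign_subgroup"]

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


@dataclass(frozen=True)
class Evidence:
    n_domains: int
    finger_classes: tuple[str, ...]
    spacer1: int | None = None
    rule_fired: str | None = None
    nearest_reference: str | None = None
    identity: float | None = None
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupCall:
    protein_id: str
    group: str  # I | II | III | unclassified
    subgroup: str | None
    evidence: Evidence

    def __post_init__(self):
        if self.group not in ("I", "II", "III", "unclassified"):
            raise ValueError(f"bad group {self.group!r}")
        if self.subgroup is not None and self.group != "II":
            raise ValueError("subgroup is only meaningful for group II")
        if self.subgroup is not None and self.subgroup not in SUBGROUPS:
            raise ValueError(f"bad subgroup {self.subgroup!r}")


@dataclass(frozen=True)
class ReferenceSet:
    """Labelled group II domain sequences for nearest-neighbour calls."""

    members: tuple[tuple[str, str], ...]  # (subgroup label, domain sequence)

    def __post_init__(self):
        for label, seq in self.members:
            if label not in SUBGROUPS:
                raise ValueError(f"reference label {label!r} is not a group II subgroup")
            if not seq:
                raise ValueError("reference sequences must be non-empty")


def assign_group(domains: list[WRKYDomain], *, protein_id: str | None = None) -> GroupCall:
    """Structural group call from the domains of one protein (N->C order)."""
    pid = protein_id if protein_id is not None else (domains[0].protein_id if domains else "")
    classes = tuple(d.finger.finger_class for d in domains)
    ev = Evidence(n_domains=len(domains), finger_classes=classes)
    if len(domains) >= 2:
        notes = ()
        if len(domains) > 2:
            notes = (f"{len(domains)} domains; N-most treated as NTWD, C-most as CTWD",)
        return GroupCall(pid, "I", None, Evidence(len(domains), classes, notes=notes))
    if len(domains) == 1:
        d = domains[0]
        if d.finger.terminal_ligand == "C":
            return GroupCall(pid, "III", None, Evidence(1, classes, spacer1=d.finger.spacer1))
        return GroupCall(pid, "II", None, Evidence(1, classes, spacer1=d.finger.spacer1))
    return GroupCall(pid, "unclassified", None, ev)


def assign_subgroup(
    domain: WRKYDomain,
    refs: ReferenceSet | None = None,
    domain_seq: str | None = None,
    *,
    full_seq: str | None = None,
) -> tuple[str | None, Evidence]:
    """Subgroup for a single-domain C2H2 protein: rules first, then 1-NN.

    Returns ``(subgroup_or_None, evidence)``.  ``domain_seq`` is the
    amino-acid string of the domain (needed only for the 1-NN fallback);
    ``full_seq`` is the whole protein (needed only for the HARF rule).
    """
    if domain.finger.terminal_ligand != "H":
        raise ValueError("subgroup assignment applies to C2H2 (group II) domains only")
    classes = (domain.finger.finger_class,)
    spacer1 = domain.finger.spacer1

    subgroup: str | None = None
    rule: str | None = None
    if spacer1 == 4:
        subgroup, rule = "IIc", "spacer1=4"
    if full_seq is not None and find_protein_motif(full_seq, "HARF"):
        subgroup, rule = "IId", "HARF"

    if subgroup is not None:
        return subgroup, Evidence(1, classes, spacer1=spacer1, rule_fired=rule)

    if refs is None or not refs.members or domain_seq is None:
        return None, Evidence(1, classes, spacer1=spacer1, rule_fired=None)

    best_label: str | None = None
    best_ref_idx = None
    best_identity = -1.0
    for idx, (label, ref_seq) in enumerate(refs.members):
        identity = pairwise_align(domain_seq, ref_seq).identity
        better = identity > best_identity + 1e-12
        tie = abs(identity - best_identity) <= 1e-12
        if better or (tie and label < best_label):
            best_identity = identity if better else best_identity
            best_label = label
            best_ref_idx = idx
    ev = Evidence(
        1,
        classes,
        spacer1=spacer1,
        rule_fired="1-NN",
        nearest_reference=f"{best_label}#{best_ref_idx}",
        identity=best_identity,
    )
    return best_label, ev
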