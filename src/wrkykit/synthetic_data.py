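"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`make_protein` — a protein with WRKY domains and/or short linear
  motifs planted at chosen positions in random background.  Background
  residues are drawn uniformly from the 19 amino acids excluding Trp, so
  accidental heptapeptides are vanishingly rare; filler residues inside
  planted fingers and linkers additionally exclude Cys and His so the
  spacer boundaries stay unambiguous.  A post-validation scan is the
  hard guarantee: the background is resampled (bounded retries) until
  the domain scanner recovers exactly the planted annotation.
* :func:`make_family` — per-subgroup sequence families obtained by
  mutating a seed domain everywhere except the heptapeptide and the four
  zinc ligands, for classifier and phylogeny benchmarks.
* :func:`make_panel_ct` — replicate Ct tables for a gene panel with
  programmed fold-change profiles and Gaussian technical noise, plus a
  ready-made two-treatment study design (:func:`build_study_panel`)
  mirroring a pathogen-infection versus salicylic-acid time course over
  0/9/12/24/48 h with a flat reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_scan import (
    CANONICAL_HEPTAPEPTIDE,
    DEFAULT_GRAMMAR,
    FingerGrammar,
    parse_pattern,
    scan_domains,
    scan_heptapeptide,
)
from .expression import CT_COLUMNS, call_response

__all__ = [
    "BACKGROUND_ALPHABET",
    "FILLER_ALPHABET",
    "PlantedDomain",
    "PlantedMotif",
    "ProteinSpec",
    "PanelDesign",
    "make_protein",
    "make_family",
    "make_panel_ct",
    "build_study_panel",
    "STUDY_PANEL_GENES",
    "PATHOGEN_UNCHANGED",
    "PATHOGEN_REPRESSED",
    "SA_UNCHANGED",
]

#: 19 residues (no Trp) used for random background.
BACKGROUND_ALPHABET = "ACDEFGHIKLMNPQRSTVY"
#: 17 residues (no Trp, Cys, His) used inside planted elements.
FILLER_ALPHABET = "ADEFGIKLMNPQRSTVY"

_MOTIF_LITERALS = {
    "LXXLL": "LAALL",
    "LXLXLX": "LALALA",
    "HARF": "RTGHARFRRAP",
}


@dataclass(frozen=True)
class PlantedDomain:
    position: int
    pattern: str = "C-X4-C-X23-HXH"
    heptapeptide: str = CANONICAL_HEPTAPEPTIDE
    linker_len: int = 10

    def __post_init__(self):
        if len(self.heptapeptide) != 7:
            raise ValueError("heptapeptide must be 7 residues")
        if not 0 <= self.linker_len < 30:
            raise ValueError("linker must fit inside the 30-residue search window")
        parse_pattern(self.pattern)  # validates syntax

    @property
    def length(self) -> int:
        f = parse_pattern(self.pattern)
        return 7 + self.linker_len + 4 + f.spacer1 + f.spacer2 + f.spacer3


@dataclass(frozen=True)
class PlantedMotif:
    position: int
    motif: str
    literal: str | None = None

    def __post_init__(self):
        if self.motif not in _MOTIF_LITERALS:
            raise ValueError(f"unknown motif {self.motif!r}")

    @property
    def rendered(self) -> str:
        return self.literal if self.literal is not None else _MOTIF_LITERALS[self.motif]

    @property
    def length(self) -> int:
        return len(self.rendered)


@dataclass(frozen=True)
class ProteinSpec:
    protein_id: str
    length: int
    elements: tuple = ()
    seed: int = 0

    def __post_init__(self):
        spans = []
        for el in self.elements:
            span = (el.position, el.position + el.length)
            if span[0] < 0 or span[1] > self.length:
                raise ValueError(f"element {el} exceeds protein length {self.length}")
            spans.append(span)
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted elements overlap")


def _fill(rng: np.random.Generator, n: int, alphabet: str = FILLER_ALPHABET) -> str:
    if n == 0:
        return ""
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _render_domain(el: PlantedDomain, rng: np.random.Generator) -> str:
    f = parse_pattern(el.pattern)
    inter = "".join(
        c if c != "X" else _fill(rng, 1) for c in f.observed_intervening
    )
    return (
        el.heptapeptide
        + _fill(rng, el.linker_len)
        + "C"
        + _fill(rng, f.spacer1)
        + "C"
        + _fill(rng, f.spacer2)
        + "H"
        + inter
        + f.terminal_ligand
    )


def make_protein(
    spec: ProteinSpec,
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
    *,
    max_retries: int = 50,
) -> tuple[str, dict]:
    """Generate a protein with planted elements and its truth annotation.

    Returns ``(sequence, truth)`` where ``truth`` maps ``"domains"`` to
    ``(start, end, pattern, heptapeptide)`` tuples and ``"motifs"`` to
    ``(motif, start, matched)`` tuples.  Deterministic per spec (the
    seed lives in the spec).  Raises if post-validation keeps failing.
    """
    rng = np.random.default_rng(spec.seed)
    rendered = []
    for el in sorted(spec.elements, key=lambda e: e.position):
        rendered.append((el, _render_domain(el, rng) if isinstance(el, PlantedDomain) else el.rendered))

    truth = {"domains": [], "motifs": []}
    for el, text in rendered:
        if isinstance(el, PlantedDomain):
            truth["domains"].append(
                (el.position, el.position + el.length, el.pattern, el.heptapeptide)
            )
        else:
            truth["motifs"].append((el.motif, el.position, text))

    expected_hepta = sorted(start for start, *_ in truth["domains"])
    expected_domains = sorted((s, e, p) for s, e, p, _ in truth["domains"])

    for _attempt in range(max_retries):
        chars = list(_fill(rng, spec.length, BACKGROUND_ALPHABET))
        for el, text in rendered:
            chars[el.position : el.position + len(text)] = list(text)
        seq = "".join(chars)
        hits = scan_heptapeptide(seq, grammar.max_mismatch, require_invariant_w=grammar.require_invariant_w)
        if sorted(h.start for h in hits) != expected_hepta:
            continue
        found = scan_domains(seq, grammar, protein_id=spec.protein_id)
        if sorted((d.start, d.end, d.pattern) for d in found) != expected_domains:
            continue
        return seq, truth
    raise RuntimeError(
        f"could not generate a clean background for {spec.protein_id!r} "
        f"after {max_retries} attempts"
    )


def make_family(
    subgroup_seeds: dict[str, str],
    n_per: int,
    mutation_rate: float,
    seed: int = 0,
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
) -> list[tuple[str, str, str]]:
    """Mutated copies of each subgroup seed with truth labels.

    Each member carries i.i.d. substitutions at ``mutation_rate`` at
    every position except the heptapeptide and the four zinc-ligand
    positions of the seed's domain; substitutions draw from the filler
    alphabet (no Trp/Cys/His) so the domain stays detectable.  Returns
    ``(member_id, subgroup_label, sequence)`` triples.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    members = []
    for label in sorted(subgroup_seeds):
        seed_seq = subgroup_seeds[label]
        domains = scan_domains(seed_seq, grammar)
        if not domains:
            raise ValueError(f"subgroup seed {label!r} contains no detectable WRKY domain")
        protected = set()
        for d in domains:
            protected.update(range(d.hepta.start, d.hepta.end))
            protected.update(d.ligand_positions)
        for k in range(n_per):
            chars = list(seed_seq)
            for i in range(len(chars)):
                if i in protected:
                    continue
                if rng.random() < mutation_rate:
                    choices = [c for c in FILLER_ALPHABET if c != chars[i]]
                    chars[i] = choices[rng.integers(0, len(choices))]
            members.append((f"{label}_{k}", label, "".join(chars)))
    return members


@dataclass(frozen=True)
class PanelDesign:
    """Programmed fold-change design for a replicate Ct time course."""

    genes: tuple[str, ...]
    profiles: dict = field(default_factory=dict)  # (gene, treatment) -> {t: fold}
    replicates: int = 3
    noise_sd: float = 0.15
    baseline_ct: float = 24.0
    baseline_ref_ct: float = 20.0
    timepoints: tuple[int, ...] = (0, 9, 12, 24, 48)
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        for key, prof in self.profiles.items():
            for t, fold in prof.items():
                if fold <= 0:
                    raise ValueError(f"fold change must be positive ({key}, t={t})")
                if t not in self.timepoints:
                    raise ValueError(f"profile timepoint {t} not in design timepoints")

    def fold(self, gene: str, treatment: str, t: int) -> float:
        if t == 0:
            return 1.0
        return self.profiles.get((gene, treatment), {}).get(t, 1.0)

    def truth_calls(self, up_fold: float = 2.0, down_fold: float = 0.5) -> dict:
        """Noise-free calls implied by the programmed folds."""
        out = {}
        for (gene, treatment) in self.profiles:
            rq = {t: self.fold(gene, treatment, t) for t in self.timepoints}
            out[(gene, treatment)] = call_response(rq, up_fold, down_fold)[0]
        return out


def make_panel_ct(design: PanelDesign) -> pd.DataFrame:
    """Replicate Ct table for the design: Ct_target drops by log2(fold).

    ``ct_target = baseline - log2(fold) + N(0, sd)`` and the reference
    gene sits flat at its own baseline plus noise.  Deterministic per
    design seed.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    treatments = sorted({tr for (_, tr) in design.profiles})
    for gene in design.genes:
        for treatment in treatments:
            if (gene, treatment) not in design.profiles:
                continue
            for t in design.timepoints:
                fold = design.fold(gene, treatment, t)
                for rep in range(1, design.replicates + 1):
                    ct_t = design.baseline_ct - math.log2(fold)
                    ct_r = design.baseline_ref_ct
                    if design.noise_sd > 0:
                        ct_t += rng.normal(0.0, design.noise_sd)
                        ct_r += rng.normal(0.0, design.noise_sd)
                    rows.append((gene, treatment, t, rep, ct_t, ct_r))
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# -- the two-treatment study design ----------------------------------------

#: 28-gene expression panel.  The published panel enumeration prints 26
#: names (after normalizing two obvious typos); two further family
#: members pad it to the stated panel size of 28.
STUDY_PANEL_GENES = (
    "VvWRKY1-1",
    "VvWRKY2-1",
    "VvWRKY3",
    "VvWRKY6-1",
    "VvWRKY7-1",
    "VvWRKY11-4",
    "VvWRKY14",
    "VvWRKY18",
    "VvWRKY22-1",
    "VvWRKY28",
    "VvWRKY30",
    "VvWRKY32",
    "VvWRKY40",
    "VvWRKY41",
    "VvWRKY42",
    "VvWRKY45",
    "VvWRKY46",
    "VvWRKY48",
    "VvWRKY51",
    "VvWRKY53",
    "VvWRKY55",
    "VvWRKY65",
    "VvWRKY70-1",
    "VvWRKY70-2",
    "VvWRKY72",
    "VvWRKY74",
    "VvWRKY6-2",
    "VvWRKY47",
)

PATHOGEN_UNCHANGED = ("VvWRKY48", "VvWRKY51", "VvWRKY45")
PATHOGEN_REPRESSED = ("VvWRKY3", "VvWRKY41")
SA_UNCHANGED = ("VvWRKY41", "VvWRKY30", "VvWRKY42", "VvWRKY46", "VvWRKY70-1")

_INDUCED_PROFILE = {24: 8.0, 48: 4.0}
_REPRESSED_PROFILE = {24: 0.125, 48: 0.25}


def build_study_panel(
    seed: int = 0,
    *,
    noise_sd: float = 0.15,
    replicates: int = 3,
) -> PanelDesign:
    """The pathogen-vs-SA study design over the 28-gene panel.

    Under pathogen treatment three genes stay flat and two are
    repressed; under SA five stay flat; every other gene is induced
    (programmed peak fold 8 at 24 h, well above the 2-fold call
    threshold even with technical noise).
    """
    profiles = {}
    for gene in STUDY_PANEL_GENES:
        if gene in PATHOGEN_UNCHANGED:
            profiles[(gene, "pathogen")] = {}
        elif gene in PATHOGEN_REPRESSED:
            profiles[(gene, "pathogen")] = dict(_REPRESSED_PROFILE)
        else:
            profiles[(gene, "pathogen")] = dict(_INDUCED_PROFILE)
        if gene in SA_UNCHANGED:
            profiles[(gene, "SA")] = {}
        else:
            profiles[(gene, "SA")] = dict(_INDUCED_PROFILE)
    return PanelDesign(
        genes=STUDY_PANEL_GENES,
        profiles=profiles,
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )
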