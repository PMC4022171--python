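# wrkykit

A reusable, tested pipeline for annotating the grape (*Vitis* spp.) WRKY
transcription-factor family — and, more generally, for the rule-based
analyses that genome-wide WRKY surveys rely on.

WRKY proteins are plant transcription factors central to defense
signalling. Each carries one or two ~60-residue WRKY domains defined by
the near-invariant heptapeptide **WRKYGQK** followed by a zinc finger
whose ligands are spaced `C-X(a)-C-X(b)-H-X(c)-[H|C]`. The family
divides into group I (two domains), group II (one domain, C2H2 finger,
subgroups IIa–IIe) and group III (one domain, C2HC finger), and the
domain binds the W-box element `(C/T)TGAC(T/C)` in target promoters.

`wrkykit` packages this grammar and everything around it:

* **catalog** — a machine-readable catalog of the 80-protein grape WRKY
  family (names, GI labels, chromosome, length, pI, MW, species,
  group/subgroup, finger pattern) with count and range summaries;
* **domain_scan** — heptapeptide + zinc-finger-grammar domain detection,
  and parsing/formatting of pattern strings like `C-X4-C-X23-HXH`;
* **classify** — group I/II/III assignment from domain structure plus a
  rule-and-nearest-reference surrogate for group II subgroups;
* **motif_scan** — LXXLL (coactivator), LXLXLX (EAR-like repressor),
  HARF (`RTGHARFRR(A/G)P`, group IId), a leucine-zipper heptad
  heuristic, and W-box scanning on DNA (both strands);
* **properties** — length, average molecular weight, and isoelectric
  point by Henderson–Hasselbalch bisection;
* **phylo** — Needleman–Wunsch affine-gap alignment (BLOSUM62, gap
  open 10 / extend 0.5), p-distances, Saitou–Nei neighbor joining,
  1,000-replicate column bootstrap, newick serialization;
* **expression** — comparative-Ct (2^–ΔΔCt) relative quantification of
  replicate Ct tables and induced/repressed/unchanged response calls;
* **synthetic_data** — ground-truth generators: proteins with planted
  domains/motifs, mutated subgroup families, and programmed Ct panels.

## Worked example

Scan a synthetic protein with two planted domains
(`python examples/02_scan_domains.py`):

```
synthetic protein, 220 aa; planted domains: [(30, 79, 'C-X4-C-X23-HXH', 'WRKYGQK'), (140, 192, 'C-X7-C-X23-HTC', 'WRKYGQK')]
  found  30-79  heptapeptide=WRKYGQK pattern=C-X4-C-X23-HXH class=C2H2
  found 140-192 heptapeptide=WRKYGQK pattern=C-X7-C-X23-HTC class=C2HC
```

Both planted domains are recovered with exact boundaries; the first is a
C2H2 finger (groups I/II), the second the C2HC form diagnostic of group
III. Summarize the packaged catalog
(`python examples/01_catalog_summary.py`):

```
proteins in catalog: 80
per group: {'I': 18, 'III': 8, 'IIa': 7, 'IIb': 8, 'IIc': 22, 'IId': 9, 'IIe': 8}
length range: 127-798 aa
pI range: 4.7-9.84
Vv-prefixed C2HC (group III) members: 7
```

And run the simulated two-treatment qRT-PCR panel
(`python examples/07_expression_panel.py`):

```
panel size: 28
  pathogen: {'induced': 23, 'repressed': 2, 'unchanged': 3}  (altered: 25)
        SA: {'induced': 23, 'repressed': 0, 'unchanged': 5}  (altered: 23)
induced under both treatments: 19
```

25 of the 28 genes change after pathogen infection (23 up, 2 down), 23
are induced by salicylic acid, and the both-induced intersection follows
by exact set algebra. The `examples/` directory holds one short script
per capability; a `wrkykit` command-line interface mirrors the library
(`wrkykit scan`, `wrkykit classify`, `wrkykit motifs`, `wrkykit wbox`,
`wrkykit props`, `wrkykit phylo`, `wrkykit expr`, `wrkykit catalog`).

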