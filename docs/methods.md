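# Methods

This note records the models and procedures `wrkykit` implements, the
defaults it ships, and the reasoning behind the choices that were
genuinely open. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Domain detection

A WRKY domain is called when two features co-occur:

1. **Heptapeptide.** A 7-residue window within Hamming distance
   `max_mismatch` (default 1) of `WRKYGQK`. The leading Trp is required
   to be invariant by default — the natural variants (e.g. `WRKYGKK`)
   all preserve it — with a flag to relax. `X` counts as a mismatch.
2. **Zinc finger.** Downstream of the heptapeptide, the leftmost match
   of `C-X(a)-C-X(b)-H-X(c)-[H|C]`, with the first Cys required within
   a 30-residue linker window of the heptapeptide's end. Spacer ranges
   default to `a ∈ [4,8]`, `b ∈ [22,28]`, `c ∈ [1,2]` — the permissive
   union over every pattern the family catalog contains. (The narrower
   ranges sometimes quoted for the C2HC form would exclude the
   catalog's own group III rows, which are `C-X7-C-X23-HTC`.) Among
   overlapping candidates the smallest first-Cys position wins, then
   the smallest spacer1, spacer2, spacer3, making detection
   deterministic.

A terminal His gives finger class C2H2, a terminal Cys C2HC. Domains
whose total span exceeds 80 residues are rejected (the domain is ~60
residues; the bound is a guard, not a tuning knob). All heptapeptide
hits are retained at scan stage; each is greedily paired with its
leftmost finger, and domains strictly nested inside another are then
removed. Coordinates are 0-based half-open throughout; the CLI adds
1-based display columns implicitly via spans.

Detection is deliberately grammar-based — no profile HMM, no E-values.
That makes every call explainable by the pattern string it emits, at
the cost of ignoring position-specific conservation outside the
heptapeptide and ligands.

**Pattern strings.** `parse_pattern`/`format_pattern` round-trip the
catalog's notation (`C-X4-C-X23-HXH`, `C-X7-C-X23-HTC`). C2H2 fingers
print their intervening residue as the placeholder `X` (the catalog
convention); C2HC fingers interpolate the observed residue. Subscript
markup (underscores) is stripped before parsing.

## Group and subgroup assignment

Group assignment is purely structural: ≥2 domains → group I (N-most
labelled NTWD, C-most CTWD), a single C2HC domain → group III, a single
C2H2 domain → group II, none → unclassified.

Group II subgroups are defined phylogenetically in the literature; with
no fixed reference phylogeny in the package, subgrouping uses a
transparent surrogate and records which path fired:

1. spacer1 = 4 → IIc (every IIc catalog pattern is `C-X4-…`);
2. HARF (`RTGHARFRR[AG]P`) anywhere in the protein → IId, overriding
   rule 1 (HARF is the stronger, subgroup-specific signal);
3. otherwise 1-nearest-neighbour by global-alignment identity
   (matches / alignment length) against a user-supplied labelled
   reference set; ties break to the lexicographically smallest label.

On synthetic families mutated 10% away from per-subgroup seeds the 1-NN
layer recovers ≥90% of labels (seeded test); this measures the
surrogate's internal consistency, not agreement with phylogenetic
subgrouping of real proteins.

## Accessory motifs

`LXXLL` (L,any,any,L,L), `LXLXLX` (L at window offsets 0/2/4 — the
printed EAR-like form; stricter variants would be config additions),
and the literal HARF block. Scanners are exhaustive over positions,
case-insensitive, and report all overlapping hits. The leucine-zipper
predictor is an explicitly labelled heuristic (`LZ-heuristic`): maximal
runs of Leu (optionally Ile) at every 7th position, ≥4 heptads by
default. It is a periodicity check, not a coiled-coil model, and is not
expected to reproduce dedicated predictors. The W-box scanner matches
`[CT]TGAC[TC]` on both strands, `N` never matching; minus-strand hits
are reported at the plus-strand coordinate of the matched hexamer's
start.

## Physical properties

Molecular weight is the sum of average residue masses plus one water
(18.01524 Da). The isoelectric point solves net charge = 0 under
Henderson–Hasselbalch over the termini and D/E/C/Y/H/K/R, with the
EMBOSS pKa table as default (swappable dict). The charge is strictly
decreasing in pH, so bisection on [0, 14] converges; the interval is
narrowed to ~1e-9 pH units because on shallow charge curves the region
where |charge| < 1e-4 can span several hundredths of a pH unit — the
crossing itself is the quantity of interest. The catalog's printed pI
and MW columns cannot be recomputed (the catalog carries no sequences,
and the original computation's pKa set is unknown), so validation
against them is summary-level (min/max); the catalog stores printed
values verbatim, flagging physically implausible ones (one entry lists
3.9 kDa for a 278-residue protein) in an `anomaly` column.

## Phylogeny

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh),
BLOSUM62, gap open 10, extend 0.5; a gap of length L costs
`open + (L−1)·extend`. Traceback ties prefer substitution over gap in
the first sequence over gap in the second, so alignments are
deterministic. Distances are p-distances (mismatch fraction over
gap-free columns). Neighbor joining is the Saitou–Nei Q-criterion;
Q-ties break to the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest leaf label), and negative branch lengths
are clamped to zero with a warning — a standard presentation choice
that never affects topology. Trees are unrooted (trifurcation at the
final join); published figure rootings are presentation, not inference.

Multiple alignment, needed to give bootstrap columns a shared
coordinate system, is a small progressive aligner: NJ join order as
guide, profile-profile NW where a column pair scores the mean BLOSUM62
value over its gap-free residue pairs. On synthetic families it keeps
every pair's in-MSA identity within 0.05 of its direct pairwise
identity (tested); it is not a substitute for a production MSA program
on divergent real sequences.

The bootstrap resamples alignment columns with replacement (default
1,000 replicates, seeded NumPy generator), builds an NJ tree per
replicate, and counts how many replicates contain each internal
bipartition of the reference tree. Identical seeds give bit-identical
supports; a display threshold like 500/1000 belongs to reporting, never
to computation.

## Expression analysis

Relative quantity follows the comparative-Ct method: ΔCt = mean target
Ct − mean reference Ct per condition, ΔΔCt against the 0 h calibrator,
RQ = 2^−ΔΔCt (exactly 1 at the calibrator). Replicates average on the
Ct scale before differencing (common practice); a per-replicate mode
with geometric-mean aggregation is available and agrees exactly at zero
noise. When a mock-treatment series is present, RQs can additionally be
divided by the control's RQ at the same timepoint. RQ is invariant to
any constant Ct offset (tested), which is what makes the method
calibration-free.

No fold-change cutoff is inherited from anywhere authoritative, so the
calls use the conventional qRT-PCR thresholds: induced if any
post-treatment RQ ≥ 2, repressed if any RQ ≤ 0.5, else unchanged; if
both thresholds are crossed the larger |log2 RQ| decides, ties going to
induced. Thresholds are parameters, and each call records the
triggering timepoint. Panel summaries are exact set algebra over the
gene panel; genes covered under only one treatment are counted
per-treatment but excluded from the both-induced intersection, with a
logged warning. Primer-efficiency correction (Pfaffl) and melt-curve QC
are out of scope.

## Synthetic data: what it emulates and what it does not

`make_protein` plants domains (heptapeptide + linker + finger rendered
from a pattern string) and motif literals at fixed positions in random
background. Background residues are uniform over the 19 amino acids
excluding Trp, making accidental heptapeptides vanishingly rare;
fillers inside planted elements additionally exclude Cys and His so the
planted ligands are the leftmost grammar match. Neither choice is a
guarantee, so generation post-validates by running the scanner and
resamples the background (up to 50 tries) until exactly the planted
annotation is recovered. `make_family` mutates a seed everywhere except
the heptapeptide and ligand positions, substituting from the same
restricted alphabet so members stay detectable by construction.

The Ct generator writes `Ct_target = baseline − log2(fold) + N(0, sd)`
with a flat reference gene, triplicate wells, timepoints 0/9/12/24/48 h
and technical noise sd 0.15 cycles — a typical qRT-PCR replicate
spread. The bundled study design covers a 28-gene panel under two
treatments: after pathogen, 3 genes flat and 2 repressed (the remaining
23 induced); after salicylic acid, 5 genes flat (23 induced). Induced
genes peak at fold 8, repressed at 0.125, far enough from the 2-fold
thresholds that triplicates at sd 0.15 are called correctly with
overwhelming probability. The published panel enumeration prints only
26 names (and contains two obvious typos, normalized here); two further
family members pad the panel to its stated size of 28. The honest
both-induced intersection of this design is 19 genes — the source
survey prints "16 of 23" while listing 18 names; the package exposes
the set algebra and leaves the discrepancy documented rather than
resolved.

Passing these benchmarks shows the pipeline's arithmetic and rule
logic are correct on data matching its assumptions: uniform background
composition, exact motif literals, Gaussian Ct noise, no primer
efficiency drift. Real proteomes have biased composition (more
accidental motif hits), real domains drift beyond one heptapeptide
mismatch, and real qRT-PCR has correlated, non-Gaussian error; none of
that is simulated.

## Catalog conventions

The packaged TSV stores one line per domain; two-line group I rows
collapse into one entry with NTWD/CTWD records. The duplicated printed
row label `VvWRKY 13-1` (two distinct GI numbers) is normalized to
`VvWRKY13-1a`/`VvWRKY13-1b`, with the printed label kept in
`source_label`. Chromosome `∗` maps to `unknown`. Printed oddities —
the swapped `44C`/`44N` domain labels, a `72-2` label on the
`VvWRKY72-1` row, the implausible MW — are preserved verbatim and
flagged, never corrected. The source survey's internal inconsistencies
(a group I count of 19 in prose versus 18 two-domain table rows; prose
subgroup counts that disagree with its own summary table; a total of 72
versus the abstract's 80) are resolved in favour of the table itself,
which is what the fixture transcribes. The reference-gene primer pair
(EF1γ, accession AF176496) is stored as metadata constants only.

## Problem sizes

The test suite and acceptance script run at desk scale by choice:
1,000 random sequences (≤300 aa) for the scanner-vs-enumeration check,
100 random additive trees (4–8 taxa) for NJ recovery, a 5-taxon
alignment with 1,000-replicate bootstrap checked against a 10,000-rep
independent resampler (±3 support points), 100 random peptides for the
pI grid cross-check, and 100–200 generated proteins for planted-element
recovery. These sizes give exhaustive oracles room to stay exhaustive
while the whole suite completes in well under a minute.
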