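"""Scan a protein for accessory motifs and a promoter for W-boxes.

LXXLL marks coactivator capability, LXLXLX an EAR-like repressor,
HARF the group IId signature; the W-box (C/T)TGAC(T/C) is the DNA
element WRKY domains bind.
"""

from wrkykit.motif_scan import find_protein_motif, find_wbox, predict_leucine_zipper

protein = "MSTRTGHARFRRAPDDLAALLKEQSLALALALEHKT"
for motif in ("HARF", "LXXLL", "LXLXLX"):
    for hit in find_protein_motif(protein, motif, sequence_id="demo"):
        print(f"protein {motif:>6} at {hit.start:>2}: {hit.matched}")

zipper = ("L" + "AQRDEF") * 5
for region in predict_leucine_zipper(zipper, min_heptads=4):
    print(f"leucine-zipper heuristic: {region.n_heptads} heptads at {region.start}-{region.end}")

promoter = "GGTTGACTAAAGGTCAACC"  # one W-box per strand
for hit in find_wbox(promoter, sequence_id="promoter"):
    print(f"W-box on {hit.strand} strand at {hit.start}: {hit.matched}")
# Minus-strand positions are reported in plus-strand coordinates.
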