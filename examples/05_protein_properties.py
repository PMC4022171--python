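"""Length, molecular weight and isoelectric point from sequence.

MW sums average residue masses plus one water; pI is the pH where the
Henderson-Hasselbalch net charge crosses zero (EMBOSS pKa set).
"""

from wrkykit.properties import net_charge, protein_properties

for name, seq in (
    ("heptapeptide", "WRKYGQK"),
    ("acidic", "DDEEDDEE"),
    ("basic", "KKRRKKHH"),
):
    p = protein_properties(seq)
    print(
        f"{name:>12}: {p.length_aa:>2} aa  MW {p.mw_da:8.2f} Da  pI {p.pi:5.2f}"
        f"  (net charge there: {net_charge(seq, p.pi):+.1e})"
    )
# The residual charge at the reported pI is ~0 by construction; acidic
# compositions sit low, basic ones high.
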