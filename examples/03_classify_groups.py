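"""Assign family groups from domain structure.

Two domains -> group I; one C2HC domain -> group III; one C2H2 domain ->
group II, with the subgroup from the rule layer (spacer of 4 -> IIc,
HARF motif -> IId) or a nearest-reference fallback.
"""

from wrkykit.classify import assign_group, assign_subgroup
from wrkykit.domain_scan import scan_domains
from wrkykit.synthetic_data import PlantedDomain, PlantedMotif, ProteinSpec, make_protein

cases = {
    "two-domain": ProteinSpec(
        "two-domain", 260, (PlantedDomain(20), PlantedDomain(150)), seed=1
    ),
    "C2HC": ProteinSpec("C2HC", 120, (PlantedDomain(20, "C-X7-C-X23-HTC"),), seed=2),
    "spacer4": ProteinSpec("spacer4", 120, (PlantedDomain(20, "C-X4-C-X23-HXH"),), seed=3),
    "harf": ProteinSpec(
        "harf",
        160,
        (PlantedDomain(20, "C-X5-C-X23-HXH"), PlantedMotif(120, "HARF")),
        seed=4,
    ),
}

for name, spec in cases.items():
    seq, _ = make_protein(spec)
    domains = scan_domains(seq, protein_id=name)
    call = assign_group(domains, protein_id=name)
    subgroup = ""
    if call.group == "II":
        sub, ev = assign_subgroup(domains[0], full_seq=seq)
        subgroup = f" subgroup={sub} (rule: {ev.rule_fired})"
    print(f"{name:>10}: group {call.group}{subgroup}")
# group I from the domain count, III from the terminal Cys, II otherwise;
# the IIc/IId subgroups here fire from spacing and HARF rules alone.
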