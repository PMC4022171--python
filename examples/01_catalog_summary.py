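"""Load the packaged family catalog and print its census.

The catalog is a machine-readable transcription of the published grape
WRKY survey: 80 proteins with identity, chromosome, physical properties,
group/subgroup and zinc-finger pattern.
"""

from wrkykit.catalog import count_entries, load_catalog, summarize

entries = load_catalog()
s = summarize(entries)

print(f"proteins in catalog: {s.n_total}")
print("per group:", dict(sorted(s.per_group.items())))
print(f"length range: {s.length_min}-{s.length_max} aa")
print(f"pI range: {s.pi_min}-{s.pi_max}")
print("Vv-prefixed C2HC (group III) members:",
      count_entries(entries, finger_class="C2HC", name_prefix="Vv"))

# The group III count of 7 refers to V. vinifera/aestivalis 'Vv' names;
# VpWRKY1 (V. pseudoreticulata) is the eighth C2HC protein overall.
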