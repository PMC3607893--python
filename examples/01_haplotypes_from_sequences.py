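"""Call variants from raw control-region reads and collapse to haplotypes.

Builds a tiny simulated sample, pushes the emitted sequences through
alignment -> variant calling -> haplotype collapse, and prints the unique
haplotypes with their counts.
"""

import mitopop as mp

seqs, truth = mp.simulate_coalescent(
    mp.DemographicModel("constant", theta=3.0),
    mp.SimulationConfig(n=8, seed=42),
)

ref = mp.default_reference()
records = []
for sample_id, segments in seqs.items():
    variants = []
    for segment, seq in segments.items():
        pair = mp.align_to_reference(seq, ref, segment=segment)
        called, _partial = mp.call_variants(pair, ref=ref)
        variants.extend(called)
    records.append((sample_id, "POP", variants))

profiles = mp.collapse_haplotypes(records)

print(f"{len(records)} sequences collapsed into {len(profiles)} haplotypes:")
for p in profiles:
    labels = ", ".join(p.key) or "(reference haplotype)"
    print(f"  {p.id}  n={p.n:<2d}  {labels}")
print(
    "\nEach line is one unique variant set relative to the reference; "
    "n is how many sampled sequences carry it."
)
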