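"""Design a polyantigen cassette and address peptides in k-of-n pools.

Concatenates neoantigen windows (with and without Gly/Ser linkers) into a
cassette with exact coordinates, locates a candidate peptide and a
junction artifact, then assigns peptides unique 6-of-11 pool combinations
and deconvolves an activation pattern.
"""

from neoscreen import (
    assign_pools,
    build_window,
    deconvolve,
    design_cassette,
    enumerate_candidates,
    locate_peptide,
)

KRAS_N = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAG"
variants = [
    build_window(KRAS_N, 12, "G", "D", variant_id="KRAS_G12D"),
    build_window(KRAS_N, 12, "G", "V", variant_id="KRAS_G12V"),
    build_window(KRAS_N, 13, "G", "D", variant_id="KRAS_G13D"),
]
segments = [(v.variant_id, v.window_seq) for v in variants]
controls = [("pp65", "NLVPMVATV")]

no_linker = design_cassette(segments, linker="", controls=controls)
linker = design_cassette(segments, linker="GGSGGS", controls=controls)
print(f"no-linker cassette: {len(no_linker.full_seq)} aa; "
      f"linker cassette: {len(linker.full_seq)} aa")
print("coordinates (linker design):")
for sid, (start, end) in linker.coord_map.items():
    print(f"  {sid:10s} [{start:3d}, {end:3d}]")

nine_mer = enumerate_candidates(variants[0], lengths=[9])[0].sequence
print(f"\nlocating candidate {nine_mer}: {locate_peptide(nine_mer, no_linker)}")
junction = no_linker.full_seq[20:29]  # spans the G12D|G12V boundary
print(f"locating junction 9-mer {junction}: {locate_peptide(junction, no_linker)}")
print("(junction-spanning matches are concatenation artifacts, not neoepitopes)")

peptides = [c.sequence for v in variants for c in enumerate_candidates(v, lengths=[9])]
assignment = assign_pools(peptides, n_pools=11, k=6)
first = peptides[0]
combo = assignment[first]
print(f"\n{len(peptides)} peptides addressed in 6-of-11 pools "
      f"(capacity C(11,6) = 462)")
print(f"{first} -> pools {sorted(combo)}")
print(f"deconvolve(pools {sorted(combo)}) -> {deconvolve(combo, assignment)}")
union = assignment[peptides[0]] | assignment[peptides[1]]
print(f"two responders activate {sorted(union)}; subset mode recovers "
      f"{len(deconvolve(union, assignment, mode='subset'))} compatible peptides")
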