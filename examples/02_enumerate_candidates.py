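"""Enumerate mutation-spanning candidate neoepitopes for KRAS G12D.

Builds the ~25-aa mutant window around the substitution, lists every
8-11-mer covering the mutated residue, and expands a small variant set into
a screen manifest.
"""

from neoscreen import build_manifest, build_window, enumerate_candidates

# human KRAS, first 60 residues (wild type: glycine at position 12)
KRAS_N = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAG"

g12d = build_window(KRAS_N, 12, "G", "D", variant_id="KRAS_G12D")
print(f"window ({len(g12d.window_seq)} aa): {g12d.window_seq}")
print(f"mutated residue at window offset {g12d.mutation_offset}\n")

candidates = enumerate_candidates(g12d)
print(f"{len(candidates)} candidate neoepitopes (8+9+10+11 for an interior site):")
for cand in candidates[:6]:
    print(f"  {cand.sequence:11s}  mutation at peptide position {cand.mutation_pos_in_peptide}")
print("  ...")

g12v = build_window(KRAS_N, 12, "G", "V", variant_id="KRAS_G12V")
alleles = ["A*02:01", "A*03:01", "A*11:01", "B*07:02"]
manifest = build_manifest([g12d, g12v], alleles, excluded_alleles=["B*07:02"])
print(
    f"\nmanifest: {len(manifest)} unique (peptide, allele) pairs from 2 variants"
    f" x {len(alleles) - 1} retained alleles"
)
print(f"sequence collisions between overlapping variants: {manifest.n_sequence_collisions}")
print("(G12D and G12V windows differ at the mutant residue, so no collisions here)")
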