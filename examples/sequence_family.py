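"""Tetraspan-family comparison: percentages, NJ tree, hydropathy scan.

Runs the sequence track on the synthetic stand-in family (random sequences
carrying the family's documented divergence structure): pairwise identity
and strong-group similarity, a neighbor-joining tree on alignment
p-distances, and a Kyte-Doolittle scan for transmembrane segments.
"""

import sjtools as sj

records, truth = sj.synthetic_tetraspan_family(seed=0)
by_id = {r.id: r for r in records}
print("family members:", ", ".join(f"{r.id} ({len(r)} aa)" for r in records))

aln = sj.global_align(by_id["Pasi1_synth"], by_id["CG13288_synth"])
identity = sj.percent_identity(aln, denominator="shorter")
print(f"\nPasi1 vs CG13288: {identity:.1f}% identity "
      f"(planted {truth.identity_pasi1_cg13288_pct:.1f}%)")

similarity = sj.percent_similarity(truth.generating_alignment, denominator="shorter")
print(f"Pasi1 vs Pasi2:   {similarity:.1f}% similarity on the generating alignment "
      f"(planted {truth.similarity_pasi1_pasi2_pct:.1f}%)")

tree = sj.build_tree(records)
print("\nNJ tree (Newick):", str(tree).strip())
d_orth = tree.find("Pasi1_synth").distance(tree.find("Pasi1_ortholog_synth"))
d_p2 = tree.find("Pasi1_synth").distance(tree.find("Pasi2_synth"))
print(f"Pasi1 is closer to its ortholog ({d_orth:.2f}) than to Pasi2 ({d_p2:.2f}): "
      "the two founders separated anciently")

# hydropathy scan on a designed 4-pass membrane topology
tm = "ILVFILVFILVFILVFILVF"
linker = "DDRKNDQERKDDSNQERKDD"
toy = sj.ProteinRecord("toy_tetraspan", linker + (tm + linker) * 4)
scan = sj.hydropathy_segments(toy)
print(f"\nhydropathy scan of a designed tetraspan: {len(scan.segments)} TM segments "
      f"at {scan.segments}")
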