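"""Clade-wise conservation counting and mapping onto a structure.

Builds a multi-clade alignment with planted conserved sets, counts
absolutely conserved positions per clade, and paints 1-9 conservation bins
into B-factors of the synthetic receptor.
"""

from fivetm import conservation, synthetic
from fivetm.structure import write_structure

aln, truths = synthetic.make_clade_msa(seed=0)

for clade, label in [("mammal", "mammals"), ("avian", "avians/reptiles"), ("virus", "all viral")]:
    ids = [i for i in aln.ids if i.startswith(clade)]
    count, _ = conservation.absolute_conservation(aln, "ref_human", ids)
    print(f"absolutely conserved vs reference, {label:16s}: {count:3d} of 305 ({len(ids)} sequences)")

profile = conservation.identity_bins(aln, "ref_human")
print(f"identity bins span {profile.bins.min()}-{profile.bins.max()} over {len(profile.positions)} positions")

structure, _ = synthetic.make_toy_receptor()
painted = conservation.paint_conservation(structure, profile)
write_structure(painted, "conservation_painted.pdb")
print("wrote conservation_painted.pdb (B-factor = conservation bin, -1 unmapped)")
print()
print("'Absolutely conserved' means the aligned character equals the")
print("reference in every clade member; gaps count as mismatch. The 1-9")
print("bins are ceil(9 * identity fraction), the familiar colour scale.")
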