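"""Run the full static battery on a deposited coordinate file.

Usage:
    python 05_analyze_deposited_structure.py RECEPTOR.pdb CHAIN [ECD_REF.pdb ECD_CHAIN]

Point this at a crystal or cryo-EM structure of a full-length five-helix
receptor (e.g. a locally downloaded PDB entry) to measure: domain tilt,
membrane span, helix-III contacts, the W118/F119 ring pair, the Y184
hydrogen bonds, side-chain burials, hydrophobic layers, and, if a second
file is given, the Calpha RMSD of the shared extracellular-domain atoms.

Chain identifiers are deliberately user-supplied: deposited entries differ
in how they name receptor and antibody-fragment chains.
"""

import sys

import numpy as np

from fivetm import anatomy
from fivetm.geometry import buried_area, ring_geometry, superpose
from fivetm.structure import default_segment_map, read_structure, select

if len(sys.argv) < 3:
    sys.exit(__doc__)

path, chain = sys.argv[1], sys.argv[2]
structure = read_structure(path)
model = select(structure, chain=chain).first
seg = default_segment_map()
frame = anatomy.build_frame(model, seg)

print(f"ECD tilt             : {anatomy.ecd_tilt(model, frame):6.1f} deg")
print(f"membrane span        : {anatomy.helix_span(model, frame):6.1f} A")

contacts = anatomy.segment_contacts(model, seg, cutoff=3.5)
partners = sorted(({c.segment_a for c in contacts} | {c.segment_b for c in contacts}) - {"helix III"})
print(f"helix III contacts   : {len(contacts)} pairs with {partners}")

try:
    angle, dist = ring_geometry(model, 118, 119)
    print(f"W118/F119 ring pair  : {angle:5.1f} deg, centroids {dist:.1f} A apart")
except ValueError as exc:
    print(f"ring pair skipped    : {exc}")

for b in anatomy.hydrogen_bonds(model):
    for da, aa in ((b.donor_atom, b.acceptor_atom), (b.acceptor_atom, b.donor_atom)):
        if da[1] == 184 and da[2] == "OH":
            print(f"Y184 OH .. {aa[1]:3d} {aa[2]:3s}: {b.distance:.2f} A")

print(f"W118+F119 side-chain burial : {buried_area(model, [118, 119], side_chain_only=True):7.1f} A^2")
helix3 = [r for r in seg.residues('helix III')]
hydroph = [r for r in helix3 if (model.res_seq == r).any()
           and str(model.res_name[model.res_seq == r][0]) in anatomy.HYDROPHOBIC_RESIDUES]
print(f"helix III hydrophobic burial: {buried_area(model, hydroph, side_chain_only=True):7.1f} A^2")

if len(sys.argv) >= 5:
    other = select(read_structure(sys.argv[3]), chain=sys.argv[4]).first
    ours = model.subset(model.mask(atom_names=["CA"]))
    theirs = other.subset(other.mask(atom_names=["CA"]))
    ours_keys = {int(r): i for i, r in enumerate(ours.res_seq)}
    pairing = [(i, ours_keys[int(r)]) for i, r in enumerate(theirs.res_seq) if int(r) in ours_keys]
    _, rmsd = superpose(theirs.xyz, ours.xyz, pairing)
    print(f"Calpha RMSD vs {sys.argv[3]}: {rmsd:.2f} A over {len(pairing)} atoms")
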