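"""Static structural anatomy of a multi-helix membrane receptor.

Everything here is computed in a *membrane frame*: the center of mass of the
transmembrane-bundle backbone sits at the origin, the membrane normal is the
bundle's first principal axis (+z pointing extracellular, fixed by two
boundary reference residues), and the membrane mid-plane is z = 0. On top of
that frame the module measures the extracellular-domain tilt, inter-segment
contacts, hydrogen bonds and salt bridges (heavy-atom distance criteria,
suitable for crystal structures without hydrogens), the intracellular polar
network, hydrophobic core layering, the trans-membrane span, and helix kink
angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .geometry import BACKBONE_ATOMS, center_of_mass
from .structure import Model, SegmentMap

__all__ = [
    "MembraneFrame",
    "ContactRecord",
    "HBond",
    "build_frame",
    "ecd_tilt",
    "segment_contacts",
    "hydrogen_bonds",
    "salt_bridges",
    "ic_polar_network",
    "hydrophobic_layers",
    "helix_span",
    "kink_angle",
    "HYDROPHOBIC_RESIDUES",
    "DONOR_ATOMS",
    "ACCEPTOR_ATOMS",
]

#: Residues counted as hydrophobic in core-packing analyses.
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})

#: Heavy-atom hydrogen-bond donors per residue type (backbone N handled
#: separately; proline's backbone N has no amide hydrogen).
DONOR_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: Heavy-atom hydrogen-bond acceptors per residue type (backbone O/OXT
#: handled separately).
ACCEPTOR_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}


@dataclass
class MembraneFrame:
    """Membrane coordinate frame: origin, normal, and boundary references."""

    origin: np.ndarray
    z_axis: np.ndarray
    boundary_refs: tuple[int, int] = (123, 274)  # (extracellular, intracellular)
    x_axis: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_axis: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_axis = np.asarray(self.z_axis, float)
        self.z_axis = self.z_axis / np.linalg.norm(self.z_axis)
        if self.x_axis is None:
            # deterministic completion of the basis
            seed = np.array([1.0, 0.0, 0.0])
            if abs(self.z_axis @ seed) > 0.9:
                seed = np.array([0.0, 1.0, 0.0])
            x = seed - (seed @ self.z_axis) * self.z_axis
            self.x_axis = x / np.linalg.norm(x)
            self.y_axis = np.cross(self.z_axis, self.x_axis)

    def coords(self, xyz: np.ndarray) -> np.ndarray:
        """Lab coordinates -> frame coordinates (z along the normal)."""
        rel = np.atleast_2d(np.asarray(xyz, float)) - self.origin
        out = np.column_stack([rel @ self.x_axis, rel @ self.y_axis, rel @ self.z_axis])
        return out if np.asarray(xyz).ndim == 2 else out[0]

    def z_of(self, xyz: np.ndarray) -> np.ndarray | float:
        rel = np.asarray(xyz, float) - self.origin
        return rel @ self.z_axis


@dataclass
class ContactRecord:
    atom_a: tuple[str, int, str]  # (chain, res_seq, atom_name)
    atom_b: tuple[str, int, str]
    distance: float
    segment_a: str
    segment_b: str
    res_name_a: str = ""
    res_name_b: str = ""

    @property
    def contact_class(self) -> str:
        def is_c(name: tuple[str, int, str]) -> bool:
            return name[2].startswith("C")

        if is_c(self.atom_a) and is_c(self.atom_b):
            return "hydrophobic"
        if not is_c(self.atom_a) and not is_c(self.atom_b):
            return "polar"
        return "other"


@dataclass
class HBond:
    donor_atom: tuple[str, int, str]
    acceptor_atom: tuple[str, int, str]
    distance: float
    donor_res: str = ""
    acceptor_res: str = ""


def _ca_of(model: Model, res_seq: int, chain: str | None = None) -> np.ndarray:
    m = model.mask(chain=chain, residues=[res_seq], atom_names=["CA"])
    if not m.any():
        raise ValueError(f"Calpha of residue {res_seq} not present")
    return model.xyz[m][0]


def build_frame(model: Model, seg: SegmentMap, chain: str | None = None) -> MembraneFrame:
    """Membrane frame from the TM-bundle backbone.

    Origin: center of mass of backbone atoms (N, CA, C, O) of every helix
    segment. Normal: their first principal axis, sign-fixed so that the
    extracellular boundary reference (residue 123 by default) has z greater
    than the intracellular one (residue 274).
    """
    prot = model.heavy_protein()
    if chain is not None:
        prot = prot.subset(prot.mask(chain=chain))
    helix_res: list[int] = []
    for name in seg.helices():
        helix_res.extend(seg.residues(name))
    bb = prot.subset(prot.mask(residues=helix_res, atom_names=list(BACKBONE_ATOMS[:4])))
    if bb.n_atoms < 12:
        raise ValueError("too few TM backbone atoms to define a membrane frame")
    origin = center_of_mass(bb, weighting="mass")
    centred = bb.xyz - bb.xyz.mean(axis=0)
    cov = centred.T @ centred
    eigval, eigvec = np.linalg.eigh(cov)
    z = eigvec[:, np.argmax(eigval)]
    ec, ic = 123, 274
    z_ec = (_ca_of(prot, ec) - origin) @ z
    z_ic = (_ca_of(prot, ic) - origin) @ z
    if z_ec < z_ic:
        z = -z
    return MembraneFrame(origin=origin, z_axis=z, boundary_refs=(ec, ic))


def ecd_tilt(
    model: Model,
    frame: MembraneFrame,
    tip_residues: Iterable[int] = range(32, 37),
    chain: str | None = None,
) -> float:
    """Tilt (degrees, [0, 90]) of the extracellular domain.

    Angle between the vector from the frame origin to the center of mass of
    the Calpha atoms of the domain-tip residues (32-36 by default, the
    beta-hairpin tip) and the membrane plane z = 0.
    """
    tip_residues = list(tip_residues)
    m = model.mask(chain=chain, residues=tip_residues, atom_names=["CA"])
    present = set(int(r) for r in model.res_seq[m])
    missing = sorted(set(tip_residues) - present)
    if missing:
        raise ValueError(f"tip residues missing Calpha: {missing}")
    tip = model.subset(m)
    com = center_of_mass(tip, weighting="mass")
    v = com - frame.origin
    v = v / np.linalg.norm(v)
    return float(np.degrees(np.arcsin(np.clip(abs(v @ frame.z_axis), 0.0, 1.0))))


def segment_contacts(
    model: Model,
    seg: SegmentMap,
    target: str = "helix III",
    cutoff: float = 3.5,
) -> list[ContactRecord]:
    """Heavy-atom contacts between ``target`` and every other named segment.

    Pairs within the same segment are excluded, as are bonded neighbours
    (|delta res_seq| <= 1 within a chain). ``cutoff`` should lie in the
    3-5 A window typical for contact reporting.
    """
    if target not in seg:
        raise ValueError(f"unknown segment {target!r}; known: {list(seg)}")
    prot = model.heavy_protein()
    seg_of = np.array([seg.segment_of(int(r)) for r in prot.res_seq], dtype=object)
    in_any = seg_of != None  # noqa: E711  (elementwise)
    sub = prot.subset(in_any)
    seg_sub = seg_of[in_any]
    is_target = seg_sub == target
    if not is_target.any():
        return []
    tree = cKDTree(sub.xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    records: list[ContactRecord] = []
    for i, j in pairs:
        si, sj = seg_sub[i], seg_sub[j]
        if si == sj:
            continue
        if si != target and sj != target:
            continue
        if si != target:
            i, j, si, sj = j, i, sj, si
        if sub.chain[i] == sub.chain[j] and abs(int(sub.res_seq[i]) - int(sub.res_seq[j])) <= 1:
            continue
        d = float(np.linalg.norm(sub.xyz[i] - sub.xyz[j]))
        a = (str(sub.chain[i]), int(sub.res_seq[i]), str(sub.atom_name[i]))
        b = (str(sub.chain[j]), int(sub.res_seq[j]), str(sub.atom_name[j]))
        if b < a:  # canonical ordering within the record
            a, b, si, sj = b, a, sj, si
            rn_a, rn_b = str(sub.res_name[j]), str(sub.res_name[i])
        else:
            rn_a, rn_b = str(sub.res_name[i]), str(sub.res_name[j])
        records.append(ContactRecord(a, b, d, si, sj, rn_a, rn_b))
    records.sort(key=lambda r: (r.atom_a, r.atom_b))
    return records


def _donor_acceptor_masks(model: Model) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_atoms
    don = np.zeros(n, dtype=bool)
    acc = np.zeros(n, dtype=bool)
    for i in range(n):
        rn = str(model.res_name[i])
        an = str(model.atom_name[i])
        if an == "N" and rn != "PRO":
            don[i] = True
        if an in ("O", "OXT"):
            acc[i] = True
        if an in DONOR_ATOMS.get(rn, ()):
            don[i] = True
        if an in ACCEPTOR_ATOMS.get(rn, ()):
            acc[i] = True
    return don, acc


def hydrogen_bonds(
    model: Model,
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
    cutoff: float = 3.5,
    min_distance: float = 2.2,
) -> list[HBond]:
    """Heavy-atom donor-acceptor pairs with 2.2 A <= d <= cutoff.

    No angular criterion is applied: the intended inputs are crystal
    structures without explicit hydrogens. ``donors``/``acceptors`` are
    optional boolean masks over the atoms of ``model.heavy_protein()``
    restricting each side; by default a residue-dictionary typing is used.
    """
    prot = model.heavy_protein()
    for name, m in (("donors", donors), ("acceptors", acceptors)):
        if m is not None and len(m) != prot.n_atoms:
            raise ValueError(f"{name} mask must cover the heavy-protein view ({prot.n_atoms} atoms)")
    auto_don, auto_acc = _donor_acceptor_masks(prot)
    if donors is not None:
        auto_don &= donors
    if acceptors is not None:
        auto_acc &= acceptors
    di = np.flatnonzero(auto_don)
    ai = np.flatnonzero(auto_acc)
    if len(di) == 0 or len(ai) == 0:
        return []
    tree = cKDTree(prot.xyz[ai])
    bonds: list[HBond] = []
    for i in di:
        for k in tree.query_ball_point(prot.xyz[i], cutoff):
            j = ai[k]
            if i == j:
                continue
            if prot.chain[i] == prot.chain[j] and prot.res_seq[i] == prot.res_seq[j]:
                continue  # intra-residue pairs are not hydrogen bonds
            d = float(np.linalg.norm(prot.xyz[i] - prot.xyz[j]))
            if min_distance <= d <= cutoff:
                bonds.append(
                    HBond(
                        (str(prot.chain[i]), int(prot.res_seq[i]), str(prot.atom_name[i])),
                        (str(prot.chain[j]), int(prot.res_seq[j]), str(prot.atom_name[j])),
                        d,
                        str(prot.res_name[i]),
                        str(prot.res_name[j]),
                    )
                )
    bonds.sort(key=lambda b: (b.donor_atom, b.acceptor_atom))
    return bonds


def salt_bridges(model: Model, cutoff: float = 4.0) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
    """Acid/base residue pairs whose minimal side-chain O-N distance is
    within ``cutoff``. Returns ((chain, acidic res), (chain, basic res), d)."""
    prot = model.heavy_protein()
    acids: dict[tuple[str, int], list[int]] = {}
    bases: dict[tuple[str, int], list[int]] = {}
    for i in range(prot.n_atoms):
        rn = str(prot.res_name[i])
        an = str(prot.atom_name[i])
        key = (str(prot.chain[i]), int(prot.res_seq[i]))
        if an in _ACIDIC_ATOMS.get(rn, ()):
            acids.setdefault(key, []).append(i)
        if an in _BASIC_ATOMS.get(rn, ()):
            bases.setdefault(key, []).append(i)
    out = []
    for akey, aidx in sorted(acids.items()):
        for bkey, bidx in sorted(bases.items()):
            d = np.linalg.norm(prot.xyz[aidx][:, None, :] - prot.xyz[bidx][None, :, :], axis=-1).min()
            if d <= cutoff:
                out.append((akey, bkey, float(d)))
    return out


def ic_polar_network(
    model: Model,
    members: Iterable[int] = (141, 145, 206, 227, 264),
    cutoff: float = 3.5,
) -> tuple[list[HBond], list[set[int]]]:
    """Side-chain polar contacts among the intracellular network members.

    Returns the member-to-member side-chain hydrogen bonds plus the connected
    components (sets of residue numbers) they induce. Missing members produce
    a warning, not an error.
    """
    members = sorted(set(int(m) for m in members))
    prot = model.heavy_protein()
    present = [m for m in members if (prot.res_seq == m).any()]
    missing = sorted(set(members) - set(present))
    if missing:
        warnings.warn(f"polar-network members not modelled: {missing}")
    side = ~np.isin(prot.atom_name, BACKBONE_ATOMS)
    member_side = side & np.isin(prot.res_seq, present)
    bonds = hydrogen_bonds(prot, donors=member_side, acceptors=member_side, cutoff=cutoff)
    # connected components over residues (union-find)
    parent = {m: m for m in present}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in bonds:
        ra, rb = b.donor_atom[1], b.acceptor_atom[1]
        parent[find(ra)] = find(rb)
    comps: dict[int, set[int]] = {}
    for m in present:
        comps.setdefault(find(m), set()).add(m)
    components = sorted((c for c in comps.values()), key=min)
    return bonds, components


def hydrophobic_layers(
    model: Model,
    frame: MembraneFrame,
    seg: SegmentMap,
    gap_threshold: float = 3.0,
) -> list[dict]:
    """Layering of core-facing hydrophobic side chains along the membrane
    normal.

    A residue is *core-facing* when its side-chain center of mass lies
    nearer the bundle axis than its Calpha. Core-facing hydrophobic residues
    are clustered along z by single-linkage with a ``gap_threshold`` break;
    layers are numbered from the extracellular side (layer 1 = highest z).

    All modelled residues participate (loop residues can and do join the
    outermost layer); ``segment`` is annotated from the map where a residue
    falls in a named range. Returns one record per hydrophobic residue that
    has both a Calpha and side-chain atoms:
    ``{chain, res_seq, res_name, segment, core_facing, z, layer}`` with
    ``layer = None`` for outward-facing residues.
    """
    prot = model.heavy_protein()
    records: list[dict] = []
    for res in sorted(set(int(r) for r in prot.res_seq)):
        m = prot.mask(residues=[res])
        sub = prot.subset(m)
        rn = str(sub.res_name[0])
        if rn not in HYDROPHOBIC_RESIDUES:
            continue
        ca_m = sub.mask(atom_names=["CA"])
        sc_m = ~np.isin(sub.atom_name, BACKBONE_ATOMS)
        if not ca_m.any() or not sc_m.any():
            continue
        ca = frame.coords(sub.xyz[ca_m][0])
        sc = frame.coords(sub.subset(sc_m).xyz.mean(axis=0))
        r_ca = float(np.hypot(ca[0], ca[1]))
        r_sc = float(np.hypot(sc[0], sc[1]))
        records.append(
            {
                "chain": str(sub.chain[0]),
                "res_seq": int(res),
                "res_name": rn,
                "segment": seg.segment_of(res),
                "core_facing": r_sc < r_ca,
                "z": float(sc[2]),
                "layer": None,
            }
        )
    core = sorted((r for r in records if r["core_facing"]), key=lambda r: -r["z"])
    layer = 0
    prev_z = None
    for rec in core:
        if prev_z is None or prev_z - rec["z"] > gap_threshold:
            layer += 1
        rec["layer"] = layer
        prev_z = rec["z"]
    return records


def helix_span(model: Model, frame: MembraneFrame) -> float:
    """Extent (A) along the membrane normal between the boundary reference
    residues: z(Calpha of the extracellular ref) - z(Calpha intracellular)."""
    prot = model.heavy_protein()
    ec, ic = frame.boundary_refs
    return float(frame.z_of(_ca_of(prot, ec)) - frame.z_of(_ca_of(prot, ic)))


def _oriented_axis(xyz: np.ndarray) -> np.ndarray:
    """Principal axis of an ordered Calpha trace, oriented start-to-end.

    The trace is first averaged over a one-turn window (four residues) so
    the helical spiral does not bias the axis of short segments; straight
    traces are unaffected.
    """
    if len(xyz) >= 6:
        kernel = 4
        csum = np.vstack([np.zeros(3), np.cumsum(xyz, axis=0)])
        xyz = (csum[kernel:] - csum[:-kernel]) / kernel
    centred = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    if axis @ (xyz[-1] - xyz[0]) < 0:
        axis = -axis
    return axis


def kink_angle(
    model: Model,
    seg: SegmentMap,
    helix: str = "helix I",
    pivot: int = 131,
    min_arm: int = 4,
) -> float:
    """Kink (degrees) at ``pivot``: the angle between the principal axes of
    the Calpha sets before and after the pivot within the helix."""
    prot = model.heavy_protein()
    a, b = seg[helix]
    cas = prot.subset(prot.mask(residues=range(a, b + 1), atom_names=["CA"]))
    order = np.argsort(cas.res_seq)
    res = cas.res_seq[order]
    xyz = cas.xyz[order]
    before = xyz[res < pivot]
    after = xyz[res > pivot]
    if len(before) < min_arm or len(after) < min_arm:
        raise ValueError(
            f"kink at {pivot} needs >= {min_arm} residues each side "
            f"(got {len(before)}/{len(after)})"
        )
    ax1 = _oriented_axis(before)
    ax2 = _oriented_axis(after)
    return float(np.degrees(np.arccos(np.clip(ax1 @ ax2, -1.0, 1.0))))
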