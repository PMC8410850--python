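"""Synthetic inputs with known ground truth for every analysis in the package.

The centrepiece is a toy receptor: five ideal, vertical transmembrane
helices on a pentagonal cross-section (standard alpha-helix geometry,
1.5 A rise and 100 deg twist per residue), residue-numbered to match the
default segment table, plus a rigid pseudo-extracellular-domain whose tip
is *placed* so the tilt metric equals the requested angle by construction.
An extracellular-loop cluster plants the remaining measurable geometry at
prescribed values: a tryptophan/phenylalanine ring pair at a chosen
interplanar angle, a tyrosine hydroxyl at hydrogen-bond distances from a
backbone carbonyl and a backbone amide, a glutamate/lysine salt bridge, and
a top layer of inward-pointing hydrophobic side chains. The defaults plant
the geometry of the crystallographic study conditions: an 80 deg domain
tilt, a 45 deg edge-to-face ring pair, 2.9/3.0 A hydrogen bonds, a 32 A
boundary-to-boundary span, and the {127, 179, 192, 238, 253} membership of
the outermost hydrophobic layer.

Every generator is bit-reproducible for a fixed seed, and every ground
truth record carries enough to check the downstream operation without
re-deriving it. None of this is physically realistic (no force field, no
membrane) — the generators target geometric and statistical structure only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import anatomy
from .hdx import D2O_FRACTION, HDXPeptide, UptakeRecord
from .conservation import Alignment
from .structure import Model, Structure, default_segment_map

__all__ = [
    "ToyReceptorSpec",
    "ToyReceptorTruth",
    "make_toy_receptor",
    "make_kinked_helix",
    "make_contact_fixture",
    "TwoStateTrajSpec",
    "TwoStateTruth",
    "make_trajectory",
    "make_tilt_trajectory",
    "default_hdx_design",
    "make_hdx_tables",
    "make_msa",
    "make_clade_msa",
]

_CHAIN = "A"

# helix name -> (start, end, z at start, dz per residue, pentagon vertex index)
# z-centers are balanced around the pentagon so the bundle's first principal
# axis stays near the lab vertical while keeping the boundary references
# (E123 at z = +16, V274 at z = -16) 32 A apart
_HELIX_LAYOUT = {
    "helix I": (121, 140, 19.0, -1.5, 0),
    "helix II": (160, 178, -13.0, 1.5, 1),
    "helix III": (186, 207, 15.9, -1.5, 2),
    "helix IV": (224, 242, -8.3, 1.5, 3),
    "helix V": (251, 278, 18.5, -1.5, 4),
}
_PENTAGON_RADIUS = 8.0
_TWIST_DEG = 100.0
# backbone atom -> (radius, phase offset deg, z offset) on the helical path
_BB_OFFSETS = {"N": (1.6, -26.0, -0.6), "CA": (2.3, 0.0, 0.0), "C": (2.0, 21.0, 0.55), "O": (2.0, 23.0, 1.6)}

_SPECIAL_NAMES = {123: "GLU", 127: "ILE", 187: "LYS", 274: "VAL"}

#: Planted members of the outermost hydrophobic layer and the z of their
#: side-chain centroids (clustered within the 3 A single-linkage gap).
_TOP_LAYER = {127: 12.0, 179: 13.0, 192: 10.5, 238: 11.5, 253: 13.0}

_TRP_RING = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _element_of(atom_name: str) -> str:
    return atom_name[0]


class _Builder:
    def __init__(self) -> None:
        self.rows: list[tuple[str, int, str, str, np.ndarray]] = []

    def add(self, res_seq: int, res_name: str, atom_name: str, xyz) -> None:
        self.rows.append((res_name, res_seq, atom_name, _element_of(atom_name), np.asarray(xyz, float)))

    def model(self) -> Model:
        order = sorted(range(len(self.rows)), key=lambda k: (self.rows[k][1], k))
        rows = [self.rows[k] for k in order]
        n = len(rows)
        return Model(
            chain=np.array([_CHAIN] * n, dtype=object),
            res_seq=np.array([r[1] for r in rows], dtype=int),
            icode=np.array([""] * n, dtype=object),
            res_name=np.array([r[0] for r in rows], dtype=object),
            atom_name=np.array([r[2] for r in rows], dtype=object),
            element=np.array([r[3] for r in rows], dtype=object),
            xyz=np.array([r[4] for r in rows], dtype=float),
            occupancy=np.ones(n),
            bfactor=np.zeros(n),
            het=np.zeros(n, dtype=bool),
        )


@dataclass
class ToyReceptorSpec:
    """Construction parameters of the toy receptor (all planted truths)."""

    tilt_deg: float = 80.0
    ecd_distance: float = 40.0
    ring_angle_deg: float = 45.0
    ring_centroid_distance: float = 5.0
    hbond_distances: tuple[float, float] = (2.9, 3.0)
    saltbridge_distance: float = 3.0
    plant_top_layer: bool = True
    extra_tiers: tuple[float, ...] = ()
    sidechains: str = "none"  # "none" | "out" (outward CB on every helix residue)
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_deg <= 90.0:
            raise ValueError("tilt must be in [0, 90] degrees")
        if self.sidechains not in ("none", "out"):
            raise ValueError("sidechains must be 'none' or 'out'")


@dataclass
class ToyReceptorTruth:
    tilt_deg: float
    span: float
    ring_angle_deg: float
    ring_centroid_distance: float
    hbonds: dict[tuple[int, str, int, str], float]
    saltbridge: tuple[int, int, float]
    layers: dict[int, set[int]]
    boundary_refs: tuple[int, int] = (123, 274)


def _helix_phase(start: int, i: int, vertex: int) -> float:
    return np.radians(_TWIST_DEG * (i - start) + 72.0 * vertex)


def _vertex_xy(k: int) -> np.ndarray:
    ang = np.radians(90.0 + 72.0 * k)
    return _PENTAGON_RADIUS * np.array([np.cos(ang), np.sin(ang)])


def _backbone_atom(name: str, start: int, i: int, z0: float, dz: float, vertex: int) -> np.ndarray:
    r, dphi, dzoff = _BB_OFFSETS[name]
    phi = _helix_phase(start, i, vertex) + np.radians(dphi)
    vx, vy = _vertex_xy(vertex)
    return np.array([vx + r * np.cos(phi), vy + r * np.sin(phi), z0 + dz * (i - start) + dzoff])


def _ring_coords(centroid: np.ndarray, b1: np.ndarray, b2: np.ndarray, n_atoms: int) -> list[np.ndarray]:
    # both shells are rotationally symmetric, so the atom centroid is exact
    coords = []
    for k in range(min(n_atoms, 6)):
        ang = np.radians(60.0 * k)
        coords.append(centroid + 1.39 * (np.cos(ang) * b1 + np.sin(ang) * b2))
    for k in range(n_atoms - 6):
        ang = np.radians(120.0 * k)
        coords.append(centroid + 2.4 * (np.cos(ang) * b1 + np.sin(ang) * b2))
    return coords


def make_toy_receptor(spec: ToyReceptorSpec | None = None, **overrides) -> tuple[Structure, ToyReceptorTruth]:
    """Build the toy receptor; see the module docstring for the layout."""
    spec = spec or ToyReceptorSpec(**overrides)
    b = _Builder()

    def res_name_of(i: int) -> str:
        return _SPECIAL_NAMES.get(i, "LEU")

    for name, (start, end, z0, dz, vtx) in _HELIX_LAYOUT.items():
        for i in range(start, end + 1):
            for an in ("N", "CA", "C", "O"):
                b.add(i, res_name_of(i), an, _backbone_atom(an, start, i, z0, dz, vtx))

    # residue 179 (first extracellular-loop residue) continues the helix II path
    start, _, z0, dz, vtx = _HELIX_LAYOUT["helix II"]
    for an in ("N", "CA", "C", "O"):
        b.add(179, "PHE", an, _backbone_atom(an, start, 179, z0, dz, vtx))

    helix_of: dict[int, str] = {}
    for name, (start, end, *_rest) in _HELIX_LAYOUT.items():
        for i in range(start, end + 1):
            helix_of[i] = name
    helix_of[179] = "helix II"

    def ca_lab(i: int) -> np.ndarray:
        name = helix_of[i]
        start, _, z0, dz, vtx = _HELIX_LAYOUT[name]
        return _backbone_atom("CA", start, i, z0, dz, vtx)

    def inward_sidechain(i: int, sc_z: float) -> None:
        ca = ca_lab(i)
        radial = np.array([ca[0], ca[1], 0.0])
        u = -radial / np.linalg.norm(radial)  # toward the bundle axis
        rn = res_name_of(i) if i != 179 else "PHE"
        b.add(i, rn, "CB", ca + 1.0 * u + np.array([0, 0, sc_z - ca[2] - 0.3]))
        b.add(i, rn, "CG", ca + 2.3 * u + np.array([0, 0, sc_z - ca[2] + 0.3]))

    layers: dict[int, set[int]] = {}
    planted: set[int] = set()
    if spec.plant_top_layer:
        for i, sc_z in _TOP_LAYER.items():
            inward_sidechain(i, sc_z)
            planted.add(i)
        layers[1] = set(_TOP_LAYER)
    for t, tier_z in enumerate(sorted(spec.extra_tiers, reverse=True)):
        members = set()
        for name, (start, end, z0, dz, vtx) in _HELIX_LAYOUT.items():
            candidates = [
                i for i in range(start, end + 1)
                if i not in planted and res_name_of(i) in anatomy.HYDROPHOBIC_RESIDUES
            ]
            if not candidates:
                continue
            i = min(candidates, key=lambda i: abs(z0 + dz * (i - start) - tier_z))
            inward_sidechain(i, tier_z)
            planted.add(i)
            members.add(i)
        layers[len(layers) + 1] = members
    if spec.sidechains == "out":
        for i in helix_of:
            if i in planted or res_name_of(i) not in anatomy.HYDROPHOBIC_RESIDUES:
                continue
            ca = ca_lab(i)
            radial = np.array([ca[0], ca[1], 0.0])
            u = radial / np.linalg.norm(radial)  # away from the axis
            rn = res_name_of(i) if i != 179 else "PHE"
            b.add(i, rn, "CB", ca + 1.5 * u)

    # frame of the bundle so far: the pseudo-ECD and loop cluster are placed
    # in that frame, which makes the planted angles exact by construction
    frame = anatomy.build_frame(b.model(), default_segment_map())
    o, xa, ya, za = frame.origin, frame.x_axis, frame.y_axis, frame.z_axis

    def lab(x: float, y: float, z: float) -> np.ndarray:
        return o + x * xa + y * ya + z * za

    # pseudo-ECD: Calpha cross centred exactly on the planted tip direction
    t = np.radians(spec.tilt_deg)
    u = np.cos(t) * xa + np.sin(t) * za
    tip = o + spec.ecd_distance * u
    for res, (dx, dy) in zip(range(32, 37), [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]):
        b.add(res, "ALA", "CA", tip + dx * xa + dy * ya)
    b.add(20, "ALA", "CA", o + 0.70 * spec.ecd_distance * u)
    b.add(45, "ALA", "CA", o + 0.85 * spec.ecd_distance * u)

    # ring pair: tryptophan plane normal along x, phenylalanine plane tilted
    cen1 = lab(-9.0, 0.0, 22.0)
    for an, pos in zip(_TRP_RING, _ring_coords(cen1, ya, za, 9)):
        b.add(118, "TRP", an, pos)
    cen2 = cen1 + spec.ring_centroid_distance * ya
    n2 = np.cos(np.radians(spec.ring_angle_deg)) * xa + np.sin(np.radians(spec.ring_angle_deg)) * za
    b2 = np.cross(n2, ya)
    for an, pos in zip(_PHE_RING, _ring_coords(cen2, ya, b2, 6)):
        b.add(119, "PHE", an, pos)

    # tyrosine switch residue: hydroxyl at planted hydrogen-bond distances
    d_co, d_nh = spec.hbond_distances
    h4_start, _, h4_z0, h4_dz, h4_vtx = _HELIX_LAYOUT["helix IV"]
    o242_lab = _backbone_atom("O", h4_start, 242, h4_z0, h4_dz, h4_vtx)
    oh = o242_lab + d_co * za
    b.add(184, "TYR", "OH", oh)
    b.add(184, "TYR", "CB", oh + 1.5 * xa)
    vx, vy = _vertex_xy(3)
    w = np.array([vx, vy, 0.0])
    w = (w @ xa) * xa + (w @ ya) * ya
    w = w / np.linalg.norm(w)
    n244 = oh + d_nh * w
    b.add(244, "ALA", "N", n244)
    b.add(244, "ALA", "CA", n244 + 1.45 * w)

    # glutamate/lysine salt bridge between the loop and the central helix
    ca187 = ca_lab(187)
    radial = np.array([ca187[0], ca187[1], 0.0])
    uout = radial / np.linalg.norm(radial)
    nz = ca187 + 3.4 * uout
    b.add(187, "LYS", "NZ", nz)
    oe1 = nz + spec.saltbridge_distance * np.array([0.0, 0.0, 1.0])
    b.add(183, "GLU", "OE1", oe1)
    b.add(183, "GLU", "OE2", oe1 + np.array([0.0, 1.1, 0.6]))
    b.add(183, "GLU", "CD", oe1 + np.array([0.0, 0.6, -0.9]))

    model = b.model()
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        model = model.with_xyz(model.xyz + rng.normal(0.0, spec.jitter_sd, model.xyz.shape))

    truth = ToyReceptorTruth(
        tilt_deg=spec.tilt_deg,
        span=32.0,
        ring_angle_deg=spec.ring_angle_deg,
        ring_centroid_distance=spec.ring_centroid_distance,
        hbonds={
            (184, "OH", 242, "O"): d_co,
            (244, "N", 184, "OH"): d_nh,
        },
        saltbridge=(183, 187, spec.saltbridge_distance),
        layers=layers,
    )
    return Structure(models=[model], source_id="toy-receptor"), truth


def make_kinked_helix(kink_deg: float = 30.0, pivot: int = 131, arm: int = 8) -> tuple[Model, float]:
    """Calpha trace of a helix with a planted kink at ``pivot``.

    Both arms are straight 1.5 A/residue traces, so the principal-axis kink
    equals ``kink_deg`` exactly. Residues span pivot-arm .. pivot+arm.
    """
    b = _Builder()
    k = np.radians(kink_deg)
    axis1 = np.array([0.0, 0.0, 1.0])
    axis2 = np.array([0.0, np.sin(k), np.cos(k)])
    apex = np.zeros(3)
    for i in range(pivot - arm, pivot + arm + 1):
        if i <= pivot:
            pos = apex - (pivot - i) * 1.5 * axis1
        else:
            pos = apex + (i - pivot) * 1.5 * axis2
        b.add(i, "LEU", "CA", pos)
    return b.model(), kink_deg


def make_contact_fixture() -> tuple[Model, set[tuple[int, int]], float]:
    """A star of single atoms around a central helix III atom.

    One atom from each of four helices and one loop sits at a planted
    distance from the centre, all but one within the 3.5 A cutoff. Returns
    (model, expected contacting residue pairs at 3.5 A, cutoff).
    """
    b = _Builder()
    centre = np.zeros(3)
    b.add(195, "LEU", "CB", centre)
    plants = [
        (130, 3.20, (1.0, 0.0, 0.0)),   # helix I
        (170, 3.40, (0.0, 1.0, 0.0)),   # helix II
        (230, 3.49, (-1.0, 0.0, 0.0)),  # helix IV
        (260, 3.30, (0.0, -1.0, 0.0)),  # helix V
        (181, 3.45, (0.0, 0.0, 1.0)),   # ECL1
        (131, 3.60, (0.0, 0.0, -1.0)),  # helix I, just beyond the cutoff
    ]
    expected = set()
    for res, d, direction in plants:
        b.add(res, "LEU", "CB", centre + d * np.asarray(direction))
        if d <= 3.5:
            expected.add((res, 195))
    return b.model(), expected, 3.5


# ---------------------------------------------------------------------------
# two-state trajectories


@dataclass
class TwoStateTrajSpec:
    """A noisy two-state step process: mean1 before the transition, mean2 after."""

    state_means: tuple[float, float] = (17.0, 40.0)
    state_sds: tuple[float, float] = (6.0, 3.0)
    transition_ns: float = 300.0
    frame_spacing_ns: float = 0.1
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        # means are (pre-transition, post-transition); either order is legal
        # so the same process serves rising deviations and falling distances
        if min(self.state_sds) < 0:
            raise ValueError("state SDs must be non-negative")


@dataclass
class TwoStateTruth:
    state_means: tuple[float, float]
    state_sds: tuple[float, float]
    transition_ns: float
    occupancies: tuple[float, float]


def make_trajectory(spec: TwoStateTrajSpec | None = None, **overrides) -> tuple[pd.DataFrame, TwoStateTruth]:
    """Sample the two-state process onto a regular time grid.

    Returns a ``time_ns``/``value`` DataFrame plus the planted truth.
    """
    spec = spec or TwoStateTrajSpec(**overrides)
    rng = np.random.default_rng(spec.seed)
    time = np.arange(spec.n_frames) * spec.frame_spacing_ns
    in_state2 = time >= spec.transition_ns
    means = np.where(in_state2, spec.state_means[1], spec.state_means[0])
    sds = np.where(in_state2, spec.state_sds[1], spec.state_sds[0])
    values = means + rng.normal(0.0, 1.0, spec.n_frames) * sds
    df = pd.DataFrame({"time_ns": time, "value": values})
    occ2 = float(in_state2.mean())
    truth = TwoStateTruth(spec.state_means, spec.state_sds, spec.transition_ns, (1.0 - occ2, occ2))
    return df, truth


def make_tilt_trajectory(
    theta_ref: float = 80.0,
    deviation_means: tuple[float, float] = (17.0, 40.0),
    state_sds: tuple[float, float] = (6.0, 3.0),
    transition_ns: float = 300.0,
    frame_spacing_ns: float = 0.1,
    n_frames: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, TwoStateTruth, float]:
    """Tilt-angle table whose *deviations* from ``theta_ref`` follow the
    two-state process (the second state sits at larger deviation)."""
    dev, truth = make_trajectory(
        TwoStateTrajSpec(deviation_means, state_sds, transition_ns, frame_spacing_ns, n_frames, seed)
    )
    theta = dev.copy()
    theta["value"] = theta_ref - dev["value"]
    return theta, truth, theta_ref


# ---------------------------------------------------------------------------
# HDX tables

_TIMEPOINTS_S = (20.0, 60.0, 300.0, 900.0, 3600.0)
_PEPTIDE_RANGES = ((111, 126), (112, 126), (114, 126), (119, 126), (184, 194), (195, 202), (244, 253))
_BASE_UPTAKE = {
    (111, 126): (15.0, 20.0, 25.0, 28.0, 30.0),
    (112, 126): (15.5, 20.5, 25.5, 28.5, 30.5),
    (114, 126): (16.0, 21.0, 26.0, 29.0, 31.0),
    (119, 126): (16.0, 21.0, 26.0, 29.0, 30.0),
    (184, 194): (2.0, 3.0, 4.0, 5.0, 6.0),
    (195, 202): (2.5, 3.5, 4.5, 5.5, 6.5),
    (244, 253): (18.0, 24.0, 29.0, 32.0, 34.0),
}
#: Extra uptake (percentage points) of each mutant on linker-region peptides.
_MUTANT_DELTAS = {"C245S": 12.0, "Y184F": 6.0, "Y184A": 9.0, "W118A": 12.5}
_LINKER_PEPTIDES = {(111, 126), (112, 126), (114, 126), (119, 126)}


def _region_sequence() -> str:
    """Synthetic one-letter sequence for residues 100-260 (fixed, arbitrary),
    except that the mutated positions carry the wild-type letters their
    construct names imply (W118, F119, Y184, C245)."""
    rng = np.random.default_rng(2026)
    letters = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # proline-free on purpose
    seq = list(rng.choice(letters, size=161))
    for pos, letter in ((118, "W"), (119, "F"), (184, "Y"), (245, "C")):
        seq[pos - _REGION_START] = letter
    return "".join(seq)


_REGION_START = 100
_REGION_SEQ = _region_sequence()


def _peptide_sequence(start: int, end: int, mutations: Mapping[int, str] | None = None) -> str:
    seq = list(_REGION_SEQ[start - _REGION_START : end - _REGION_START + 1])
    for pos, letter in (mutations or {}).items():
        if start <= pos <= end:
            seq[pos - start] = letter
    return "".join(seq)


def _parse_mutation(construct: str) -> dict[int, str]:
    if construct == "WT":
        return {}
    return {int(construct[1:-1]): construct[-1]}


def default_hdx_design(constructs: Sequence[str] = ("WT", "C245S", "Y184F", "Y184A", "W118A")) -> pd.DataFrame:
    """Planted per-cell uptake design: construct, peptide, timepoint, uptake %.

    Mutants carry their planted extra uptake on the linker-region peptides
    only; mutated peptide sequences differ from wild type, which is what
    makes mutation-covering peptides uncomparable downstream.
    """
    rows = []
    for construct in constructs:
        muts = _parse_mutation(construct)
        for (start, end) in _PEPTIDE_RANGES:
            seq = _peptide_sequence(start, end, muts)
            for tp, base in zip(_TIMEPOINTS_S, _BASE_UPTAKE[(start, end)]):
                uptake = base
                if construct in _MUTANT_DELTAS and (start, end) in _LINKER_PEPTIDES:
                    uptake = base + _MUTANT_DELTAS[construct]
                rows.append(
                    {
                        "construct": construct,
                        "start_res": start,
                        "end_res": end,
                        "sequence": seq,
                        "timepoint_s": tp,
                        "uptake_pct": uptake,
                    }
                )
    return pd.DataFrame(rows)


def make_hdx_tables(
    design: pd.DataFrame | None = None,
    noise_sd_da: float = 0.05,
    replicates: int = 2,
    seed: int = 0,
    d2o_fraction: float = D2O_FRACTION,
) -> tuple[list[UptakeRecord], pd.DataFrame]:
    """Replicate uptake records realising a planted design.

    Mass shifts are back-computed from the planted uptake through the
    inverse of the percent-uptake formula, then Gaussian noise (Da) is
    added per replicate. Returns (records, design) — the design is the
    ground truth.
    """
    design = default_hdx_design() if design is None else design
    rng = np.random.default_rng(seed)
    records: list[UptakeRecord] = []
    for _, row in design.iterrows():
        pep = HDXPeptide(row["construct"], int(row["start_res"]), int(row["end_res"]), row["sequence"])
        mx = pep.max_exchangeable
        clean_shift = row["uptake_pct"] / 100.0 * mx * d2o_fraction
        for rep in range(1, replicates + 1):
            shift = clean_shift + (rng.normal(0.0, noise_sd_da) if noise_sd_da > 0 else 0.0)
            records.append(UptakeRecord(pep, float(row["timepoint_s"]), rep, float(shift)))
    return records, design


# ---------------------------------------------------------------------------
# alignments

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def make_msa(
    n_seqs: int,
    ref_length: int = 305,
    conserved_positions: set[int] | None = None,
    mutation_rate: float = 1.0,
    seed: int = 0,
    ref_id: str = "ref",
    id_prefix: str = "seq",
) -> tuple[Alignment, set[int]]:
    """Reference plus ``n_seqs`` derived sequences.

    Outside ``conserved_positions`` (1-based) every position of every derived
    sequence mutates with probability ``mutation_rate``; a mutation always
    changes the character. At rate 1.0 the absolutely conserved set over all
    sequences is exactly the planted set.
    """
    conserved = set(conserved_positions or set())
    if not conserved <= set(range(1, ref_length + 1)):
        raise ValueError("conserved positions outside 1..ref_length")
    rng = np.random.default_rng(seed)
    ref = rng.choice(_AA20, size=ref_length)
    records = [(ref_id, "".join(ref))]
    conserved_mask = np.zeros(ref_length, dtype=bool)
    for p in conserved:
        conserved_mask[p - 1] = True
    for k in range(n_seqs):
        seq = ref.copy()
        mutate = (~conserved_mask) & (rng.random(ref_length) < mutation_rate)
        for idx in np.flatnonzero(mutate):
            choices = _AA20[_AA20 != ref[idx]]
            seq[idx] = rng.choice(choices)
        records.append((f"{id_prefix}_{k + 1:03d}", "".join(seq)))
    return Alignment(records), conserved


#: Clade design echoing the scale of a curated cross-species receptor set:
#: (clade id prefix, number of sequences, planted conserved positions).
_CLADE_DESIGN = (
    ("mammal", 71, frozenset(range(1, 63))),        # 62 positions
    ("avian", 59, frozenset(range(1, 18))),         # 17 positions
    ("virus_near", 12, frozenset(range(1, 56))),    # 55 positions
    ("virus_far", 10, frozenset(range(1, 8))),      # 7 positions
)


def make_clade_msa(ref_length: int = 305, seed: int = 0) -> tuple[Alignment, dict[str, set[int]]]:
    """A combined multi-clade alignment with planted per-clade conservation.

    Each clade's members conserve their own planted position set and mutate
    everywhere else (saturating rate), so the absolute-conservation count
    within a clade equals its planted set size; the 22 viral sequences
    together conserve only the intersection of the near/far viral sets.
    """
    rng = np.random.default_rng(seed)
    ref = rng.choice(_AA20, size=ref_length)
    records = [("ref_human", "".join(ref))]
    truths: dict[str, set[int]] = {}
    for prefix, n, conserved in _CLADE_DESIGN:
        conserved_mask = np.zeros(ref_length, dtype=bool)
        for p in conserved:
            conserved_mask[p - 1] = True
        for k in range(n):
            seq = ref.copy()
            for idx in np.flatnonzero(~conserved_mask):
                choices = _AA20[_AA20 != ref[idx]]
                seq[idx] = rng.choice(choices)
            records.append((f"{prefix}_{k + 1:03d}", "".join(seq)))
        truths[prefix] = set(conserved)
    truths["virus_all"] = truths["virus_near"] & truths["virus_far"]
    return Alignment(records), truths


def write_series_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a time/value table in the package's TSV convention."""
    df.to_csv(path, sep="\t", index=False)
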