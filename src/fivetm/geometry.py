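"""Core computational geometry.

Centers of mass, least-squares rigid-body superposition (Kabsch), a
deterministic Shrake–Rupley solvent-accessible surface area, buried-area
bookkeeping, and aromatic ring-plane geometry.

SASA convention
---------------
Sphere points come from a golden-section spiral, so the area is bit-stable
across runs for a fixed ``n_points``. Van der Waals radii are per element
(C 1.70, N 1.55, O 1.52, S 1.80 A) with a 1.4 A water probe by default;
published programs differ slightly in their radius sets, which is why buried
areas carry a ~10% method tolerance rather than a fixed truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Model

__all__ = [
    "Transform",
    "SasaResult",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "center_of_mass",
    "superpose",
    "sphere_points",
    "sasa",
    "buried_area",
    "ring_geometry",
    "RING_ATOMS",
    "BACKBONE_ATOMS",
]

ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

#: Per-element van der Waals radii (A) used for SASA.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
    "D": 1.20,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Ring atoms used for plane fits. The tryptophan plane is fit to all nine
#: indole ring atoms; six-membered rings use their six ring atoms.
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class Transform:
    """Rigid-body map ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas in A^2."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


def center_of_mass(model: Model, weighting: str = "mass") -> np.ndarray:
    """Weighted mean position of a (non-empty) atom set.

    ``weighting='mass'`` uses standard atomic masses by element;
    ``'geometric'`` weights every atom equally.
    """
    if model.n_atoms == 0:
        raise ValueError("center_of_mass of an empty atom set")
    if weighting == "geometric":
        return model.xyz.mean(axis=0)
    if weighting != "mass":
        raise ValueError(f"unknown weighting {weighting!r}")
    try:
        w = np.array([ATOMIC_MASSES[str(e).upper()] for e in model.element])
    except KeyError as exc:
        raise ValueError(f"no atomic mass for element {exc}") from exc
    return (model.xyz * w[:, None]).sum(axis=0) / w.sum()


def superpose(
    mobile: np.ndarray, reference: np.ndarray, pairing: Sequence[tuple[int, int]] | None = None
) -> tuple[Transform, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    ``pairing`` is a list of (mobile_index, reference_index) pairs; by
    default atoms are paired by position. Reflections are excluded. Returns
    the transform and the RMSD over the paired atoms after applying it.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pairing is not None:
        mi, ri = zip(*pairing)
        mobile_p = mobile[list(mi)]
        ref_p = reference[list(ri)]
    else:
        if len(mobile) != len(reference):
            raise ValueError("unpaired superposition requires equal-length coordinate sets")
        mobile_p, ref_p = mobile, reference
    if len(mobile_p) < 3:
        raise ValueError("superposition needs at least 3 paired atoms")

    mc = mobile_p.mean(axis=0)
    rc = ref_p.mean(axis=0)
    a = mobile_p - mc
    b = ref_p - rc
    # conditioning check: near-collinear references still get a best fit
    sv = np.linalg.svd(b, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        warnings.warn("reference atoms are nearly collinear; rotation is ill-conditioned")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    t = Transform(rot, trans)
    diff = t.apply(mobile_p) - ref_p
    rmsd = float(np.sqrt((diff**2).sum() / len(mobile_p)))
    return t, rmsd


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


class UnknownElementError(ValueError):
    pass


def _radii(model: Model, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(model.n_atoms)
    for i, e in enumerate(model.element):
        key = str(e).upper()
        if key not in radii:
            raise UnknownElementError(
                f"no van der Waals radius for element {key!r} "
                f"(atom {model.atom_name[i]} in {model.res_name[i]} {model.res_seq[i]})"
            )
        out[i] = radii[key]
    return out


def sasa(
    model: Model,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area, per atom.

    Deterministic: the test-point set depends only on ``n_points``. The
    caller chooses which atoms participate (pass ``model.heavy_protein()``
    to exclude hydrogens/waters/heteroatoms, which is what the higher-level
    analyses do).
    """
    if model.n_atoms == 0:
        return SasaResult(np.zeros(0), probe_radius, n_points)
    r = _radii(model, radii or VDW_RADII) + probe_radius
    pts = sphere_points(n_points)
    xyz = model.xyz
    tree = cKDTree(xyz)
    max_r = r.max()
    areas = np.empty(model.n_atoms)
    for i in range(model.n_atoms):
        neighbours = tree.query_ball_point(xyz[i], r[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        test = xyz[i] + r[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((test - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > r[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * r[i] ** 2 * accessible.sum() / n_points
    return SasaResult(areas, probe_radius, n_points)


def buried_area(
    model: Model,
    residues: Iterable[tuple[str | None, int]] | Iterable[int],
    side_chain_only: bool = False,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Surface area (A^2) of the named residues' atoms that the rest of the
    structure occludes.

    Defined as SASA of the selected atoms extracted alone minus SASA of the
    same atoms inside the full context, identical probe and point count.
    ``residues`` is a set of residue numbers or (chain, res_seq) pairs;
    ``side_chain_only`` restricts the selection to non-backbone atoms.
    """
    context = model.heavy_protein()
    pairs = []
    for item in residues:
        if isinstance(item, tuple):
            pairs.append((item[0], int(item[1])))
        else:
            pairs.append((None, int(item)))
    sel = np.zeros(context.n_atoms, dtype=bool)
    for chain, res in pairs:
        m = context.res_seq == res
        if chain is not None:
            m &= context.chain == chain
        if not m.any():
            raise ValueError(f"residue {res} (chain {chain or 'any'}) not present in context")
        sel |= m
    if side_chain_only:
        sel &= ~np.isin(context.atom_name, BACKBONE_ATOMS)
        if not sel.any():
            raise ValueError("selection has no side-chain atoms")
    isolated = sasa(context.subset(sel), probe_radius, n_points)
    in_context = sasa(context, probe_radius, n_points)
    return float(isolated.per_atom_area.sum() - in_context.per_atom_area[sel].sum())


def _ring_plane(model: Model, chain: str | None, res_seq: int) -> tuple[np.ndarray, np.ndarray]:
    m = model.mask(chain=chain, residues=[res_seq])
    sub = model.subset(m)
    if sub.n_atoms == 0:
        raise ValueError(f"residue {res_seq} not found")
    res_name = str(sub.res_name[0])
    if res_name not in RING_ATOMS:
        raise ValueError(f"residue {res_name} {res_seq} is not aromatic")
    wanted = RING_ATOMS[res_name]
    ring = sub.subset(sub.mask(atom_names=wanted))
    missing = set(wanted) - set(map(str, ring.atom_name))
    if missing:
        raise ValueError(f"{res_name} {res_seq}: missing ring atoms {sorted(missing)}")
    centroid = ring.xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(ring.xyz - centroid)
    normal = vt[2] / np.linalg.norm(vt[2])
    return centroid, normal


def ring_geometry(
    model: Model,
    res1: int | tuple[str | None, int],
    res2: int | tuple[str | None, int],
) -> tuple[float, float]:
    """Interplanar angle (degrees, folded into [0, 90]) and centroid distance
    (A) between two aromatic rings.

    Residues are given as res_seq or (chain, res_seq). Symmetric in its
    arguments.
    """
    c1, r1 = res1 if isinstance(res1, tuple) else (None, res1)
    c2, r2 = res2 if isinstance(res2, tuple) else (None, res2)
    cen1, n1 = _ring_plane(model, c1, r1)
    cen2, n2 = _ring_plane(model, c2, r2)
    cosang = np.clip(abs(float(n1 @ n2)), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    dist = float(np.linalg.norm(cen1 - cen2))
    return angle, dist
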