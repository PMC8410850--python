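"""Macromolecular coordinate I/O and selection.

Coordinates are held column-wise in :class:`Model` (one numpy array per
field), which keeps geometry operations vectorised while preserving the
per-atom identity needed for reporting (chain, author residue number,
insertion code, residue/atom names).

Author (PDB) residue numbering is the only numbering used anywhere in this
package: every residue a user refers to (W118, Y184, C245, ...) is an author
number, and structures with unmodelled gaps are represented simply by the
absence of those residues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Model",
    "Structure",
    "SegmentMap",
    "read_structure",
    "write_structure",
    "select",
    "default_segment_map",
    "STANDARD_AMINO_ACIDS",
]

#: Three-letter codes treated as protein when filtering heavy protein atoms.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

_WATERS = frozenset({"HOH", "WAT", "DOD"})


class Atom(NamedTuple):
    """A single atom record (a row view of :class:`Model`)."""

    chain: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    xyz: np.ndarray
    occupancy: float
    bfactor: float
    het: bool


@dataclass
class Model:
    """One coordinate model, stored column-wise.

    All arrays share length ``n_atoms``; ``xyz`` has shape ``(n_atoms, 3)``
    in Angstroms.
    """

    chain: np.ndarray
    res_seq: np.ndarray
    icode: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    occupancy: np.ndarray
    bfactor: np.ndarray
    het: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chain)
        for f in dataclasses.fields(self):
            arr = getattr(self, f.name)
            if len(arr) != n:
                raise ValueError(f"column {f.name!r} has length {len(arr)}, expected {n}")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def atom(self, i: int) -> Atom:
        return Atom(
            str(self.chain[i]),
            int(self.res_seq[i]),
            str(self.icode[i]),
            str(self.res_name[i]),
            str(self.atom_name[i]),
            str(self.element[i]),
            self.xyz[i],
            float(self.occupancy[i]),
            float(self.bfactor[i]),
            bool(self.het[i]),
        )

    # -- selection ---------------------------------------------------------

    def mask(
        self,
        chain: str | Sequence[str] | None = None,
        residues: Iterable[int] | range | None = None,
        atom_names: Iterable[str] | None = None,
        res_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms; ``None`` for any filter means 'all'."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            m &= np.isin(self.chain, chains)
        if residues is not None:
            m &= np.isin(self.res_seq, np.fromiter(residues, dtype=int))
        if atom_names is not None:
            m &= np.isin(self.atom_name, list(atom_names))
        if res_names is not None:
            m &= np.isin(self.res_name, list(res_names))
        return m

    def subset(self, mask: np.ndarray) -> "Model":
        return Model(
            self.chain[mask],
            self.res_seq[mask],
            self.icode[mask],
            self.res_name[mask],
            self.atom_name[mask],
            self.element[mask],
            self.xyz[mask],
            self.occupancy[mask],
            self.bfactor[mask],
            self.het[mask],
        )

    def heavy_protein(self) -> "Model":
        """Standard amino-acid atoms, hydrogens and waters excluded.

        Geometry operations work on this view by default so that glycans,
        waters and other heteroatoms do not pollute surface or contact
        measurements unless explicitly selected.
        """
        m = np.isin(self.res_name, list(STANDARD_AMINO_ACIDS))
        m &= ~np.isin(self.element, ["H", "D"])
        return self.subset(m)

    def residues_present(self, chain: str | None = None) -> set[int]:
        m = self.mask(chain=chain)
        return set(int(r) for r in np.unique(self.res_seq[m]))

    def with_xyz(self, xyz: np.ndarray) -> "Model":
        new = self.subset(np.ones(self.n_atoms, dtype=bool))
        new.xyz = np.asarray(xyz, dtype=float)
        return new

    def with_bfactor(self, bfactor: np.ndarray) -> "Model":
        new = self.subset(np.ones(self.n_atoms, dtype=bool))
        new.bfactor = np.asarray(bfactor, dtype=float)
        return new


@dataclass
class Structure:
    """An ordered list of models plus provenance."""

    models: list[Model]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("Structure requires at least one model")

    @property
    def first(self) -> Model:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def resolved_residues(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        m = self.first
        for ch in np.unique(m.chain):
            out[str(ch)] = m.residues_present(chain=str(ch))
        return out


class SegmentMap(Mapping[str, tuple[int, int]]):
    """Named inclusive residue ranges (author numbering)."""

    def __init__(self, ranges: Mapping[str, tuple[int, int]]):
        self._ranges: dict[str, tuple[int, int]] = {}
        for name, (a, b) in ranges.items():
            a, b = int(a), int(b)
            if a > b:
                raise ValueError(f"segment {name!r}: start {a} > end {b}")
            if name in self._ranges:
                raise ValueError(f"duplicate segment name {name!r}")
            self._ranges[name] = (a, b)

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self._ranges[name]

    def __iter__(self):
        return iter(self._ranges)

    def __len__(self) -> int:
        return len(self._ranges)

    def residues(self, name: str) -> range:
        a, b = self._ranges[name]
        return range(a, b + 1)

    def segment_of(self, res_seq: int) -> str | None:
        for name, (a, b) in self._ranges.items():
            if a <= res_seq <= b:
                return name
        return None

    def helices(self) -> list[str]:
        return [n for n in self._ranges if n.startswith("helix")]


def default_segment_map() -> SegmentMap:
    """The receptor's segment table: linker, five TM helices, two ECLs.

    Linker 114-120, helix I 121-140, helix II 160-178, ECL1 179-185,
    helix III 186-207, helix IV 224-242, ECL2 243-250, helix V 251-278.
    Intracellular loops fall in the gaps and are deliberately unnamed.
    """
    return SegmentMap(
        {
            "linker": (114, 120),
            "helix I": (121, 140),
            "helix II": (160, 178),
            "ECL1": (179, 185),
            "helix III": (186, 207),
            "helix IV": (224, 242),
            "ECL2": (243, 250),
            "helix V": (251, 278),
        }
    )


# ---------------------------------------------------------------------------
# reading / writing via gemmi


class StructureParseError(ValueError):
    pass


def _resolve_altlocs(rows: list[tuple]) -> list[tuple]:
    """Keep one atom per (chain, res_seq, icode, atom_name): highest
    occupancy, ties broken by file order."""
    best: dict[tuple, tuple[int, tuple]] = {}
    order: list[tuple] = []
    for idx, row in enumerate(rows):
        key = (row[0], row[1], row[2], row[4])  # chain, res_seq, icode, atom_name
        if key not in best:
            best[key] = (idx, row)
            order.append(key)
        else:
            _, prev = best[key]
            if row[7] > prev[7]:  # occupancy strictly higher wins; tie -> first
                best[key] = (best[key][0], row)
    return [best[k][1] for k in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records are retained; each MODEL block becomes one
    :class:`Model`. Alternate locations are resolved to the highest-occupancy
    conformer (ties: first in file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"could not parse {path}: {exc}") from exc

    models: list[Model] = []
    for gm in st:
        rows: list[tuple] = []
        for chain in gm:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    rows.append(
                        (
                            chain.name,
                            res.seqid.num,
                            res.seqid.icode.strip(),
                            res.name,
                            at.name,
                            at.element.name.upper(),
                            (at.pos.x, at.pos.y, at.pos.z),
                            at.occ,
                            at.b_iso,
                            het,
                            at.altloc,
                        )
                    )
        rows = _resolve_altlocs(rows)
        if not rows:
            continue
        models.append(
            Model(
                chain=np.array([r[0] for r in rows], dtype=object),
                res_seq=np.array([r[1] for r in rows], dtype=int),
                icode=np.array([r[2] for r in rows], dtype=object),
                res_name=np.array([r[3] for r in rows], dtype=object),
                atom_name=np.array([r[4] for r in rows], dtype=object),
                element=np.array([r[5] for r in rows], dtype=object),
                xyz=np.array([r[6] for r in rows], dtype=float),
                occupancy=np.array([r[7] for r in rows], dtype=float),
                bfactor=np.array([r[8] for r in rows], dtype=float),
                het=np.array([r[9] for r in rows], dtype=bool),
            )
        )
    if not models:
        raise StructureParseError(f"{path}: no atoms found")
    return Structure(models=models, source_id=st.name or path.stem)


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure as PDB (default) or mmCIF, inferred from suffix."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = s.source_id or "fivetm"
    for mi, model in enumerate(s.models, start=1):
        gm = gemmi.Model(mi)
        # gemmi copies containers on add_*, so build each chain completely
        # (grouping consecutive atoms into residues) before attaching it.
        chain_order: list[str] = []
        chain_residues: dict[str, list[gemmi.Residue]] = {}
        last_res_key = None
        cur_res: gemmi.Residue | None = None
        for a in model:
            key = (a.chain, a.res_seq, a.icode, a.res_name)
            if key != last_res_key:
                cur_res = gemmi.Residue()
                cur_res.name = a.res_name
                cur_res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
                cur_res.het_flag = "H" if a.het else "A"
                chain_residues.setdefault(a.chain, []).append(cur_res)
                if a.chain not in chain_order:
                    chain_order.append(a.chain)
                last_res_key = key
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*map(float, a.xyz))
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            cur_res.add_atom(ga)
        for chain_name in chain_order:
            ch = gemmi.Chain(chain_name)
            for res in chain_residues[chain_name]:
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureParseError(f"unknown format {format!r}")


def select(
    s: Structure,
    chain: str | Sequence[str] | None = None,
    residues: Iterable[int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> Structure:
    """Subset every model of ``s`` by chain / residue range / atom names.

    ``None`` means 'all'. Atom order is preserved; empty selections are legal.
    """
    residues = None if residues is None else list(residues)
    atom_names = None if atom_names is None else list(atom_names)
    models = [m.subset(m.mask(chain=chain, residues=residues, atom_names=atom_names)) for m in s.models]
    return Structure(models=models, source_id=s.source_id)
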