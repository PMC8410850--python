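"""Sequence-conservation analysis on multiple sequence alignments.

Counts *absolute conservation* (reference positions identical across every
member of a named clade, gaps counting as mismatch), computes a simple
identity-fraction conservation score binned onto the familiar 1-9 colour
scale, performs global pairwise alignment, and paints conservation bins
onto structure B-factors.

The identity-fraction binning is a deliberately transparent stand-in for
Bayesian evolutionary-rate estimators: it reproduces identity-count
statements exactly and keeps the 1-9 painting scale, but it does not model
substitution rates or phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure import Structure

__all__ = [
    "Alignment",
    "ConservationProfile",
    "read_alignment",
    "map_to_reference",
    "absolute_conservation",
    "identity_bins",
    "global_align",
    "paint_conservation",
]

GAP = "-"


@dataclass
class Alignment:
    """A case-normalised MSA: (id, aligned sequence) records of equal width."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        widths = {len(seq) for _, seq in self.records}
        if len(widths) != 1:
            bad = [i for i, (_, s) in enumerate(self.records) if len(s) != len(self.records[0][1])]
            raise ValueError(f"ragged alignment (records {bad} differ in width)")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        self.records = [(i, s.upper()) for i, s in self.records]

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(f"sequence id {seq_id!r} not in alignment")


@dataclass
class ConservationProfile:
    """Per-reference-position conservation: identity fraction and 1-9 bin."""

    ref_id: str
    positions: np.ndarray  # reference positions, 1-based
    identity_fraction: np.ndarray
    bins: np.ndarray


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read a FASTA or Clustal alignment."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal", ".clu") else "fasta"
    msa = AlignIO.read(str(path), fmt)
    return Alignment([(rec.id, str(rec.seq)) for rec in msa])


def map_to_reference(a: Alignment, ref_id: str) -> dict[int, int]:
    """Bijection from alignment columns (0-based) holding a reference
    residue to reference positions 1..L."""
    ref = a.sequence(ref_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            pos += 1
            mapping[col] = pos
    return mapping


def absolute_conservation(
    a: Alignment, ref_id: str, clade: Iterable[str] | None = None
) -> tuple[int, set[int]]:
    """Reference positions whose character is identical in every clade member.

    Gaps count as mismatch. ``clade`` defaults to every non-reference
    sequence. Returns (count, set of reference positions).
    """
    clade_ids = set(clade) if clade is not None else set(a.ids) - {ref_id}
    if not clade_ids:
        raise ValueError("empty clade")
    unknown = clade_ids - set(a.ids)
    if unknown:
        raise ValueError(f"clade ids not in alignment: {sorted(unknown)}")
    ref = a.sequence(ref_id)
    members = [a.sequence(i) for i in sorted(clade_ids)]
    colmap = map_to_reference(a, ref_id)
    conserved: set[int] = set()
    for col, pos in colmap.items():
        ch = ref[col]
        if all(m[col] == ch for m in members):
            conserved.add(pos)
    return len(conserved), conserved


def identity_bins(a: Alignment, ref_id: str) -> ConservationProfile:
    """Identity-fraction conservation per reference position, binned 1-9.

    Fraction = share of non-reference sequences matching the reference
    character at that column; bin = ceil(9 * fraction) clipped to [1, 9],
    so the bins are monotone in the fraction and a fully conserved column
    maps to 9.
    """
    others = [i for i in a.ids if i != ref_id]
    if not others:
        raise ValueError("identity binning needs at least two sequences")
    ref = a.sequence(ref_id)
    seqs = [a.sequence(i) for i in others]
    colmap = map_to_reference(a, ref_id)
    positions = np.array(sorted(colmap.values()))
    fractions = np.empty(len(positions))
    for k, (col, pos) in enumerate(sorted(colmap.items(), key=lambda kv: kv[1])):
        ch = ref[col]
        fractions[k] = sum(1 for s in seqs if s[col] == ch) / len(seqs)
    bins = np.clip(np.ceil(9 * fractions).astype(int), 1, 9)
    return ConservationProfile(ref_id, positions, fractions, bins)


def global_align(
    seq_a: str,
    seq_b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[tuple[str, str], float, float]:
    """Needleman–Wunsch global alignment with affine gaps.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``. Returns the
    aligned strings, the score, and percent identity (matches over alignment
    columns; pairwise alignments have no dual-gap columns).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    try:
        matrix = substitution_matrices.load(substitution)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {substitution!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    top, bottom = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(top, bottom) if x == y and x != GAP)
    columns = sum(1 for x, y in zip(top, bottom) if not (x == GAP and y == GAP))
    identity = 100.0 * matches / columns
    return (top, bottom), float(aln.score), identity


def paint_conservation(s: Structure, profile: ConservationProfile, sentinel: float = -1.0) -> Structure:
    """Write conservation bins into B-factors (profile positions are taken
    as author residue numbers); unmapped residues get ``sentinel``."""
    by_pos = dict(zip(profile.positions.tolist(), profile.bins.tolist()))
    models = []
    for m in s.models:
        b = np.full(m.n_atoms, sentinel)
        for pos, bin_ in by_pos.items():
            b[m.res_seq == pos] = float(bin_)
        models.append(m.with_bfactor(b))
    return Structure(models=models, source_id=s.source_id)
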