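"""Peptide-level hydrogen/deuterium-exchange (HDX-MS) uptake analysis.

Inputs start at what vendor software exports: per-replicate centroid mass
shifts (Da) for identified peptic peptides. The module computes each
peptide's theoretical maximum number of exchangeable backbone amide
hydrogens (peptide length minus the two N-terminal residues minus prolines
beyond position 2), converts mass shifts to percent deuterium uptake with a
D2O-fraction correction (91.7% by default), summarises replicates, builds
wild-type-versus-mutant differential tables over the peptides the two
constructs share, and paints per-residue uptake onto structure B-factors.

No back-exchange correction is applied: values are relative uptake, which is
the standard reporting convention when fully deuterated controls are not
measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .structure import Structure

__all__ = [
    "HDXPeptide",
    "UptakeRecord",
    "max_exchangeable",
    "percent_uptake",
    "records_to_frame",
    "summarize",
    "differential",
    "paint_uptake",
    "D2O_FRACTION",
]

#: Default deuterium fraction of the labelling buffer.
D2O_FRACTION = 0.917

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class HDXPeptide:
    """A peptic peptide of one construct, in author numbering (inclusive)."""

    construct: str
    start_res: int
    end_res: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end_res - self.start_res + 1:
            raise ValueError(
                f"{self.construct} {self.start_res}-{self.end_res}: sequence length "
                f"{len(self.sequence)} does not match the residue range"
            )

    @property
    def max_exchangeable(self) -> int:
        return max_exchangeable(self.sequence)

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start_res, self.end_res, self.sequence)


@dataclass(frozen=True)
class UptakeRecord:
    """One replicate measurement: observed centroid mass shift in Da."""

    peptide: HDXPeptide
    timepoint_s: float
    replicate: int
    mass_shift_da: float


def max_exchangeable(sequence: str) -> int:
    """Theoretical maximum number of exchangeable backbone amide hydrogens.

    The two N-terminal residues are excluded (fast back-exchange at the
    N-terminus), as is every proline beyond them (no amide hydrogen):
    ``max(0, L - 2 - #Pro at positions 3..L)``.
    """
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-standard residue letters {sorted(bad)} in {sequence!r}")
    return max(0, len(seq) - 2 - seq[2:].count("P"))


def percent_uptake(
    mass_shift_da: float, max_exch: int, d2o_fraction: float = D2O_FRACTION
) -> float:
    """Percent deuterium uptake: 100 * shift / (max exchangeable * D2O fraction)."""
    if max_exch <= 0:
        raise ValueError("percent uptake is undefined for a peptide with no exchangeable amides")
    return 100.0 * mass_shift_da / (max_exch * d2o_fraction)


def records_to_frame(records: Iterable[UptakeRecord], d2o_fraction: float = D2O_FRACTION) -> pd.DataFrame:
    """Flatten replicate records into a tidy table with uptake percentages."""
    rows = []
    for r in records:
        rows.append(
            {
                "construct": r.peptide.construct,
                "start_res": r.peptide.start_res,
                "end_res": r.peptide.end_res,
                "sequence": r.peptide.sequence,
                "max_exchangeable": r.peptide.max_exchangeable,
                "timepoint_s": r.timepoint_s,
                "replicate": r.replicate,
                "mass_shift_da": r.mass_shift_da,
                "uptake_pct": percent_uptake(r.mass_shift_da, r.peptide.max_exchangeable, d2o_fraction),
            }
        )
    return pd.DataFrame(rows)


_CELL = ["construct", "start_res", "end_res", "sequence", "timepoint_s"]


def summarize(records: Iterable[UptakeRecord] | pd.DataFrame, d2o_fraction: float = D2O_FRACTION) -> pd.DataFrame:
    """Mean and sample SD (n-1) of percent uptake per (construct, peptide,
    timepoint). Single-replicate cells get SD 0 and ``single_replicate=True``."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records, d2o_fraction)
    if df.empty:
        return pd.DataFrame(columns=_CELL + ["mean_uptake_pct", "sd_uptake_pct", "n_replicates", "single_replicate"])
    g = df.groupby(_CELL, as_index=False)["uptake_pct"].agg(["mean", "std", "count"])
    g = g.rename(columns={"mean": "mean_uptake_pct", "std": "sd_uptake_pct", "count": "n_replicates"})
    g["single_replicate"] = g["n_replicates"] == 1
    g.loc[g["single_replicate"], "sd_uptake_pct"] = 0.0
    return g


def differential(wt: pd.DataFrame, mutant: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutant-minus-wild-type uptake differences over common peptides.

    Peptides are joined on (start, end, sequence, timepoint); a peptide whose
    sequence changed with the mutation therefore naturally drops out of the
    comparison. Returns ``(comparison, uncomparable)``: the second table
    lists every peptide cell present on only one side, so nothing is
    silently discarded. An empty intersection yields an explicitly empty
    comparison.
    """
    key = ["start_res", "end_res", "sequence", "timepoint_s"]
    w = wt.rename(columns={"mean_uptake_pct": "mean_uptake_wt", "sd_uptake_pct": "sd_wt"})
    m = mutant.rename(columns={"mean_uptake_pct": "mean_uptake_mut", "sd_uptake_pct": "sd_mut"})
    merged = w.merge(m, on=key, how="outer", suffixes=("_wt", "_mut"), indicator=True)
    common = merged[merged["_merge"] == "both"].copy()
    common["delta_pct"] = common["mean_uptake_mut"] - common["mean_uptake_wt"]
    comparison = common[key + ["mean_uptake_wt", "mean_uptake_mut", "delta_pct", "sd_wt", "sd_mut"]]
    only = merged[merged["_merge"] != "both"].copy()
    only["present_in"] = np.where(only["_merge"] == "left_only", "wt", "mutant")
    uncomparable = only[key + ["present_in"]]
    return comparison.reset_index(drop=True), uncomparable.reset_index(drop=True)


def paint_uptake(
    s: Structure,
    summarized: pd.DataFrame,
    timepoint_s: float,
    construct: str | None = None,
    sentinel: float = -1.0,
) -> Structure:
    """Write per-residue uptake into B-factors of a copy of ``s``.

    A residue covered by several peptides gets the mean of their uptakes;
    residues covered by none get ``sentinel``.
    """
    tbl = summarized[summarized["timepoint_s"] == timepoint_s]
    if construct is not None:
        tbl = tbl[tbl["construct"] == construct]
    per_res: dict[int, list[float]] = {}
    for _, row in tbl.iterrows():
        for res in range(int(row["start_res"]), int(row["end_res"]) + 1):
            per_res.setdefault(res, []).append(float(row["mean_uptake_pct"]))
    models = []
    for m in s.models:
        b = np.full(m.n_atoms, sentinel)
        for res, vals in per_res.items():
            b[m.res_seq == res] = float(np.mean(vals))
        models.append(m.with_bfactor(b))
    return Structure(models=models, source_id=s.source_id)
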