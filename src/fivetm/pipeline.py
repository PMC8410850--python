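"""Orchestration: configuration, report assembly, and the end-to-end demo.

``run_anatomy_report`` ties the static structural measurements together and
writes a report bundle (TSV tables plus a JSON summary in which every scalar
is logged with the parameters that produced it). ``run_full_demo`` generates
every class of synthetic input, runs every analysis, and writes a summary
comparing recovered values against the planted truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anatomy, conservation, hdx, synthetic, trajectory
from .geometry import ring_geometry
from .structure import SegmentMap, Structure, default_segment_map, read_structure

__all__ = ["RunConfig", "run_anatomy_report", "run_full_demo"]


@dataclass
class RunConfig:
    """All tunables of an anatomy run, with documented defaults."""

    structure_path: str = ""
    chain: str | None = None
    segments: dict[str, tuple[int, int]] | None = None
    contact_cutoff: float = 3.5
    hbond_cutoff: float = 3.5
    saltbridge_cutoff: float = 4.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    layer_gap: float = 3.0
    tip_residues: tuple[int, int] = (32, 36)
    ring_pair: tuple[int, int] = (118, 119)
    kink_pivot: int = 131
    network_members: tuple[int, ...] = (141, 145, 206, 227, 264)
    d2o_fraction: float = 0.917
    seed: int = 0
    out_dir: str = "report"

    def segment_map(self) -> SegmentMap:
        if self.segments is None:
            return default_segment_map()
        return SegmentMap(self.segments)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tip_residues", "ring_pair", "network_members"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("segments"):
            raw["segments"] = {k: tuple(v) for k, v in raw["segments"].items()}
        return cls(**raw)


def _log(entries: list[dict], operation: str, params: dict, value: Any) -> Any:
    entries.append({"operation": operation, "params": params, "value": value})
    return value


def run_anatomy_report(
    cfg: RunConfig, structure: Structure | None = None
) -> dict[str, Any]:
    """Run the full static-anatomy battery and write the report bundle.

    Measurements whose required residues are absent from the model (for
    example a non-aromatic residue at the ring-pair positions) are recorded
    as ``null`` with a reason; genuine errors in a stage abort with the
    stage name, preserving partial outputs on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if structure is None:
        structure = read_structure(cfg.structure_path)
    model = structure.first
    if cfg.chain is not None:
        available = sorted(set(map(str, model.chain)))
        if cfg.chain not in available:
            raise ValueError(f"chain {cfg.chain!r} not in structure; available: {available}")
        model = model.subset(model.mask(chain=cfg.chain))
    seg = cfg.segment_map()
    log: list[dict] = []
    summary: dict[str, Any] = {"source": structure.source_id, "config": dataclasses.asdict(cfg)}
    stage = "build_frame"
    try:
        frame = anatomy.build_frame(model, seg)
        summary["frame_origin"] = [round(float(v), 3) for v in frame.origin]
        summary["frame_z_axis"] = [round(float(v), 6) for v in frame.z_axis]

        stage = "ecd_tilt"
        lo, hi = cfg.tip_residues
        try:
            tilt = anatomy.ecd_tilt(model, frame, tip_residues=range(lo, hi + 1))
        except ValueError as exc:
            tilt = None
            summary["ecd_tilt_skipped"] = str(exc)
        summary["ecd_tilt_deg"] = _log(log, "ecd_tilt", {"tip": list(cfg.tip_residues)}, tilt)

        stage = "helix_span"
        summary["helix_span_A"] = _log(
            log, "helix_span", {"refs": list(frame.boundary_refs)}, anatomy.helix_span(model, frame)
        )

        stage = "kink_angle"
        try:
            kink = anatomy.kink_angle(model, seg, pivot=cfg.kink_pivot)
        except ValueError as exc:
            kink = None
            summary["kink_skipped"] = str(exc)
        summary["kink_angle_deg"] = _log(log, "kink_angle", {"pivot": cfg.kink_pivot}, kink)

        stage = "segment_contacts"
        contacts = anatomy.segment_contacts(model, seg, cutoff=cfg.contact_cutoff)
        pd.DataFrame(
            [
                {
                    "chain_a": c.atom_a[0], "res_a": c.atom_a[1], "atom_a": c.atom_a[2],
                    "chain_b": c.atom_b[0], "res_b": c.atom_b[1], "atom_b": c.atom_b[2],
                    "distance_A": round(c.distance, 3),
                    "segment_a": c.segment_a, "segment_b": c.segment_b, "class": c.contact_class,
                }
                for c in contacts
            ]
        ).to_csv(out / "contacts.tsv", sep="\t", index=False)
        partners = sorted(
            ({c.segment_a for c in contacts} | {c.segment_b for c in contacts}) - {"helix III"}
        )
        summary["helixIII_contact_partners"] = _log(
            log, "segment_contacts", {"cutoff": cfg.contact_cutoff}, partners
        )
        summary["helixIII_contact_count"] = len(contacts)

        stage = "hydrogen_bonds"
        bonds = anatomy.hydrogen_bonds(model, cutoff=cfg.hbond_cutoff)
        pd.DataFrame(
            [
                {
                    "donor_chain": b.donor_atom[0], "donor_res": b.donor_atom[1],
                    "donor_atom": b.donor_atom[2], "donor_res_name": b.donor_res,
                    "acceptor_chain": b.acceptor_atom[0], "acceptor_res": b.acceptor_atom[1],
                    "acceptor_atom": b.acceptor_atom[2], "acceptor_res_name": b.acceptor_res,
                    "distance_A": round(b.distance, 3),
                }
                for b in bonds
            ]
        ).to_csv(out / "hbonds.tsv", sep="\t", index=False)
        summary["n_hydrogen_bonds"] = _log(log, "hydrogen_bonds", {"cutoff": cfg.hbond_cutoff}, len(bonds))
        switch = {}
        for b in bonds:
            for da, aa in ((b.donor_atom, b.acceptor_atom), (b.acceptor_atom, b.donor_atom)):
                if da[1] == 184 and da[2] == "OH":
                    switch[f"Y184_OH_to_{aa[1]}_{aa[2]}_A"] = round(b.distance, 3)
        summary["switch_residue_hbonds"] = switch

        stage = "salt_bridges"
        sb = anatomy.salt_bridges(model, cutoff=cfg.saltbridge_cutoff)
        summary["salt_bridges"] = _log(
            log,
            "salt_bridges",
            {"cutoff": cfg.saltbridge_cutoff},
            [{"acidic": list(a), "basic": list(bb), "distance_A": round(d, 3)} for a, bb, d in sb],
        )

        stage = "ic_polar_network"
        net_bonds, comps = anatomy.ic_polar_network(model, members=cfg.network_members, cutoff=cfg.hbond_cutoff)
        summary["ic_network_components"] = _log(
            log, "ic_polar_network", {"members": list(cfg.network_members)}, [sorted(c) for c in comps]
        )

        stage = "hydrophobic_layers"
        layers = anatomy.hydrophobic_layers(model, frame, seg, gap_threshold=cfg.layer_gap)
        pd.DataFrame(layers).to_csv(out / "layers.tsv", sep="\t", index=False)
        by_layer: dict[int, list[int]] = {}
        for r in layers:
            if r["layer"] is not None:
                by_layer.setdefault(r["layer"], []).append(r["res_seq"])
        summary["hydrophobic_layers"] = _log(
            log, "hydrophobic_layers", {"gap": cfg.layer_gap}, {k: sorted(v) for k, v in sorted(by_layer.items())}
        )

        stage = "ring_geometry"
        r1, r2 = cfg.ring_pair
        try:
            angle, dist = ring_geometry(model, r1, r2)
            summary["ring_pair"] = _log(
                log,
                "ring_geometry",
                {"residues": [r1, r2]},
                {"interplanar_angle_deg": round(angle, 2), "centroid_distance_A": round(dist, 2)},
            )
        except ValueError as exc:
            summary["ring_pair"] = None
            summary["ring_pair_skipped"] = str(exc)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        (out / "summary.partial.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(f"anatomy report failed in stage {stage!r}: {exc}") from exc

    summary["log"] = log
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def run_full_demo(seed: int = 0, out_dir: str | Path = "demo") -> dict[str, Any]:
    """Generate every synthetic input class, run every analysis, and compare
    recovered values with planted truth. Returns (and writes) the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {"seed": seed}

    # --- static anatomy on the toy receptor -------------------------------
    toy, truth = synthetic.make_toy_receptor(jitter_sd=0.05, seed=seed)
    cfg = RunConfig(out_dir=str(out / "anatomy"), seed=seed)
    report = run_anatomy_report(cfg, structure=toy)
    results["anatomy"] = {
        "tilt_recovered_deg": report["ecd_tilt_deg"],
        "tilt_planted_deg": truth.tilt_deg,
        "span_recovered_A": report["helix_span_A"],
        "span_planted_A": truth.span,
        "ring_angle_recovered_deg": report["ring_pair"]["interplanar_angle_deg"],
        "ring_angle_planted_deg": truth.ring_angle_deg,
        "layer1_recovered": report["hydrophobic_layers"].get(1, []),
        "layer1_planted": sorted(truth.layers.get(1, [])),
    }

    # --- trajectory macrostates ------------------------------------------
    table, ttruth, theta_ref = synthetic.make_tilt_trajectory(seed=seed)
    series = trajectory.tilt_series(table, theta_ref=theta_ref)
    summary = trajectory.find_macrostates(series, seed=seed)
    sb_table, sb_truth = synthetic.make_trajectory(
        state_means=(5.5, 3.0), state_sds=(0.4, 0.25), transition_ns=200.0, seed=seed
    )
    occ, first, _ = trajectory.saltbridge_occupancy(sb_table)
    results["trajectory"] = {
        "state_means_recovered_deg": list(summary.state_means),
        "state_means_planted_deg": list(ttruth.state_means),
        "transition_recovered_ns": summary.transition_time_ns,
        "transition_planted_ns": ttruth.transition_ns,
        "occupancies_recovered": list(summary.occupancies),
        "saltbridge_formation_recovered_ns": first,
        "saltbridge_formation_planted_ns": sb_truth.transition_ns,
        "saltbridge_occupancy": occ,
    }

    # --- HDX --------------------------------------------------------------
    records, design = synthetic.make_hdx_tables(seed=seed)
    summarized = hdx.summarize(records)
    wt = summarized[summarized["construct"] == "WT"]
    mut = summarized[summarized["construct"] == "C245S"]
    comparison, _ = hdx.differential(wt, mut)
    linker = comparison[(comparison.start_res == 111) & (comparison.timepoint_s == 3600.0)]
    results["hdx"] = {
        "delta_recovered_pct": float(linker["delta_pct"].iloc[0]),
        "delta_planted_pct": 12.0,
        "n_common_peptides": int(comparison[["start_res", "end_res"]].drop_duplicates().shape[0]),
    }

    # --- conservation -----------------------------------------------------
    aln, ctruth = synthetic.make_clade_msa(seed=seed)
    mammals = [i for i in aln.ids if i.startswith("mammal")]
    count, _ = conservation.absolute_conservation(aln, "ref_human", mammals)
    results["conservation"] = {
        "mammal_conserved_recovered": count,
        "mammal_conserved_planted": len(ctruth["mammal"]),
    }

    (out / "demo_summary.json").write_text(json.dumps(results, indent=2, default=str))
    return results
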