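"""Time-series analysis of receptor trajectories.

The central object is a :class:`TiltSeries`: per-frame extracellular-domain
tilt angles together with their *deviation* from a reference (crystal)
value. Deviation is defined as ``theta_ref - theta_t``, so a domain tilting
toward the membrane produces positive deviations and the second macrostate
sits at larger deviation.

Macrostate detection fits a Gaussian mixture to the deviation series (EM
with k-means initialisation, a fixed seed and multiple restarts) — a
deterministic, documented replacement for reading peaks off a histogram.
Event trackers (side-chain switch, salt-bridge formation) are simple
threshold detectors with a dwell requirement so that single-frame
excursions do not count as transitions.

Trajectories enter either as multi-model structures (each frame is
superposed on the reference TM backbone before the tilt is measured) or as
plain two-column tables (``time_ns<TAB>value``), which is how pre-computed
observables from any MD engine can be analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from . import anatomy
from .geometry import BACKBONE_ATOMS, superpose
from .structure import Model, SegmentMap, Structure

__all__ = [
    "TiltSeries",
    "MacrostateSummary",
    "EventSeries",
    "read_series_table",
    "tilt_series",
    "rolling_average",
    "deviation_histogram",
    "find_macrostates",
    "track_switch",
    "saltbridge_occupancy",
]


@dataclass
class TiltSeries:
    """Per-frame tilt angles (degrees) on a strictly increasing time grid (ns)."""

    time_ns: np.ndarray
    theta_deg: np.ndarray
    theta_ref: float
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, float)
        self.theta_deg = np.asarray(self.theta_deg, float)
        if len(self.time_ns) != len(self.theta_deg):
            raise ValueError("time and theta lengths differ")
        if len(self.time_ns) and not np.all(np.diff(self.time_ns) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def deviation(self) -> np.ndarray:
        """theta_ref - theta_t (positive = tilted toward the membrane)."""
        return self.theta_ref - self.theta_deg

    def __len__(self) -> int:
        return len(self.time_ns)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_ns": self.time_ns, "theta_deg": self.theta_deg, "deviation_deg": self.deviation}
        )
        if self.smoothed is not None:
            df["smoothed_deg"] = self.smoothed
        return df


@dataclass
class MacrostateSummary:
    """Gaussian-mixture summary of the deviation series."""

    state_means: tuple[float, ...]  # deviation degrees, ascending
    state_sds: tuple[float, ...]
    occupancies: tuple[float, ...]
    transition_time_ns: float | None
    n_states: int
    bic: float


@dataclass
class EventSeries:
    """Per-frame atom-pair distance with an in/out threshold state."""

    time_ns: np.ndarray
    value: np.ndarray
    threshold: float
    state_in: np.ndarray  # True where value <= threshold
    switch_time_ns: float | None


def read_series_table(path: str | Path) -> pd.DataFrame:
    """Read a ``time_ns<TAB>value`` table (header required)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "time_ns" not in cols or len(cols) < 2:
        raise ValueError(f"{path}: expected columns 'time_ns' and a value column, got {cols}")
    value_col = [c for c in cols if c != "time_ns"][0]
    return df.rename(columns={value_col: "value"})[["time_ns", "value"]]


def _frame_times(n: int, times: Sequence[float] | None, spacing: float) -> np.ndarray:
    if times is not None:
        return np.asarray(list(times), float)
    return np.arange(n) * spacing


def tilt_series(
    traj: Structure | pd.DataFrame | str | Path,
    ref: Model | None = None,
    seg: SegmentMap | None = None,
    theta_ref: float | None = None,
    times_ns: Sequence[float] | None = None,
    frame_spacing_ns: float = 0.1,
    tip_residues: Iterable[int] = range(32, 37),
) -> TiltSeries:
    """Extracellular-domain tilt per trajectory frame.

    Structural input: every frame's TM backbone is superposed onto ``ref``
    (whose membrane frame defines the z-axis) and the tilt is measured in
    that frame; ``theta_ref`` defaults to the tilt of ``ref`` itself.
    Tabular input (path or DataFrame with ``time_ns``/``value``): the values
    are taken as tilt angles directly, and ``theta_ref`` must be supplied.
    """
    if isinstance(traj, (str, Path)):
        traj = read_series_table(traj)
    if isinstance(traj, pd.DataFrame):
        if theta_ref is None:
            raise ValueError("theta_ref is required for tabular input")
        return TiltSeries(traj["time_ns"].to_numpy(), traj["value"].to_numpy(), theta_ref)

    if ref is None or seg is None:
        raise ValueError("structural input requires a reference model and a segment map")
    frame = anatomy.build_frame(ref, seg)
    if theta_ref is None:
        theta_ref = anatomy.ecd_tilt(ref, frame, tip_residues=tip_residues)
    helix_res: list[int] = []
    for name in seg.helices():
        helix_res.extend(seg.residues(name))
    ref_bb = ref.heavy_protein()
    ref_bb = ref_bb.subset(ref_bb.mask(residues=helix_res, atom_names=list(BACKBONE_ATOMS[:4])))
    ref_keys = {
        (str(c), int(r), str(a)): k
        for k, (c, r, a) in enumerate(zip(ref_bb.chain, ref_bb.res_seq, ref_bb.atom_name))
    }
    thetas = []
    for fi, fm in enumerate(traj.models):
        prot = fm.heavy_protein()
        bb = prot.subset(prot.mask(residues=helix_res, atom_names=list(BACKBONE_ATOMS[:4])))
        pairing = []
        for k, (c, r, a) in enumerate(zip(bb.chain, bb.res_seq, bb.atom_name)):
            key = (str(c), int(r), str(a))
            if key in ref_keys:
                pairing.append((k, ref_keys[key]))
        if len(pairing) < 3:
            raise ValueError(f"frame {fi}: too few TM backbone atoms shared with the reference")
        t, _ = superpose(bb.xyz, ref_bb.xyz, pairing)
        moved = fm.with_xyz(t.apply(fm.xyz))
        thetas.append(anatomy.ecd_tilt(moved, frame, tip_residues=tip_residues))
    time = _frame_times(len(thetas), times_ns, frame_spacing_ns)
    return TiltSeries(time, np.array(thetas), theta_ref)


def rolling_average(series: TiltSeries, window_ns: float = 1.0) -> TiltSeries:
    """Centered mean of theta over frames within +-window/2 (edges truncate)."""
    if window_ns <= 0:
        raise ValueError("window must be positive")
    t = series.time_ns
    if len(t) > 1 and window_ns <= np.diff(t).max():
        raise ValueError("window must exceed the maximum frame spacing")
    half = window_ns / 2.0
    csum = np.concatenate([[0.0], np.cumsum(series.theta_deg)])
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(series, smoothed=smoothed)


def deviation_histogram(
    series: TiltSeries, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised frequency distribution of the deviation series.

    Returns (bin centers, frequencies summing to 1).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    dev = series.deviation
    lo = np.floor(dev.min() / bin_width) * bin_width
    hi = np.ceil(dev.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(dev, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / counts.sum()


def find_macrostates(
    series: TiltSeries,
    n_states: int | str = 2,
    seed: int = 0,
    n_restarts: int = 50,
    dwell_ns: float = 10.0,
    smoothing_window_ns: float = 1.0,
) -> MacrostateSummary:
    """Identify tilt macrostates by a Gaussian mixture on the deviation series.

    ``n_states`` is 1, 2 or ``"auto"`` (BIC choice between 1 and 2). States
    are reported sorted by ascending mean deviation; occupancies are the
    mixture weights. The transition time is the first time the 1-ns smoothed
    series enters within one SD of the last state's mean and stays there for
    at least ``dwell_ns``.
    """
    if len(series) < 200:
        raise ValueError(f"macrostate fit needs >= 200 frames (got {len(series)})")
    dev = series.deviation.reshape(-1, 1)

    def fit(k: int) -> GaussianMixture:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            init_params="kmeans",
            random_state=seed,
            max_iter=500,
        )
        gm.fit(dev)
        if not gm.converged_:
            raise RuntimeError(
                f"mixture EM did not converge after {n_restarts} restarts "
                f"(lower bound {gm.lower_bound_:.3f})"
            )
        return gm

    if n_states == "auto":
        fits = {k: fit(k) for k in (1, 2)}
        bics = {k: fits[k].bic(dev) for k in fits}
        k = min(bics, key=bics.get)
        gm = fits[k]
    else:
        k = int(n_states)
        gm = fit(k)

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k, -1)[:, 0])
    weights = gm.weights_
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    transition = None
    if k >= 2:
        smoothed_series = series if series.smoothed is not None else rolling_average(series, smoothing_window_ns)
        sm_dev = smoothed_series.theta_ref - smoothed_series.smoothed
        inside = np.abs(sm_dev - means[-1]) <= sds[-1]
        transition = _first_sustained(series.time_ns, inside, dwell_ns)

    return MacrostateSummary(
        state_means=tuple(float(m) for m in means),
        state_sds=tuple(float(s) for s in sds),
        occupancies=tuple(float(w) for w in weights),
        transition_time_ns=transition,
        n_states=k,
        bic=float(gm.bic(dev)),
    )


def _first_sustained(time: np.ndarray, condition: np.ndarray, dwell_ns: float) -> float | None:
    """First time at which ``condition`` holds continuously for >= dwell."""
    n = len(time)
    i = 0
    while i < n:
        if not condition[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and condition[j + 1]:
            j += 1
        if time[j] - time[i] >= dwell_ns:
            return float(time[i])
        i = j + 1
    return None


def _min_distance_trace(
    traj: Structure,
    donor: tuple[str | None, int, str],
    acceptors: Sequence[tuple[str | None, int, str]],
) -> np.ndarray:
    values = []
    for fi, fm in enumerate(traj.models):
        dm = fm.mask(chain=donor[0], residues=[donor[1]], atom_names=[donor[2]])
        if not dm.any():
            raise ValueError(f"frame {fi}: donor atom {donor} absent")
        dxyz = fm.xyz[dm][0]
        best = np.inf
        for acc in acceptors:
            am = fm.mask(chain=acc[0], residues=[acc[1]], atom_names=[acc[2]])
            if not am.any():
                raise ValueError(f"frame {fi}: acceptor atom {acc} absent")
            best = min(best, float(np.linalg.norm(fm.xyz[am][0] - dxyz)))
        values.append(best)
    return np.array(values)


def track_switch(
    traj: Structure | pd.DataFrame | str | Path,
    donor: tuple[str | None, int, str] = (None, 184, "OH"),
    acceptors: Sequence[tuple[str | None, int, str]] = ((None, 242, "O"), (None, 244, "N")),
    threshold: float = 3.5,
    dwell_ns: float = 5.0,
    times_ns: Sequence[float] | None = None,
    frame_spacing_ns: float = 0.1,
) -> EventSeries:
    """Track a side-chain 'in/out' switch via a min-distance threshold.

    Per frame the minimum donor-acceptor distance is taken; the state is
    'in' while it stays at or below ``threshold``. The switch time is the
    first time the state leaves 'in' and remains out for >= ``dwell_ns``.
    """
    if isinstance(traj, (str, Path)):
        traj = read_series_table(traj)
    if isinstance(traj, pd.DataFrame):
        time = traj["time_ns"].to_numpy(float)
        values = traj["value"].to_numpy(float)
    else:
        values = _min_distance_trace(traj, donor, acceptors)
        time = _frame_times(len(values), times_ns, frame_spacing_ns)
    state_in = values <= threshold
    switch = _first_sustained(time, ~state_in, dwell_ns)
    return EventSeries(time, values, threshold, state_in, switch)


def saltbridge_occupancy(
    traj: Structure | pd.DataFrame | str | Path,
    acid_res: int = 183,
    base_res: int = 187,
    cutoff: float = 4.0,
    dwell_ns: float = 5.0,
    times_ns: Sequence[float] | None = None,
    frame_spacing_ns: float = 0.1,
) -> tuple[float, float | None, EventSeries]:
    """Fraction of frames with the salt bridge formed, plus its first
    sustained formation time.

    Distance per frame is the minimal side-chain carboxylate-O to
    amine/guanidinium-N distance; 'formed' means distance <= ``cutoff``
    sustained for >= ``dwell_ns``.
    """
    if isinstance(traj, (str, Path)):
        traj = read_series_table(traj)
    if isinstance(traj, pd.DataFrame):
        time = traj["time_ns"].to_numpy(float)
        values = traj["value"].to_numpy(float)
    else:
        values = []
        for fi, fm in enumerate(traj.models):
            prot = fm.heavy_protein()
            am = prot.mask(residues=[acid_res], atom_names=["OD1", "OD2", "OE1", "OE2"])
            bm = prot.mask(residues=[base_res], atom_names=["NZ", "NE", "NH1", "NH2", "ND1", "NE2"])
            if not am.any() or not bm.any():
                raise ValueError(f"frame {fi}: salt-bridge atoms absent for {acid_res}/{base_res}")
            d = np.linalg.norm(
                prot.xyz[am][:, None, :] - prot.xyz[bm][None, :, :], axis=-1
            ).min()
            values.append(float(d))
        values = np.array(values)
        time = _frame_times(len(values), times_ns, frame_spacing_ns)
    formed = np.asarray(values) <= cutoff
    occupancy = float(formed.mean()) if len(formed) else 0.0
    first = _first_sustained(np.asarray(time), formed, dwell_ns)
    ev = EventSeries(np.asarray(time), np.asarray(values), cutoff, formed, first)
    return occupancy, first, ev
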