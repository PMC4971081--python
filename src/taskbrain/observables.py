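"""From neural activity to imaging observables.

Integrated synaptic activity (ISA) is the sum of the absolute values of all
synaptic inputs IN_i to every member of a region of interest, integrated
over 50-ms windows — the neural drive a synaptic-imaging method would see.
The ISA of each ROI feeds a Balloon-Windkessel hemodynamic model

    ds/dt = eff * x - s / tau_s - (f - 1) / tau_f
    df/dt = s
    tau0 dv/dt = f - v^(1/alpha)
    tau0 dq/dt = f (1 - (1 - E0)^(1/f)) / E0 - v^(1/alpha) q / v

read out as y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)), with
k1 = 4.3 theta0 E0 TE, k2 = eps r0 E0 TE, k3 = 1 - eps.  The resulting
series is decimated to the scanner TR (2 s).

ISA is normalized to zero mean and unit range before entering the balloon
model, so the efficacy parameter acts on a bounded, baseline-free drive (the
read-out is thereby invariant to a constant ISA offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import REGION_MODULES, Roi
from .experiment import ExperimentDesign, Recordings
from .params import BalloonParams

__all__ = [
    "IsaSeries",
    "BoldSeries",
    "unit_input_magnitude",
    "integrated_synaptic_activity",
    "isa_by_region",
    "balloon_bold",
    "BlockSignalChange",
    "block_signal_change",
]


@dataclass
class IsaSeries:
    """ROI-level integrated synaptic activity at fixed bins (arbitrary units)."""

    values: np.ndarray
    bin_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class BoldSeries:
    """ROI-level BOLD signal at scanner TR (arbitrary units)."""

    values: np.ndarray
    tr_s: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def unit_input_magnitude(
    unit_state: tuple[float, float],
    weights: dict[str, float],
    afferent_states: tuple[np.ndarray, np.ndarray] = ((), ()),
) -> float:
    """Reference IN_i: sum of absolute values of all inputs to one unit.

    ``unit_state`` is (E_i, I_i); ``weights`` needs w_EE, w_EI, w_IE;
    ``afferent_states`` is (weight_k, E_k) over all long-range afferents
    (task units and connectome nodes alike).
    """
    E, I = unit_state
    wk, Ek = (np.asarray(a, dtype=float) for a in afferent_states)
    if wk.shape != Ek.shape:
        raise ValueError("afferent weight/activity length mismatch")
    return float(
        abs(weights["w_EE"] * E)
        + abs(weights["w_EI"] * E)
        + abs(weights["w_IE"] * I)
        + np.abs(wk * Ek).sum()
    )


def _roi_columns(recordings: Recordings, roi: Roi) -> tuple[slice | None, list[int]]:
    units = recordings.unit_slice(roi.module) if roi.module is not None else None
    return units, list(roi.nodes)


def integrated_synaptic_activity(
    recordings: Recordings,
    roi: Roi | list[Roi],
    window_ms: float = 50.0,
    label: str = "",
) -> IsaSeries:
    """ISA of one ROI (or the union of several) from recorded input traces.

    Per output bin: the sum of IN_i over all ROI members (module units and
    connectome nodes) and all time steps inside the window.
    """
    rois = roi if isinstance(roi, list) else [roi]
    ratio = window_ms / recordings.input_bin_ms
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"window {window_ms} ms is not a multiple of the recorded "
            f"input bin ({recordings.input_bin_ms} ms)"
        )
    group = int(round(ratio))
    per_bin = np.zeros(recordings.in_nodes.shape[0])
    seen_nodes: set[int] = set()
    for r in rois:
        units, nodes = _roi_columns(recordings, r)
        if units is not None:
            per_bin += recordings.in_units[:, units].sum(axis=1)
        new_nodes = [n for n in nodes if n not in seen_nodes]
        seen_nodes.update(new_nodes)
        if new_nodes:
            per_bin += recordings.in_nodes[:, new_nodes].sum(axis=1)
    n_out = per_bin.shape[0] // group
    vals = per_bin[: n_out * group].reshape(n_out, group).sum(axis=1)
    return IsaSeries(values=vals, bin_ms=window_ms, label=label or (rois[0].module or "roi"))


def isa_by_region(
    recordings: Recordings,
    rois: dict[str, Roi],
    region_map: dict[str, tuple[str, ...]] | None = None,
    window_ms: float = 50.0,
) -> dict[str, IsaSeries]:
    """ISA per anatomical region, merging orientation-channel ROIs (V1, V4)."""
    region_map = region_map or REGION_MODULES
    out: dict[str, IsaSeries] = {}
    for region, modules in region_map.items():
        members = [rois[m] for m in modules if m in rois]
        if members:
            out[region] = integrated_synaptic_activity(
                recordings, members, window_ms, label=region
            )
    return out


def balloon_bold(
    isa: IsaSeries,
    params: BalloonParams | None = None,
    tr_s: float = 2.0,
    substeps: int = 1,
) -> BoldSeries:
    """Balloon-Windkessel BOLD from an ISA series, decimated to TR.

    The ISA is normalized to zero mean / unit range (an all-constant series
    maps to zero drive).  The hemodynamic ODEs start from rest
    (s, f, v, q) = (0, 1, 1, 1) and are integrated with explicit Euler at the
    ISA bin width divided by ``substeps``.
    """
    p = params or BalloonParams()
    x_raw = np.asarray(isa.values, dtype=float)
    if not np.all(np.isfinite(x_raw)):
        raise ValueError("non-finite ISA values")
    rng_ = x_raw.max() - x_raw.min() if x_raw.size else 0.0
    x = (x_raw - x_raw.mean()) / rng_ if rng_ > 0 else np.zeros_like(x_raw)

    bin_s = isa.bin_ms / 1000.0
    h = bin_s / substeps
    s, f, v, q = 0.0, 1.0, 1.0, 1.0
    y = np.empty_like(x)
    for i, xi in enumerate(x):
        for _ in range(substeps):
            ds = p.efficacy * xi - s / p.tau_s - (f - 1.0) / p.tau_f
            df = s
            dv = (f - v ** (1.0 / p.alpha)) / p.tau0
            dq = (
                f * (1.0 - (1.0 - p.E0) ** (1.0 / f)) / p.E0
                - v ** (1.0 / p.alpha) * q / v
            ) / p.tau0
            s += h * ds
            f += h * df
            v += h * dv
            q += h * dq
            # physiological floors: inflow, volume and dHb stay positive even
            # under strongly negative noise-driven drive (Euler robustness)
            f = max(f, 1e-2)
            v = max(v, 1e-2)
            q = max(q, 1e-2)
        y[i] = p.V0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v) + p.k3 * (1.0 - v))

    stride = tr_s / bin_s
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("TR must be a multiple of the ISA bin width")
    stride = int(round(stride))
    n_tr = len(y) // stride
    vals = y[stride - 1 : n_tr * stride : stride]  # sample at the end of each TR
    return BoldSeries(values=vals, tr_s=tr_s, label=isa.label)


@dataclass
class BlockSignalChange:
    """Per-condition block-evoked signal change (percent about the mean)."""

    dms_mean: float
    ctl_mean: float

    @property
    def difference(self) -> float:
        return self.dms_mean - self.ctl_mean


def block_signal_change(
    bold: BoldSeries,
    design: ExperimentDesign,
    timepoints: tuple[int, ...] = (4, 5, 6),
) -> BlockSignalChange:
    """Mean signal at selected TRs after each block onset, per condition.

    The signal is expressed as percent change about the series mean;
    timepoint k is the k-th TR after (and excluding) the onset volume.
    """
    y = bold.values
    pct = 100.0 * (y - y.mean())
    per_cond: dict[str, list[float]] = {"DMS": [], "CTL": []}
    for onset_s, cond in design.block_onsets():
        onset_tr = int(np.floor(onset_s / bold.tr_s))
        idx = [onset_tr + k for k in timepoints]
        if max(idx) >= len(y):
            raise ValueError("block extends past the end of the BOLD series")
        per_cond[cond].append(float(np.mean(pct[idx])))
    return BlockSignalChange(
        dms_mean=float(np.mean(per_cond["DMS"])) if per_cond["DMS"] else np.nan,
        ctl_mean=float(np.mean(per_cond["CTL"])) if per_cond["CTL"] else np.nan,
    )
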