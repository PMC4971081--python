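"""Within-condition functional connectivity and group statistics.

Functional connectivity (FC) is the Pearson correlation of two regions' time
series over the timepoints belonging to one task condition.  Per-subject FC
values are averaged across subjects through a Fisher Z transform
(tanh of the mean atanh), and condition differences are assessed with paired
t-tests (two-sided, uncorrected — each region pair tested on its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .experiment import ExperimentDesign

__all__ = [
    "condition_timepoints",
    "functional_connectivity",
    "group_average_fc",
    "TTestResult",
    "paired_ttest",
    "fc_condition_table",
]


def condition_timepoints(
    design: ExperimentDesign,
    sampling_interval_s: float,
    lag: int = 0,
    duration_s: float | None = None,
) -> dict[str, np.ndarray]:
    """Disjoint per-condition sample-index sets for a sampled series.

    Sample i (acquired at ``i * sampling_interval_s``) belongs to the block
    containing that time.  ``lag`` shifts every index forward (e.g. to
    compensate hemodynamic delay), truncating at the series end.
    """
    total = duration_s if duration_s is not None else design.total_s
    n = int(np.floor(total / sampling_interval_s))
    out: dict[str, list[int]] = {"DMS": [], "CTL": []}
    if design.trials:
        onsets = design.block_onsets()
        bounds = [t for t, _ in onsets] + [design.total_s]
        conds = [c for _, c in onsets]
        for i in range(n):
            t = i * sampling_interval_s
            b = int(np.searchsorted(bounds, t, side="right")) - 1
            if 0 <= b < len(conds):
                out[conds[b]].append(i)
    result = {}
    for cond, idx in out.items():
        arr = np.asarray(idx, dtype=int) + lag
        result[cond] = arr[arr < n]
    return result


def functional_connectivity(x: np.ndarray, y: np.ndarray, indices: np.ndarray) -> float:
    """Pearson correlation of two series over the selected samples."""
    idx = np.asarray(indices, dtype=int)
    if idx.size < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    a = np.asarray(x, dtype=float)[idx]
    b = np.asarray(y, dtype=float)[idx]
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite series values")
    a = a - a.mean()
    b = b - b.mean()
    va = np.dot(a, a)
    vb = np.dot(b, b)
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-variance series")
    return float(np.dot(a, b) / np.sqrt(va * vb))


def group_average_fc(r_values) -> float:
    """Fisher-Z average of correlations: tanh(mean(atanh(r)))."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 cannot be Fisher-averaged")
    return float(np.tanh(np.arctanh(r).mean()))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def paired_ttest(a, b) -> TTestResult:
    """Paired two-sided t-test: t = mean(d) / (sd(d) / sqrt(n)), df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero difference variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p))


def fc_condition_table(
    seed_series: list[dict[str, np.ndarray]],
    seed_region: str,
    indices: dict[str, np.ndarray],
) -> "object":
    """Per-region FC-vs-seed summary across subjects.

    ``seed_series``: one dict per subject mapping region name -> series
    (uniformly sampled, same grid as ``indices``).  Returns a DataFrame with
    Fisher-averaged within-condition FC per region, the mean within-subject
    DMS-CTL difference, and its paired t statistic.
    """
    import pandas as pd

    regions = [r for r in seed_series[0] if r != seed_region]
    rows = []
    for region in regions:
        per_cond = {}
        for cond in ("DMS", "CTL"):
            per_cond[cond] = np.array(
                [
                    functional_connectivity(s[seed_region], s[region], indices[cond])
                    for s in seed_series
                ]
            )
        diff = per_cond["DMS"] - per_cond["CTL"]
        row = {
            "region": region,
            "dms_mean": group_average_fc(per_cond["DMS"]),
            "dms_sd": float(per_cond["DMS"].std(ddof=1)) if len(seed_series) > 1 else np.nan,
            "ctl_mean": group_average_fc(per_cond["CTL"]),
            "ctl_sd": float(per_cond["CTL"].std(ddof=1)) if len(seed_series) > 1 else np.nan,
            "mean_difference": float(diff.mean()),
        }
        if len(seed_series) > 1 and diff.std(ddof=1) > 0:
            res = paired_ttest(per_cond["DMS"], per_cond["CTL"])
            row["t"] = res.t
            row["p"] = res.p
        else:
            row["t"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
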