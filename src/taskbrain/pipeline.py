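"""High-level study pipeline: from config + seed to group-level statistics.

Chains the pieces a full simulated experiment needs: synthesize (or load) a
connectome, embed the task circuit, generate retained subjects through the
inclusion loop, compute ROI-level integrated synaptic activity and BOLD, and
produce the group tables (per-condition block signal change and seed-based
functional connectivity).  The command-line interface and the acceptance
script are thin wrappers around these calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import condition_timepoints, fc_condition_table, paired_ttest
from .connectome import Connectome
from .embedding import (
    REGION_MODULES,
    HybridNetwork,
    Roi,
    build_embedding,
    contralateral_roi,
    default_module_specs,
    define_rois,
)
from .experiment import (
    ExperimentDesign,
    Recordings,
    SubjectWeights,
    build_dms_design,
    generate_accepted_subjects,
    run_connectome_stimulation,
)
from .observables import balloon_bold, block_signal_change, isa_by_region
from .params import BalloonParams, LsnmParams, TvbNodeParams
from .synth import SyntheticConnectomeSpec, synthesize_connectome
from .templates import default_module_params

__all__ = ["StudySetup", "SubjectResult", "StudyResult", "build_setup", "run_study"]


@dataclass
class StudySetup:
    """The shared substrate of a study: connectome, embedding, ROIs, design."""

    connectome: Connectome
    hybrid: HybridNetwork
    rois: dict[str, Roi]
    cit_roi: Roi
    design: ExperimentDesign
    tvb_params: TvbNodeParams
    module_params: dict[str, LsnmParams]
    balloon_params: BalloonParams


@dataclass
class SubjectResult:
    """One retained subject's recordings and derived series."""

    subject: SubjectWeights
    recordings: Recordings
    accuracy: float
    isa: dict[str, np.ndarray] = field(default_factory=dict)  # region -> series
    bold: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class StudyResult:
    setup: StudySetup
    subjects: list[SubjectResult]
    signal_change: pd.DataFrame | None = None
    fc_isa: pd.DataFrame | None = None
    fc_bold: pd.DataFrame | None = None


def build_setup(config: dict, seed: int, connectome: Connectome | None = None) -> StudySetup:
    """Construct the study substrate from a validated config dict."""
    rng = np.random.default_rng(seed)
    specs = default_module_specs()
    if connectome is None:
        cc = config["connectome"]
        anchors = [s.target_talairach for s in specs] if cc["anchor_modules"] else []
        connectome = synthesize_connectome(
            SyntheticConnectomeSpec(
                n_nodes=cc["n_nodes"],
                density=cc["density"],
                decay_mm=cc["decay_mm"],
                weight_scale=cc["weight_scale"],
                seed=int(cc["seed"] if cc["seed"] else rng.integers(2**31)),
                anchor_points=anchors,
            )
        )
    ec = config["embedding"]
    hybrid = build_embedding(
        connectome,
        specs,
        G=ec["G"],
        rng=rng,
        coupling_sd_frac=ec["coupling_sd_frac"],
        on_collision=ec["on_collision"],
    )
    rois = define_rois(hybrid, k=ec["k_roi"])
    cit = contralateral_roi(hybrid, "IT", k=ec["k_roi"])
    xc = config["experiment"]
    design = build_dms_design(
        n_blocks=xc["n_blocks"],
        attention_range=(xc["attention_min"], xc["attention_max"]),
        ctl_attention=xc["ctl_attention"],
        rng=np.random.default_rng(rng.integers(2**31)),
        retention=xc["retention"],
    )
    dc = config["dynamics"]
    tvb = TvbNodeParams(noise_sd=dc["tvb_noise_sd"], conduction_speed=dc["conduction_speed"])
    mp = default_module_params(LsnmParams(noise_sd=dc["lsnm_noise_sd"]))
    return StudySetup(
        connectome=connectome,
        hybrid=hybrid,
        rois=rois,
        cit_roi=cit,
        design=design,
        tvb_params=tvb,
        module_params=mp,
        balloon_params=BalloonParams(),
    )


def _derive_series(setup: StudySetup, rec: Recordings, config: dict) -> tuple[dict, dict]:
    """Region-level ISA and BOLD series (cIT control region included)."""
    window = config["bold"]["isa_window_ms"]
    isa = isa_by_region(rec, setup.rois, REGION_MODULES, window_ms=window)
    from .observables import integrated_synaptic_activity

    isa["cIT"] = integrated_synaptic_activity(rec, setup.cit_roi, window, label="cIT")
    bold = {
        name: balloon_bold(
            s, setup.balloon_params, tr_s=config["bold"]["tr_s"],
            substeps=config["bold"]["substeps"],
        )
        for name, s in isa.items()
    }
    return (
        {k: v.values for k, v in isa.items()},
        {k: v.values for k, v in bold.items()},
    )


def run_study(
    config: dict,
    seed: int,
    n_subjects: int | None = None,
    connectome: Connectome | None = None,
    setup: StudySetup | None = None,
) -> StudyResult:
    """Run the full multi-subject study and compute group statistics.

    Subjects are generated through the inclusion loop (retained only above
    the accuracy bound); each retained subject contributes ROI ISA and BOLD
    series, per-condition block signal change, and seed-based FC.
    """
    setup = setup or build_setup(config, seed, connectome=connectome)
    xc = config["experiment"]
    n_subjects = n_subjects if n_subjects is not None else xc["n_subjects"]
    rng = np.random.default_rng(seed + 1)

    accepted = generate_accepted_subjects(
        setup.hybrid,
        setup.design,
        n_subjects,
        rng,
        min_accuracy=xc["min_accuracy"],
        max_attempts=xc["max_attempts"],
        tvb_params=setup.tvb_params,
        module_params=setup.module_params,
        dt_ms=config["dynamics"]["dt_ms"],
        burn_in_s=xc["burn_in_s"],
    )

    subjects = []
    for subj, rec, acc in accepted:
        isa, bold = _derive_series(setup, rec, config)
        subjects.append(SubjectResult(subject=subj, recordings=rec, accuracy=acc, isa=isa, bold=bold))

    result = StudyResult(setup=setup, subjects=subjects)
    if subjects:
        result.signal_change = _signal_change_table(setup, subjects, config)
        tr = config["bold"]["tr_s"]
        window_s = config["bold"]["isa_window_ms"] / 1000.0
        idx_isa = condition_timepoints(setup.design, window_s)
        idx_bold = condition_timepoints(setup.design, tr)
        result.fc_isa = fc_condition_table([s.isa for s in subjects], "IT", idx_isa)
        result.fc_bold = fc_condition_table([s.bold for s in subjects], "IT", idx_bold)
    return result


def _signal_change_table(setup, subjects, config) -> pd.DataFrame:
    from .observables import BoldSeries

    rows = []
    tr = config["bold"]["tr_s"]
    regions = [r for r in subjects[0].bold if r != "cIT"]
    for region in regions:
        per_subj = [
            block_signal_change(BoldSeries(s.bold[region], tr), setup.design)
            for s in subjects
        ]
        dms = np.array([b.dms_mean for b in per_subj])
        ctl = np.array([b.ctl_mean for b in per_subj])
        row = {
            "region": region,
            "dms_mean": dms.mean(),
            "dms_sd": dms.std(ddof=1) if len(dms) > 1 else np.nan,
            "ctl_mean": ctl.mean(),
            "ctl_sd": ctl.std(ddof=1) if len(ctl) > 1 else np.nan,
            "mean_difference": (dms - ctl).mean(),
        }
        if len(dms) > 1 and (dms - ctl).std(ddof=1) > 0:
            res = paired_ttest(dms, ctl)
            row["t"], row["p"] = res.t, res.p
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_stimulation_control(
    config: dict, seed: int, setup: StudySetup
) -> tuple[Recordings, dict[str, np.ndarray]]:
    """Connectome-only pulse-stimulation control at the V1 host node."""
    rng = np.random.default_rng(seed + 2)
    target = setup.hybrid.placements["V1h"].host_node
    rec = run_connectome_stimulation(
        setup.connectome,
        setup.design,
        rng,
        target_node=target,
        amplitude=config["stimulation"]["amplitude"],
        G=config["embedding"]["G"],
        tvb_params=setup.tvb_params,
        dt_ms=config["dynamics"]["dt_ms"],
        burn_in_s=config["experiment"]["burn_in_s"],
    )
    # node-only ROIs: same node membership as the hybrid ROIs
    from .observables import integrated_synaptic_activity

    window = config["bold"]["isa_window_ms"]
    isa = {}
    for region, modules in REGION_MODULES.items():
        rois = [Roi(module=None, host_node=setup.rois[m].host_node, nodes=setup.rois[m].nodes)
                for m in modules if m in setup.rois]
        isa[region] = integrated_synaptic_activity(rec, rois, window, label=region).values
    isa["cIT"] = integrated_synaptic_activity(rec, setup.cit_roi, window, label="cIT").values
    return rec, isa
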