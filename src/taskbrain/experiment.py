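"""Delayed match-to-sample experiments on the hybrid network.

An experiment is an alternating sequence of DMS and passive-viewing (CTL)
blocks of three trials each.  One trial is S1 (1 s), delay (1.5 s), S2 (1 s),
inter-trial interval (2 s) — 5.5 s, so a 3-trial block lasts 16.5 s and the
default 12-block experiment 198 s.  During DMS trials the attention/task-
control parameter is high (varied per block across 0.24-0.34); CTL trials run
at a constant low attention (0.05) with degraded stimuli, and no response is
expected.  A trial is answered when at least ``min_units`` response-module
(FR) units exceed a 0.7 activity threshold during the response window (the
S2 period); on match trials that counts as correct, on mismatch trials as a
false alarm.

Simulated subjects differ in their feed-forward inter-module weights (each
template scaled by an independent uniform draw in [0.95, 1]) and in their
noise stream; the structural connectome is shared.  Subjects are retained
when their DMS accuracy exceeds 60%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CompiledNetwork, step_network
from .connectome import Connectome
from .embedding import UNITS_PER_MODULE, HybridNetwork, build_embedding
from .params import LsnmParams, TvbNodeParams
from .templates import (
    SHAPE_LIBRARY,
    LsnmWeightSet,
    StimulusPattern,
    default_weight_set,
    shape_grids,
)

__all__ = [
    "Trial",
    "ExperimentDesign",
    "build_dms_design",
    "make_stimulus",
    "SubjectWeights",
    "generate_subject",
    "Recordings",
    "run_experiment",
    "TrialOutcome",
    "score_trial",
    "score_experiment",
    "compute_performance",
    "generate_accepted_subjects",
    "run_connectome_stimulation",
]

# canonical phase durations (s)
S1_S = 1.0
DELAY_S = 1.5
S2_S = 1.0
ITI_S = 2.0
TRIAL_S = S1_S + DELAY_S + S2_S + ITI_S  # 5.5
TRIALS_PER_BLOCK = 3
BLOCK_S = TRIALS_PER_BLOCK * TRIAL_S  # 16.5


def make_stimulus(
    shape_id: str,
    degraded: bool = False,
    rng: np.random.Generator | None = None,
    retention: float = 0.5,
) -> StimulusPattern:
    """Instantiate a library shape as an orientation-channel pattern.

    Degraded patterns randomly retain ``retention`` of the active cells
    (independently per cell), emulating the noisy, partial shapes shown
    during passive viewing.
    """
    gh, gv = shape_grids(shape_id)
    if degraded:
        if rng is None:
            raise ValueError("degraded stimuli require an rng")
        keep = rng.random(gh.shape) < retention
        gh = gh * keep
        gv = gv * keep
    return StimulusPattern(shape_id=shape_id, grid_h=gh, grid_v=gv, degraded=degraded)


@dataclass
class Trial:
    """One timed trial with its stimuli and control parameters."""

    condition: str  # "DMS" or "CTL"
    s1: StimulusPattern
    s2: StimulusPattern
    match: bool | None  # None for CTL
    attention: float
    onset_s: float

    @property
    def s1_off_s(self) -> float:
        return self.onset_s + S1_S

    @property
    def s2_on_s(self) -> float:
        return self.onset_s + S1_S + DELAY_S

    @property
    def s2_off_s(self) -> float:
        return self.s2_on_s + S2_S

    @property
    def end_s(self) -> float:
        return self.onset_s + TRIAL_S


@dataclass
class ExperimentDesign:
    """A timed block/trial schedule."""

    trials: list[Trial]
    iti_attention: float = 0.05  # attention between trials (resets the loop)
    ctl_attention: float = 0.05

    @property
    def total_s(self) -> float:
        return self.trials[-1].end_s if self.trials else 0.0

    @property
    def n_blocks(self) -> int:
        return len(self.trials) // TRIALS_PER_BLOCK

    def block_onsets(self) -> list[tuple[float, str]]:
        """(onset_s, condition) per 3-trial block."""
        out = []
        for b in range(self.n_blocks):
            t = self.trials[b * TRIALS_PER_BLOCK]
            out.append((t.onset_s, t.condition))
        return out

    def dms_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.condition == "DMS"]


def build_dms_design(
    n_blocks: int = 12,
    attention_range: tuple[float, float] = (0.24, 0.34),
    ctl_attention: float = 0.05,
    rng: np.random.Generator | None = None,
    match_sequence: tuple[str, ...] = ("match", "mismatch", "match"),
    retention: float = 0.5,
) -> ExperimentDesign:
    """Alternating DMS/CTL blocks of three trials (DMS first).

    DMS attention is evenly spaced across the DMS blocks within
    ``attention_range``; CTL blocks run at the constant ``ctl_attention``.
    Shapes are drawn from the library (S2 repeats S1 on match trials); CTL
    trials always use degraded patterns.
    """
    lo, hi = attention_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("attention_range must lie within (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    shape_ids = [s for s in SHAPE_LIBRARY if s != "blank"]
    n_dms = (n_blocks + 1) // 2
    att = np.linspace(lo, hi, n_dms) if n_dms > 1 else np.array([(lo + hi) / 2])

    trials: list[Trial] = []
    dms_i = 0
    for b in range(n_blocks):
        is_dms = b % 2 == 0
        attention = float(att[dms_i]) if is_dms else ctl_attention
        if is_dms:
            dms_i += 1
        for k in range(TRIALS_PER_BLOCK):
            onset = b * BLOCK_S + k * TRIAL_S
            s1_id = shape_ids[rng.integers(len(shape_ids))]
            if is_dms:
                match = match_sequence[k % len(match_sequence)] == "match"
                if match:
                    s2_id = s1_id
                else:
                    others = [s for s in shape_ids if s != s1_id]
                    s2_id = others[rng.integers(len(others))]
                s1 = make_stimulus(s1_id)
                s2 = make_stimulus(s2_id)
                trials.append(Trial("DMS", s1, s2, match, attention, onset))
            else:
                s1 = make_stimulus(s1_id, degraded=True, rng=rng, retention=retention)
                s2_id = shape_ids[rng.integers(len(shape_ids))]
                s2 = make_stimulus(s2_id, degraded=True, rng=rng, retention=retention)
                trials.append(Trial("CTL", s1, s2, None, attention, onset))
    return ExperimentDesign(trials=trials, iti_attention=ctl_attention, ctl_attention=ctl_attention)


@dataclass
class SubjectWeights:
    """Per-subject feed-forward weight multipliers (feedback untouched)."""

    multipliers: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.multipliers.items():
            if not (0.95 <= v <= 1.0):
                raise ValueError(f"multiplier {k}={v} outside [0.95, 1]")


def generate_subject(base_weights: LsnmWeightSet, rng: np.random.Generator) -> SubjectWeights:
    """One simulated subject: an independent uniform multiplier in
    [0.95, 1] per feed-forward template."""
    return SubjectWeights(
        {key: float(rng.uniform(0.95, 1.0)) for key in base_weights.feedforward_keys()}
    )


@dataclass
class Recordings:
    """Per-timestep activities plus binned absolute-input traces.

    ``lsnm_E``/``lsnm_I`` are (n_steps, U) unit activities, ``tvb_E``
    (n_steps, n) node activities (float32).  ``in_units``/``in_nodes`` hold
    the per-member input magnitudes IN_i summed over ``input_bin_ms`` bins —
    the raw material of integrated synaptic activity.
    """

    dt_ms: float
    module_names: list[str]
    host_nodes: dict[str, int]
    lsnm_E: np.ndarray
    lsnm_I: np.ndarray
    tvb_E: np.ndarray
    input_bin_ms: float
    in_units: np.ndarray
    in_nodes: np.ndarray
    design: ExperimentDesign | None = None

    @property
    def n_steps(self) -> int:
        return self.lsnm_E.shape[0] if self.lsnm_E.size else self.tvb_E.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.tvb_E.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_ms / 1000.0

    def unit_slice(self, module: str) -> slice:
        i = self.module_names.index(module)
        return slice(i * UNITS_PER_MODULE, (i + 1) * UNITS_PER_MODULE)

    def module_E(self, module: str) -> np.ndarray:
        return self.lsnm_E[:, self.unit_slice(module)]


def _drive_segments(
    design: ExperimentDesign, ws: LsnmWeightSet, net: CompiledNetwork, dt_ms: float
) -> list[tuple[int, np.ndarray | None]]:
    """Piecewise-constant unit-drive schedule as (start_step, vector) pairs."""
    names = net.hybrid.module_names
    sl = {m: net.hybrid.unit_slice(m) for m in names}

    def vec(stim: StimulusPattern | None, attention: float) -> np.ndarray:
        v = np.zeros(net.U)
        if stim is not None:
            v[sl["V1h"]] = ws.stimulus_gain * stim.grid_h.ravel()
            v[sl["V1v"]] = ws.stimulus_gain * stim.grid_v.ravel()
        v[sl["D2"]] += ws.attention_gain * attention
        return v

    def step_of(t_s: float) -> int:
        return int(round(t_s * 1000.0 / dt_ms))

    segs: list[tuple[int, np.ndarray | None]] = []
    for tr in design.trials:
        att = tr.attention
        segs.append((step_of(tr.onset_s), vec(tr.s1, att)))
        segs.append((step_of(tr.s1_off_s), vec(None, att)))
        segs.append((step_of(tr.s2_on_s), vec(tr.s2, att)))
        segs.append((step_of(tr.s2_off_s), vec(None, design.iti_attention)))
    return segs


def run_experiment(
    hybrid: HybridNetwork,
    design: ExperimentDesign,
    rng: np.random.Generator,
    subject: SubjectWeights | None = None,
    weight_set: LsnmWeightSet | None = None,
    tvb_params: TvbNodeParams | None = None,
    module_params: dict[str, LsnmParams] | None = None,
    dt_ms: float = 5.0,
    input_bin_ms: float = 50.0,
    burn_in_s: float = 2.0,
) -> Recordings:
    """Simulate one subject through a full design; returns :class:`Recordings`.

    The burn-in period (default 2 s, not recorded) lets the connectome settle
    into its stochastic steady state (the noise-sustained high branch of the
    node dynamics) before the first trial.
    """
    needed = {"V1h", "V1v", "D2", "FR"}
    have = set(hybrid.module_names)
    if not needed <= have:
        raise ValueError(f"design needs modules {sorted(needed - have)} not present in network")
    ws = weight_set if weight_set is not None else default_weight_set()
    if subject is not None:
        ws = ws.scaled(subject.multipliers)
    hybrid.lsnm_weights = ws

    net = CompiledNetwork.compile(
        hybrid, tvb_params=tvb_params, module_params=module_params, weight_set=ws, dt_ms=dt_ms
    )
    bin_steps = input_bin_ms / dt_ms
    if abs(bin_steps - round(bin_steps)) > 1e-9:
        raise ValueError("input_bin_ms must be a multiple of dt_ms")
    bin_steps = int(round(bin_steps))

    n_steps = int(round(design.total_s * 1000.0 / dt_ms))
    n_bins = n_steps // bin_steps
    state = net.init_state()

    for _ in range(int(round(burn_in_s * 1000.0 / dt_ms))):
        step_network(net, state, rng)
    state.step = 0

    segs = _drive_segments(design, ws, net, dt_ms)
    seg_starts = np.array([s for s, _ in segs])

    lsnm_E = np.empty((n_steps, net.U), dtype=np.float32)
    lsnm_I = np.empty((n_steps, net.U), dtype=np.float32)
    tvb_E = np.empty((n_steps, net.n), dtype=np.float32)
    in_units = np.zeros((n_bins, net.U), dtype=np.float32)
    in_nodes = np.zeros((n_bins, net.n), dtype=np.float32)

    drive = None
    seg_i = -1
    for t in range(n_steps):
        while seg_i + 1 < len(segs) and seg_starts[seg_i + 1] <= t:
            seg_i += 1
            drive = segs[seg_i][1]
        b = t // bin_steps
        res = step_network(net, state, rng, unit_drive=drive, compute_inputs=b < n_bins)
        if res is not None:
            in_units[b] += res[0]
            in_nodes[b] += res[1]
        lsnm_E[t] = state.lsnm_E
        lsnm_I[t] = state.lsnm_I
        tvb_E[t] = state.tvb_E

    return Recordings(
        dt_ms=dt_ms,
        module_names=list(hybrid.module_names),
        host_nodes=dict(hybrid.host_nodes),
        lsnm_E=lsnm_E,
        lsnm_I=lsnm_I,
        tvb_E=tvb_E,
        input_bin_ms=input_bin_ms,
        in_units=in_units,
        in_nodes=in_nodes,
        design=design,
    )


@dataclass
class TrialOutcome:
    """Behavioral outcome of one trial."""

    condition: str
    responded: bool
    n_FR_units_above_threshold: int
    correct: bool | None  # None for CTL trials


def score_trial(
    fr_trace: np.ndarray,
    response_window: tuple[int, int],
    threshold: float = 0.7,
    min_units: int = 2,
    match: bool | None = None,
    condition: str = "DMS",
) -> TrialOutcome:
    """Score one trial from the FR module's excitatory trace.

    ``fr_trace`` is (n_steps, n_units); ``response_window`` a half-open step
    range.  The subject responds when at least ``min_units`` units exceed
    ``threshold`` (strictly) at any step inside the window.
    """
    i0, i1 = response_window
    if i1 <= i0:
        raise ValueError("empty response window")
    window = np.asarray(fr_trace)[i0:i1]
    n_above = int((window.max(axis=0) > threshold).sum())
    responded = n_above >= min_units
    correct: bool | None = None
    if condition == "DMS" and match is not None:
        correct = responded if match else not responded
    return TrialOutcome(condition, responded, n_above, correct)


def score_experiment(
    recordings: Recordings,
    design: ExperimentDesign | None = None,
    threshold: float = 0.7,
    min_units: int = 2,
) -> list[TrialOutcome]:
    """Score every trial of a design against the recorded FR activity."""
    design = design or recordings.design
    if design is None:
        raise ValueError("no design attached to recordings")
    fr = recordings.module_E("FR")
    dt = recordings.dt_ms
    out = []
    for tr in design.trials:
        w = (int(round(tr.s2_on_s * 1000 / dt)), int(round(tr.s2_off_s * 1000 / dt)))
        out.append(score_trial(fr, w, threshold, min_units, tr.match, tr.condition))
    return out


def compute_performance(outcomes: list[TrialOutcome]) -> float:
    """Percent correct over DMS trials."""
    dms = [o for o in outcomes if o.condition == "DMS"]
    if not dms:
        raise ValueError("no DMS trials to score")
    return 100.0 * sum(1 for o in dms if o.correct) / len(dms)


def generate_accepted_subjects(
    hybrid: HybridNetwork,
    design: ExperimentDesign,
    n_subjects: int,
    rng: np.random.Generator,
    base_weights: LsnmWeightSet | None = None,
    min_accuracy: float = 60.0,
    max_attempts: int = 50,
    **run_kwargs,
) -> list[tuple[SubjectWeights, Recordings, float]]:
    """The subject-inclusion loop: draw subjects until ``n_subjects`` score
    strictly above ``min_accuracy`` percent on the DMS trials.

    Returns (subject, recordings, accuracy) triples for the retained
    subjects.  Raises RuntimeError when ``max_attempts`` runs out.
    """
    base = base_weights if base_weights is not None else default_weight_set()
    accepted: list[tuple[SubjectWeights, Recordings, float]] = []
    attempts = 0
    while len(accepted) < n_subjects:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"subject generation: {attempts} attempts produced only "
                f"{len(accepted)}/{n_subjects} subjects above {min_accuracy}%"
            )
        attempts += 1
        subject = generate_subject(base, rng)
        run_rng = np.random.default_rng(rng.integers(2**31))
        rec = run_experiment(
            hybrid, design, run_rng, subject=subject, weight_set=base, **run_kwargs
        )
        acc = compute_performance(score_experiment(rec, design))
        if acc > min_accuracy:
            accepted.append((subject, rec, acc))
    return accepted


def run_connectome_stimulation(
    connectome: Connectome,
    design: ExperimentDesign,
    rng: np.random.Generator,
    target_node: int,
    amplitude: float = 0.2,
    G: float = 0.05,
    tvb_params: TvbNodeParams | None = None,
    dt_ms: float = 5.0,
    input_bin_ms: float = 50.0,
    burn_in_s: float = 2.0,
) -> Recordings:
    """Connectome-only control: pulse the would-be V1 host, no task circuit.

    The target node's excitatory population receives an additive drive of
    ``amplitude`` during every S1 and S2 period of ``design`` (pulse timing
    identical to stimulus presentation); there are no task units and no
    attention input.
    """
    if not (0 <= target_node < connectome.n_nodes):
        raise ValueError(f"target node {target_node} out of range")
    hybrid = build_embedding(connectome, [], G, rng)
    net = CompiledNetwork.compile(
        hybrid, tvb_params=tvb_params, weight_set=LsnmWeightSet([]), dt_ms=dt_ms
    )
    bin_steps = int(round(input_bin_ms / dt_ms))
    n_steps = int(round(design.total_s * 1000.0 / dt_ms))
    n_bins = n_steps // bin_steps

    pulse_on = np.zeros(n_steps, dtype=bool)
    for tr in design.trials:
        for a, b in ((tr.onset_s, tr.s1_off_s), (tr.s2_on_s, tr.s2_off_s)):
            pulse_on[int(round(a * 1000 / dt_ms)) : int(round(b * 1000 / dt_ms))] = True
    drive = np.zeros(connectome.n_nodes)
    drive[target_node] = amplitude

    state = net.init_state()
    for _ in range(int(round(burn_in_s * 1000.0 / dt_ms))):
        step_network(net, state, rng)

    tvb_E = np.empty((n_steps, net.n), dtype=np.float32)
    in_nodes = np.zeros((n_bins, net.n), dtype=np.float32)
    empty_u = np.zeros((n_steps, 0), dtype=np.float32)
    for t in range(n_steps):
        b = t // bin_steps
        res = step_network(
            net, state, rng,
            node_drive=drive if pulse_on[t] else None,
            compute_inputs=b < n_bins,
        )
        if res is not None:
            in_nodes[b] += res[1]
        tvb_E[t] = state.tvb_E

    return Recordings(
        dt_ms=dt_ms,
        module_names=[],
        host_nodes={},
        lsnm_E=empty_u,
        lsnm_I=empty_u,
        tvb_E=tvb_E,
        input_bin_ms=input_bin_ms,
        in_units=np.zeros((n_bins, 0), dtype=np.float32),
        in_nodes=in_nodes,
        design=design,
    )
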