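"""Hybrid network dynamics: two Wilson-Cowan variants and their coupling.

Connectome nodes follow the neural-mass form

    tau_E dE/dt = -E + (k_E - r_E E) S_E[alpha_E (c_EE E - c_IE I - theta_E + Gamma)]
    tau_I dI/dt = -I + (k_I - r_I I) S_I[alpha_I (c_EI E - c_II I - theta_I + Gamma)]

with Gamma = a_Gamma * sum_k u_ik E_k(t - d_ik) the delayed long-range
coupling (plus undelayed feedback from embedded task units).  Task units
follow the modified rate-of-change/decay form

    dE = Delta L(K_E [w_EE E + w_IE I + in_E - phi_E + N]) - delta E
    dI = Delta L(K_I [w_EI E       + in_I - phi_I + N]) - delta I

with L the unit logistic, N(t) zero-mean Gaussian noise, and no
inhibitory-to-inhibitory self-connection.  Connectome-sourced signals
(node->node and node->unit) are read from a delay ring buffer at lag
round(tract_length / (speed * dt)), never less than one step; task-internal
connections are undelayed.  Integration is stochastic explicit Euler at a
common 5-ms cadence for both subsystems; unit activities are clamped to
[0, 1].

The module exposes scalar reference operations (`sigmoid_response`,
`connectome_node_derivative`, `lsnm_unit_derivative`, `lsnm_inputs`, ...)
and a vectorized engine (:class:`CompiledNetwork` + :func:`step_network`)
that the experiment runner drives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import fsolve
from scipy.special import expit

from .embedding import UNITS_PER_MODULE, HybridNetwork
from .params import LsnmParams, TvbNodeParams
from .templates import LsnmWeightSet

__all__ = [
    "sigmoid_response",
    "long_range_coupling",
    "connectome_node_derivative",
    "lsnm_unit_derivative",
    "lsnm_inputs",
    "uniform_fixed_point",
    "CompiledNetwork",
    "NetworkState",
    "step_network",
]

REFERENCE_DT_MS = 5.0  # the cadence the unit rates Delta/delta refer to


# ---------------------------------------------------------------------------
# scalar reference operations
# ---------------------------------------------------------------------------


def sigmoid_response(f, a: float, b: float, c: float):
    """Saturating response c / (1 + exp(-a (f - b))), in (0, c)."""
    if c <= 0:
        raise ValueError("sigmoid ceiling c must be > 0")
    return c * expit(a * (np.asarray(f, dtype=float) - b))


def long_range_coupling(E_sources, incoming_weights, a_Gamma: float):
    """a_Gamma * sum_k u_ik E_k for one target; linear in every argument."""
    E = np.asarray(E_sources, dtype=float)
    u = np.asarray(incoming_weights, dtype=float)
    if E.shape != u.shape:
        raise ValueError(f"length mismatch: {E.shape} activities vs {u.shape} weights")
    return float(a_Gamma * np.dot(u, E))


def connectome_node_derivative(
    state: tuple[float, float], params: TvbNodeParams, Gamma_in: float
) -> tuple[float, float]:
    """(dE/dt, dI/dt) of one connectome node given its coupling input."""
    E, I = state
    p = params
    sE = sigmoid_response(
        p.alpha_E * (p.c_EE * E - p.c_IE * I - p.theta_E + Gamma_in),
        p.sigmoid_E.a, p.sigmoid_E.b, p.sigmoid_E.c,
    )
    sI = sigmoid_response(
        p.alpha_I * (p.c_EI * E - p.c_II * I - p.theta_I + Gamma_in),
        p.sigmoid_I.a, p.sigmoid_I.b, p.sigmoid_I.c,
    )
    dE = (-E + (p.k_E - p.r_E * E) * sE) / p.tau_E
    dI = (-I + (p.k_I - p.r_I * I) * sI) / p.tau_I
    return float(dE), float(dI)


def lsnm_unit_derivative(
    state: tuple[float, float],
    params: LsnmParams,
    inputs: tuple[float, float],
    noise_sample: float = 0.0,
) -> tuple[float, float]:
    """(dE, dI) of one task unit, per reference step."""
    E, I = state
    in_E, in_I = inputs
    p = params
    dE = p.Delta * expit(p.K_E * (p.w_EE * E + p.w_IE * I + in_E - p.phi_E + noise_sample)) - p.delta * E
    dI = p.Delta * expit(p.K_I * (p.w_EI * E + in_I - p.phi_I + noise_sample)) - p.delta * I
    return float(dE), float(dI)


def lsnm_inputs(
    unit: tuple[str, int],
    hybrid: HybridNetwork,
    lsnm_states: dict[str, tuple[np.ndarray, np.ndarray]],
    connectome_delayed_E: np.ndarray,
    weights: LsnmWeightSet | None = None,
) -> tuple[float, float]:
    """Reference (non-vectorized) input sums (in_E, in_I) for one unit.

    ``unit`` is (module name, unit index); ``lsnm_states`` maps module name
    to its (E, I) activity arrays; ``connectome_delayed_E`` holds each
    connectome node's excitatory activity at the lag appropriate for this
    module's host.  Connectome afferents feed the excitatory element only.
    """
    module, i = unit
    if module not in hybrid.placements:
        raise ValueError(f"unit belongs to unplaced module {module!r}")
    ws = weights if weights is not None else hybrid.lsnm_weights
    in_E = 0.0
    in_I = 0.0
    if ws is not None:
        for t in ws.templates:
            if t.dst != module:
                continue
            act = lsnm_states[t.src][0 if t.source_pop == "E" else 1]
            contrib = float(np.dot(t.matrix[:, i], act))
            if t.target_input == "E":
                in_E += contrib
            else:
                in_I += contrib
    p = hybrid.placements[module]
    if len(p.afferent_nodes):
        C = np.asarray(connectome_delayed_E, dtype=float)[p.afferent_nodes]
        in_E += float(np.dot(p.coupling_samples[:, i] * p.structural_weights, C))
    return in_E, in_I


def uniform_fixed_point(
    params: TvbNodeParams, total_in_weight: float, a_Gamma: float
) -> tuple[float, float]:
    """Noise-free fixed point of a spatially uniform connectome.

    Every node sees coupling Gamma = a_Gamma * total_in_weight * E; solves
    the two stationarity equations for (E*, I*).
    """

    def f(x):
        E, I = x
        g = a_Gamma * total_in_weight * E
        return connectome_node_derivative((E, I), params, g)

    sol = fsolve(f, x0=(0.1, 0.05), full_output=False)
    return float(sol[0]), float(sol[1])


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Full dynamical state of the hybrid network at one time step."""

    tvb_E: np.ndarray
    tvb_I: np.ndarray
    lsnm_E: np.ndarray
    lsnm_I: np.ndarray
    buf: np.ndarray  # (L, n) ring buffer of past tvb_E
    head: int = 0
    step: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.tvb_E.copy(), self.tvb_I.copy(),
            self.lsnm_E.copy(), self.lsnm_I.copy(),
            self.buf.copy(), self.head, self.step,
        )


@dataclass
class CompiledNetwork:
    """Precompiled matrices and per-unit parameter vectors for fast stepping."""

    hybrid: HybridNetwork
    tvb: TvbNodeParams
    dt_ms: float
    n: int
    U: int
    # node coupling
    Win: np.ndarray  # (n, n) incoming weights, Win[i, k] = w(k -> i)
    lag_in: np.ndarray  # (n, n) int delay steps for Win
    buf_len: int
    a_Gamma: float
    # task-unit templates compiled to sparse matrices (source -> input sums)
    A_ee: sp.csr_matrix
    A_ei: sp.csr_matrix
    A_ie: sp.csr_matrix
    A_ii: sp.csr_matrix
    Aabs_E: sp.csr_matrix  # |into E| + |into I| from E sources
    Aabs_I: sp.csr_matrix
    # connectome -> module forward coupling, per module
    mod_aff: list[np.ndarray]
    mod_lag: list[np.ndarray]
    mod_M: list[np.ndarray]  # (81, n_aff) entries c_ji * z_ji
    # module -> connectome feedback
    F: sp.csr_matrix  # (n, U)
    # per-unit parameter vectors
    Delta: np.ndarray
    delta: np.ndarray
    K_E: np.ndarray
    K_I: np.ndarray
    phi_E: np.ndarray
    phi_I: np.ndarray
    w_EE: np.ndarray
    w_IE: np.ndarray
    w_EI: np.ndarray
    unit_noise_sd: np.ndarray
    _col_idx: np.ndarray = field(default=None, repr=False)

    @classmethod
    def compile(
        cls,
        hybrid: HybridNetwork,
        tvb_params: TvbNodeParams | None = None,
        module_params: dict[str, LsnmParams] | None = None,
        weight_set: LsnmWeightSet | None = None,
        dt_ms: float = REFERENCE_DT_MS,
    ) -> "CompiledNetwork":
        if dt_ms <= 0:
            raise ValueError("dt must be > 0")
        from .templates import default_module_params, default_weight_set

        tvb = tvb_params or TvbNodeParams()
        mp = module_params or default_module_params()
        ws = weight_set if weight_set is not None else (hybrid.lsnm_weights or default_weight_set())

        conn = hybrid.connectome
        n = conn.n_nodes
        names = hybrid.module_names
        U = UNITS_PER_MODULE * len(names)
        sl = {m: hybrid.unit_slice(m) for m in names}

        Win = conn.weights.T.copy()
        if conn.tract_lengths is None or math.isinf(tvb.conduction_speed):
            lag = np.ones((n, n), dtype=np.int64)
        else:
            lag = np.rint(conn.tract_lengths / (tvb.conduction_speed * dt_ms)).astype(np.int64)
            np.maximum(lag, 1, out=lag)
        lag_in = lag.T.copy()
        buf_len = int(lag.max()) + 1

        def build(target_input: str, source_pop: str) -> sp.csr_matrix:
            m = sp.lil_matrix((U, U))
            for t in ws.templates:
                if t.target_input != target_input or t.source_pop != source_pop:
                    continue
                if t.src not in sl or t.dst not in sl:
                    raise ValueError(f"template {t.key} references unplaced module")
                # matrix[src, dst]: accumulate transposed so rows index targets
                m[sl[t.dst], sl[t.src]] = m[sl[t.dst], sl[t.src]] + t.matrix.T
            return m.tocsr()

        A_ee = build("E", "E")
        A_ei = build("E", "I")
        A_ie = build("I", "E")
        A_ii = build("I", "I")
        Aabs_E = (abs(A_ee) + abs(A_ie)).tocsr()
        Aabs_I = (abs(A_ei) + abs(A_ii)).tocsr()

        mod_aff, mod_lag, mod_M = [], [], []
        F = sp.lil_matrix((n, U))
        for m in names:
            p = hybrid.placements[m]
            aff = p.afferent_nodes
            mod_aff.append(aff)
            mod_lag.append(lag_in[p.host_node, aff] if len(aff) else np.zeros(0, dtype=np.int64))
            mod_M.append((p.coupling_samples * p.structural_weights[:, None]).T.copy())
            if len(aff):
                F[np.ix_(aff, range(sl[m].start, sl[m].stop))] = np.repeat(
                    p.feedback_weights[:, None], UNITS_PER_MODULE, axis=1
                )

        def vec(attr: str) -> np.ndarray:
            if not names:
                return np.zeros(0)
            return np.concatenate(
                [np.full(UNITS_PER_MODULE, getattr(mp[m], attr)) for m in names]
            )

        return cls(
            hybrid=hybrid, tvb=tvb, dt_ms=dt_ms, n=n, U=U,
            Win=Win, lag_in=lag_in, buf_len=buf_len, a_Gamma=hybrid.long_range_G,
            A_ee=A_ee, A_ei=A_ei, A_ie=A_ie, A_ii=A_ii,
            Aabs_E=Aabs_E, Aabs_I=Aabs_I,
            mod_aff=mod_aff, mod_lag=mod_lag, mod_M=mod_M,
            F=F.tocsr(),
            Delta=vec("Delta"), delta=vec("delta"),
            K_E=vec("K_E"), K_I=vec("K_I"),
            phi_E=vec("phi_E"), phi_I=vec("phi_I"),
            w_EE=vec("w_EE"), w_IE=vec("w_IE"), w_EI=vec("w_EI"),
            unit_noise_sd=vec("noise_sd"),
            _col_idx=np.broadcast_to(np.arange(n), (n, n)),
        )

    def init_state(self, tvb_E0: float | None = None, tvb_I0: float | None = None) -> NetworkState:
        """Resting initial state: nodes near their uncoupled fixed point,
        units silent, delay history filled with the initial node activity."""
        if tvb_E0 is None:
            tvb_E0, tvb_I0 = uniform_fixed_point(self.tvb, 0.0, self.a_Gamma)
        E = np.full(self.n, float(tvb_E0))
        I = np.full(self.n, float(tvb_I0 if tvb_I0 is not None else 0.0))
        buf = np.tile(E, (self.buf_len, 1))
        return NetworkState(
            tvb_E=E, tvb_I=I,
            lsnm_E=np.zeros(self.U), lsnm_I=np.zeros(self.U),
            buf=buf, head=0, step=0,
        )


def step_network(
    net: CompiledNetwork,
    state: NetworkState,
    rng: np.random.Generator | None = None,
    unit_drive: np.ndarray | None = None,
    node_drive: np.ndarray | None = None,
    compute_inputs: bool = False,
):
    """Advance the hybrid state by one Euler step (in place).

    ``unit_drive`` adds external excitatory drive (stimulus, attention) to
    task units' in_E; ``node_drive`` adds drive to node coupling (used by the
    connectome-only stimulation paradigm).  With ``compute_inputs`` the
    per-unit and per-node absolute input sums IN_i at the *current* time are
    returned as ``(IN_units, IN_nodes)``; otherwise returns None.

    The noise stream consumes draws in a fixed order (node E, node I, unit E,
    unit I), so a fixed seed yields bit-identical trajectories.
    """
    p = net.tvb
    E_n, I_n = state.tvb_E, state.tvb_I
    E_u, I_u = state.lsnm_E, state.lsnm_I
    dt = net.dt_ms

    # delayed node activities (ring buffer); lag >= 1 so reads are causal
    ptr = (state.head - net.lag_in) % net.buf_len
    Ed = state.buf[ptr, net._col_idx]
    coup = net.a_Gamma * np.einsum("ik,ik->i", net.Win, Ed)
    coup += net.F @ E_u
    if node_drive is not None:
        coup = coup + node_drive

    # task-unit input sums at time t
    in_conn = np.zeros(net.U)
    in_conn_abs = np.zeros(net.U)
    for mi, aff in enumerate(net.mod_aff):
        if len(aff) == 0:
            continue
        C = state.buf[(state.head - net.mod_lag[mi]) % net.buf_len, aff]
        sl = slice(mi * UNITS_PER_MODULE, (mi + 1) * UNITS_PER_MODULE)
        in_conn[sl] = net.mod_M[mi] @ C
        if compute_inputs:
            in_conn_abs[sl] = net.mod_M[mi] @ np.abs(C)
    in_E = net.A_ee @ E_u + net.A_ei @ I_u + in_conn
    in_I = net.A_ie @ E_u + net.A_ii @ I_u
    if unit_drive is not None:
        in_E = in_E + unit_drive

    result = None
    if compute_inputs:
        IN_units = (
            (np.abs(net.w_EE) + np.abs(net.w_EI)) * np.abs(E_u)
            + np.abs(net.w_IE) * np.abs(I_u)
            + net.Aabs_E @ np.abs(E_u)
            + net.Aabs_I @ np.abs(I_u)
            + in_conn_abs
        )
        IN_nodes = (
            (abs(p.c_EE) + abs(p.c_EI)) * np.abs(E_n)
            + (abs(p.c_IE) + abs(p.c_II)) * np.abs(I_n)
            + net.a_Gamma * np.einsum("ik,ik->i", net.Win, np.abs(Ed))
            + net.F @ np.abs(E_u)  # feedback weights are nonnegative
        )
        result = (IN_units, IN_nodes)

    # node update (stochastic Euler, additive noise)
    sE = p.sigmoid_E.c * expit(
        p.sigmoid_E.a * (p.alpha_E * (p.c_EE * E_n - p.c_IE * I_n - p.theta_E + coup) - p.sigmoid_E.b)
    )
    sI = p.sigmoid_I.c * expit(
        p.sigmoid_I.a * (p.alpha_I * (p.c_EI * E_n - p.c_II * I_n - p.theta_I + coup) - p.sigmoid_I.b)
    )
    dE_n = (-E_n + (p.k_E - p.r_E * E_n) * sE) / p.tau_E
    dI_n = (-I_n + (p.k_I - p.r_I * I_n) * sI) / p.tau_I
    new_E_n = E_n + dt * dE_n
    new_I_n = I_n + dt * dI_n
    if p.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        new_E_n += rng.normal(0.0, p.noise_sd, net.n)
        new_I_n += rng.normal(0.0, p.noise_sd, net.n)

    # unit update (rates are per reference 5-ms step)
    dt_ratio = dt / REFERENCE_DT_MS
    NE = np.zeros(net.U)
    NI = np.zeros(net.U)
    if np.any(net.unit_noise_sd > 0):
        if rng is None:
            raise ValueError("unit noise requires an rng")
        NE = rng.normal(0.0, 1.0, net.U) * net.unit_noise_sd
        NI = rng.normal(0.0, 1.0, net.U) * net.unit_noise_sd
    argE = net.K_E * (net.w_EE * E_u + net.w_IE * I_u + in_E - net.phi_E + NE)
    argI = net.K_I * (net.w_EI * E_u + in_I - net.phi_I + NI)
    new_E_u = E_u + dt_ratio * (net.Delta * expit(argE) - net.delta * E_u)
    new_I_u = I_u + dt_ratio * (net.Delta * expit(argI) - net.delta * I_u)
    np.clip(new_E_u, 0.0, 1.0, out=new_E_u)
    np.clip(new_I_u, 0.0, 1.0, out=new_I_u)

    state.tvb_E = new_E_n
    state.tvb_I = new_I_n
    state.lsnm_E = new_E_u
    state.lsnm_I = new_I_u
    state.head = (state.head + 1) % net.buf_len
    state.buf[state.head] = new_E_n
    state.step += 1
    return result
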