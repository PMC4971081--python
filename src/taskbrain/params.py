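"""Parameter sets for the three dynamical layers.

Three parameter families live here:

* :class:`TvbNodeParams` — the Wilson-Cowan neural-mass equations used for
  every connectome node (classical constants of the whole-brain-simulator
  tradition; time constants in ms).
* :class:`LsnmParams` — the modified Wilson-Cowan microcircuit used for task
  units: a rate-of-change/decay form with a logistic response, no
  inhibitory-to-inhibitory self-connection, and activities bounded in [0, 1].
  Rates are expressed per reference step (5 ms).
* :class:`BalloonParams` — the Balloon-Windkessel hemodynamic model constants
  (standard published values at 1.5 T).

All values are defaults and config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

__all__ = ["SigmoidSpec", "TvbNodeParams", "LsnmParams", "BalloonParams"]


@dataclass(frozen=True)
class SigmoidSpec:
    """Saturating response c / (1 + exp(-a (f - b)))."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("sigmoid ceiling c must be > 0")


@dataclass
class TvbNodeParams:
    """Wilson-Cowan neural-mass parameters for connectome nodes.

    The node equations are

        tau_E dE/dt = -E + (k_E - r_E E) S_E[alpha_E (c_EE E - c_IE I - theta_E + Gamma)]
        tau_I dI/dt = -I + (k_I - r_I I) S_I[alpha_I (c_EI E - c_II I - theta_I + Gamma)]

    with Gamma the long-range coupling input.  ``noise_sd`` is the standard
    deviation of the additive per-step Gaussian noise of the stochastic Euler
    scheme; ``conduction_speed`` (mm/ms) converts tract lengths to delays.
    """

    tau_E: float = 10.0  # ms
    tau_I: float = 10.0  # ms
    k_E: float = 1.0
    k_I: float = 1.0
    r_E: float = 1.0
    r_I: float = 1.0
    alpha_E: float = 1.0
    alpha_I: float = 1.0
    c_EE: float = 12.0
    c_EI: float = 4.0
    c_IE: float = 13.0
    c_II: float = 11.0
    theta_E: float = 0.0
    theta_I: float = 0.0
    sigmoid_E: SigmoidSpec = field(default_factory=lambda: SigmoidSpec(a=1.2, b=2.8, c=1.0))
    sigmoid_I: SigmoidSpec = field(default_factory=lambda: SigmoidSpec(a=1.0, b=4.0, c=1.0))
    noise_sd: float = 0.01
    conduction_speed: float = 3.0  # mm/ms; math.inf disables delays

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be > 0")


@dataclass
class LsnmParams:
    """Modified Wilson-Cowan microcircuit parameters for task units.

    The unit equations (per reference step of 5 ms) are

        dE = Delta * L(K_E [w_EE E + w_IE I + in_E - phi_E + N]) - delta * E
        dI = Delta * L(K_I [w_EI E       + in_I - phi_I + N]) - delta * I

    with L the unit logistic.  There is no inhibitory-to-inhibitory
    self-connection; ``w_IE`` (inhibitory onto excitatory) must be <= 0.
    ``noise_sd`` is the standard deviation of the zero-mean Gaussian noise
    term N(t), drawn independently per element and per step.
    """

    Delta: float = 0.5  # rate of change, per 5-ms step
    delta: float = 0.5  # rate of decay, per 5-ms step
    K_E: float = 12.0
    K_I: float = 12.0
    phi_E: float = 0.5
    phi_I: float = 0.45
    w_EE: float = 0.3
    w_IE: float = -0.3
    w_EI: float = 0.5
    noise_sd: float = 0.13

    def __post_init__(self) -> None:
        if self.Delta <= 0 or self.delta <= 0:
            raise ValueError("Delta and delta must be > 0")
        if self.w_IE > 0:
            raise ValueError("w_IE is inhibitory-to-excitatory and must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BalloonParams:
    """Balloon-Windkessel constants (1.5 T defaults).

    The BOLD read-out is y = V0 (k1 (1-q) + k2 (1 - q/v) + k3 (1 - v)) with
    k1 = 4.3 theta0 E0 TE, k2 = epsilon_ratio r0 E0 TE, k3 = 1 - epsilon_ratio.
    """

    V0: float = 0.04  # resting venous blood volume fraction
    E0: float = 0.32  # resting oxygen extraction fraction
    TE: float = 0.040  # echo time, s
    epsilon_ratio: float = 1.43  # intra-/extra-vascular signal ratio
    r0: float = 25.0  # intravascular relaxation slope, 1/s
    theta0: float = 40.3  # frequency offset of deoxygenated blood, 1/s
    tau0: float = 2.0  # mean transit time, s
    alpha: float = 0.32  # vessel stiffness (Grubb exponent)
    efficacy: float = 0.5  # neural->vasodilatory signal efficacy, 1/s
    tau_s: float = 2.0  # vasodilatory signal decay (1/kappa), s
    tau_f: float = 3.5  # flow autoregulation (1/gamma), s

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "epsilon_ratio" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    @property
    def k1(self) -> float:
        return 4.3 * self.theta0 * self.E0 * self.TE

    @property
    def k2(self) -> float:
        return self.epsilon_ratio * self.r0 * self.E0 * self.TE

    @property
    def k3(self) -> float:
        return 1.0 - self.epsilon_ratio
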