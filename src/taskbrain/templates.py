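"""Inter-module weight templates, stimulus shapes, and module-level parameters.

The task circuit is a ventral-stream hierarchy with a prefrontal working-
memory loop, wired between 9x9 unit grids:

* stimulus -> V1h / V1v: orientation channels, retinotopic drive;
* V1 -> V4: 3x3 receptive-field convergence along the preferred orientation
  (V4h from V1h rows, V4v from V1v columns, V4c from both channels);
* V4 -> IT: divergent, fixed pseudo-random fan-out producing a distributed
  object representation in IT;
* IT -> FS, IT -> D2: topographic projections into prefrontal cortex;
* D1 <-> D2: the recurrent loop that holds the memory trace during the delay;
* D1 -> D1 and D1 -> D2 (onto inhibitory elements): saturating pool
  inhibition from the formed memory trace — once a trace occupies the
  D1/D2 loop it suppresses recruitment of new delay units, so a second
  stimulus cannot overwrite the remembered pattern;
* D2 -> IT: feedback priming of the remembered pattern;
* D1 -> FR and IT -> FR: convergent match detection — an FR unit crosses
  threshold only where the remembered trace (D1) and the current stimulus
  (IT) coincide;
* attention -> D2: a scalar task-control drive to all D2 excitatory elements.

Template values are data (constructed here, serialisable to config), not
hard-wired into the dynamics code.  Feed-forward templates are tagged, since
simulated-subject generation rescales only those.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .embedding import GRID_SHAPE, UNITS_PER_MODULE
from .params import LsnmParams

__all__ = [
    "Template",
    "LsnmWeightSet",
    "default_weight_set",
    "default_module_params",
    "StimulusPattern",
    "SHAPE_LIBRARY",
    "shape_grids",
]

_N = UNITS_PER_MODULE


def _idx(r: int, c: int) -> int:
    return r * GRID_SHAPE[1] + c


@dataclass
class Template:
    """One inter-module projection between two 9x9 grids.

    ``matrix[src_unit, dst_unit]`` adds ``matrix[s, d] * act[s]`` to the
    destination unit's input.  ``source_pop`` selects the presynaptic element
    (E or I activity of the source module); ``target_input`` selects whether
    the projection enters the destination's excitatory (in_E) or inhibitory
    (in_I) input sum.
    """

    src: str
    dst: str
    matrix: np.ndarray
    source_pop: str = "E"
    target_input: str = "E"
    feedforward: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (_N, _N):
            raise ValueError("template matrix must be 81x81")
        if self.source_pop not in ("E", "I") or self.target_input not in ("E", "I"):
            raise ValueError("source_pop/target_input must be 'E' or 'I'")

    @property
    def key(self) -> str:
        return f"{self.src}->{self.dst}:{self.source_pop}{self.target_input}"


@dataclass
class LsnmWeightSet:
    """All inter-module templates plus the two external drives."""

    templates: list[Template]
    attention_gain: float = 1.3  # attention value * gain -> drive to D2 in_E
    stimulus_gain: float = 0.7  # stimulus grid * gain -> drive to V1 in_E

    def feedforward_keys(self) -> list[str]:
        return [t.key for t in self.templates if t.feedforward]

    def scaled(self, multipliers: dict[str, float]) -> "LsnmWeightSet":
        """Return a copy with feed-forward templates multiplied per-key.

        Feedback/lateral templates are returned bit-identical; unknown keys
        raise.
        """
        known = {t.key for t in self.templates if t.feedforward}
        unknown = set(multipliers) - known
        if unknown:
            raise KeyError(f"multipliers for unknown feed-forward templates: {sorted(unknown)}")
        out = []
        for t in self.templates:
            if t.feedforward and t.key in multipliers:
                out.append(replace(t, matrix=t.matrix * multipliers[t.key]))
            else:
                out.append(replace(t, matrix=t.matrix))
        return LsnmWeightSet(out, self.attention_gain, self.stimulus_gain)


def _one_to_one(w: float) -> np.ndarray:
    return np.eye(_N) * w


def _uniform(w_total: float) -> np.ndarray:
    # every destination unit reads the source-module mean activity times w_total
    return np.full((_N, _N), w_total / _N)


def _row_convergence(w: float) -> np.ndarray:
    """Horizontal 1x3 convergence: dst (r, c) <- src (r, c-1..c+1)."""
    m = np.zeros((_N, _N))
    for r in range(GRID_SHAPE[0]):
        for c in range(GRID_SHAPE[1]):
            for dc in (-1, 0, 1):
                cc = c + dc
                if 0 <= cc < GRID_SHAPE[1]:
                    m[_idx(r, cc), _idx(r, c)] = w
    return m


def _col_convergence(w: float) -> np.ndarray:
    """Vertical 3x1 convergence: dst (r, c) <- src (r-1..r+1, c)."""
    m = np.zeros((_N, _N))
    for r in range(GRID_SHAPE[0]):
        for c in range(GRID_SHAPE[1]):
            for dr in (-1, 0, 1):
                rr = r + dr
                if 0 <= rr < GRID_SHAPE[0]:
                    m[_idx(rr, c), _idx(r, c)] = w
    return m


def _patch_convergence(w: float) -> np.ndarray:
    """3x3 patch convergence: dst (r, c) <- src (r-1..r+1, c-1..c+1)."""
    m = np.zeros((_N, _N))
    for r in range(GRID_SHAPE[0]):
        for c in range(GRID_SHAPE[1]):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < GRID_SHAPE[0] and 0 <= cc < GRID_SHAPE[1]:
                        m[_idx(rr, cc), _idx(r, c)] = w
    return m


def _divergent_pool(
    w: float, in_degree: int, n_sources: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distributed code: each destination unit reads ``in_degree`` fixed
    pseudo-random source units drawn from a pool spanning several source
    modules (``n_sources`` modules of 81 units each).  Returns one 81x81
    matrix per source module."""
    mats = [np.zeros((_N, _N)) for _ in range(n_sources)]
    for d in range(_N):
        picks = rng.choice(n_sources * _N, size=in_degree, replace=False)
        for p in picks:
            mats[p // _N][p % _N, d] = w
    return mats


# Template weights of the reference ("ideal") subject.  Calibrated so the
# circuit shows the canonical response repertoire: stimulus-locked V1/V4,
# sparse distributed IT, stimulus-gated FS, delay-period D1/D2 under high
# attention only, and FR match detection by D1 x IT coincidence.
_W = {
    "v1_v4": 0.2,
    "v1_v4c": 0.09,
    "v4_it": 0.3,
    "it_fs": 0.6,
    "it_d2": 0.35,
    "d2_d1": 0.7,
    "d1_d2": 0.65,
    "d1_d1_inh": 1.2,
    "d1_d2_inh": 9.0,  # module-mean D1 -> D2 pool inhibition  # module-mean lateral inhibition within D1
    "d2_it_fb": 0.1,
    "d1_fr": 0.38,
    "it_fr": 0.36,
}

_STRUCT_SEED = 20160803  # fixed: the V4->IT fan-out is anatomy, not noise


def default_weight_set(weights: dict[str, float] | None = None) -> LsnmWeightSet:
    """Build the default inter-module weight set.

    ``weights`` overrides individual entries of the calibrated weight table
    (keys as in the module docstring's pathway list).
    """
    w = dict(_W)
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise KeyError(f"unknown weight keys: {sorted(unknown)}")
        w.update(weights)
    rng = np.random.default_rng(_STRUCT_SEED)
    it_mats = _divergent_pool(w["v4_it"], in_degree=6, n_sources=3, rng=rng)
    t = [
        # ventral stream (feed-forward)
        Template("V1h", "V4h", _row_convergence(w["v1_v4"]), feedforward=True),
        Template("V1v", "V4v", _col_convergence(w["v1_v4"]), feedforward=True),
        Template("V1h", "V4c", _patch_convergence(w["v1_v4c"]), feedforward=True),
        Template("V1v", "V4c", _patch_convergence(w["v1_v4c"]), feedforward=True),
        Template("V4h", "IT", it_mats[0], feedforward=True),
        Template("V4c", "IT", it_mats[1], feedforward=True),
        Template("V4v", "IT", it_mats[2], feedforward=True),
        Template("IT", "FS", _one_to_one(w["it_fs"]), feedforward=True),
        Template("IT", "D2", _one_to_one(w["it_d2"]), feedforward=True),
        Template("IT", "FR", _one_to_one(w["it_fr"]), feedforward=True),
        Template("D1", "FR", _one_to_one(w["d1_fr"]), feedforward=True),
        # prefrontal loop and feedback (not rescaled across subjects)
        Template("D2", "D1", _one_to_one(w["d2_d1"])),
        Template("D1", "D2", _one_to_one(w["d1_d2"])),
        Template("D1", "D1", _uniform(w["d1_d1_inh"]), target_input="I"),
        Template("D1", "D2", _uniform(w["d1_d2_inh"]), target_input="I"),
        Template("D2", "IT", _one_to_one(w["d2_it_fb"])),
    ]
    return LsnmWeightSet(t)


def default_module_params(base: LsnmParams | None = None) -> dict[str, LsnmParams]:
    """Per-module unit parameters (shared base with a few threshold tweaks)."""
    base = base or LsnmParams()
    params = {
        name: replace(base)
        for name in ("V1h", "V1v", "V4h", "V4c", "V4v", "IT", "FS", "D1", "D2", "FR")
    }
    # IT: lower threshold so two of three distributed inputs suffice
    params["IT"] = replace(base, phi_E=0.55, K_E=24.0)
    # D1/D2: slow integrators that carry the memory trace across phases.
    # D1 additionally has strong self-excitation (hysteresis: the stimulus-
    # gated inhibition from FS blocks new ignition but spares a lit trace),
    # a sensitive inhibitory element driven purely by FS (w_EI = 0), and a
    # low inhibitory threshold.
    params["D1"] = replace(base, w_EE=0.45, w_IE=-0.45, w_EI=0.0, phi_I=0.05)
    # D2 is a monostable attention-gated relay: it follows IT + attention
    # (stimulus periods) or D1 + attention (delay), and collapses within a
    # few hundred ms once attention drops.  Its slow rate constants bridge
    # the stimulus-offset gap until D1 ignites.
    params["D2"] = replace(base, Delta=0.15, delta=0.15, w_EE=0.2, phi_E=0.68, w_EI=0.0, phi_I=0.22)
    # FR is a pure coincidence detector: higher threshold, steeper gain,
    # no self-excitation so it cannot latch
    params["FR"] = replace(base, phi_E=0.55, K_E=24.0, w_EE=0.0)
    return params


# ---------------------------------------------------------------------------
# stimulus shapes
# ---------------------------------------------------------------------------


@dataclass
class StimulusPattern:
    """A 9x9 oriented-stroke stimulus split into orientation channels.

    ``grid_h`` drives the horizontal channel (V1h), ``grid_v`` the vertical
    channel (V1v); both are in [0, 1].
    """

    shape_id: str
    grid_h: np.ndarray
    grid_v: np.ndarray
    degraded: bool = False

    @property
    def grid(self) -> np.ndarray:
        """Channel union (for display / cell counting)."""
        return np.maximum(self.grid_h, self.grid_v)

    @property
    def n_active(self) -> int:
        return int((self.grid > 0).sum())


# Strokes: ("h", row, col0, col1) inclusive, or ("v", col, row0, row1).
SHAPE_LIBRARY: dict[str, list[tuple]] = {
    "blank": [],
    "tee": [("h", 0, 1, 7), ("v", 4, 1, 8)],
    "ell": [("v", 0, 0, 7), ("h", 8, 1, 7)],
    "plus": [("h", 4, 1, 7), ("v", 4, 1, 7)],
    "cup": [("v", 1, 1, 7), ("v", 7, 1, 7), ("h", 7, 2, 6)],
    "aitch": [("v", 1, 0, 8), ("v", 7, 0, 8), ("h", 4, 2, 6)],
    "beam": [("v", 4, 0, 8), ("h", 0, 2, 6), ("h", 8, 2, 6)],
    "gamma": [("h", 0, 0, 6), ("v", 6, 1, 8)],
    "box": [("h", 2, 2, 6), ("h", 6, 2, 6), ("v", 2, 3, 5), ("v", 6, 3, 5)],
    "bars": [("h", 2, 0, 8), ("h", 6, 0, 8)],
    "rails": [("v", 2, 0, 8), ("v", 6, 0, 8)],
}


def shape_grids(shape_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Intact (grid_h, grid_v) binary channel grids for a library shape."""
    if shape_id not in SHAPE_LIBRARY:
        raise ValueError(f"unknown shape_id {shape_id!r}")
    gh = np.zeros(GRID_SHAPE)
    gv = np.zeros(GRID_SHAPE)
    for stroke in SHAPE_LIBRARY[shape_id]:
        kind, a, b0, b1 = stroke
        if kind == "h":
            gh[a, b0 : b1 + 1] = 1.0
        elif kind == "v":
            gv[b0 : b1 + 1, a] = 1.0
        else:
            raise ValueError(f"bad stroke kind {kind!r}")
    return gh, gv
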