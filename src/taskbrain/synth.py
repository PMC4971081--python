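"""Synthetic structural connectomes.

Emulates the statistical shape of a DSI-derived cortical connectome (the kind
of ~1000-node substrate whole-brain simulators ship with): nodes sampled on a
two-hemisphere cortical shell in Talairach-like mm coordinates, sparse
symmetric nonnegative weights whose probability and magnitude decay with
inter-node distance, and tract lengths equal to Euclidean distance.  The
generator is the test substrate for the whole pipeline, so it is seeded and
fully deterministic.

What it does *not* emulate: true fibre geometry (tract lengths are chords,
not curved bundles), hemispheric asymmetries, and the community structure of
real parcellations beyond what distance dependence induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome

__all__ = ["SyntheticConnectomeSpec", "synthesize_connectome"]

# Semi-axes (mm) of the cortical shell per hemisphere and its centre in a
# Talairach-like frame; chosen so sampled nodes span the coordinate ranges of
# a human cortical parcellation (|x| <= ~70, y in [-105, 70], z in [-45, 75]).
_SHELL_SEMI_AXES = (62.0, 84.0, 58.0)
_SHELL_CENTRE = (0.0, -18.0, 12.0)
_HEMI_GAP_MM = 4.0  # minimum |x| keeps the medial wall free of nodes


@dataclass
class SyntheticConnectomeSpec:
    """Parameters of the synthetic-connectome generator.

    ``density`` is the target fraction of nonzero off-diagonal (undirected)
    pairs; realized density is stochastic but lands close to it.  Connection
    probability at distance d is proportional to exp(-d / decay_mm), scaled to
    hit the target density.  ``anchor_points`` pins exact node coordinates
    (e.g. at module target locations) so stereotaxic lookups resolve to
    distinct, well-placed hosts even at small n.
    """

    n_nodes: int = 998
    density: float = 0.05
    decay_mm: float = 40.0
    weight_scale: float = 0.3
    extent_mm: tuple[float, float, float] = _SHELL_SEMI_AXES
    seed: int = 0
    anchor_points: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes < 8:
            raise ValueError("n_nodes must be >= 8")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if len(self.anchor_points) > self.n_nodes:
            raise ValueError("more anchor points than nodes")


def _sample_shell(n: int, rng: np.random.Generator, extent) -> np.ndarray:
    """Sample n points on a two-hemisphere ellipsoidal shell (mm)."""
    ax, ay, az = extent
    cx, cy, cz = _SHELL_CENTRE
    # isotropic directions, pushed onto the ellipsoid with radial jitter to
    # mimic cortical folding thickness
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = 1.0 - 0.12 * rng.random(n)  # shell thickness ~12% of the radius
    pts = v * r[:, None] * np.array([ax, ay, az])
    # split into hemispheres, keeping a medial gap
    hemi = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    pts[:, 0] = hemi * (np.abs(pts[:, 0]) + _HEMI_GAP_MM)
    pts += np.array([cx, cy, cz])
    return pts


def synthesize_connectome(spec: SyntheticConnectomeSpec) -> Connectome:
    """Generate a seeded synthetic :class:`Connectome` per ``spec``.

    The result is symmetric with a zero diagonal; tract lengths are the
    Euclidean inter-node distances.  The same spec (same seed) always yields
    a bit-identical connectome.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _sample_shell(spec.n_nodes, rng, spec.extent_mm)
    for i, pt in enumerate(spec.anchor_points):
        coords[i] = np.asarray(pt, dtype=float)

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))

    iu = np.triu_indices(spec.n_nodes, k=1)
    decay = np.exp(-dist[iu] / spec.decay_mm)
    # scale connection probabilities so the expected density hits the target
    scale = spec.density * len(decay) / decay.sum()
    p_edge = np.minimum(1.0, scale * decay)
    present = rng.random(len(decay)) < p_edge
    # magnitudes: distance decay times a lognormal spread, as in DSI weight
    # distributions (heavy right tail)
    mags = spec.weight_scale * decay * rng.lognormal(mean=0.0, sigma=0.6, size=len(decay))
    vals = np.where(present, mags, 0.0)

    weights = np.zeros((spec.n_nodes, spec.n_nodes))
    weights[iu] = vals
    weights += weights.T

    return Connectome(
        weights=weights,
        coords=coords,
        tract_lengths=dist,
        labels=[f"syn{i + 1:04d}" for i in range(spec.n_nodes)],
    )
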