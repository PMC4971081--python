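"""Embedding task-circuit modules into a structural connectome.

Each task module is a 9x9 grid of 81 Wilson-Cowan microcircuits with a
hypothesized stereotaxic (Talairach) location.  Embedding follows four steps:

1. take the module's hypothesized Talairach coordinate;
2. designate the closest connectome node as the module's *host*;
3. connect every connectome node that projects to the host to all 81 units of
   the module ("forward" noise input) — because the 81 units vastly outnumber
   the single host node, the global long-range coupling constant G is divided
   by 81 and used as the mean of a Gaussian from which each per-(afferent,
   unit) coupling sample c_ji is drawn;
4. create reciprocal feedback edges from the module back to exactly those
   afferent nodes, scaled by G times the structural weight.

The host node itself stays an active connectome node with all its original
edges; embedding only adds edges.  Weights among non-host node pairs are
preserved bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import Connectome, nearest_node

__all__ = [
    "UNITS_PER_MODULE",
    "GRID_SHAPE",
    "LsnmModuleSpec",
    "ModulePlacement",
    "HybridNetwork",
    "default_module_specs",
    "build_embedding",
    "Roi",
    "define_rois",
    "embedding_report",
]

GRID_SHAPE = (9, 9)
UNITS_PER_MODULE = GRID_SHAPE[0] * GRID_SHAPE[1]  # 81


@dataclass(frozen=True)
class LsnmModuleSpec:
    """One embeddable 81-unit neuronal population and its target location."""

    name: str
    target_talairach: tuple[float, float, float]
    receives_connectome_input: bool = True
    sends_feedback: bool = True


# Hypothesized Talairach locations of the visual short-term-memory modules.
# V1/V2, V4, IT and D1 come from the visual experimental literature; FS, D2
# and FR (and the secondary orientation/corner channels V1v, V4c, V4v) sit at
# illustrative nearby locations so each module resolves to its own host.
_DEFAULT_TARGETS: dict[str, tuple[float, float, float]] = {
    "V1h": (18.0, -88.0, 8.0),
    "V1v": (10.0, -92.0, 6.0),
    "V4h": (30.0, -72.0, -12.0),
    "V4c": (22.0, -78.0, -10.0),
    "V4v": (36.0, -66.0, -8.0),
    "IT": (28.0, -36.0, -8.0),
    "FS": (47.0, 19.0, 9.0),
    "D1": (42.0, 26.0, 20.0),
    "D2": (42.0, 39.0, 2.0),
    "FR": (29.0, 25.0, 40.0),
}

MODULE_NAMES = tuple(_DEFAULT_TARGETS)

# Anatomical grouping used for imaging ROIs: orientation channels of a
# cortical area are analysed together.
REGION_MODULES: dict[str, tuple[str, ...]] = {
    "V1": ("V1h", "V1v"),
    "V4": ("V4h", "V4c", "V4v"),
    "IT": ("IT",),
    "FS": ("FS",),
    "D1": ("D1",),
    "D2": ("D2",),
    "FR": ("FR",),
}


def default_module_specs() -> list[LsnmModuleSpec]:
    """The ten 81-unit modules of the visual short-term-memory circuit."""
    return [LsnmModuleSpec(name, tgt) for name, tgt in _DEFAULT_TARGETS.items()]


@dataclass
class ModulePlacement:
    """Where one module landed and how it couples to the connectome.

    ``coupling_samples[j, i]`` is c_ji: the Gaussian coupling draw from
    afferent node ``afferent_nodes[j]`` to unit ``i``; ``structural_weights``
    holds z_ji (the connectome weight into the host, one value per afferent);
    ``feedback_weights`` the per-unit weight of the reciprocal module->node
    edges (G * z / 81, so the 81-unit aggregate carries G * z).
    """

    module: str
    host_node: int
    target: tuple[float, float, float]
    distance_mm: float
    afferent_nodes: np.ndarray  # (n_aff,) node ids
    coupling_samples: np.ndarray  # (n_aff, 81)
    structural_weights: np.ndarray  # (n_aff,)
    feedback_weights: np.ndarray  # (n_aff,) per-unit weight toward each node


@dataclass
class HybridNetwork:
    """A connectome plus embedded task modules.

    The original connectome is kept untouched (edge preservation is an
    invariant, not a convention to re-check downstream); the added structure
    lives entirely in ``placements``.
    """

    connectome: Connectome
    module_specs: list[LsnmModuleSpec]
    placements: dict[str, ModulePlacement]
    long_range_G: float
    lsnm_weights: "object | None" = None  # LsnmWeightSet, attached by experiment

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.module_specs]

    @property
    def n_units(self) -> int:
        return UNITS_PER_MODULE * len(self.module_specs)

    def unit_slice(self, module: str) -> slice:
        i = self.module_names.index(module)
        return slice(i * UNITS_PER_MODULE, (i + 1) * UNITS_PER_MODULE)

    @property
    def host_nodes(self) -> dict[str, int]:
        return {name: p.host_node for name, p in self.placements.items()}


def build_embedding(
    connectome: Connectome,
    module_specs: list[LsnmModuleSpec],
    G: float,
    rng: np.random.Generator,
    coupling_sd_frac: float = 0.1,
    on_collision: str = "error",
) -> HybridNetwork:
    """Embed ``module_specs`` into ``connectome`` (the 4-step procedure).

    Parameters
    ----------
    G
        Global long-range coupling constant (> 0).  Forward coupling samples
        c_ji are drawn from N(G/81, (coupling_sd_frac * G/81)^2), clipped at
        zero; feedback edges carry G * z / 81 per unit.
    on_collision
        ``"error"``: two modules resolving to the same host raise;
        ``"next-nearest"``: later modules take the nearest not-yet-used node.
    """
    if G <= 0:
        raise ValueError("long-range coupling constant G must be > 0")
    if on_collision not in ("error", "next-nearest"):
        raise ValueError("on_collision must be 'error' or 'next-nearest'")
    names = [m.name for m in module_specs]
    if len(set(names)) != len(names):
        raise ValueError("module names must be unique")

    mean = G / UNITS_PER_MODULE
    sd = coupling_sd_frac * mean
    placements: dict[str, ModulePlacement] = {}
    used_hosts: set[int] = set()

    for spec in module_specs:
        host, dist = nearest_node(connectome, spec.target_talairach)
        if host in used_hosts:
            if on_collision == "error":
                raise ValueError(
                    f"module {spec.name!r} resolves to host {host}, already "
                    "taken by another module (hosts must be distinct)"
                )
            order = np.argsort(
                np.linalg.norm(
                    connectome.coords - np.asarray(spec.target_talairach)[None, :], axis=1
                ),
                kind="stable",
            )
            host = next(int(i) for i in order if int(i) not in used_hosts)
            dist = float(
                np.linalg.norm(connectome.coords[host] - np.asarray(spec.target_talairach))
            )
        used_hosts.add(host)

        afferents = connectome.in_neighbors(host) if spec.receives_connectome_input else np.array([], dtype=int)
        if spec.receives_connectome_input and len(afferents) == 0:
            warnings.warn(
                f"module {spec.name!r}: host node {host} has no afferents; "
                "the module receives no connectome input",
                stacklevel=2,
            )
        z = connectome.weights[afferents, host]
        samples = rng.normal(mean, sd, size=(len(afferents), UNITS_PER_MODULE))
        np.clip(samples, 0.0, None, out=samples)  # excitatory coupling only
        feedback = (G * z / UNITS_PER_MODULE) if spec.sends_feedback else np.zeros_like(z)
        placements[spec.name] = ModulePlacement(
            module=spec.name,
            host_node=host,
            target=tuple(spec.target_talairach),
            distance_mm=dist,
            afferent_nodes=afferents,
            coupling_samples=samples,
            structural_weights=z,
            feedback_weights=feedback,
        )

    return HybridNetwork(
        connectome=connectome,
        module_specs=list(module_specs),
        placements=placements,
        long_range_G=G,
    )


@dataclass
class Roi:
    """An imaging region of interest: one module plus nearby connectome nodes.

    ``nodes`` always contains the host first, then the k adjacent nodes.
    Node-only control ROIs (no task units) carry ``module=None``.
    """

    module: str | None
    host_node: int
    nodes: list[int]

    @property
    def n_members(self) -> int:
        return (UNITS_PER_MODULE if self.module is not None else 0) + len(self.nodes)


def define_rois(hybrid: HybridNetwork, k: int = 5, disjoint: bool = True) -> dict[str, Roi]:
    """Per-module ROI: the module's 81 units, its host node, and the ``k``
    connectome nodes closest to the module.

    Host-nodes of other modules are never eligible, so task-related hosts do
    not leak into a neighbour's ROI.  With ``disjoint`` (default) every
    adjacent node belongs to at most one ROI — nodes are assigned greedily
    by distance, mirroring how an imaging voxel contributes to a single
    region — which matters on coarse connectomes where the neighbourhoods
    of nearby modules would otherwise overlap.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    conn = hybrid.connectome
    hosts = set(hybrid.host_nodes.values())
    names = list(hybrid.placements)
    dist = {
        name: np.linalg.norm(
            conn.coords - conn.coords[hybrid.placements[name].host_node][None, :], axis=1
        )
        for name in names
    }
    adjacent: dict[str, list[int]] = {name: [] for name in names}
    if disjoint:
        candidates = sorted(
            (dist[name][node], name, node)
            for name in names
            for node in range(conn.n_nodes)
            if node not in hosts
        )
        taken: set[int] = set()
        for d, name, node in candidates:
            if node in taken or len(adjacent[name]) >= k:
                continue
            adjacent[name].append(node)
            taken.add(node)
    else:
        for name in names:
            order = np.argsort(dist[name], kind="stable")
            adjacent[name] = [int(i) for i in order if int(i) not in hosts][:k]
    rois: dict[str, Roi] = {}
    for name in names:
        if len(adjacent[name]) < k:
            warnings.warn(
                f"ROI {name!r}: only {len(adjacent[name])} adjacent nodes "
                f"available (k={k})",
                stacklevel=2,
            )
        host = hybrid.placements[name].host_node
        rois[name] = Roi(module=name, host_node=host, nodes=[host] + adjacent[name])
    return rois


def contralateral_roi(hybrid: HybridNetwork, module: str = "IT", k: int = 5) -> Roi:
    """Noise-only control ROI: the node nearest the mirror image (-x) of a
    module's target coordinate, plus its ``k`` nearest neighbours.

    Used as the contralateral-IT control region — it carries no task units,
    so its activity is pure connectome noise.
    """
    p = hybrid.placements[module]
    mirror = np.array([-p.target[0], p.target[1], p.target[2]])
    conn = hybrid.connectome
    hosts = set(hybrid.host_nodes.values())
    centre, _ = nearest_node(conn, mirror)
    d = np.linalg.norm(conn.coords - conn.coords[centre][None, :], axis=1)
    order = np.argsort(d, kind="stable")
    adjacent = [int(i) for i in order if int(i) not in hosts and int(i) != centre][:k]
    return Roi(module=None, host_node=centre, nodes=[centre] + adjacent)


def embedding_report(hybrid: HybridNetwork) -> pd.DataFrame:
    """Tabular embedding summary (node ids reported 1-based)."""
    rows = []
    for name, p in hybrid.placements.items():
        hx, hy, hz = hybrid.connectome.coords[p.host_node]
        rows.append(
            {
                "module": name,
                "target_x": p.target[0],
                "target_y": p.target[1],
                "target_z": p.target[2],
                "host_id": p.host_node + 1,
                "host_x": hx,
                "host_y": hy,
                "host_z": hz,
                "distance_mm": p.distance_mm,
                "n_afferents": len(p.afferent_nodes),
            }
        )
    return pd.DataFrame(rows)
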