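"""Structural connectomes: container, validation, bundle I/O and spatial queries.

A connectome here is a weighted directed graph over cortical regions of
interest.  Each node carries a stereotaxic (Talairach) coordinate in mm; edge
weights are nonnegative white-matter connection densities.  Diffusion-derived
matrices are symmetric, but the container is directed (``weights[i, j]`` is
the weight of the projection from node ``i`` to node ``j``) so asymmetric
matrices also work.

The on-disk format is the de-facto TVB connectivity dialect: a directory (or
zip archive) holding ``weights.txt`` (whitespace-delimited square matrix),
``centres.txt`` (``label x y z`` per line) and, optionally,
``tract_lengths.txt``.  A plain CSV triple (``weights.csv``, ``centres.csv``,
``tract_lengths.csv``) is accepted as well.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "load_connectome",
    "save_connectome",
    "nearest_node",
]


class ConnectomeFormatError(ValueError):
    """A bundle is missing files or a file cannot be parsed."""


class ConnectomeValidationError(ValueError):
    """Parsed data violate a structural invariant (negative weight, ...)."""


@dataclass
class Connectome:
    """A weighted graph of brain regions with 3-D coordinates.

    Parameters
    ----------
    weights
        ``(n, n)`` nonnegative matrix, zero diagonal; ``weights[i, j]`` is the
        strength of the projection i -> j.
    coords
        ``(n, 3)`` stereotaxic coordinates in mm (Talairach frame).
    tract_lengths
        Optional ``(n, n)`` symmetric nonnegative fibre lengths in mm, used
        for conduction delays.
    labels
        Per-node identifiers; autogenerated ``n0001``-style names if omitted.
    region_of
        Optional node -> anatomical-region map (index array).
    """

    weights: np.ndarray
    coords: np.ndarray
    tract_lengths: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)
    region_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ConnectomeValidationError("weights must be a square matrix")
        n = self.weights.shape[0]
        if self.coords.shape != (n, 3):
            raise ConnectomeValidationError(
                f"coords shape {self.coords.shape} does not match {n} nodes"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ConnectomeValidationError("weights contain non-finite values")
        if not np.all(np.isfinite(self.coords)):
            raise ConnectomeValidationError("coords contain non-finite values")
        if np.any(self.weights < 0):
            raise ConnectomeValidationError("negative connection weight")
        if np.any(np.diag(self.weights) != 0):
            raise ConnectomeValidationError("weights must have a zero diagonal")
        if self.tract_lengths is not None:
            tl = np.asarray(self.tract_lengths, dtype=float)
            if tl.shape != (n, n):
                raise ConnectomeValidationError("tract_lengths shape mismatch")
            if np.any(tl < 0):
                raise ConnectomeValidationError("negative tract length")
            if not np.allclose(tl, tl.T):
                raise ConnectomeValidationError("tract_lengths must be symmetric")
            self.tract_lengths = tl
        if not self.labels:
            self.labels = [f"n{i + 1:04d}" for i in range(n)]
        elif len(self.labels) != n:
            raise ConnectomeValidationError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def in_neighbors(self, node: int) -> np.ndarray:
        """Indices j with a nonzero projection j -> ``node``."""
        return np.nonzero(self.weights[:, node] > 0)[0]

    def copy(self) -> "Connectome":
        return Connectome(
            weights=self.weights.copy(),
            coords=self.coords.copy(),
            tract_lengths=None if self.tract_lengths is None else self.tract_lengths.copy(),
            labels=list(self.labels),
            region_of=None if self.region_of is None else self.region_of.copy(),
        )


def _parse_centres(text: str) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ConnectomeFormatError(f"centres line {ln}: expected 'label x y z'")
        if len(parts) == 3:  # coordinates only
            label, coords = "", parts
        else:
            label, coords = parts[0], parts[-3:]
        try:
            rows.append([float(v) for v in coords])
        except ValueError as exc:
            raise ConnectomeFormatError(f"centres line {ln}: bad coordinate") from exc
        labels.append(label)
    if not rows:
        raise ConnectomeFormatError("centres file is empty")
    if all(not l for l in labels):
        labels = []
    return labels, np.asarray(rows)


def _parse_matrix(text: str, name: str) -> np.ndarray:
    try:
        mat = np.loadtxt(io.StringIO(text.replace(",", " ")), ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{name}: cannot parse matrix") from exc
    return mat


def _read_bundle_texts(bundle_path: str | Path) -> dict[str, str]:
    """Return {stem: text} for the bundle files, from a dir or a zip."""
    path = Path(bundle_path)
    texts: dict[str, str] = {}
    stems = ("weights", "centres", "tract_lengths")
    if path.is_dir():
        for stem in stems:
            for suffix in (".txt", ".csv", ".tsv"):
                f = path / f"{stem}{suffix}"
                if f.exists():
                    texts[stem] = f.read_text()
                    break
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for member in zf.namelist():
                stem = Path(member).stem
                if stem in stems and not member.endswith("/"):
                    texts[stem] = zf.read(member).decode()
    else:
        raise ConnectomeFormatError(f"{path}: not a directory or zip bundle")
    return texts


def load_connectome(bundle_path: str | Path) -> Connectome:
    """Load a connectivity bundle (directory or zip) into a :class:`Connectome`.

    Raises :class:`ConnectomeFormatError` when weights or centres are missing
    or unparseable, and :class:`ConnectomeValidationError` when the parsed
    data violate invariants (negative weights, shape mismatch, ...).
    """
    texts = _read_bundle_texts(bundle_path)
    if "weights" not in texts:
        raise ConnectomeFormatError(f"{bundle_path}: bundle has no weights file")
    if "centres" not in texts:
        raise ConnectomeFormatError(f"{bundle_path}: bundle has no centres file")
    weights = _parse_matrix(texts["weights"], "weights")
    labels, coords = _parse_centres(texts["centres"])
    tract_lengths = None
    if "tract_lengths" in texts:
        tract_lengths = _parse_matrix(texts["tract_lengths"], "tract_lengths")
    if weights.shape[0] != coords.shape[0]:
        raise ConnectomeValidationError(
            f"weights are {weights.shape[0]}x{weights.shape[1]} but centres "
            f"list {coords.shape[0]} nodes"
        )
    return Connectome(weights=weights, coords=coords, tract_lengths=tract_lengths, labels=labels)


def save_connectome(conn: Connectome, out_dir: str | Path) -> Path:
    """Write ``conn`` as a directory bundle in the TVB text dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "weights.txt", conn.weights, fmt="%.10g")
    with open(out / "centres.txt", "w") as fh:
        for label, (x, y, z) in zip(conn.labels, conn.coords):
            fh.write(f"{label} {x:.6g} {y:.6g} {z:.6g}\n")
    if conn.tract_lengths is not None:
        np.savetxt(out / "tract_lengths.txt", conn.tract_lengths, fmt="%.10g")
    return out


def nearest_node(conn: Connectome, point_mm) -> tuple[int, float]:
    """Node closest (Euclidean) to ``point_mm``; ties break to the lowest index.

    Returns ``(node_id, distance_mm)``.
    """
    if conn.n_nodes == 0:
        raise ValueError("empty connectome")
    point = np.asarray(point_mm, dtype=float).reshape(3)
    d = np.linalg.norm(conn.coords - point[None, :], axis=1)
    idx = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return idx, float(d[idx])
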