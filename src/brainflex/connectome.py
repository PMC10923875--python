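"""Weighted structural connectomes: I/O, synthesis, null models, node selection.

The structural network is a symmetric, nonnegative, zero-diagonal weight
matrix ``G`` (DTI streamline counts in the empirical case) whose element
``g_kl`` couples the neural-mass oscillators of regions ``k`` and ``l``.
This module loads such matrices from dense or edge-list files, generates
modular synthetic surrogates with heavy-tailed weights, builds the
weight-shuffled null model, and selects stimulation targets by node
strength (weighted degree).

All node indices exposed to users are 1-based, matching the region
numbering of common parcellation atlases; arrays are stored 0-based
internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "StructuralConnectome",
    "NodeSelection",
    "read_connectome",
    "write_connectome",
    "generate_synthetic_connectome",
    "shuffle_connectome",
    "weighted_degree",
    "select_nodes",
]

SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric nonnegative weight matrix with zero diagonal.

    Parameters
    ----------
    weights
        ``(N, N)`` array of nonnegative coupling weights ``g_kl``
        (arbitrary units, e.g. streamline counts).
    node_labels
        ``N`` region identifiers. Defaults to ``"R1"..."RN"``.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError(f"a connectome needs at least 2 nodes, got {n}")
        dev = np.max(np.abs(w - w.T)) if n else 0.0
        if dev > SYMMETRY_TOL:
            raise ValueError(f"weight matrix is asymmetric (max deviation {dev:.3e})")
        if np.any(w < 0):
            raise ValueError("weight matrix has negative entries")
        if np.any(np.diag(w) != 0):
            raise ValueError("nonzero diagonal: self-coupling is not allowed")
        if not np.all(np.isfinite(w)):
            raise ValueError("weight matrix has non-finite entries")
        # exact symmetry after the tolerance check
        w = (w + w.T) / 2.0
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        labels = tuple(self.node_labels) or tuple(f"R{i + 1}" for i in range(n))
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} nodes")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class NodeSelection:
    """Ordered set of stimulated nodes (1-based indices)."""

    indices: tuple[int, ...]
    scenario: Literal["custom", "wm", "light", "mid", "heavy"] = "custom"

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate node indices in selection: {idx}")
        if any(i < 1 for i in idx):
            raise ValueError("node indices are 1-based and must be >= 1")
        object.__setattr__(self, "indices", idx)

    @property
    def count(self) -> int:
        return len(self.indices)

    def zero_based(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int) - 1


def _parse_dense(text: str, delimiter: Optional[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty connectome file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    first = [f.strip() for f in lines[0].split(delimiter)]
    labels: tuple[str, ...] = ()
    try:
        [float(f) for f in first]
    except ValueError:
        labels = tuple(first)
        lines = lines[1:]
    rows = [[float(f) for f in ln.split(delimiter)] for ln in lines]
    w = np.asarray(rows, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"dense connectome must be square, got shape {w.shape}")
    return w, labels


def _parse_edgelist(text: str, n_nodes: Optional[int]) -> np.ndarray:
    edges: dict[tuple[int, int], float] = {}
    max_node = 0
    for ln in text.splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"edge list rows need 3 columns, got: {ln!r}")
        a, b, wt = int(parts[0]), int(parts[1]), float(parts[2])
        if a < 1 or b < 1:
            raise ValueError(f"edge list node ids are 1-based, got ({a}, {b})")
        if a == b:
            raise ValueError(f"self-loop on node {a} is not allowed")
        key = (min(a, b), max(a, b))
        if key in edges:
            raise ValueError(f"duplicate undirected edge {key}")
        edges[key] = wt
        max_node = max(max_node, a, b)
    n = n_nodes if n_nodes is not None else max_node
    if max_node > n:
        raise ValueError(f"edge references node {max_node} but n_nodes={n}")
    w = np.zeros((n, n))
    for (a, b), wt in edges.items():
        w[a - 1, b - 1] = w[b - 1, a - 1] = wt
    return w


def read_connectome(
    path: str | Path,
    format: Literal["dense", "edgelist"] = "dense",
    n_nodes: Optional[int] = None,
) -> StructuralConnectome:
    """Load a connectome from a dense matrix (CSV/TSV) or a 3-column edge list.

    Dense files may carry one header row of region labels. Edge lists are
    undirected TSV rows ``node_a  node_b  weight`` with 1-based ids; each
    pair may appear at most once and is mirrored to both triangles.
    ``n_nodes`` declares the network size for edge lists whose largest node
    id is not the last node.
    """
    text = Path(path).read_text()
    if format == "dense":
        w, labels = _parse_dense(text, None)
        return StructuralConnectome(w, labels)
    if format == "edgelist":
        return StructuralConnectome(_parse_edgelist(text, n_nodes))
    raise ValueError(f"unknown format {format!r}")


def write_connectome(G: StructuralConnectome, path: str | Path, header: bool = True) -> None:
    """Write a dense CSV; one optional header row of node labels."""
    buf = io.StringIO()
    if header:
        buf.write(",".join(G.node_labels) + "\n")
    np.savetxt(buf, G.weights, delimiter=",", fmt="%.17g")
    Path(path).write_text(buf.getvalue())


def generate_synthetic_connectome(
    n_nodes: int,
    n_modules: int,
    intra_weight_scale: float = 0.05,
    inter_weight_scale: float = 0.01,
    lognormal_sigma: float = 0.6,
    density: float = 0.3,
    seed: int = 0,
) -> StructuralConnectome:
    """Generate a modular surrogate for an averaged DTI matrix.

    Nodes are split into ``n_modules`` contiguous blocks. Each node pair is
    connected with probability ``density``; the weight is the within- or
    between-module scale times a log-normal multiplier ``exp(sigma * Z)``,
    giving the heavy-tailed, nonnegative weight distribution typical of
    streamline-count matrices. With ``lognormal_sigma=0`` and ``density=1``
    all within-module weights equal ``intra_weight_scale`` exactly.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_modules < 1 or n_modules > n_nodes:
        raise ValueError("need 1 <= n_modules <= n_nodes")
    if intra_weight_scale <= 0 or inter_weight_scale <= 0:
        raise ValueError("weight scales must be positive")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    membership = module_blocks(n_nodes, n_modules)
    iu, ju = np.triu_indices(n_nodes, k=1)
    same = membership[iu] == membership[ju]
    scale = np.where(same, intra_weight_scale, inter_weight_scale)
    present = rng.random(iu.size) < density
    mult = np.exp(lognormal_sigma * rng.standard_normal(iu.size))
    vals = scale * mult * present
    w = np.zeros((n_nodes, n_nodes))
    w[iu, ju] = vals
    w[ju, iu] = vals
    return StructuralConnectome(w)


def module_blocks(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous block membership: node i -> module in 0..n_modules-1."""
    return np.minimum(
        np.arange(n_nodes) * n_modules // n_nodes, n_modules - 1
    ).astype(int)


def shuffle_connectome(G: StructuralConnectome, seed: int = 0) -> StructuralConnectome:
    """Null model G': permute the strictly-upper-triangle weights.

    The shuffled upper triangle is mirrored to the lower triangle, so the
    result is symmetric with zero diagonal and exactly the same edge-weight
    multiset as the input; only the placement of weights changes.
    """
    rng = np.random.default_rng(seed)
    n = G.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = G.weights[iu, ju]
    perm = rng.permutation(vals.size)
    w = np.zeros((n, n))
    w[iu, ju] = vals[perm]
    w[ju, iu] = vals[perm]
    return StructuralConnectome(w, G.node_labels)


def weighted_degree(G: StructuralConnectome) -> np.ndarray:
    """Node strengths ``s_k = sum_l g_kl`` (row sums)."""
    return G.weights.sum(axis=1)


def select_nodes(
    G: StructuralConnectome,
    scenario: Literal["light", "mid", "heavy", "custom"],
    count: int = 6,
    custom_indices: Optional[Sequence[int]] = None,
) -> NodeSelection:
    """Pick stimulation targets by weighted degree.

    ``light``/``heavy`` take the ``count`` weakest/strongest nodes;
    ``mid`` takes a contiguous rank window centred on the median rank of
    the strength-sorted list (ascending ranks ``ceil((N-count)/2)+1`` ...
    ``+count``, 1-based). Ties in strength are broken by ascending node
    index, so the selection is a deterministic function of the matrix.
    Returned indices are 1-based, ordered by ascending strength rank.
    """
    n = G.n_nodes
    if count < 1 or count > n:
        raise ValueError(f"count must be in [1, {n}], got {count}")
    if scenario == "custom":
        if custom_indices is None:
            raise ValueError("custom scenario requires custom_indices")
        idx = [int(i) for i in custom_indices]
        if any(i < 1 or i > n for i in idx):
            raise ValueError(f"custom indices out of range 1..{n}: {idx}")
        if len(idx) != count:
            count = len(idx)
        return NodeSelection(tuple(idx), "custom")
    s = weighted_degree(G)
    order = np.argsort(s, kind="stable")  # ascending; ties -> smaller index
    if scenario == "light":
        chosen = order[:count]
    elif scenario == "heavy":
        chosen = np.argsort(-s, kind="stable")[:count][::-1]
    elif scenario == "mid":
        start = -(-(n - count) // 2)  # ceil((N - count) / 2)
        chosen = order[start : start + count]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return NodeSelection(tuple(int(i) + 1 for i in chosen), scenario)
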