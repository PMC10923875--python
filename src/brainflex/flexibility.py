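"""Dynamic-network reconfiguration metrics: template and distance flexibility.

Template flexibility measures, for each pair of consecutive sliding
windows, the fraction of nodes whose strongest affiliation to a fixed
a-priori module template changes:

    H' = |A^win| M,   h_ij = h'_ij / K_j,   Omega_win[i] = argmax_j h_ij,
    F(win, win-1) = 1 - (1/N) sum_i delta(Omega_win[i], Omega_{win-1}[i])

where M is a binary N x P region-to-module matrix with column sums K_j.
Values lie on the lattice {0, 1/N, ..., 1}.

Distance flexibility (the d-measure) is template-free: one minus the
Pearson correlation between the N^2 elements (diagonal included) of
consecutive functional matrices; it lies in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .funconn import FunctionalMatrixSequence

__all__ = [
    "ModuleTemplate",
    "FlexibilitySeries",
    "read_template",
    "generate_synthetic_template",
    "module_strengths",
    "affiliation_vector",
    "template_flexibility",
    "distance_flexibility",
    "flexibility_series",
]


@dataclass(frozen=True)
class ModuleTemplate:
    """Binary N x P region-to-module assignment; every module non-empty.

    Single membership (one module per region) is the common case, but
    multi-membership binary templates are accepted.
    """

    M: np.ndarray
    module_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2:
            raise ValueError("template must be a 2-D matrix")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("template entries must be binary (0/1)")
        M = M.astype(float)
        sizes = M.sum(axis=0)
        if np.any(sizes < 1):
            empty = np.flatnonzero(sizes < 1) + 1
            raise ValueError(f"empty module(s): {list(empty)}")
        M.flags.writeable = False
        object.__setattr__(self, "M", M)
        labels = tuple(self.module_labels) or tuple(
            f"M{j + 1}" for j in range(M.shape[1])
        )
        if len(labels) != M.shape[1]:
            raise ValueError("one label per module required")
        object.__setattr__(self, "module_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.M.shape[0]

    @property
    def n_modules(self) -> int:
        return self.M.shape[1]

    @property
    def module_sizes(self) -> np.ndarray:
        """Column sums K_j."""
        return self.M.sum(axis=0)


@dataclass(frozen=True)
class FlexibilitySeries:
    """Per-window-pair flexibility values; entry t compares windows t and t+1."""

    kind: Literal["template", "distance"]
    values: np.ndarray
    pair_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.values)


def read_template(path: str | Path) -> ModuleTemplate:
    """Load a template from a 2-column region->module TSV or a binary matrix CSV.

    The mapping dialect has 1-based ``region_id<TAB>module_id`` rows, one
    per region; regions must cover 1..N exactly and every module 1..P must
    receive at least one region.
    """
    text = Path(path).read_text()
    rows = [ln.split() if "\t" in ln or " " in ln else ln.split(",")
            for ln in text.splitlines() if ln.strip()]
    # strip a header row if present
    def _numeric(row: list[str]) -> bool:
        try:
            [float(x) for x in row]
            return True
        except ValueError:
            return False

    if rows and not _numeric(rows[0]):
        rows = rows[1:]
    if not rows:
        raise ValueError("empty template file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged template file")
    vals = {float(x) for r in rows for x in r}
    if width == 2 and not vals <= {0.0, 1.0}:
        pairs = [(int(a), int(b)) for a, b in rows]
        n = len(pairs)
        regions = sorted(r for r, _ in pairs)
        if regions != list(range(1, n + 1)):
            raise ValueError("region ids must cover 1..N exactly once")
        p = max(m for _, m in pairs)
        if min(m for _, m in pairs) < 1:
            raise ValueError("module ids are 1-based")
        M = np.zeros((n, p))
        for r, m in pairs:
            M[r - 1, m - 1] = 1.0
        return ModuleTemplate(M)
    M = np.asarray([[float(x) for x in r] for r in rows])
    return ModuleTemplate(M)


def generate_synthetic_template(N: int, P: int, seed: int = 0) -> ModuleTemplate:
    """Random single-membership template with every module non-empty."""
    if not 1 <= P <= N:
        raise ValueError("need 1 <= P <= N")
    rng = np.random.default_rng(seed)
    omega = np.concatenate([np.arange(P), rng.integers(0, P, size=N - P)])
    rng.shuffle(omega)
    M = np.zeros((N, P))
    M[np.arange(N), omega] = 1.0
    return ModuleTemplate(M)


def module_strengths(
    A: np.ndarray, template: ModuleTemplate, include_diagonal: bool = True
) -> np.ndarray:
    """Size-normalized module affiliation strengths H = (|A| M) / K.

    The defining sums run over all matrix elements, diagonal included;
    ``include_diagonal=False`` drops the unit self-correlations for
    sensitivity analysis.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[1] != template.n_regions:
        raise ValueError(
            f"matrix has {A.shape[1]} columns but template has "
            f"{template.n_regions} regions"
        )
    absA = np.abs(A)
    if not include_diagonal:
        absA = absA.copy()
        np.fill_diagonal(absA, 0.0)
    return (absA @ template.M) / template.module_sizes


def affiliation_vector(H: np.ndarray) -> np.ndarray:
    """Per-node winning module (1-based labels); ties go to the lowest index."""
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("affiliation strengths must be finite")
    return np.argmax(H, axis=1) + 1


def template_flexibility(omega_prev: np.ndarray, omega_cur: np.ndarray) -> float:
    """Fraction of nodes whose winning module changed between windows."""
    omega_prev = np.asarray(omega_prev)
    omega_cur = np.asarray(omega_cur)
    if omega_prev.shape != omega_cur.shape:
        raise ValueError("affiliation vectors must have equal length")
    return 1.0 - float(np.mean(omega_prev == omega_cur))


def distance_flexibility(
    A_prev: np.ndarray, A_cur: np.ndarray, include_diagonal: bool = True
) -> float:
    """Pearson distance between the element sets of two functional matrices.

    1 minus the Pearson correlation over all N^2 elements, diagonal
    included as the definition is written (``include_diagonal=False``
    restricts to off-diagonal elements for sensitivity analysis). Raises on
    a constant matrix (zero element variance).
    """
    A_prev = np.asarray(A_prev, dtype=float)
    A_cur = np.asarray(A_cur, dtype=float)
    if A_prev.shape != A_cur.shape:
        raise ValueError("matrices must have the same shape")
    if include_diagonal:
        a, b = A_prev.ravel(), A_cur.ravel()
    else:
        mask = ~np.eye(A_prev.shape[0], dtype=bool)
        a, b = A_prev[mask], A_cur[mask]
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0 or nb == 0:
        raise ValueError("degenerate window: matrix has zero element variance")
    return 1.0 - float(np.dot(da, db) / (na * nb))


def flexibility_series(
    seq: FunctionalMatrixSequence, template: Optional[ModuleTemplate] = None
) -> tuple[Optional[FlexibilitySeries], FlexibilitySeries]:
    """Template (if a template is given) and distance flexibility series.

    Both series have one value per consecutive window pair, i.e. length
    ``n_windows - 1``, in window order.
    """
    W = seq.n_windows
    if W < 2:
        raise ValueError("need at least 2 windows")
    pair_times = np.asarray(seq.window_start_times[1:], dtype=float)
    dist = np.empty(W - 1)
    for t in range(W - 1):
        dist[t] = distance_flexibility(seq.matrices[t], seq.matrices[t + 1])
    dist_series = FlexibilitySeries("distance", dist, pair_times)
    if template is None:
        return None, dist_series
    omegas = [affiliation_vector(module_strengths(seq.matrices[t], template)) for t in range(W)]
    tmpl = np.array([template_flexibility(omegas[t], omegas[t + 1]) for t in range(W - 1)])
    return FlexibilitySeries("template", tmpl, pair_times), dist_series
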