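"""Temporal hypergraphs and order-resolved adjacency projections.

A temporal hypergraph is a node set together with a time-ordered sequence of
snapshots, each snapshot being a set of hyperedges (node subsets of size
``2..max_order``).  For every order ``d`` the interactions at time ``t`` are
projected onto an ``N x N`` integer adjacency matrix whose entry ``(i, j)``
counts the order-``d`` hyperedges that contain both ``i`` and ``j`` (diagonal
zeroed).  The time-average of that sequence is the *annealed* adjacency
matrix, which serves as the centering term for every correlation estimator in
:mod:`hypermem.correlations`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "Hyperedge",
    "TemporalHypergraph",
    "AdjacencySequence",
    "build_incidence",
    "project_adjacency",
    "adjacency_sequence",
    "read_events",
    "write_events",
]


class Hyperedge(tuple):
    """A canonical, hashable group interaction.

    Stored as the sorted tuple of distinct integer node ids, so two
    hyperedges compare equal iff their node sets are equal, regardless of the
    order nodes were supplied in.

    >>> Hyperedge([2, 0, 1]) == Hyperedge((1, 2, 0))
    True
    >>> Hyperedge([2, 0, 1]).order
    3
    """

    __slots__ = ()

    def __new__(cls, nodes: Iterable[int]) -> "Hyperedge":
        canon = tuple(sorted(int(n) for n in nodes))
        if len(set(canon)) != len(canon):
            raise InputError(f"hyperedge {canon} has duplicate nodes")
        if len(canon) < 2:
            raise InputError(f"hyperedge {canon} has fewer than two nodes")
        if canon[0] < 0:
            raise InputError(f"hyperedge {canon} has a negative node id")
        return tuple.__new__(cls, canon)

    @property
    def order(self) -> int:
        """Number of nodes involved in the interaction."""
        return len(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Hyperedge({tuple(self)})"


Snapshot = frozenset  # alias: a snapshot is a frozenset of Hyperedges


def _as_snapshot(edges: Iterable) -> frozenset:
    return frozenset(e if isinstance(e, Hyperedge) else Hyperedge(e) for e in edges)


@dataclass
class TemporalHypergraph:
    """Node set plus a length-``T`` sequence of hyperedge sets.

    Parameters
    ----------
    num_nodes
        Number of nodes ``N``; node ids are the contiguous integers
        ``0..N-1``.  Input files with arbitrary labels are mapped to this
        range by the readers (see :mod:`hypermem.reconstruct`).
    max_order
        Largest admissible hyperedge order ``D``.
    snapshots
        Sequence of hyperedge sets; empty snapshots are allowed and meaningful
        (a lag of ``tau`` always means ``tau`` time steps, not ``tau`` events).
    times
        Optional original timestamps (one per snapshot), preserved by file
        round trips.  Analysis only ever uses the dense index ``0..T-1``.
    """

    num_nodes: int
    max_order: int
    snapshots: list
    times: list | None = None

    def __post_init__(self) -> None:
        if self.num_nodes < 1:
            raise InputError("num_nodes must be >= 1")
        if self.max_order < 2:
            raise InputError("max_order must be >= 2")
        if len(self.snapshots) < 1:
            raise InputError("a temporal hypergraph needs at least one snapshot")
        self.snapshots = [_as_snapshot(s) for s in self.snapshots]
        for t, snap in enumerate(self.snapshots):
            for e in snap:
                if e.order > self.max_order:
                    raise InputError(
                        f"hyperedge {tuple(e)} at step {t} exceeds max_order={self.max_order}"
                    )
                if e[-1] >= self.num_nodes:
                    raise InputError(
                        f"hyperedge {tuple(e)} at step {t} references node >= num_nodes={self.num_nodes}"
                    )
        if self.times is not None and len(self.times) != len(self.snapshots):
            raise InputError("times must have one entry per snapshot")

    @property
    def num_steps(self) -> int:
        """Length ``T`` of the snapshot sequence."""
        return len(self.snapshots)

    @property
    def orders_present(self) -> list:
        """Sorted list of orders that occur at least once."""
        seen = {e.order for snap in self.snapshots for e in snap}
        return sorted(seen)

    def count(self, d: int) -> int:
        """Total number of order-``d`` hyperedge occurrences over all steps."""
        return sum(1 for snap in self.snapshots for e in snap if e.order == d)

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self.snapshots)


def _order_d_edges(snapshot: Iterable, d: int) -> list:
    """Order-``d`` hyperedges of a snapshot in lexicographic order."""
    return sorted(e for e in snapshot if len(e) == d)


def _check_nodes(edges: Sequence, num_nodes: int) -> None:
    for e in edges:
        if e[0] < 0 or e[-1] >= num_nodes:
            raise InputError(
                f"hyperedge {tuple(e)} references a node outside 0..{num_nodes - 1}"
            )


def build_incidence(snapshot: Iterable, d: int, num_nodes: int) -> np.ndarray:
    """Node-by-hyperedge binary incidence matrix for one order.

    Columns are the order-``d`` hyperedges of ``snapshot`` in lexicographic
    order of their sorted node tuples (deterministic); entry ``(i, a)`` is 1
    iff node ``i`` belongs to hyperedge ``a``.
    """
    if d < 2:
        raise InputError(f"order must be >= 2, got {d}")
    edges = _order_d_edges(snapshot, d)
    _check_nodes(edges, num_nodes)
    inc = np.zeros((num_nodes, len(edges)), dtype=np.int64)
    for col, e in enumerate(edges):
        inc[list(e), col] = 1
    return inc


def project_adjacency(snapshot: Iterable, d: int, num_nodes: int) -> np.ndarray:
    """Symmetric co-membership count matrix for one order.

    Computed as ``E @ E.T`` with the diagonal zeroed, where ``E`` is the
    incidence matrix of :func:`build_incidence`; entry ``(i, j)`` counts the
    order-``d`` hyperedges containing both ``i`` and ``j``.
    """
    inc = build_incidence(snapshot, d, num_nodes)
    adj = inc @ inc.T
    np.fill_diagonal(adj, 0)
    return adj


@dataclass
class AdjacencySequence:
    """Per-order adjacency matrices over time plus their annealed average.

    ``matrices`` has shape ``(T, N, N)`` with symmetric integer slices and
    zero diagonals; ``annealed`` is their elementwise time-average.
    """

    order: int
    matrices: np.ndarray
    annealed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise InputError("matrices must have shape (T, N, N)")
        if self.annealed is None:
            self.annealed = self.matrices.mean(axis=0)
        else:
            self.annealed = np.asarray(self.annealed, dtype=float)

    @property
    def num_steps(self) -> int:
        return self.matrices.shape[0]

    @property
    def num_nodes(self) -> int:
        return self.matrices.shape[1]


def adjacency_sequence(th: TemporalHypergraph, d: int) -> AdjacencySequence:
    """Project every snapshot of ``th`` at order ``d`` and time-average.

    Equivalent to stacking :func:`project_adjacency` over all snapshots but
    implemented by direct pair counting, which is much faster for long
    sequences.  The equivalence is covered by the test suite.
    """
    if not 2 <= d <= th.max_order:
        raise InputError(f"order {d} outside 2..{th.max_order}")
    n, t_len = th.num_nodes, th.num_steps
    mats = np.zeros((t_len, n, n), dtype=np.int64)
    for t, snap in enumerate(th.snapshots):
        m = mats[t]
        for e in snap:
            if len(e) != d:
                continue
            for i, j in itertools.combinations(e, 2):
                m[i, j] += 1
                m[j, i] += 1
    return AdjacencySequence(order=d, matrices=mats)


# ---------------------------------------------------------------------------
# Hyperedge event file I/O
#
# One line per (time, hyperedge):  t<TAB>n1,n2,...,nk
# '#' starts a comment.  Metadata comments written by `write_events` allow
# lossless round trips (leading/trailing empty snapshots included).
# ---------------------------------------------------------------------------


def write_events(th: TemporalHypergraph, path) -> None:
    """Write a hyperedge event file (TSV, one hyperedge per line)."""
    path = Path(path)
    times = th.times if th.times is not None else list(range(th.num_steps))
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# num_nodes={th.num_nodes}\n")
        fh.write(f"# max_order={th.max_order}\n")
        fh.write(f"# num_steps={th.num_steps}\n")
        fh.write(f"# times={','.join(str(t) for t in times)}\n")
        for t, snap in zip(times, th.snapshots):
            for e in sorted(snap):
                fh.write(f"{t}\t{','.join(str(n) for n in e)}\n")


def read_events(
    path,
    fill_gaps: bool = True,
    num_nodes: int | None = None,
    max_order: int | None = None,
) -> TemporalHypergraph:
    """Read a hyperedge event file.

    Timestamps are mapped to a dense index.  With ``fill_gaps`` (default)
    missing grid points between the first and last timestamp become empty
    snapshots, the grid step being the gcd of the observed timestamp
    differences; with ``fill_gaps=False`` only observed timestamps are kept,
    as consecutive indices.  Metadata comments written by
    :func:`write_events` take precedence and make round trips exact.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta: dict[str, str] = {}
    by_time: dict[int, set] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 't<TAB>n1,n2,...', got {line!r}")
            try:
                t = int(parts[0])
                nodes = [int(tok) for tok in parts[1].split(",") if tok != ""]
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            by_time.setdefault(t, set()).add(Hyperedge(nodes))
    if not by_time and "times" not in meta:
        raise InputError(f"{path}: no events found")

    if "times" in meta and meta["times"]:
        times = [int(tok) for tok in meta["times"].split(",")]
    else:
        observed = sorted(by_time)
        if fill_gaps and len(observed) > 1:
            diffs = np.diff(observed)
            step = int(math.gcd(*[int(x) for x in diffs])) or 1
            times = list(range(observed[0], observed[-1] + 1, step))
        else:
            times = observed
    snapshots = [frozenset(by_time.get(t, set())) for t in times]

    all_edges = [e for s in snapshots for e in s]
    if num_nodes is None:
        if "num_nodes" in meta:
            num_nodes = int(meta["num_nodes"])
        elif all_edges:
            num_nodes = 1 + max(e[-1] for e in all_edges)
        else:
            raise InputError(f"{path}: empty event file without metadata")
    if max_order is None:
        if "max_order" in meta:
            max_order = int(meta["max_order"])
        elif all_edges:
            max_order = max(e.order for e in all_edges)
        else:
            max_order = 2
    return TemporalHypergraph(
        num_nodes=num_nodes, max_order=max_order, snapshots=snapshots, times=times
    )
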