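"""Promotion of pairwise contact streams to temporal hypergraphs.

Proximity datasets record dyadic contacts ``(t, i, j)`` on a regular grid
(e.g. 20 s frames).  Group interactions are recovered per frame by promoting
each *maximal* clique of simultaneous contacts of size ``d`` to a
``d``-hyperedge: an edge inside a triangle is part of the triad, not
additionally a dyad.  (Promoting all cliques instead — available behind a
flag for sensitivity analysis — would make every group imply all of its
subgroups and trivialize cross-order structure.)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .core import Hyperedge, TemporalHypergraph
from .errors import HypermemError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ContactStream",
    "read_contact_stream",
    "promote_cliques",
    "reconstruct_hypergraph",
]

#: abort a frame whose maximal-clique count exceeds this
CLIQUE_GUARD = 100_000


@dataclass
class ContactStream:
    """Deduplicated undirected contact records on a regular frame grid.

    ``records`` holds ``(frame, i, j)`` with dense node ids ``i < j``;
    ``labels[i]`` is the original label of node ``i``; ``resolution`` is the
    nominal number of raw time units per frame.
    """

    records: list
    labels: list
    resolution: int = 1

    @property
    def num_nodes(self) -> int:
        return len(self.labels)

    def frames(self) -> dict:
        """Mapping frame index -> set of undirected edges ``(i, j)``."""
        out: dict[int, set] = {}
        for t, i, j in self.records:
            out.setdefault(t, set()).add((i, j))
        return out


def read_contact_stream(path, resolution: int = 1) -> ContactStream:
    """Parse a contact list with lines ``t i j`` (extra columns ignored).

    Whitespace, tabs and commas all separate fields; ``#`` starts a comment.
    Node labels may be arbitrary strings and are mapped to dense integer ids
    in sorted label order (numeric when all labels are integers), so the
    result is independent of record order.  Raw timestamps are regularized to
    frames by integer division by ``resolution``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if resolution < 1:
        raise InputError("resolution must be >= 1")
    raw: list[tuple[int, str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected 't i j', got {line!r}")
            try:
                t = int(float(parts[0]))
            except ValueError:
                raise InputError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from None
            i, j = parts[1], parts[2]
            if i == j:
                raise InputError(f"{path}:{lineno}: self-contact {i!r}")
            raw.append((t, i, j))
    if not raw:
        raise InputError(f"{path}: no contact records found")
    labels = sorted({lab for _, i, j in raw for lab in (i, j)}, key=_label_key)
    ids = {lab: k for k, lab in enumerate(labels)}
    seen = set()
    records = []
    for t, i, j in raw:
        a, b = sorted((ids[i], ids[j]))
        rec = (t // resolution, a, b)
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    records.sort()
    return ContactStream(records=records, labels=labels, resolution=resolution)


def _label_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def promote_cliques(
    frame: Iterable,
    max_order: int | None = None,
    all_cliques: bool = False,
    split_large: bool = False,
) -> frozenset:
    """Promote the cliques of one frame graph to hyperedges.

    By default each *maximal* clique of size ``2..max_order`` becomes one
    hyperedge.  Maximal cliques larger than ``max_order`` are skipped with a
    warning, or — with ``split_large`` — emitted as all of their
    ``max_order``-subsets.  ``all_cliques`` promotes every clique of size
    ``>= 2`` instead (capped at ``max_order``).
    """
    g = nx.Graph()
    g.add_edges_from(frame)
    out: set = set()
    n_cliques = 0
    for clique in nx.find_cliques(g):
        n_cliques += 1
        if n_cliques > CLIQUE_GUARD:
            raise HypermemError(
                f"frame exceeds {CLIQUE_GUARD} maximal cliques; refusing to continue"
            )
        size = len(clique)
        if size < 2:
            continue
        if all_cliques:
            top = size if max_order is None else min(size, max_order)
            for d in range(2, top + 1):
                out.update(Hyperedge(c) for c in itertools.combinations(clique, d))
        elif max_order is not None and size > max_order:
            if split_large:
                out.update(
                    Hyperedge(c) for c in itertools.combinations(clique, max_order)
                )
            else:
                logger.warning(
                    "skipping maximal clique of size %d > max_order=%d", size, max_order
                )
        else:
            out.add(Hyperedge(clique))
    return frozenset(out)


def reconstruct_hypergraph(
    stream: ContactStream,
    max_order: int | None = None,
    fill_gaps: bool = True,
    all_cliques: bool = False,
    split_large: bool = False,
) -> TemporalHypergraph:
    """Promote every frame of ``stream`` and assemble a temporal hypergraph.

    Frames are densified to consecutive indices; with ``fill_gaps`` (default)
    frames with no contacts between the first and last observed frame become
    empty snapshots, so a lag always counts time steps.  With
    ``max_order=None`` the maximum order is the largest clique found (no
    truncation).
    """
    frames = stream.frames()
    observed = sorted(frames)
    grid = list(range(observed[0], observed[-1] + 1)) if fill_gaps else observed
    snapshots = [
        promote_cliques(
            frames.get(t, ()),
            max_order=max_order,
            all_cliques=all_cliques,
            split_large=split_large,
        )
        for t in grid
    ]
    if max_order is None:
        found = [e.order for s in snapshots for e in s]
        max_order = max(found) if found else 2
    return TemporalHypergraph(
        num_nodes=stream.num_nodes,
        max_order=max_order,
        snapshots=snapshots,
        times=grid,
    )
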