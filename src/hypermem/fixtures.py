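"""Synthetic inputs with known ground truth.

Every fixture is reproducible from its spec (including the seed) and carries
machine-readable ground truth, so the whole analysis stack is testable
without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Hyperedge, TemporalHypergraph
from .errors import ConfigError
from .models import enumerate_hyperedges
from .reconstruct import ContactStream

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "KINDS"]

KINDS = ("iid_bernoulli", "planted_periodic", "planted_cross_lag", "contact_stream_toy")


@dataclass
class FixtureSpec:
    """What to generate.

    kind
        ``iid_bernoulli``: every candidate hyperedge active i.i.d. per step.
        ``planted_periodic``: background noise plus one hyperedge active
        exactly every ``period`` steps.
        ``planted_cross_lag``: the 2-hyperedge ``{0,1}`` is i.i.d.
        Bernoulli(1/2) and its activity is copied into the covering
        3-hyperedge ``{0,1,2}`` exactly ``planted_lag`` steps later, so the
        (2,3) gap function peaks at the planted lag by construction.
        ``contact_stream_toy``: a pairwise contact stream whose frames are
        unions of cliques on disjoint node sets, with the promoted
        hypergraph known exactly.
    """

    kind: str
    num_nodes: int = 6
    max_order: int = 3
    horizon: int = 200
    density: float = 0.1
    planted_lag: int = 5
    period: int = 10
    seed: int = 0


@dataclass
class Fixture:
    """A generated input plus its ground truth."""

    spec: FixtureSpec
    hypergraph: TemporalHypergraph | None = None
    stream: ContactStream | None = None
    truth: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec) -> Fixture:
    if spec.kind not in KINDS:
        raise ConfigError(f"unknown fixture kind {spec.kind!r}; choose from {KINDS}")
    if spec.horizon < 1:
        raise ConfigError("horizon must be >= 1")
    if not 0.0 <= spec.density <= 1.0:
        raise ConfigError("density must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "iid_bernoulli":
        return _iid_bernoulli(spec, rng)
    if spec.kind == "planted_periodic":
        return _planted_periodic(spec, rng)
    if spec.kind == "planted_cross_lag":
        return _planted_cross_lag(spec, rng)
    return _contact_stream_toy(spec, rng)


def _candidate_states(spec: FixtureSpec, rng) -> tuple:
    edges = enumerate_hyperedges(spec.num_nodes, spec.max_order)
    states = rng.random((spec.horizon, len(edges))) < spec.density
    return edges, states


def _to_hypergraph(spec: FixtureSpec, edges, states) -> TemporalHypergraph:
    snaps = [frozenset(edges[k] for k in np.flatnonzero(row)) for row in states]
    return TemporalHypergraph(
        num_nodes=spec.num_nodes, max_order=spec.max_order, snapshots=snaps
    )


def _iid_bernoulli(spec: FixtureSpec, rng) -> Fixture:
    edges, states = _candidate_states(spec, rng)
    return Fixture(spec=spec, hypergraph=_to_hypergraph(spec, edges, states), truth={})


def _planted_periodic(spec: FixtureSpec, rng) -> Fixture:
    if spec.period < 1:
        raise ConfigError("period must be >= 1")
    edges, states = _candidate_states(spec, rng)
    planted = Hyperedge(range(spec.max_order))
    col = edges.index(planted)
    states[:, col] = False
    states[:: spec.period, col] = True
    return Fixture(
        spec=spec,
        hypergraph=_to_hypergraph(spec, edges, states),
        truth={"planted": planted, "period": spec.period},
    )


def _planted_cross_lag(spec: FixtureSpec, rng) -> Fixture:
    if spec.max_order < 3 or spec.num_nodes < 3:
        raise ConfigError("planted_cross_lag needs max_order >= 3 and num_nodes >= 3")
    lag = spec.planted_lag
    if not 1 <= lag < spec.horizon:
        raise ConfigError("planted_lag must satisfy 1 <= lag < horizon")
    edges, states = _candidate_states(spec, rng)
    src = Hyperedge((0, 1))
    dst = Hyperedge((0, 1, 2))
    ci, cj = edges.index(src), edges.index(dst)
    driver = rng.random(spec.horizon) < 0.5
    states[:, ci] = driver
    states[:lag, cj] = rng.random(lag) < 0.5
    states[lag:, cj] = driver[:-lag]
    return Fixture(
        spec=spec,
        hypergraph=_to_hypergraph(spec, edges, states),
        truth={"lag": lag, "source": src, "target": dst},
    )


def _contact_stream_toy(spec: FixtureSpec, rng) -> Fixture:
    """Frames built as unions of cliques on disjoint node sets.

    Because planted cliques never share nodes within a frame, they are
    exactly the maximal cliques of the frame graph, so the promoted
    hypergraph is known by construction.
    """
    if spec.num_nodes < spec.max_order:
        raise ConfigError("num_nodes must be >= max_order")
    records = []
    truth_snaps = []
    for t in range(spec.horizon):
        nodes = list(rng.permutation(spec.num_nodes))
        snap = set()
        while len(nodes) >= 2:
            top = min(spec.max_order, len(nodes))
            size = int(rng.integers(2, top + 1))
            group, nodes = nodes[:size], nodes[size:]
            snap.add(Hyperedge(group))
            for a in range(size):
                for b in range(a + 1, size):
                    i, j = sorted((int(group[a]), int(group[b])))
                    records.append((t, i, j))
            if rng.random() < 0.5:  # leave some nodes isolated
                break
        truth_snaps.append(frozenset(snap))
    stream = ContactStream(
        records=sorted(records),
        labels=[str(i) for i in range(spec.num_nodes)],
        resolution=1,
    )
    truth_th = TemporalHypergraph(
        num_nodes=spec.num_nodes,
        max_order=spec.max_order,
        snapshots=truth_snaps,
        times=list(range(spec.horizon)),
    )
    return Fixture(spec=spec, stream=stream, truth={"hypergraph": truth_th})
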