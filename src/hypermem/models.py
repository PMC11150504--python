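"""Generative models of temporal hypergraphs with tunable memory.

Every candidate hyperedge of every order ``2..D`` carries a binary state
(absent/present) evolving as an autoregressive process.  At each step, a
hyperedge of order ``d`` either redraws its state as Bernoulli(``y(d)``)
(probability ``1 - q(d)``) or copies a uniformly chosen state from memory
(probability ``q(d)``).  In the plain model the memory is the hyperedge's own
last ``m_s`` states.  The cross-memory variant additionally lets the copy
source be an *overlapping* hyperedge of a different order: with probability
``p(d)`` the hyperedge picks an order ``d'`` from a distribution ``rho``, a
uniformly random overlapping candidate of that order, and copies one of that
candidate's ``m_c(d', d)`` most recent past states.

All hyperedges update synchronously from the histories as of the end of the
previous step; copies always read strictly past states (lag >= 1).  Histories
are initialized with i.i.d. Bernoulli(``y(d)``) draws, and a burn-in (default
ten times the longest memory) is discarded before output, so the returned
sequence is effectively stationary.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import Hyperedge, TemporalHypergraph
from .errors import ConfigError, InputError

__all__ = [
    "MemoryModelConfig",
    "enumerate_hyperedges",
    "overlapping_candidates",
    "sample_memory_lengths",
    "darh_simulate",
    "cdarh_simulate",
]

#: candidate-count threshold above which simulation cost becomes punishing
SCALE_GUARD = 100_000


def enumerate_hyperedges(num_nodes: int, max_order: int) -> list:
    """All candidate hyperedges of orders ``2..max_order``, ordered by order
    then lexicographically over node tuples."""
    if max_order < 2:
        raise InputError("max_order must be >= 2")
    if num_nodes < max_order:
        raise InputError(f"need num_nodes >= max_order, got {num_nodes} < {max_order}")
    out = []
    for d in range(2, max_order + 1):
        out.extend(Hyperedge(c) for c in itertools.combinations(range(num_nodes), d))
    return out


def overlapping_candidates(edge: Hyperedge, d_prime: int, num_nodes: int) -> list:
    """Hyperedges of order ``d_prime`` overlapping ``edge``.

    For ``d_prime < d`` these are all size-``d_prime`` subsets of the edge
    (count ``C(d, d_prime)``); for ``d_prime > d`` all supersets within the
    ``num_nodes`` node set (count ``C(N - d, d_prime - d)``).
    """
    d = len(edge)
    if d_prime == d:
        raise InputError("d_prime must differ from the edge's own order")
    if d_prime < 2:
        raise InputError("d_prime must be >= 2")
    if d_prime < d:
        return [Hyperedge(c) for c in itertools.combinations(edge, d_prime)]
    others = [n for n in range(num_nodes) if n not in edge]
    return sorted(
        Hyperedge(tuple(edge) + extra)
        for extra in itertools.combinations(others, d_prime - d)
    )


def sample_memory_lengths(m_s_max: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-hyperedge memory lengths i.i.d. uniform on ``{1..m_s_max}``."""
    if m_s_max < 1:
        raise ConfigError("m_s_max must be >= 1")
    return rng.integers(1, m_s_max + 1, size=count)


def _as_order_map(value, orders, name) -> dict:
    """Broadcast a scalar to all orders, or validate a per-order mapping."""
    if value is None:
        return {d: 0.0 for d in orders}
    if isinstance(value, (int, float)):
        return {d: float(value) for d in orders}
    out = {}
    for d in orders:
        if d not in value:
            raise ConfigError(f"{name} missing entry for order {d}")
        out[d] = value[d]
    return out


@dataclass
class MemoryModelConfig:
    """Parameters for the memory models.

    Per-order parameters (``q``, ``y``, ``p`` and the memory specs) accept
    either a scalar, applied to every order, or a mapping keyed by order.
    For each order exactly one of ``m_s`` (fixed length) or ``m_s_max``
    (per-hyperedge lengths sampled uniformly on ``{1..m_s_max}``) applies;
    orders listed in neither default to ``m_s = 1``.  ``m_c`` maps pairs
    ``(d_from, d_to)`` to the number of past states of a ``d_from`` hyperedge
    readable by a ``d_to`` hyperedge.  ``rho[d]`` is the distribution over
    source orders ``d' != d`` used by cross copies (default: uniform over the
    other orders).
    """

    num_nodes: int
    max_order: int
    horizon: int
    q: Mapping[int, float] | float = 0.0
    y: Mapping[int, float] | float = 0.1
    p: Mapping[int, float] | float | None = None
    m_s: Mapping[int, int] | int | None = None
    m_s_max: Mapping[int, int] | int | None = None
    m_c: Mapping[tuple, int] | None = None
    rho: Mapping[int, Mapping[int, float]] | None = None
    seed: int = 0
    burn_in: int | None = None

    # normalized views, filled by validate()
    _q: dict = field(default_factory=dict, repr=False)
    _y: dict = field(default_factory=dict, repr=False)
    _p: dict = field(default_factory=dict, repr=False)
    _ms_fixed: dict = field(default_factory=dict, repr=False)
    _ms_max: dict = field(default_factory=dict, repr=False)
    _mc: dict = field(default_factory=dict, repr=False)
    _rho: dict = field(default_factory=dict, repr=False)

    @property
    def orders(self) -> list:
        return list(range(2, self.max_order + 1))

    def validate(self) -> "MemoryModelConfig":
        if self.max_order < 2:
            raise ConfigError("max_order must be >= 2")
        if self.num_nodes < self.max_order:
            raise ConfigError("num_nodes must be >= max_order")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if self.burn_in is not None and self.burn_in < 0:
            raise ConfigError("burn_in must be >= 0")
        orders = self.orders
        self._q = _as_order_map(self.q, orders, "q")
        self._y = _as_order_map(self.y, orders, "y")
        self._p = _as_order_map(self.p, orders, "p")
        for name, m in (("q", self._q), ("y", self._y), ("p", self._p)):
            for d, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}({d})={v} outside [0, 1]")
        # intra-order memory: fixed length xor sampled maximum, default m_s=1
        ms = self.m_s if self.m_s is not None else {}
        msx = self.m_s_max if self.m_s_max is not None else {}
        if isinstance(ms, int):
            ms = {d: ms for d in orders}
        if isinstance(msx, int):
            msx = {d: msx for d in orders}
        self._ms_fixed, self._ms_max = {}, {}
        for d in orders:
            if d in ms and d in msx:
                raise ConfigError(f"order {d}: give m_s or m_s_max, not both")
            if d in msx:
                if msx[d] < 1:
                    raise ConfigError(f"m_s_max({d}) must be >= 1")
                self._ms_max[d] = int(msx[d])
            else:
                length = int(ms.get(d, 1))
                if length < 1:
                    raise ConfigError(f"m_s({d}) must be >= 1")
                self._ms_fixed[d] = length
        # cross-order memory lengths and source-order distributions
        self._mc = {}
        if self.m_c:
            for key, length in self.m_c.items():
                pair = tuple(int(v) for v in (key.split(",") if isinstance(key, str) else key))
                if len(pair) != 2:
                    raise ConfigError(f"m_c key {key!r} is not a (d_from, d_to) pair")
                if length < 1:
                    raise ConfigError(f"m_c{pair} must be >= 1")
                self._mc[pair] = int(length)
        self._rho = {}
        for d in orders:
            if self._p[d] == 0.0:
                continue
            choices = [dp for dp in orders if dp != d]
            if not choices:
                raise ConfigError(
                    f"p({d}) > 0 but there is no other order to copy from (max_order={self.max_order})"
                )
            if self.rho and d in self.rho:
                dist = {int(k): float(v) for k, v in self.rho[d].items()}
                if any(dp == d or dp not in choices for dp in dist):
                    raise ConfigError(f"rho({d}) support must be a subset of {choices}")
                total = sum(dist.values())
                if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                    raise ConfigError(f"rho({d}) sums to {total}, expected 1")
            else:
                dist = {dp: 1.0 / len(choices) for dp in choices}
            for dp, w in dist.items():
                if w > 0 and (dp, d) not in self._mc:
                    raise ConfigError(
                        f"p({d}) > 0 with rho({d})({dp}) > 0 requires m_c ({dp}, {d})"
                    )
            self._rho[d] = dist
        return self

    def max_memory(self) -> int:
        self.validate()
        lengths = list(self._ms_fixed.values()) + list(self._ms_max.values())
        lengths += [self._mc[pair] for d, dist in self._rho.items() for pair in
                    ((dp, d) for dp in dist)]
        return max(lengths)

    @classmethod
    def from_file(cls, path) -> "MemoryModelConfig":
        """Load a configuration from YAML or JSON.

        Keys: ``N, D, T, seed, burn_in``; per-order maps ``q, y, p, m_s,
        m_s_max``; pair map ``m_c`` keyed ``"d_from,d_to"``; optional nested
        ``rho``.
        """
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            import yaml

            raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise InputError(f"{path}: expected a mapping at top level")

        def intkeys(m):
            if m is None or isinstance(m, (int, float)):
                return m
            return {int(k): v for k, v in m.items()}

        rho = raw.get("rho")
        if isinstance(rho, dict):
            rho = {int(k): {int(kk): float(vv) for kk, vv in v.items()} for k, v in rho.items()}
        try:
            return cls(
                num_nodes=int(raw["N"]),
                max_order=int(raw["D"]),
                horizon=int(raw["T"]),
                q=intkeys(raw.get("q", 0.0)),
                y=intkeys(raw.get("y", 0.1)),
                p=intkeys(raw.get("p")),
                m_s=intkeys(raw.get("m_s")),
                m_s_max=intkeys(raw.get("m_s_max")),
                m_c=raw.get("m_c"),
                rho=rho,
                seed=int(raw.get("seed", 0)),
                burn_in=raw.get("burn_in"),
            ).validate()
        except KeyError as exc:
            raise InputError(f"{path}: missing required key {exc}") from None


# ---------------------------------------------------------------------------
# simulation engines
# ---------------------------------------------------------------------------


def _prepare(config: MemoryModelConfig):
    """Shared set-up: candidate list, per-edge parameter vectors, history."""
    config.validate()
    edges = enumerate_hyperedges(config.num_nodes, config.max_order)
    m = len(edges)
    if m > SCALE_GUARD:
        import warnings

        warnings.warn(
            f"{m} candidate hyperedges: simulation will be slow", stacklevel=3
        )
    rng = np.random.default_rng(config.seed)
    order_of = np.array([e.order for e in edges], dtype=np.int64)
    q_vec = np.array([config._q[d] for d in order_of])
    y_vec = np.array([config._y[d] for d in order_of])
    # intra memory lengths: fixed per order, or sampled per hyperedge
    ms_vec = np.empty(m, dtype=np.int64)
    for d in config.orders:
        sel = order_of == d
        if d in config._ms_fixed:
            ms_vec[sel] = config._ms_fixed[d]
        else:
            ms_vec[sel] = sample_memory_lengths(config._ms_max[d], int(sel.sum()), rng)
    max_mem = config.max_memory()
    burn = config.burn_in if config.burn_in is not None else 10 * max_mem
    prefix = max_mem
    total = prefix + burn + config.horizon
    hist = np.zeros((total, m), dtype=np.int8)
    hist[:prefix] = rng.random((prefix, m)) < y_vec
    return edges, order_of, q_vec, y_vec, ms_vec, prefix, burn, total, hist, rng


def _emit(config: MemoryModelConfig, edges, hist, prefix, burn) -> TemporalHypergraph:
    out = hist[prefix + burn :]
    snapshots = [
        frozenset(edges[k] for k in np.flatnonzero(row)) for row in out
    ]
    return TemporalHypergraph(
        num_nodes=config.num_nodes, max_order=config.max_order, snapshots=snapshots
    )


def darh_simulate(config: MemoryModelConfig) -> TemporalHypergraph:
    """Simulate the intra-order memory model.

    Each candidate hyperedge evolves independently: copy a uniformly chosen
    one of its own last ``m_s`` states with probability ``q(d)``, otherwise
    redraw Bernoulli(``y(d)``).  Cross-order parameters are ignored.
    """
    edges, order_of, q_vec, y_vec, ms_vec, prefix, burn, total, hist, rng = _prepare(config)
    m = len(edges)
    for t in range(prefix, total):
        copy = rng.random(m) < q_vec
        bern = rng.random(m) < y_vec
        lag = rng.integers(1, ms_vec + 1)
        past = hist[t - lag, np.arange(m)]
        hist[t] = np.where(copy, past, bern)
    return _emit(config, edges, hist, prefix, burn)


def cdarh_simulate(config: MemoryModelConfig) -> TemporalHypergraph:
    """Simulate the cross-memory model.

    As :func:`darh_simulate`, except that a memory copy reads, with
    probability ``p(d)``, the recent past of a uniformly chosen overlapping
    hyperedge of another order ``d'`` (drawn from ``rho``), reaching back up
    to ``m_c(d', d)`` steps.  With ``p = 0`` for every order the process is
    distributionally identical to :func:`darh_simulate` (not bit-for-bit:
    the random streams differ).
    """
    edges, order_of, q_vec, y_vec, ms_vec, prefix, burn, total, hist, rng = _prepare(config)
    m = len(edges)
    p_vec = np.array([config._p[d] for d in order_of])
    index_of = {e: k for k, e in enumerate(edges)}
    # Per (d, d'): candidate matrix (rows: edges of order d in enumeration
    # order, columns: overlapping candidates of order d').  Within a fixed
    # (d, d') every edge has the same number of candidates.
    cross_orders = sorted(config._rho)
    local = np.full(m, -1, dtype=np.int64)
    cand: dict = {}
    rho_opts: dict = {}
    rho_cum: dict = {}
    for d in cross_orders:
        rows = np.flatnonzero(order_of == d)
        local[rows] = np.arange(rows.size)
        opts = sorted(dp for dp, w in config._rho[d].items() if w > 0)
        rho_opts[d] = opts
        rho_cum[d] = np.cumsum([config._rho[d][dp] for dp in opts])
        for dp in opts:
            mat = np.array(
                [
                    [index_of[b] for b in overlapping_candidates(edges[k], dp, config.num_nodes)]
                    for k in rows
                ],
                dtype=np.int64,
            )
            cand[(d, dp)] = mat
    own = np.arange(m)
    for t in range(prefix, total):
        copy = rng.random(m) < q_vec
        bern = rng.random(m) < y_vec
        cross = copy & (rng.random(m) < p_vec)
        src = own.copy()
        lag_max = ms_vec.copy()
        if cross.any():
            for d in cross_orders:
                sel = np.flatnonzero(cross & (order_of == d))
                if sel.size == 0:
                    continue
                pick_dp = np.searchsorted(rho_cum[d], rng.random(sel.size), side="right")
                for j, dp in enumerate(rho_opts[d]):
                    sub = sel[pick_dp == j]
                    if sub.size == 0:
                        continue
                    mat = cand[(d, dp)]
                    cols = rng.integers(0, mat.shape[1], size=sub.size)
                    src[sub] = mat[local[sub], cols]
                    lag_max[sub] = config._mc[(dp, d)]
        lag = rng.integers(1, lag_max + 1)
        past = hist[t - lag, src]
        hist[t] = np.where(copy, past, bern)
    return _emit(config, edges, hist, prefix, burn)
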