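"""Time-shuffled null models and null ensembles.

The reference model permutes the snapshot sequence uniformly at random: each
snapshot moves as a block (one permutation shared by all orders), which
preserves every instantaneous cross-sectional structure — and hence the
annealed matrices and all lag-0 statistics — while destroying temporal
correlations.  A per-order shuffle is available behind a flag for
exploration but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import TemporalHypergraph, adjacency_sequence
from .correlations import cross_order_function, cross_order_gap, intra_order_function
from .errors import InputError

__all__ = ["NullEnsembleSummary", "time_shuffle", "null_ensemble", "ensemble_to_csv"]


def time_shuffle(
    th: TemporalHypergraph, seed: int, per_order: bool = False
) -> TemporalHypergraph:
    """Return a copy of ``th`` with its snapshot sequence randomly permuted.

    Deterministic in ``seed``.  With ``per_order=True`` each order's
    hyperedges are permuted across time independently (exploratory variant).
    """
    if th.num_steps < 2:
        raise InputError("time_shuffle needs at least two snapshots")
    rng = np.random.default_rng(seed)
    if not per_order:
        perm = rng.permutation(th.num_steps)
        snaps = [th.snapshots[t] for t in perm]
    else:
        orders = list(range(2, th.max_order + 1))
        per = {d: rng.permutation(th.num_steps) for d in orders}
        snaps = []
        for t in range(th.num_steps):
            merged = set()
            for d in orders:
                src = th.snapshots[per[d][t]]
                merged.update(e for e in src if e.order == d)
            snaps.append(frozenset(merged))
    return TemporalHypergraph(
        num_nodes=th.num_nodes, max_order=th.max_order, snapshots=snaps
    )


@dataclass
class NullEnsembleSummary:
    """Per-lag mean and spread of a statistic under repeated reshuffling."""

    statistic: str
    orders: tuple
    lags: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    num_realizations: int
    seed: int


def _compute_statistic(th, statistic, orders, lags):
    if statistic == "intra":
        d = orders[0] if isinstance(orders, (tuple, list)) else orders
        return intra_order_function(adjacency_sequence(th, d), lags).values
    d1, d2 = orders
    s1 = adjacency_sequence(th, d1)
    s2 = adjacency_sequence(th, d2)
    if statistic == "cross":
        return cross_order_function(s1, s2, lags).values
    if statistic == "gap":
        return cross_order_gap(s1, s2, lags).values
    raise InputError(f"unknown statistic {statistic!r}")


def null_ensemble(
    th: TemporalHypergraph,
    statistic: str,
    orders,
    lags,
    num_realizations: int,
    seed: int,
    per_order: bool = False,
) -> NullEnsembleSummary:
    """Recompute ``statistic`` on ``num_realizations`` reshuffled copies.

    Realization ``r`` uses seed ``seed + r``; the summary reports the per-lag
    mean and population standard deviation across realizations.
    """
    if num_realizations < 1:
        raise InputError("num_realizations must be >= 1")
    rows = []
    for r in range(num_realizations):
        shuffled = time_shuffle(th, seed + r, per_order=per_order)
        rows.append(_compute_statistic(shuffled, statistic, orders, lags))
    stack = np.vstack(rows)
    if isinstance(orders, int):
        orders = (orders, orders)
    return NullEnsembleSummary(
        statistic=statistic,
        orders=tuple(orders),
        lags=np.asarray(lags, dtype=np.int64),
        mean=stack.mean(axis=0),
        std=stack.std(axis=0),
        num_realizations=num_realizations,
        seed=seed,
    )


def ensemble_to_csv(summary: NullEnsembleSummary, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            f"# statistic={summary.statistic} d1={summary.orders[0]} d2={summary.orders[1]}"
            f" R={summary.num_realizations} seed={summary.seed}\n"
        )
        fh.write("tau,null_mean,null_std\n")
        for tau, m, s in zip(summary.lags, summary.mean, summary.std):
            fh.write(f"{int(tau)},{m!r},{s!r}\n")
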