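"""Intra-order and cross-order correlation estimators.

All estimators operate on centered adjacency sequences: at every lag the
order-``d`` matrices are centered by the single annealed average computed
over the *full* sequence (no per-window re-centering).  The matrix-valued
estimators are the literal definitions; the scalar functions use the identity
``tr(X @ Y.T) = sum_ij X_ij * Y_ij`` so that long lag sweeps stay cheap.
Whether the trace is taken before or after the time-average is immaterial by
linearity.

Conventions
-----------
* the order-``d`` auto-covariance at lag ``tau`` carries a ``1/((d-1)!)**2``
  prefactor; the cross-covariance between orders ``d1`` and ``d2`` carries
  ``1/((d1-1)!(d2-1)!)``;
* ``sigma(d)`` denotes the lag-0 scalar auto-correlation (the variance);
* the normalized interaction matrix divides by ``2*sqrt(sigma(d1)*sigma(d2))``
  and is NaN (with a logged warning, never an exception) wherever a variance
  vanishes, so whole-matrix lag sweeps do not abort;
* scalar traces are *not* normalized by N — cross-instance comparability is
  delegated to the normalized interaction matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import AdjacencySequence, TemporalHypergraph, adjacency_sequence
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "BinStat",
    "CorrelationSeries",
    "InteractionMatrix",
    "intra_order_matrix",
    "intra_order_function",
    "cross_order_matrix",
    "cross_order_function",
    "interaction_matrix",
    "cross_order_gap",
    "variance",
    "binned_average",
    "series_to_csv",
    "series_from_csv",
    "binned_to_csv",
    "interaction_to_csv",
    "interaction_from_csv",
]


class BinStat(NamedTuple):
    """One bin of a binned-averaged series."""

    center: float
    mean: float
    std: float
    count: int


@dataclass
class CorrelationSeries:
    """A scalar correlation or gap function sampled on a lag grid.

    ``kind`` is one of ``{"intra", "cross", "gap"}``; ``orders`` is ``(d, d)``
    for intra series.  ``binned`` is filled by :func:`binned_average`.
    """

    kind: str
    orders: tuple
    lags: np.ndarray
    values: np.ndarray
    binned: list | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in {"intra", "cross", "gap"}:
            raise InputError(f"unknown series kind {self.kind!r}")
        if self.lags.shape != self.values.shape:
            raise InputError("lags and values must have equal length")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise InputError("lags must be strictly increasing")


@dataclass
class InteractionMatrix:
    """Normalized cross-order interaction matrix at a fixed lag.

    ``entries[a, b]`` relates order ``orders[a]`` at time ``t`` to order
    ``orders[b]`` at time ``t + lag``; ``variances[a]`` holds the lag-0
    auto-correlation of ``orders[a]``.
    """

    lag: int
    orders: list
    entries: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        k = len(self.orders)
        if self.entries.shape != (k, k):
            raise InputError("entries must be square over the listed orders")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _check_lag(lag: int, num_steps: int) -> None:
    if not 0 <= lag <= num_steps - 1:
        raise InputError(f"lag {lag} outside 0..{num_steps - 1}")


def _check_pair(seq1: AdjacencySequence, seq2: AdjacencySequence) -> None:
    if seq1.num_nodes != seq2.num_nodes:
        raise InputError("sequences have different numbers of nodes")
    if seq1.num_steps != seq2.num_steps:
        raise InputError("sequences have different lengths")


def _centered(seq: AdjacencySequence) -> np.ndarray:
    return seq.matrices.astype(float) - seq.annealed


def cross_order_matrix(
    seq1: AdjacencySequence, seq2: AdjacencySequence, lag: int
) -> np.ndarray:
    """Lag-``lag`` cross-covariance matrix between two orders.

    Averages ``[A1(t) - mu1] @ [A2(t+lag) - mu2].T`` over the ``T - lag``
    admissible ``t`` and divides by ``(d1-1)! (d2-1)!``.  With
    ``seq1 is seq2`` this is exactly the intra-order matrix.
    """
    _check_pair(seq1, seq2)
    _check_lag(lag, seq1.num_steps)
    x = _centered(seq1)
    y = _centered(seq2)
    n = seq1.num_steps - lag
    acc = np.einsum("tij,tkj->ik", x[:n], y[lag : lag + n])
    norm = n * math.factorial(seq1.order - 1) * math.factorial(seq2.order - 1)
    return acc / norm


def intra_order_matrix(seq: AdjacencySequence, lag: int) -> np.ndarray:
    """Lag-``lag`` auto-covariance matrix of one order (``1/((d-1)!)**2``)."""
    return cross_order_matrix(seq, seq, lag)


def _trace_series(
    seq1: AdjacencySequence, seq2: AdjacencySequence, lags: Sequence[int]
) -> np.ndarray:
    """Traces of the cross-covariance matrices at several lags, computed
    via flattened inner products (identical to tracing the matrix form)."""
    _check_pair(seq1, seq2)
    t_len = seq1.num_steps
    x = _centered(seq1).reshape(t_len, -1)
    y = _centered(seq2).reshape(t_len, -1)
    fact = math.factorial(seq1.order - 1) * math.factorial(seq2.order - 1)
    out = np.empty(len(lags), dtype=float)
    for k, tau in enumerate(lags):
        _check_lag(int(tau), t_len)
        n = t_len - int(tau)
        out[k] = np.einsum("ti,ti->", x[:n], y[tau : tau + n]) / (n * fact)
    return out


def cross_order_function(
    seq1: AdjacencySequence, seq2: AdjacencySequence, lags: Sequence[int]
) -> CorrelationSeries:
    """Scalar cross-order correlation function (trace of the matrix form)."""
    values = _trace_series(seq1, seq2, lags)
    return CorrelationSeries(
        kind="cross", orders=(seq1.order, seq2.order), lags=np.asarray(lags), values=values
    )


def intra_order_function(seq: AdjacencySequence, lags: Sequence[int]) -> CorrelationSeries:
    """Scalar intra-order correlation function (trace of the matrix form)."""
    values = _trace_series(seq, seq, lags)
    return CorrelationSeries(
        kind="intra", orders=(seq.order, seq.order), lags=np.asarray(lags), values=values
    )


def variance(seq: AdjacencySequence) -> float:
    """Lag-0 scalar auto-correlation ``sigma(d)``."""
    return float(_trace_series(seq, seq, [0])[0])


def cross_order_gap(
    seq1: AdjacencySequence, seq2: AdjacencySequence, lags: Sequence[int]
) -> CorrelationSeries:
    """Normalized asymmetry between the two directed cross-correlations.

    Positive values at lag ``tau`` mean order ``d1`` now predicts order
    ``d2`` a lag later more strongly than the other way around.  If either
    order has zero variance the series is all-NaN and a warning is logged.
    """
    c12 = _trace_series(seq1, seq2, lags)
    c21 = _trace_series(seq2, seq1, lags)
    s1, s2 = variance(seq1), variance(seq2)
    denom = 2.0 * math.sqrt(s1 * s2) if s1 > 0 and s2 > 0 else 0.0
    if denom == 0.0:
        logger.warning(
            "zero variance for order %d or %d: gap series is NaN", seq1.order, seq2.order
        )
        values = np.full(len(lags), np.nan)
    else:
        values = (c12 - c21) / denom
    return CorrelationSeries(
        kind="gap", orders=(seq1.order, seq2.order), lags=np.asarray(lags), values=values
    )


def interaction_matrix(
    th: TemporalHypergraph,
    lag: int,
    orders: Sequence[int] | None = None,
    sequences: dict | None = None,
) -> InteractionMatrix:
    """Normalized interaction matrix over all order pairs at one lag.

    Entry ``(d1, d2)`` is the scalar cross-correlation at ``lag`` divided by
    ``2*sqrt(sigma(d1)*sigma(d2))``; rows/columns of orders that never vary
    are NaN.  ``sequences`` may carry precomputed adjacency sequences keyed
    by order (they are built on demand otherwise).
    """
    _check_lag(lag, th.num_steps)
    if orders is None:
        orders = list(range(2, th.max_order + 1))
    orders = list(orders)
    seqs = dict(sequences) if sequences else {}
    for d in orders:
        if d not in seqs:
            seqs[d] = adjacency_sequence(th, d)
    sigma = np.array([variance(seqs[d]) for d in orders])
    k = len(orders)
    entries = np.full((k, k), np.nan)
    for a, d1 in enumerate(orders):
        for b, d2 in enumerate(orders):
            denom = 2.0 * math.sqrt(sigma[a] * sigma[b]) if sigma[a] > 0 and sigma[b] > 0 else 0.0
            if denom == 0.0:
                logger.warning(
                    "zero variance for order pair (%d, %d): entry is NaN", d1, d2
                )
                continue
            c12 = _trace_series(seqs[d1], seqs[d2], [lag])[0]
            entries[a, b] = c12 / denom
    return InteractionMatrix(lag=lag, orders=orders, entries=entries, variances=sigma)


# ---------------------------------------------------------------------------
# binned averaging
# ---------------------------------------------------------------------------


def binned_average(
    series: CorrelationSeries, num_bins: int, scale: str = "log"
) -> CorrelationSeries:
    """Partition the lag axis into bins and average within each.

    Log-spaced bins (the default, matching double-log presentation) use
    geometric edges over ``[1, max lag]`` with bin centers at the geometric
    mean of the edges; lags below 1 are excluded on the log scale.  The
    reported spread is the population (1/n) standard deviation.  Empty bins
    are omitted.
    """
    if num_bins < 1:
        raise InputError("num_bins must be >= 1")
    if scale not in {"log", "linear"}:
        raise InputError(f"unknown bin scale {scale!r}")
    lags = series.lags.astype(float)
    vals = series.values
    keep = ~np.isnan(vals)
    if scale == "log":
        keep &= lags >= 1
    lags, vals = lags[keep], vals[keep]
    if lags.size == 0:
        raise InputError("no finite values to bin")
    lo, hi = float(lags.min()), float(lags.max())
    if scale == "log":
        lo = max(lo, 1.0)
        edges = np.geomspace(lo, hi, num_bins + 1) if hi > lo else np.array([lo, hi])
    else:
        edges = np.linspace(lo, hi, num_bins + 1) if hi > lo else np.array([lo, hi])
    idx = np.clip(np.searchsorted(edges, lags, side="right") - 1, 0, len(edges) - 2)
    bins: list[BinStat] = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        center = (
            math.sqrt(edges[b] * edges[b + 1]) if scale == "log" else 0.5 * (edges[b] + edges[b + 1])
        )
        sub = vals[mask]
        bins.append(BinStat(center, float(sub.mean()), float(sub.std()), int(mask.sum())))
    return replace(series, binned=bins)


# ---------------------------------------------------------------------------
# CSV round trips (lossless: 17 significant digits)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def series_to_csv(series: CorrelationSeries, path) -> None:
    """Write the raw series as ``tau,value`` with a metadata comment line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# kind={series.kind} d1={series.orders[0]} d2={series.orders[1]}\n")
        fh.write("tau,value\n")
        for tau, val in zip(series.lags, series.values):
            fh.write(f"{int(tau)},{_FLOAT_FMT % val}\n")


def series_from_csv(path) -> CorrelationSeries:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            for tok in first.lstrip("#").split():
                key, _, val = tok.partition("=")
                meta[key] = val
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return CorrelationSeries(
        kind=meta.get("kind", "intra"),
        orders=(int(meta.get("d1", 0)), int(meta.get("d2", 0))),
        lags=df["tau"].to_numpy(),
        values=df["value"].to_numpy(),
    )


def binned_to_csv(series: CorrelationSeries, path) -> None:
    """Write the binned view as ``bin_center,mean,std,count``."""
    if series.binned is None:
        raise InputError("series has no binned data; call binned_average first")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# kind={series.kind} d1={series.orders[0]} d2={series.orders[1]}\n")
        fh.write("bin_center,mean,std,count\n")
        for b in series.binned:
            fh.write(
                f"{_FLOAT_FMT % b.center},{_FLOAT_FMT % b.mean},{_FLOAT_FMT % b.std},{b.count}\n"
            )


def interaction_to_csv(km: InteractionMatrix, path) -> None:
    """Write the interaction matrix with order labels on both axes."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# lag={km.lag}\n")
        fh.write("# variances=" + ",".join(_FLOAT_FMT % v for v in km.variances) + "\n")
        fh.write("d," + ",".join(str(d) for d in km.orders) + "\n")
        for a, d1 in enumerate(km.orders):
            row = ",".join(_FLOAT_FMT % v for v in km.entries[a])
            fh.write(f"{d1},{row}\n")


def interaction_from_csv(path) -> InteractionMatrix:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    orders = [int(d) for d in df.index]
    variances = np.array([float(v) for v in meta["variances"].split(",")])
    return InteractionMatrix(
        lag=int(meta["lag"]), orders=orders, entries=df.to_numpy(dtype=float), variances=variances
    )
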