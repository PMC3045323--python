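"""Random-walk DAG construction on the bipartite metabolite-reaction graph.

The stoichiometric network is reduced to a metabolites-only simple graph via
two binary adjacencies: CR (metabolite is substrate of reaction) and RC
(reaction produces metabolite).  Row-normalising both and composing them
gives the one-step random-walk matrix P1; a self-loop term keeps walks of
all lengths in play.  Potentiating P1 to convergence yields P_inf whose
zero columns are sources (walkers drain away) and nonzero columns sinks
(walkers accumulate).  The (sources x sinks) lower-left submatrix of P_inf
is the object all subsequent blocking works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import StoichiometricNetwork, _signed_columns

__all__ = [
    "BipartiteAdjacency",
    "WalkState",
    "ConvergenceError",
    "EmptyNetworkError",
    "build_adjacency",
    "build_transition",
    "converge_dag",
    "find_orphans",
]

#: absolute floor below which a P_inf entry counts as zero
ZERO_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Potentiation failed to converge within the iteration budget."""


class EmptyNetworkError(ValueError):
    """No internal metabolites remain to build a walk on."""


@dataclass
class BipartiteAdjacency:
    """Binary substrate (CR) and product (RC) incidences over internal metabolites.

    Reversible reactions are expanded into opposed directed pairs, so CR is
    (n_int x m_dir) and RC is (m_dir x n_int) with m_dir >= m.  Rows/columns
    of external metabolites are deleted.
    """

    CR: np.ndarray
    RC: np.ndarray
    internal_index: list[str]

    @property
    def n_internal(self) -> int:
        return len(self.internal_index)


@dataclass
class WalkState:
    """Converged random-walk state: P1, P_inf, and the sink/source split."""

    P1: np.ndarray
    Pinf: np.ndarray
    iterations: int
    internal_index: list[str]
    sinks: list[str]
    sources: list[str]
    truncated: np.ndarray  # (n_sources x n_sinks) lower-left P_inf submatrix
    truncated_binary: np.ndarray
    top_square: np.ndarray = field(default=None)  # (n_sinks x n_sinks), recorded only
    selfloop_coefficient: float = 0.25


def _rownorm(M: np.ndarray) -> np.ndarray:
    """Normalise each row to unit sum; all-zero rows are left zero."""
    s = M.sum(axis=1, keepdims=True)
    out = np.divide(M, s, out=np.zeros_like(M, dtype=float), where=s != 0)
    return out


def build_adjacency(
    net: StoichiometricNetwork, expand_reversible: bool = True
) -> BipartiteAdjacency:
    """Build CR/RC from the sign pattern of S, restricted to internal metabolites.

    CR = (|sign S| - sign S)/2 selects substrate incidences, RC the transpose
    of (|sign S| + sign S)/2 the product incidences; the sign function
    flattens stoichiometric coefficients to 0/1 adjacency.
    """
    sign = _signed_columns(net, expand_reversible)
    CR = 0.5 * (np.abs(sign) - sign)
    RC = 0.5 * (np.abs(sign) + sign).T
    internal = ~net.external
    if not internal.any():
        raise EmptyNetworkError("all metabolites are external")
    ids = [m for m, ext in zip(net.metabolite_ids, net.external) if not ext]
    return BipartiteAdjacency(CR[internal], RC[:, internal], ids)


def build_transition(adj: BipartiteAdjacency, selfloop: float = 0.25) -> np.ndarray:
    """One-step walk matrix P1 = RowNorm(RowNorm(CR).RowNorm(RC) + selfloop*I).

    The self-loop term guarantees every row has outgoing mass, so P1 is right
    stochastic even for metabolites with no internal products downstream.
    """
    P = _rownorm(adj.CR) @ _rownorm(adj.RC)
    P = P + selfloop * np.eye(adj.n_internal)
    return _rownorm(P)


def converge_dag(
    P1: np.ndarray,
    internal_index: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 60,
    zero_tol: float = ZERO_TOL,
    selfloop: float = 0.25,
) -> WalkState:
    """Potentiate P1 by repeated squaring until the Frobenius norm settles.

    Convergence criterion: ||P_{2k} - P_k||_F < tol between consecutive
    squarings.  Columns of the limit with any entry above ``zero_tol`` are
    sinks; the remainder are sources.  The returned truncated matrix is the
    (sources x sinks) block with sinks ordered first in the internal index.
    """
    if internal_index is None:
        internal_index = [str(i) for i in range(P1.shape[0])]
    P = P1.copy()
    for it in range(1, max_iter + 1):
        Pn = P @ P
        delta = float(np.linalg.norm(Pn - P))
        P = Pn
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"P_inf not converged after {max_iter} squarings (last delta {delta:.3e})"
        )
    Pinf = P
    sink_mask = np.any(Pinf > zero_tol, axis=0)
    sinks = [m for m, s in zip(internal_index, sink_mask) if s]
    sources = [m for m, s in zip(internal_index, sink_mask) if not s]
    src_idx = np.where(~sink_mask)[0]
    snk_idx = np.where(sink_mask)[0]
    truncated = Pinf[np.ix_(src_idx, snk_idx)]
    top_square = Pinf[np.ix_(snk_idx, snk_idx)]
    return WalkState(
        P1=P1,
        Pinf=Pinf,
        iterations=it,
        internal_index=list(internal_index),
        sinks=sinks,
        sources=sources,
        truncated=truncated,
        truncated_binary=(truncated > zero_tol).astype(int),
        top_square=top_square,
        selfloop_coefficient=selfloop,
    )


def find_orphans(state: WalkState) -> list[str]:
    """Sinks with an all-zero column in the truncated matrix: isolated sinks.

    An orphan receives probability from no source node, so it forms the
    smallest possible subnet on its own and is set aside for post-processing.
    """
    if state.truncated.shape[0] == 0:
        return list(state.sinks)
    zero_cols = ~np.any(state.truncated_binary, axis=0)
    return [m for m, z in zip(state.sinks, zero_cols) if z]
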