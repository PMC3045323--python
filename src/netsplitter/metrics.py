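"""Partitioning quality metrics: efficacy, occupancy, null-space validation.

The efficacy score E compares the total interpretive effort
F = f(k) + W * sum_i f(n_i), with a power-law effort f(n) = n^p, against the
theoretical optimum of sqrt(N) subnets of size sqrt(N) each (F = 2 f(sqrt N))
and the unsplit network (F = f(N)), as a percentage on a log scale.  The
exponent is calibrated to network size as p = 0.25 * sqrt(N).  Occupancy is
a percolation-style diagnostic for the loss of long-range connectivity, and
the null-space analysis verifies that a partitioning preserves the active
reaction set of the flux space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .network_model import StoichiometricNetwork
from .walk_dag import BipartiteAdjacency

__all__ = [
    "EfficacyReport",
    "OccupancyEstimate",
    "NullspaceReport",
    "effort",
    "efficacy",
    "calibrate_p",
    "efficacy_curve",
    "occupancy",
    "nullspace_activity",
    "degree_partition",
]


@dataclass
class EfficacyReport:
    N: int
    k: int
    sizes: list[float]
    p: float
    weight_mode: str  # "1/k" or "1"
    F: float
    F_lower: float
    F_upper: float
    E: float


@dataclass
class OccupancyEstimate:
    p_occ: float
    z: float
    N_nodes: int


@dataclass
class NullspaceReport:
    active_full: set[str]
    inactive_full: set[str]
    active_per_subnet: list[set[str]]
    dropped: list[str] = field(default_factory=list)

    @property
    def total_subnet_active(self) -> int:
        return sum(len(a) for a in self.active_per_subnet)


def effort(n: float, p: float) -> float:
    """Power-law interpretive effort f(n) = n^p (prefactor suppressed)."""
    return float(n) ** p


def efficacy(
    sizes, N: int, p: float | None = None, weight_mode: str = "1/k"
) -> EfficacyReport:
    """Efficacy E of a partitioning with subnet sizes ``sizes`` of an
    N-internal-node network.

    F = f(k) + W * sum f(n_i) with W = 1/k (default) or 1; the lower limit is
    F_l = 2 f(sqrt N) (k = n_i = sqrt N), the upper F_u = f(N); E is the
    percentage of the log-scale distance from F_u down to F_l.  The unsplit
    case k = 1 takes F = f(N) (no metanetwork term) so E = 0 exactly.
    """
    sizes = [float(s) for s in sizes]
    if not sizes:
        raise ValueError("sizes must be nonempty")
    if sum(sizes) > N + 1e-9:
        raise ValueError("sum of subnet sizes exceeds N")
    if p is None:
        p = calibrate_p(N)
    if p <= 1:
        raise ValueError("the effort function must be concave up: p > 1")
    k = len(sizes)
    W = 1.0 / k if weight_mode == "1/k" else 1.0
    if k == 1:
        F = effort(N, p)
    else:
        F = effort(k, p) + W * sum(effort(n, p) for n in sizes)
    F_upper = effort(N, p)
    F_lower = 2.0 * effort(np.sqrt(N), p)
    E = 100.0 * (np.log(F_upper) - np.log(F)) / (np.log(F_upper) - np.log(F_lower))
    return EfficacyReport(
        N=N,
        k=k,
        sizes=sizes,
        p=p,
        weight_mode=weight_mode,
        F=F,
        F_lower=F_lower,
        F_upper=F_upper,
        E=float(E),
    )


def calibrate_p(N: int) -> float:
    """Size-calibrated effort exponent p = 0.25 * sqrt(N), floored at 1.05.

    Larger networks need a steeper effort law to discriminate between
    homogeneous and large-subnet-dominated splits; the floor honours the
    concavity requirement p > 1.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    return max(0.25 * float(np.sqrt(N)), 1.05)


def efficacy_curve(N: int, p: float, k_values) -> list[tuple[int, float]]:
    """E(k) for k equal subnets of (real-valued) size N/k each."""
    out = []
    for k in k_values:
        if not 1 <= k <= N:
            raise ValueError(f"k={k} outside [1, N]")
        rep = efficacy([N / k] * int(k), N, p)
        out.append((int(k), rep.E))
    return out


def occupancy(
    adj: BipartiteAdjacency, z_mode: str | float = "mean_degree"
) -> OccupancyEstimate:
    """Percolation-style occupancy p = sum(CR.RC) / (z N).

    The numerator sums all entries of the metabolites-only one-step
    adjacency; z is the coordination number — by default the mean degree of
    the metabolites-only graph (each link counted at both endpoints), or
    ``"max_degree"``, or a user-supplied constant.
    """
    N = adj.n_internal
    if N == 0:
        return OccupancyEstimate(0.0, 0.0, 0)
    A = adj.CR @ adj.RC
    links = (A > 0).astype(int)
    np.fill_diagonal(links, 0)
    degree = links.sum(axis=0) + links.sum(axis=1)
    if isinstance(z_mode, str):
        z = float(degree.mean()) if z_mode == "mean_degree" else float(degree.max())
    else:
        z = float(z_mode)
    if z == 0:
        raise ValueError("coordination number z is zero (no links)")
    return OccupancyEstimate(p_occ=float(A.sum()) / (z * N), z=z, N_nodes=N)


def nullspace_activity(
    net: StoichiometricNetwork, partition=None, tol: float = 1e-10
) -> NullspaceReport:
    """Active-reaction analysis of the internal stoichiometry null space.

    A reaction is active iff some basis vector of the null space of the
    internal-rows S-matrix has an entry of magnitude above ``tol`` (relative
    to the largest singular value) for it.  With a partition supplied, the
    same analysis runs per subnet, so activity conservation can be checked:
    full-network active reactions stay active in subnets except those
    dropped because all their participants became external.
    """

    def active_set(S_int: np.ndarray, rxn_ids: list[str]) -> set[str]:
        if S_int.shape[1] == 0:
            return set()
        if S_int.shape[0] == 0:
            return set(rxn_ids)  # unconstrained: every flux vector admissible
        ns = null_space(S_int, rcond=tol)
        if ns.size == 0:
            return set()
        scale = np.abs(ns).max() or 1.0
        act = np.any(np.abs(ns) > tol * scale, axis=1)
        return {r for r, a in zip(rxn_ids, act) if a}

    internal = ~net.external
    full_active = active_set(net.S[internal], net.reaction_ids)
    per_subnet = []
    dropped = []
    if partition is not None:
        dropped = list(partition.dropped_reactions)
        for sn in partition.subnets:
            rows = [i for i, m in enumerate(sn.metabolites) if m in sn.internal_metabolites]
            per_subnet.append(active_set(sn.S[rows], sn.reactions))
    return NullspaceReport(
        active_full=full_active,
        inactive_full=set(net.reaction_ids) - full_active,
        active_per_subnet=per_subnet,
        dropped=dropped,
    )


def degree_partition(net: StoichiometricNetwork, cutoff: int) -> list[set[str]]:
    """Connectivity-cutoff partitioning: the comparison baseline.

    All internals in more than ``cutoff`` reactions become external; the
    remaining internal bipartite graph's connected components are the
    blocks.  Used to score simple degree-based splitting with the same
    efficacy code.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    from .network_model import ExternalsPolicy, apply_externals_policy

    work = net.copy()
    apply_externals_policy(work, ExternalsPolicy(connectivity_threshold=cutoff))
    internal_idx = np.where(~work.external)[0]
    if internal_idx.size == 0:
        return []
    sub = work.S[internal_idx] != 0
    n, m = sub.shape
    rr, cc = np.nonzero(sub)
    graph = csr_matrix((np.ones(len(rr)), (rr, n + cc)), shape=(n + m, n + m))
    _, labels = connected_components(graph, directed=False)
    blocks: dict[int, set[str]] = {}
    for pos, i in enumerate(internal_idx):
        blocks.setdefault(labels[pos], set()).add(net.metabolite_ids[i])
    return sorted(blocks.values(), key=lambda b: (-len(b), min(b)))
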