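"""Separator-node selection: grey cells, minimal covers, and the round loop.

Light-grey cells of the combined blocking matrix mark weak overlaps between
latent blocks.  Each such cell can be removed by reclassifying either its
row (source) or column (sink) metabolite as external, so the smallest set of
metabolites covering all grey cells is a minimum vertex cover of a bipartite
graph: an integer linear program solved exactly here by a Koenig
maximum-matching reduction (default) or a generic MILP backend.  Accepted
separators are deleted from the adjacencies and the DAG/blocking cycle
repeats until no overlaps remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, maximum_bipartite_matching

from .blocking import BlockingResult, DissimilarityConfig, consolidate, optimise_blocking
from .network_model import StoichiometricNetwork
from .walk_dag import WalkState, build_adjacency, build_transition, converge_dag, find_orphans

__all__ = [
    "CoverProblem",
    "RoundState",
    "SeparatorConfig",
    "AutoController",
    "InteractiveController",
    "InfeasibleCoverError",
    "grey_threshold",
    "solve_cover",
    "recognise_blocks",
    "set_aside_irreducible",
    "run_rounds",
]

_ONE_TOL = 1e-9  # values within this of 1 count as dark (never candidates)


class InfeasibleCoverError(RuntimeError):
    """No admissible cover exists (all candidates for some cell excluded)."""


@dataclass
class CoverProblem:
    """Grey cells to cover, as (row metabolite, column metabolite) id pairs."""

    grey_cells: list[tuple[str, str]]
    threshold: float

    def candidates(self) -> list[str]:
        out = set()
        for u, v in self.grey_cells:
            out.add(u)
            out.add(v)
        return sorted(out)


@dataclass
class SeparatorConfig:
    """Tunables for the iterative separator-selection loop."""

    grey_multiple: float = 2.0
    max_rounds: int = 50
    target_max_block_size: int | None = None
    veto: set[str] = field(default_factory=set)
    approve: set[str] | None = None
    selfloop: float = 0.25
    dissimilarity: DissimilarityConfig = field(default_factory=DissimilarityConfig)
    expand_reversible: bool = True
    cover_backend: str = "matching"


@dataclass
class RoundState:
    """Snapshot of one selection round, handed to the controller."""

    round_number: int
    blocking: BlockingResult | None
    walk: WalkState | None
    blocks: list[set[str]]
    proposed_separators: list[str]
    accepted: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)
    set_aside_blocks: list[set[str]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)
    block_shapes: list[tuple[int, int]] = field(default_factory=list)


class AutoController:
    """Non-interactive controller: accept every proposal not on the veto list."""

    def __init__(self, veto=(), approve=None):
        self.veto = set(veto)
        self.approve = set(approve) if approve is not None else None

    def decide(self, state: RoundState, proposals: list[str]) -> list[str]:
        return [
            p
            for p in proposals
            if p not in self.veto and (self.approve is None or p in self.approve)
        ]


class InteractiveController:
    """Prompt y/n per proposed separator on the terminal."""

    def decide(self, state: RoundState, proposals: list[str]) -> list[str]:
        accepted = []
        print(f"Round {state.round_number}: {len(proposals)} proposed separator(s)")
        for p in proposals:
            ans = input(f"  make {p!r} external? [y/n] ").strip().lower()
            if ans.startswith("y"):
                accepted.append(p)
        return accepted


# ---------------------------------------------------------------------------
# grey threshold
# ---------------------------------------------------------------------------


def grey_threshold(Scomb: np.ndarray, multiple: float = 2.0) -> float:
    """Adaptive light-grey cutoff: the largest value t < 1 among distinct
    nonzero entries such that at most ``multiple * J`` cells satisfy
    0 < s_ij <= t.  Falls back to the smallest nonzero entry when even that
    selects too many cells; returns 0 when the matrix holds no grey at all.
    """
    S = np.asarray(Scomb, float)
    J = S.shape[1]
    grey = S[(S > 0) & (S < 1 - _ONE_TOL)]
    if grey.size == 0:
        return 0.0
    vals = np.unique(np.round(grey, 12))
    budget = multiple * J
    best = None
    count = 0
    for v in vals:
        count += int(np.sum(np.abs(np.round(grey, 12) - v) < 1e-15))
        if count <= budget:
            best = float(v)
        else:
            break
    return best if best is not None else float(vals[0])


# ---------------------------------------------------------------------------
# minimum vertex cover (the ILP)
# ---------------------------------------------------------------------------


def _min_cover_size(cells, allowed: set[str]) -> tuple[float, set[str]]:
    """Minimum cover size restricted to ``allowed`` vertices, with forced picks.

    Iteratively selects vertices that are the sole admissible cover of some
    cell, then solves the residual bipartite problem by maximum matching
    (Koenig's theorem).  Returns (size, forced set); size is ``inf`` when
    some cell has no admissible endpoint.
    """
    remaining = [(u, v) for u, v in cells]
    forced: set[str] = set()
    changed = True
    while changed:
        changed = False
        keep = []
        for u, v in remaining:
            opts = {x for x in (u, v) if x in allowed and x not in forced}
            if forced & {u, v}:
                continue  # already covered
            if not opts:
                return inf, forced
            if len(opts) == 1:
                forced |= opts
                changed = True
            else:
                keep.append((u, v))
        remaining = [c for c in keep if not (forced & set(c))]
    if not remaining:
        return len(forced), forced
    rows = sorted({u for u, _ in remaining})
    cols = sorted({v for _, v in remaining})
    ri = {u: i for i, u in enumerate(rows)}
    ci = {v: j for j, v in enumerate(cols)}
    data = np.ones(len(remaining))
    bi = csr_matrix(
        (data, ([ri[u] for u, _ in remaining], [ci[v] for _, v in remaining])),
        shape=(len(rows), len(cols)),
    )
    match = maximum_bipartite_matching(bi, perm_type="column")
    return len(forced) + int(np.sum(match >= 0)), forced


def _min_cover_size_milp(cells, allowed: set[str]) -> float:
    """Generic ILP backend for the same quantity (scipy.optimize.milp)."""
    from scipy.optimize import Bounds, LinearConstraint, milp

    cand = sorted({x for c in cells for x in c})
    idx = {x: i for i, x in enumerate(cand)}
    ub = np.array([1.0 if x in allowed else 0.0 for x in cand])
    A = np.zeros((len(cells), len(cand)))
    for r, (u, v) in enumerate(cells):
        A[r, idx[u]] = 1
        A[r, idx[v]] = 1
    res = milp(
        c=np.ones(len(cand)),
        constraints=LinearConstraint(A, lb=np.ones(len(cells))),
        integrality=np.ones(len(cand)),
        bounds=Bounds(np.zeros(len(cand)), ub),
    )
    return float(round(res.fun)) if res.success else inf


def solve_cover(
    problem: CoverProblem, excluded=(), backend: str = "matching"
) -> list[str]:
    """Minimum-cardinality metabolite set covering every grey cell.

    Every grey cell must have its row or column metabolite selected
    (a bipartite vertex cover; cells whose row and column metabolite
    coincide force that single metabolite).  Among all optimal covers the
    lexicographically smallest (sorted by identifier) is returned, making
    the selection fully deterministic.
    """
    cells = [tuple(c) for c in problem.grey_cells]
    if not cells:
        return []
    size_fn = _min_cover_size_milp if backend == "milp" else None
    allowed = {x for c in cells for x in c} - set(excluded)
    k, _ = _min_cover_size(cells, allowed)
    if size_fn is not None:
        k = size_fn(cells, allowed)
    if k == inf:
        raise InfeasibleCoverError("grey cell with all candidate metabolites excluded")

    chosen: list[str] = []
    remaining = cells
    avail = set(allowed)
    for v in sorted(allowed):
        if not remaining:
            break
        if v not in avail:
            continue
        rem_v = [c for c in remaining if v not in c]
        sub, _ = _min_cover_size(rem_v, avail - {v})
        if size_fn is not None:
            sub = size_fn(rem_v, avail - {v}) if rem_v else 0
        if len(chosen) + 1 + sub <= k:
            chosen.append(v)
            remaining = rem_v
        avail.discard(v)
    return chosen


# ---------------------------------------------------------------------------
# block recognition
# ---------------------------------------------------------------------------


def recognise_blocks(
    Scomb: np.ndarray, tol: float = 1e-12
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray, np.ndarray]:
    """Separated blocks of a (consolidated) matrix, via bipartite components.

    Rows and columns are nodes of a bipartite graph with an edge per nonzero
    cell; each connected component's row and column sets form a block
    satisfying the definition (all nonzero band entries lie inside the
    intersection).  Returns the blocks plus row/column permutations that
    align them along the diagonal; all-zero rows/columns trail at the end.
    """
    S = np.asarray(Scomb, float)
    I, J = S.shape
    rr, cc = np.nonzero(S > tol)
    n = I + J
    graph = csr_matrix((np.ones(len(rr)), (rr, I + cc)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    order: list[int] = []
    seen = set()
    for i in range(I):
        if labels[i] not in seen and np.any(S[i] > tol):
            seen.add(labels[i])
            order.append(labels[i])
    blocks = []
    for lab in order:
        rows = np.array([i for i in range(I) if labels[i] == lab])
        cols = np.array([j for j in range(J) if labels[I + j] == lab])
        blocks.append((rows, cols))
    row_perm = np.concatenate(
        [b[0] for b in blocks] + [[i for i in range(I) if not np.any(S[i] > tol)]]
    ).astype(int) if blocks else np.arange(I)
    col_perm = np.concatenate(
        [b[1] for b in blocks] + [[j for j in range(J) if not np.any(S[:, j] > tol)]]
    ).astype(int) if blocks else np.arange(J)
    return blocks, row_perm, col_perm


def set_aside_irreducible(state: RoundState) -> RoundState:
    """Move single-row/-column separated blocks out of play for later restoration.

    Such blocks cannot be split further; their metabolites are recorded in
    ``set_aside_blocks`` and dropped from ``blocks``.  Only applies when more
    than one block is separated (a lone block is the whole matrix).
    """
    if len(state.blocks) <= 1:
        return state
    keep_blocks, keep_shapes = [], []
    for blk, (nr, nc) in zip(state.blocks, state.block_shapes):
        if nr == 1 or nc == 1:
            state.set_aside_blocks.append(set(blk))
        else:
            keep_blocks.append(blk)
            keep_shapes.append((nr, nc))
    state.blocks = keep_blocks
    state.block_shapes = keep_shapes
    return state


# ---------------------------------------------------------------------------
# the round loop
# ---------------------------------------------------------------------------


def _blocks_to_metabolites(
    blocks, result: BlockingResult, walk: WalkState
) -> list[set[str]]:
    out = []
    for rows, cols in blocks:
        mets = {walk.sources[result.row_order[p]] for p in rows}
        mets |= {walk.sinks[result.col_order[q]] for q in cols}
        out.append(mets)
    return out


def _supersink_groups(walk: WalkState, members: list[str]) -> list[set[str]]:
    """Group sinks that are mutually connected in the top square of P_inf."""
    idx = [walk.sinks.index(m) for m in members]
    if not idx:
        return []
    T = walk.top_square[np.ix_(idx, idx)] > 1e-8
    graph = csr_matrix(T | T.T)
    _, labels = connected_components(graph, directed=False)
    groups: dict[int, set[str]] = {}
    for m, lab in zip(members, labels):
        groups.setdefault(lab, set()).add(m)
    return list(groups.values())


def _component_blocks(walk: WalkState) -> list[set[str]]:
    """Blocks straight from the binary truncated matrix (no transformation)."""
    B = walk.truncated_binary
    if B.size == 0:
        # no sources at all: every internal is recurrent; group supersinks
        return _supersink_groups(walk, list(walk.sinks)) if not walk.sources else []
    blocks, _, _ = recognise_blocks(B.astype(float))
    out = []
    covered = set()
    for rows, cols in blocks:
        mets = {walk.sources[i] for i in rows} | {walk.sinks[j] for j in cols}
        covered |= mets
        out.append(mets)
    # unfed sinks (orphans) cluster by mutual top-square connectivity; a group
    # touching a fed sink through the top square joins that sink's block
    T = walk.top_square > 1e-8
    for group in _supersink_groups(walk, [m for m in walk.sinks if m not in covered]):
        host = None
        for m in group:
            j = walk.sinks.index(m)
            for j2, other in enumerate(walk.sinks):
                if other in covered and (T[j, j2] or T[j2, j]):
                    host = next(b for b in out if other in b)
                    break
            if host is not None:
                break
        if host is not None:
            host |= group
        else:
            out.append(group)
    for m in walk.sources:
        if m not in covered:
            out.append({m})
    return out


def run_rounds(
    net: StoichiometricNetwork,
    config: SeparatorConfig | None = None,
    controller=None,
):
    """Iterative separator selection on a preprocessed network.

    Loops {converge DAG -> optimise blocking -> consolidate -> recognise
    blocks -> set aside irreducibles -> grey threshold -> minimum cover ->
    controller decision -> delete accepted separators} until no grey cells
    remain, the controller stops, the round budget is exhausted, or every
    block is at or under the target size.  Returns a draft
    :class:`~netsplitter.postprocess.Partition` and the accepted separator
    list, in acceptance order.
    """
    from .postprocess import Partition  # deferred to avoid an import cycle

    config = config or SeparatorConfig()
    if controller is None:
        controller = AutoController(veto=config.veto, approve=config.approve)

    work = net.copy()
    separators: list[str] = []
    orphans: list[str] = []
    set_aside: list[set[str]] = []
    removed: set[str] = set()
    rounds_log: list[RoundState] = []
    round_number = 0
    last_walk: WalkState | None = None
    final_blocks: list[set[str]] | None = None

    guard = 0
    while True:
        guard += 1
        if guard > 4 * config.max_rounds + 20:
            break
        scratch = work.copy()
        scratch.set_external(removed & set(scratch.metabolite_ids))
        internals = scratch.internal_ids()
        if len(internals) == 0:
            break
        adj = build_adjacency(scratch, config.expand_reversible)
        P1 = build_transition(adj, config.selfloop)
        walk = converge_dag(P1, adj.internal_index, selfloop=config.selfloop)
        last_walk = walk

        new_orphans = find_orphans(walk)
        if new_orphans:
            orphans.extend(new_orphans)
            removed |= set(new_orphans)
            continue

        if walk.truncated_binary.shape[0] < 2 or walk.truncated_binary.shape[1] < 2:
            final_blocks = _component_blocks(walk)
            break

        result = consolidate(
            optimise_blocking(walk.truncated_binary, config.dissimilarity),
            config.dissimilarity,
        )
        blocks_pos, _, _ = recognise_blocks(result.Scomb)
        blocks = _blocks_to_metabolites(blocks_pos, result, walk)
        state = RoundState(
            round_number=round_number + 1,
            blocking=result,
            walk=walk,
            blocks=blocks,
            proposed_separators=[],
            set_aside_blocks=[],
            orphans=list(orphans),
            block_shapes=[(len(r), len(c)) for r, c in blocks_pos],
        )

        # irreducible single-row/column separated blocks leave the game
        state = set_aside_irreducible(state)
        if state.set_aside_blocks:
            for blk in state.set_aside_blocks:
                set_aside.append(blk)
                removed |= blk
            continue
        blocks = state.blocks

        if config.target_max_block_size is not None and len(blocks) > 1:
            if all(len(b) <= config.target_max_block_size for b in blocks):
                final_blocks = blocks
                break

        threshold = grey_threshold(result.Scomb, config.grey_multiple)
        if threshold == 0.0:
            final_blocks = blocks
            break

        S = result.Scomb
        gi, gj = np.nonzero((S > 0) & (S <= threshold + 1e-12) & (S < 1 - _ONE_TOL))
        cells = [
            (walk.sources[result.row_order[i]], walk.sinks[result.col_order[j]])
            for i, j in zip(gi, gj)
        ]
        problem = CoverProblem(grey_cells=cells, threshold=threshold)
        try:
            proposals = solve_cover(
                problem,
                excluded=set(config.veto) | set(separators),
                backend=config.cover_backend,
            )
        except InfeasibleCoverError:
            final_blocks = blocks
            break
        state.proposed_separators = proposals
        accepted = controller.decide(state, proposals)
        state.accepted = accepted
        state.rejected = [p for p in proposals if p not in accepted]
        rounds_log.append(state)
        if not accepted:
            final_blocks = blocks
            break
        separators.extend(accepted)
        work.set_external(accepted)
        round_number += 1
        if round_number >= config.max_rounds:
            break

    if final_blocks is None:
        final_blocks = _component_blocks(last_walk) if last_walk is not None else []
    # the fallback walk may predate orphan/set-aside removal: drop those members
    final_blocks = [set(b) - removed for b in final_blocks]

    blocks_all = [set(b) for b in final_blocks if b] + [set(b) for b in set_aside]
    partition = Partition(
        blocks=blocks_all,
        externals=set(net.metabolite_ids)
        - {m for b in blocks_all for m in b}
        - set(orphans),
        orphans=list(orphans),
        separators=list(separators),
        reincorporable=set(separators),
        rounds=rounds_log,
    )
    return partition, separators
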