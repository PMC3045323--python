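"""Post-processing: reincorporation, one-off blocking, subnet reconstruction.

After the selection rounds finish, the draft partition is polished in a
three-step sequence: a reincorporation pass restores externals whose whole
reaction neighbourhood lies in a single block, a one-off blocking recomputes
the block structure with the full external list applied simultaneously (so
the result does not depend on the order separators happened to be found),
and a second reincorporation pass runs on the result.  Finally each block's
stoichiometry is extracted from the full S-matrix, and the rare
internal-external overlaps between subnets are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_model import StoichiometricNetwork

__all__ = [
    "Partition",
    "Subnet",
    "OverlapReport",
    "reincorporate",
    "incorporate_orphans",
    "one_off_blocking",
    "reconstruct_subnets",
    "detect_overlap",
    "merge_blocks",
    "postprocess_partition",
    "verify_partition",
]


@dataclass
class Subnet:
    """A reconstructed subnetwork: reactions, metabolites, and S-submatrix."""

    internal_metabolites: set[str]
    reactions: list[str]
    metabolites: list[str]
    externals: set[str]
    S: np.ndarray


@dataclass
class OverlapReport:
    """Internal-external conflicts between subnets."""

    shared_reactions: dict[str, list[int]] = field(default_factory=dict)
    conflicted_metabolites: dict[str, dict] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.shared_reactions and not self.conflicted_metabolites


@dataclass
class Partition:
    """Disjoint internal-metabolite blocks plus separators, orphans, subnets."""

    blocks: list[set[str]]
    externals: set[str]
    orphans: list[str] = field(default_factory=list)
    separators: list[str] = field(default_factory=list)
    reincorporable: set[str] = field(default_factory=set)
    rounds: list = field(default_factory=list)
    subnets: list[Subnet] = field(default_factory=list)
    overlaps: OverlapReport | None = None
    dropped_reactions: list[str] = field(default_factory=list)
    orphan_pending: dict[str, int] = field(default_factory=dict)

    def block_of(self, mid: str) -> int | None:
        for k, b in enumerate(self.blocks):
            if mid in b:
                return k
        return None

    def internal_sets(self) -> list[set[str]]:
        """Blocks plus one singleton fragment per unabsorbed orphan."""
        return [set(b) for b in self.blocks] + [{o} for o in self.orphans]

    def sizes(self) -> list[int]:
        return [len(b) for b in self.internal_sets()]


# ---------------------------------------------------------------------------
# reincorporation
# ---------------------------------------------------------------------------


def _participation(net: StoichiometricNetwork):
    """met id -> reaction indices, reaction index -> participant met ids."""
    met_rxns = {m: set() for m in net.metabolite_ids}
    rxn_mets: list[set[str]] = []
    nz = net.S != 0
    for j in range(net.n_reactions):
        parts = {net.metabolite_ids[i] for i in np.where(nz[:, j])[0]}
        rxn_mets.append(parts)
        for m in parts:
            met_rxns[m].add(j)
    return met_rxns, rxn_mets


def incorporate_orphans(partition: Partition, net: StoichiometricNetwork) -> bool:
    """Second step of the two-step orphan rule: promote pending orphans.

    An orphan earlier promoted to an external of a block becomes internal to
    that block iff it has no reaction links, in either direction, to
    internals of any other block.  Returns True when anything changed.
    """
    met_rxns, rxn_mets = _participation(net)
    changed = False
    for o, target in list(partition.orphan_pending.items()):
        neighbours = set()
        for j in met_rxns[o]:
            neighbours |= rxn_mets[j]
        neighbours.discard(o)
        foreign = False
        for m in neighbours:
            b = partition.block_of(m)
            if b is not None and b != target:
                foreign = True
                break
        if not foreign:
            partition.blocks[target].add(o)
            partition.externals.discard(o)
            del partition.orphan_pending[o]
            changed = True
    return changed


def reincorporate(partition: Partition, net: StoichiometricNetwork) -> Partition:
    """Restore superfluous externals whose neighbourhood is a single block.

    Runs to a fixpoint: each eligible external (one created by the algorithm
    — threshold/list reclassification or separator — never a structural or
    a-priori external) whose reaction-linked internal neighbours all sit in
    one block is moved into that block.  Externals linked to a single block
    plus orphans trigger the two-step orphan promotion.
    """
    met_rxns, rxn_mets = _participation(net)
    orphan_set = set(partition.orphans)
    while True:
        changed = False
        for e in net.metabolite_ids:
            if e not in partition.externals or e not in partition.reincorporable:
                continue
            neighbours = set()
            for j in met_rxns[e]:
                neighbours |= rxn_mets[j]
            neighbours.discard(e)
            touched_blocks = {
                b for m in neighbours if (b := partition.block_of(m)) is not None
            }
            touched_orphans = neighbours & orphan_set
            if len(touched_blocks) == 1:
                target = touched_blocks.pop()
                partition.blocks[target].add(e)
                partition.externals.discard(e)
                changed = True
                # step one of the orphan rule: promote to external of the block
                for o in touched_orphans:
                    if o not in partition.orphan_pending:
                        partition.orphan_pending[o] = target
                        partition.orphans.remove(o)
                        orphan_set.discard(o)
                        partition.externals.add(o)
                        partition.reincorporable.add(o)
                        changed = True
        if incorporate_orphans(partition, net):
            changed = True
        if not changed:
            break
    return partition


# ---------------------------------------------------------------------------
# one-off blocking
# ---------------------------------------------------------------------------


def one_off_blocking(
    net: StoichiometricNetwork,
    partition: Partition,
    config=None,
) -> Partition:
    """Recompute block memberships with all externals applied simultaneously.

    Separator selection is progressive, so the draft blocks can depend on
    the order in which separators were found; a single DAG + blocking pass
    with the full accumulated external list removes that order dependence.
    No new separators are proposed here.
    """
    from .separators import SeparatorConfig, _component_blocks
    from .walk_dag import build_adjacency, build_transition, converge_dag, find_orphans

    config = config or SeparatorConfig()
    if not partition.externals and not partition.blocks:
        return partition
    scratch = net.copy()
    scratch.external[:] = False
    scratch.set_external(partition.externals & set(net.metabolite_ids))
    if not scratch.internal_ids():
        return partition
    orphans: list[str] = []
    while True:
        adj = build_adjacency(scratch, config.expand_reversible)
        walk = converge_dag(
            build_transition(adj, config.selfloop),
            adj.internal_index,
            selfloop=config.selfloop,
        )
        new = find_orphans(walk)
        if not new or len(scratch.internal_ids()) <= len(new):
            break
        orphans.extend(new)
        scratch.set_external(new)
    blocks = [b for b in _component_blocks(walk) if b]
    partition.blocks = blocks
    partition.orphans = [o for o in orphans]
    partition.orphan_pending = {
        o: b for o, b in partition.orphan_pending.items() if o in partition.externals
    }
    covered = {m for b in blocks for m in b} | set(orphans)
    partition.externals = set(net.metabolite_ids) - covered
    return partition


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def reconstruct_subnets(partition: Partition, net: StoichiometricNetwork) -> Partition:
    """Extract each block's reactions and S-submatrix from the full network.

    A block receives every reaction with a nonzero entry for any of its
    internal metabolites; participants outside the block's internal set are
    the subnet's externals.  Reactions whose participants are all external
    network-wide are dropped with a report — reclassification has made them
    irrelevant to every flux space.
    """
    partition.subnets = []
    nz = net.S != 0
    all_internal = {m for s in partition.internal_sets() for m in s}
    dropped = []
    for j, rid in enumerate(net.reaction_ids):
        parts = {net.metabolite_ids[i] for i in np.where(nz[:, j])[0]}
        if parts and not (parts & all_internal):
            dropped.append(rid)
    partition.dropped_reactions = dropped

    for internal in partition.internal_sets():
        if not internal:
            warnings.warn("skipping block with empty internal set")
            continue
        rows = [net.metabolite_index(m) for m in internal]
        rxn_idx = sorted(np.where(np.any(nz[rows, :], axis=0))[0])
        reactions = [net.reaction_ids[j] for j in rxn_idx]
        met_idx = sorted(np.where(np.any(nz[:, rxn_idx], axis=1))[0]) if rxn_idx else []
        metabolites = [net.metabolite_ids[i] for i in met_idx]
        partition.subnets.append(
            Subnet(
                internal_metabolites=set(internal),
                reactions=reactions,
                metabolites=metabolites,
                externals=set(metabolites) - set(internal),
                S=net.S[np.ix_(met_idx, rxn_idx)].copy(),
            )
        )
    return partition


def detect_overlap(partition: Partition) -> OverlapReport:
    """Report reactions shared between subnets and internal-external conflicts.

    A reaction allocated to more than one subnet, or a metabolite that is
    external in one subnet while internal in another, signals the rare
    bipartite overlap case; merging the affected pair is offered separately
    (never automatic).
    """
    report = OverlapReport()
    rxn_owner: dict[str, list[int]] = {}
    for k, sn in enumerate(partition.subnets):
        for r in sn.reactions:
            rxn_owner.setdefault(r, []).append(k)
    report.shared_reactions = {r: ks for r, ks in rxn_owner.items() if len(ks) > 1}
    for k, sn in enumerate(partition.subnets):
        for m in sn.externals:
            for k2, sn2 in enumerate(partition.subnets):
                if k2 != k and m in sn2.internal_metabolites:
                    entry = report.conflicted_metabolites.setdefault(
                        m, {"internal_in": [], "external_in": []}
                    )
                    if k2 not in entry["internal_in"]:
                        entry["internal_in"].append(k2)
                    if k not in entry["external_in"]:
                        entry["external_in"].append(k)
    partition.overlaps = report
    return report


def merge_blocks(
    partition: Partition, net: StoichiometricNetwork, i: int, j: int
) -> Partition:
    """Merge two subnets (by index into ``internal_sets``) into one block."""
    sets_ = partition.internal_sets()
    merged = sets_[i] | sets_[j]
    keep = [s for k, s in enumerate(sets_) if k not in (i, j)]
    partition.blocks = [merged] + keep
    partition.orphans = []
    reconstruct_subnets(partition, net)
    detect_overlap(partition)
    return partition


def verify_partition(partition: Partition, net: StoichiometricNetwork) -> None:
    """Assert the structural invariants of a finalised partition.

    Internal sets are pairwise disjoint; every reaction of the full network
    is allocated to at least one subnet or dropped as all-external; each
    block contains every reaction its internal metabolites participate in
    (context preservation, so subnet mass balances equal full-network ones);
    and each subnet's S-submatrix matches the full matrix.
    """
    sets_ = partition.internal_sets()
    for a in range(len(sets_)):
        for b in range(a + 1, len(sets_)):
            assert not (sets_[a] & sets_[b]), "internal sets overlap"
    allocated = {r for sn in partition.subnets for r in sn.reactions}
    assert allocated | set(partition.dropped_reactions) == set(net.reaction_ids), (
        "reaction coverage violated"
    )
    nz = net.S != 0
    for sn in partition.subnets:
        for m in sn.internal_metabolites:
            i = net.metabolite_index(m)
            incident = {net.reaction_ids[j] for j in np.where(nz[i])[0]}
            assert incident <= set(sn.reactions), f"context broken for {m}"
        rows = [net.metabolite_index(m) for m in sn.metabolites]
        cols = [net.reaction_ids.index(r) for r in sn.reactions]
        assert np.array_equal(sn.S, net.S[np.ix_(rows, cols)]), "S submatrix mismatch"


def postprocess_partition(
    net: StoichiometricNetwork, partition: Partition, config=None
) -> Partition:
    """The full 3-step sequence plus reconstruction and overlap detection."""
    reincorporate(partition, net)
    one_off_blocking(net, partition, config)
    reincorporate(partition, net)
    reconstruct_subnets(partition, net)
    detect_overlap(partition)
    return partition
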