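"""Planted-module synthetic networks with known separators.

The generator emulates the structure the splitting method assumes: sparse,
mostly linear pathway modules; a handful of highly connected currency
metabolites smeared across all modules; and designated bridge metabolites —
shared products consumed only towards the boundary — that are the only
connections between modules.  Modules, bridges and currency metabolites are
recorded as ground truth, so recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import StoichiometricNetwork

__all__ = ["SyntheticSpec", "GroundTruth", "generate_synthetic"]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-module network.

    ``module_size`` counts internal metabolites per module; each module is a
    linear (or midpoint-branched) pathway with an uptake and an export
    boundary metabolite.  Every module pair is joined by
    ``bridges_per_pair`` shared-product bridge metabolites.  Currency
    metabolites attach to each reaction with probability
    ``currency_attachment`` (as substrate or product alternately), giving
    them the high connectivity real carrier metabolites show.
    """

    module_count: int = 2
    module_size: int = 10
    topology: str = "linear"  # or "branched"
    bridges_per_pair: int = 1
    currency_count: int = 2
    currency_attachment: float = 0.5
    reversible_fraction: float = 0.2
    min_currency_connectivity: int = 10
    seed: int = 0


@dataclass
class GroundTruth:
    modules: list[set[str]]
    bridges: list[str]
    currency: list[str]
    boundary: list[str] = field(default_factory=list)


def generate_synthetic(spec: SyntheticSpec) -> tuple[StoichiometricNetwork, GroundTruth]:
    """Build the network deterministically from the spec (same spec+seed,
    same network)."""
    if spec.module_count < 1 or spec.module_size < 3:
        raise ValueError("need at least one module of at least 3 metabolites")
    if spec.bridges_per_pair > spec.module_size - 2:
        raise ValueError(
            "more bridges per pair than interior metabolites available to feed them"
        )
    rng = np.random.default_rng(spec.seed)
    mets: list[str] = []
    met_pos: dict[str, int] = {}
    columns: list[dict[str, float]] = []
    rxn_ids: list[str] = []
    reversible_eligible: list[int] = []

    def met(mid: str) -> str:
        if mid not in met_pos:
            met_pos[mid] = len(mets)
            mets.append(mid)
        return mid

    def reaction(rid: str, subs: dict[str, float], prods: dict[str, float], mid_chain=False):
        col: dict[str, float] = {}
        for m, c in subs.items():
            col[met(m)] = col.get(m, 0.0) - c
        for m, c in prods.items():
            col[met(m)] = col.get(m, 0.0) + c
        if mid_chain:
            reversible_eligible.append(len(columns))
        columns.append(col)
        rxn_ids.append(rid)

    modules: list[set[str]] = []
    sink_protected: set[int] = set()  # reaction indices never made reversible
    for i in range(spec.module_count):
        s = spec.module_size
        names = [f"M{i}_{j:02d}" for j in range(s)]
        modules.append(set(names))
        reaction(f"R{i}_uptake", {f"X{i}_in": 1}, {names[0]: 1})
        if spec.topology == "branched" and s >= 5:
            h = s // 2
            path = names[: h + 1]
            branch_a = names[h + 1 : h + 1 + (s - h - 1) // 2 + ((s - h - 1) % 2)]
            branch_b = names[h + 1 + len(branch_a) :]
            chains = [path, [path[-1]] + branch_a, [path[-1]] + branch_b]
        else:
            chains = [names]
        terminal_rxns = set()
        for c_idx, chain in enumerate(chains):
            for j in range(len(chain) - 1):
                rid = f"R{i}_{c_idx}_{j:02d}"
                last_step = j == len(chain) - 2
                reaction(rid, {chain[j]: 1}, {chain[j + 1]: 1}, mid_chain=not last_step)
                if last_step:
                    terminal_rxns.add(len(columns) - 1)
            if len(chain) > 1 or c_idx == 0:
                reaction(f"R{i}_{c_idx}_export", {chain[-1]: 1}, {f"X{i}_{c_idx}_out": 1})

    bridges: list[str] = []
    for i in range(spec.module_count):
        for j in range(i + 1, spec.module_count):
            for b in range(spec.bridges_per_pair):
                bid = f"B{i}{j}_{b}"
                bridges.append(bid)
                feeder_i = f"M{i}_{spec.module_size - 2 - b:02d}"
                feeder_j = f"M{j}_{spec.module_size - 2 - b:02d}"
                reaction(f"Rb{i}{j}_{b}_i", {feeder_i: 1}, {bid: 1})
                reaction(f"Rb{i}{j}_{b}_j", {feeder_j: 1}, {bid: 1})
                reaction(f"Rb{i}{j}_{b}_w", {bid: 1}, {f"W{i}{j}_{b}": 1})

    # currency metabolites: ubiquitous co-substrates/co-products.  Attachment
    # is random, but each currency metabolite is topped up to at least
    # min_currency_connectivity participations so it always clears the
    # default connectivity threshold (8) the way real carriers do.
    currency = [f"cur_{c}" for c in range(spec.currency_count)]
    n_core_rxns = len(columns)
    min_conn = min(spec.min_currency_connectivity, n_core_rxns)
    for c in currency:
        met(c)
        side = 0
        attached = []
        for j in range(n_core_rxns):
            if rng.random() < spec.currency_attachment:
                columns[j][c] = columns[j].get(c, 0.0) + (1.0 if side % 2 else -1.0)
                side += 1
                attached.append(j)
        if len(attached) < min_conn:
            spare = [j for j in range(n_core_rxns) if j not in attached]
            extra = rng.choice(len(spare), size=min_conn - len(attached), replace=False)
            for idx in np.sort(extra):
                columns[spare[int(idx)]][c] = 1.0 if side % 2 else -1.0
                side += 1

    n, m = len(mets), len(columns)
    S = np.zeros((n, m))
    for j, col in enumerate(columns):
        for mid, coeff in col.items():
            S[met_pos[mid], j] = coeff

    rev = np.zeros(m, bool)
    eligible = [j for j in reversible_eligible]
    if eligible and spec.reversible_fraction > 0:
        n_rev = int(round(spec.reversible_fraction * len(eligible)))
        pick = rng.choice(len(eligible), size=n_rev, replace=False) if n_rev else []
        for idx in np.sort(pick):
            rev[eligible[int(idx)]] = True

    boundary = [mid for mid in mets if mid.startswith(("X", "W"))]
    net = StoichiometricNetwork(
        mets, rxn_ids, S, rev, np.zeros(n, bool), list(mets)
    )
    truth = GroundTruth(
        modules=modules, bridges=bridges, currency=currency, boundary=boundary
    )
    return net, truth
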