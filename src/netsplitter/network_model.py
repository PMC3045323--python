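"""Stoichiometric network container and I/O.

A metabolic network is represented by its stoichiometric matrix S
(metabolites x reactions, negative entries for substrates, positive for
products) together with per-reaction reversibility flags and per-metabolite
internal/external status.  External metabolites carry no mass-balance
constraint and form the periphery of the network; every partitioning step in
this package works by moving selected internal metabolites to the external
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StoichiometricNetwork",
    "ExternalsPolicy",
    "NetworkValidationError",
    "SBMLParseError",
    "read_sbml",
    "write_subnet",
    "read_tsv",
    "write_tsv",
    "read_externals_list",
    "detect_structural_externals",
    "connectivity",
    "apply_externals_policy",
]


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class SBMLParseError(ValueError):
    """Raised when an SBML document cannot be parsed into a network."""


@dataclass
class StoichiometricNetwork:
    """A stoichiometric network: S-matrix plus metabolite/reaction metadata.

    Parameters
    ----------
    metabolite_ids
        Ordered, duplicate-free metabolite identifiers (S rows).
    reaction_ids
        Ordered, duplicate-free reaction identifiers (S columns).
    S
        Stoichiometric coefficients, shape ``(n_metabolites, n_reactions)``.
    reversible
        Per-reaction reversibility flags.
    external
        Per-metabolite external flags (True = no mass-balance constraint).
    metabolite_names
        Optional display names, parallel to ``metabolite_ids``.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversible: np.ndarray
    external: np.ndarray
    metabolite_names: list[str] | None = None
    _met_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.external = np.asarray(self.external, dtype=bool)
        n, m = self.S.shape
        if len(self.metabolite_ids) != n or len(self.reaction_ids) != m:
            raise NetworkValidationError("identifier lists do not match S dimensions")
        if len(set(self.metabolite_ids)) != n:
            raise NetworkValidationError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != m:
            raise NetworkValidationError("duplicate reaction identifiers")
        if self.reversible.shape != (m,) or self.external.shape != (n,):
            raise NetworkValidationError("flag vector dimensions do not match S")
        if m and not np.all(np.any(self.S != 0, axis=0)):
            raise NetworkValidationError("S contains an all-zero reaction column")
        self._met_index = {mid: i for i, mid in enumerate(self.metabolite_ids)}

    # -- convenience -------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def metabolite_index(self, mid: str) -> int:
        return self._met_index[mid]

    def internal_ids(self) -> list[str]:
        return [m for m, ext in zip(self.metabolite_ids, self.external) if not ext]

    def external_ids(self) -> list[str]:
        return [m for m, ext in zip(self.metabolite_ids, self.external) if ext]

    def set_external(self, mids, value: bool = True) -> None:
        for mid in mids:
            self.external[self._met_index[mid]] = value

    def copy(self) -> "StoichiometricNetwork":
        return StoichiometricNetwork(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            self.S.copy(),
            self.reversible.copy(),
            self.external.copy(),
            list(self.metabolite_names) if self.metabolite_names else None,
        )


@dataclass
class ExternalsPolicy:
    """How to reclassify internal metabolites as external before splitting.

    ``connectivity_threshold``: internals participating in more than this many
    distinct reactions become external (None disables).  ``force_external`` /
    ``force_internal``: explicit identifier lists; ``force_internal`` members
    are protected from the threshold rule.
    """

    connectivity_threshold: int | None = 8
    force_external: set[str] = field(default_factory=set)
    force_internal: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.force_external = set(self.force_external)
        self.force_internal = set(self.force_internal)
        if self.force_external & self.force_internal:
            raise NetworkValidationError(
                "force_external and force_internal overlap: "
                f"{sorted(self.force_external & self.force_internal)}"
            )


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------


def read_sbml(path: str | Path) -> StoichiometricNetwork:
    """Read an SBML Level 2/3 model into a :class:`StoichiometricNetwork`.

    Species with ``boundaryCondition="true"`` are marked external; reaction
    reversibility is taken from the ``reversible`` attribute.  Stoichiometry
    is accumulated from listOfReactants (negative) and listOfProducts
    (positive); a species appearing on both sides nets out.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(f"malformed SBML in {path}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"no model element in {path}")

    met_ids, met_names, external = [], [], []
    for sp in model.getListOfSpecies():
        met_ids.append(sp.getId())
        met_names.append(sp.getName() or sp.getId())
        external.append(bool(sp.getBoundaryCondition()))
    idx = {mid: i for i, mid in enumerate(met_ids)}

    rxn_ids, reversible = [], []
    n = len(met_ids)
    cols = []
    for rxn in model.getListOfReactions():
        col = np.zeros(n)
        for ref in rxn.getListOfReactants():
            sid = ref.getSpecies()
            if sid not in idx:
                raise NetworkValidationError(
                    f"reaction {rxn.getId()!r} references unknown species {sid!r}"
                )
            col[idx[sid]] -= ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            sid = ref.getSpecies()
            if sid not in idx:
                raise NetworkValidationError(
                    f"reaction {rxn.getId()!r} references unknown species {sid!r}"
                )
            col[idx[sid]] += ref.getStoichiometry()
        rxn_ids.append(rxn.getId())
        reversible.append(bool(rxn.getReversible()))
        cols.append(col)

    S = np.column_stack(cols) if cols else np.zeros((n, 0))
    return StoichiometricNetwork(
        met_ids, rxn_ids, S, np.array(reversible, bool), np.array(external, bool), met_names
    )


def write_subnet(
    net: StoichiometricNetwork,
    internal_metabolites,
    reactions,
    path: str | Path,
    model_id: str = "subnet",
) -> None:
    """Write a subnetwork as an SBML Level 3 file.

    The emitted model contains exactly ``reactions`` (identifiers from
    ``net``), all species participating in them, and flags every participant
    not listed in ``internal_metabolites`` with ``boundaryCondition=true``.
    Round-trips losslessly through :func:`read_sbml`.
    """
    import libsbml

    reactions = list(reactions)
    if not reactions:
        raise NetworkValidationError("refusing to write a subnet with no reactions")
    internal = set(internal_metabolites)
    rxn_idx = [net.reaction_ids.index(r) for r in reactions]
    participants = [
        net.metabolite_ids[i]
        for i in range(net.n_metabolites)
        if np.any(net.S[i, rxn_idx] != 0)
    ]

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(model_id)
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    names = net.metabolite_names or net.metabolite_ids
    for mid in participants:
        i = net.metabolite_index(mid)
        sp = model.createSpecies()
        sp.setId(mid)
        sp.setName(names[i])
        sp.setCompartment("c")
        sp.setBoundaryCondition(mid not in internal)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    for rid, j in zip(reactions, rxn_idx):
        rxn = model.createReaction()
        rxn.setId(rid)
        rxn.setReversible(bool(net.reversible[j]))
        for i, coeff in enumerate(net.S[:, j]):
            if coeff == 0:
                continue
            ref = rxn.createReactant() if coeff < 0 else rxn.createProduct()
            ref.setSpecies(net.metabolite_ids[i])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Tabular fallback I/O
# ---------------------------------------------------------------------------


def write_tsv(net: StoichiometricNetwork, prefix: str | Path) -> None:
    """Write the network as plain TSV files (``<prefix>.S.tsv`` plus flag sidecars)."""
    import pandas as pd

    prefix = str(prefix)
    pd.DataFrame(net.S, index=net.metabolite_ids, columns=net.reaction_ids).to_csv(
        prefix + ".S.tsv", sep="\t"
    )
    pd.DataFrame(
        {"reaction": net.reaction_ids, "reversible": net.reversible.astype(int)}
    ).to_csv(prefix + ".reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "metabolite": net.metabolite_ids,
            "external": net.external.astype(int),
            "name": net.metabolite_names or net.metabolite_ids,
        }
    ).to_csv(prefix + ".metabolites.tsv", sep="\t", index=False)


def read_tsv(prefix: str | Path) -> StoichiometricNetwork:
    """Read a network written by :func:`write_tsv`."""
    import pandas as pd

    prefix = str(prefix)
    S = pd.read_csv(prefix + ".S.tsv", sep="\t", index_col=0)
    rx = pd.read_csv(prefix + ".reactions.tsv", sep="\t")
    mets = pd.read_csv(prefix + ".metabolites.tsv", sep="\t")
    rx = rx.set_index("reaction").loc[list(S.columns)]
    mets = mets.set_index("metabolite").loc[list(S.index)]
    return StoichiometricNetwork(
        [str(m) for m in S.index],
        [str(r) for r in S.columns],
        S.to_numpy(float),
        rx["reversible"].to_numpy(bool),
        mets["external"].to_numpy(bool),
        [str(x) for x in mets["name"]],
    )


def read_externals_list(path: str | Path) -> list[str]:
    """Read a plain-text externals list: one identifier per line, ``#`` comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# External classification
# ---------------------------------------------------------------------------


def _signed_columns(net: StoichiometricNetwork, expand_reversible: bool) -> np.ndarray:
    """Sign matrix of S, with reversible reactions expanded to opposed pairs."""
    sign = np.sign(net.S)
    if expand_reversible and np.any(net.reversible):
        rev = sign[:, net.reversible]
        sign = np.concatenate([sign, -rev], axis=1)
    return sign


def detect_structural_externals(
    net: StoichiometricNetwork,
    expand_reversible: bool = True,
    iterate: bool = False,
    mark: bool = True,
) -> set[str]:
    """Identify metabolites acting purely as substrate or purely as product.

    A metabolite whose nonzero S-row entries all carry the same sign (after
    reversible reactions are expanded into opposed directed pairs, unless
    ``expand_reversible`` is False) can be recognised as external from
    topology alone.  A single pass is performed by default; ``iterate=True``
    repeats detection on the reaction set restricted to metabolites still
    internal, to a fixpoint.
    """
    found: set[str] = set()
    active_rxns = np.ones(net.n_reactions, bool)
    while True:
        sign = np.sign(net.S)
        keep = active_rxns.copy()
        if expand_reversible:
            cols = [sign[:, keep], -sign[:, keep & net.reversible]]
            sign = np.concatenate(cols, axis=1)
        else:
            sign = sign[:, keep]
        newly = set()
        for i, mid in enumerate(net.metabolite_ids):
            if net.external[i] or mid in found:
                continue
            row = sign[i][sign[i] != 0]
            if row.size and (np.all(row > 0) or np.all(row < 0)):
                newly.add(mid)
        found |= newly
        if not iterate or not newly:
            break
        # dead-end cascade: a reaction incident to a detected metabolite can
        # carry no steady-state flux, so drop it and re-examine the rest
        detected = np.array([m in found for m in net.metabolite_ids])
        active_rxns &= ~np.any(net.S[detected] != 0, axis=0)
    if mark:
        net.set_external(found)
    return found


def connectivity(net: StoichiometricNetwork) -> np.ndarray:
    """Number of distinct reactions each metabolite participates in."""
    return np.count_nonzero(net.S, axis=1)


def apply_externals_policy(
    net: StoichiometricNetwork, policy: ExternalsPolicy
) -> set[str]:
    """Reclassify internals per an :class:`ExternalsPolicy`; return the delta set.

    Internal metabolites participating in more reactions than the
    connectivity threshold, plus ``force_external`` members, become external.
    ``force_internal`` members are never reclassified by the threshold.
    Identifiers are matched on metabolite id first, then case-insensitively
    on display name; unknown identifiers produce a warning, not an error.
    """
    conn = connectivity(net)
    names_lower = {
        (nm or "").lower(): i
        for i, nm in enumerate(net.metabolite_names or net.metabolite_ids)
    }

    def resolve(mid: str) -> int | None:
        if mid in net._met_index:
            return net._met_index[mid]
        return names_lower.get(mid.lower())

    protected = set()
    for mid in policy.force_internal:
        i = resolve(mid)
        if i is None:
            warnings.warn(f"force_internal identifier not found: {mid!r}")
        else:
            protected.add(i)

    delta = set()
    if policy.connectivity_threshold is not None:
        for i, mid in enumerate(net.metabolite_ids):
            if net.external[i] or i in protected:
                continue
            if conn[i] > policy.connectivity_threshold:
                delta.add(mid)
    for mid in policy.force_external:
        i = resolve(mid)
        if i is None:
            warnings.warn(f"force_external identifier not found: {mid!r}")
        elif not net.external[i] and i not in protected:
            delta.add(net.metabolite_ids[i])
    net.set_external(delta)
    return delta
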