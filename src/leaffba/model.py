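"""Compartmented stoichiometric network containers.

A :class:`MetabolicNetwork` holds ordered metabolites and reactions and
builds the stoichiometry matrix ``N`` (one row per *internal* metabolite,
one column per reaction) that underlies the steady-state condition
``N @ v = 0``.  External metabolites (boundary species outside the cell)
are flagged and carry no balance row.

Coefficients are stored as exact :class:`fractions.Fraction` so model
round-trips and elemental audits are bit-exact; they are converted to
floats only when a linear program is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

#: Reaction role labels understood by the pipeline.  ``transporter`` is
#: assigned automatically from stoichiometry; the photosynthesis/maintenance
#: roles are assigned by the model author (or the toy generator).
KNOWN_TAGS = frozenset(
    {
        "transporter",
        "cyclic_photophos",
        "noncyclic_photophos",
        "rubisco_carboxylase",
        "rubisco_oxygenase",
        "maintenance_atpase",
        "output_transporter",
        "photon_import",
        "dissipation",
    }
)

EXTERNAL_COMPARTMENT = "external"


class ModelValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species localized to one compartment.

    ``carbon_atoms`` / ``nitrogen_atoms`` / ``oxygen_atoms`` may be ``None``
    (unknown); they are required only where carbon or nitrogen accounting
    touches the species (output scenarios, N-source shares).
    """

    id: str
    compartment: str
    is_external: bool = False
    carbon_atoms: int | None = None
    nitrogen_atoms: int | None = None
    oxygen_atoms: int | None = None


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        stoich = {k: Fraction(v) for k, v in self.stoichiometry.items()}
        if not stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in stoich.values()):
            raise ModelValidationError(f"reaction {self.id!r}: zero coefficient")
        object.__setattr__(self, "stoichiometry", stoich)
        unknown = set(self.tags) - KNOWN_TAGS
        if unknown:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown tags {sorted(unknown)}"
            )
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicNetwork:
    """Ordered collection of metabolites and reactions plus compartments."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    def reactions_with_tag(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if tag in r.tags]

    def single_reaction_with_tag(self, tag: str) -> Reaction:
        matches = self.reactions_with_tag(tag)
        if len(matches) != 1:
            raise ModelValidationError(
                f"expected exactly one reaction tagged {tag!r}, found {len(matches)}"
            )
        return matches[0]

    # -- mutation helpers ------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1
        if not met.is_external:
            self.compartments.add(met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def set_tags(self, tag_map: Mapping[str, Iterable[str]]) -> None:
        """Assign role tags to reactions by id (replaces author tags, keeps
        the automatic ``transporter``/``output`` markers already present)."""
        for rxn_id, tags in tag_map.items():
            i = self._rxn_index[rxn_id]
            rxn = self.reactions[i]
            self.reactions[i] = replace(
                rxn, tags=frozenset(rxn.tags) | frozenset(tags)
            )

    def without_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicNetwork":
        """A copy of the network with the named reactions removed (used to
        block a nutrient route, e.g. forcing the NO3-only nitrogen source)."""
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise KeyError(f"unknown reactions: {sorted(missing)}")
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[r for r in self.reactions if r.id not in drop],
            compartments=set(self.compartments),
        )

    # -- validation ------------------------------------------------------

    def validate(self, strict: bool = True) -> "MetabolicNetwork":
        """Check structural invariants; returns self for chaining."""
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    msg = f"reaction {rxn.id!r}: undeclared metabolite {met_id!r}"
                    if strict:
                        raise ModelValidationError(msg)
            if "transporter" in rxn.tags:
                if not any(
                    self.metabolite(m).is_external
                    for m in rxn.stoichiometry
                    if m in self._met_index
                ):
                    raise ModelValidationError(
                        f"transporter {rxn.id!r} references no external metabolite"
                    )
        return self

    # -- stoichiometry matrix -------------------------------------------

    def stoichiometric_matrix(self, sparse: bool = False):
        """Matrix N: rows = internal metabolites (in order), columns =
        reactions (in order).  External metabolites carry no row."""
        internal = self.internal_metabolites
        row_of = {m.id: i for i, m in enumerate(internal)}
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                i = row_of.get(met_id)
                if i is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(float(coef))
        mat = sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(internal), len(self.reactions))
        )
        return mat.tocsr() if sparse else mat.toarray()

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.internal_metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

def _element_count(met: Metabolite, element: str) -> int | None:
    return {
        "carbon": met.carbon_atoms,
        "nitrogen": met.nitrogen_atoms,
        "oxygen": met.oxygen_atoms,
    }[element]


def elemental_imbalances(
    net: MetabolicNetwork,
    elements: tuple[str, ...] = ("carbon", "nitrogen", "oxygen"),
) -> dict[str, dict[str, Fraction]]:
    """Per-reaction elemental balance audit.

    Returns ``{reaction_id: {element: imbalance}}`` for every non-transport
    reaction whose participants all have a known count for an element that
    does not sum to zero.  Transporters are exempt (they move species across
    a boundary unchanged).
    """
    bad: dict[str, dict[str, Fraction]] = {}
    for rxn in net.reactions:
        if "transporter" in rxn.tags:
            continue
        for element in elements:
            counts = {}
            known = True
            for met_id in rxn.stoichiometry:
                c = _element_count(net.metabolite(met_id), element)
                if c is None:
                    known = False
                    break
                counts[met_id] = c
            if not known:
                continue
            total = sum(
                coef * counts[met_id] for met_id, coef in rxn.stoichiometry.items()
            )
            if total != 0:
                bad.setdefault(rxn.id, {})[element] = total
    return bad


def stoichiometric_matrix(net: MetabolicNetwork, sparse: bool = False) -> np.ndarray:
    """Module-level alias for :meth:`MetabolicNetwork.stoichiometric_matrix`."""
    return net.stoichiometric_matrix(sparse=sparse)
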