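"""Model and table input/output.

Two model formats are supported:

* a plain-text reaction-list dialect (one reaction per line), the format
  the test fixtures and the toy-model writer use::

      # comment
      #@ ReactionId: tag1, tag2          (role-tag directive)
      R1: A_cyt + 2 B_cyt -> C_cyt       (irreversible)
      T1: x_CO2 <> CO2_cyt               (reversible transporter)

  Metabolite ids carry their compartment as a suffix (``_cyt``, ``_chl``,
  ``_mit``); the prefix ``x_`` marks an external (boundary) species, which
  receives no mass-balance row.  Coefficients may be integers, decimals or
  rationals (``3/2``).  Ids without a recognized suffix default to the
  cytosol.

* SBML Level 3 core, read through libsbml.  The ``reversible`` flag and
  ``boundaryCondition`` are honored; flux-bound annotations are ignored
  (bounds are imposed by the analysis pipeline, not the file).

Elemental composition (C/N/O atom counts) is supplied as a side table
rather than parsed from formulas; see :func:`read_element_table`.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, TextIO

from .model import (
    EXTERNAL_COMPARTMENT,
    MetabolicNetwork,
    Metabolite,
    ModelValidationError,
    Reaction,
)

COMPARTMENT_SUFFIXES = ("cyt", "chl", "mit")
EXTERNAL_PREFIX = "x_"
DEFAULT_COMPARTMENT = "cyt"

_ARROWS = {"->": False, "<>": True}
_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?|\d*\.\d+)\s+)?(\S+)$")


class ModelSyntaxError(ValueError):
    """Parse failure, carrying the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _compartment_of(met_id: str) -> tuple[str, bool]:
    if met_id.startswith(EXTERNAL_PREFIX):
        return EXTERNAL_COMPARTMENT, True
    for suffix in COMPARTMENT_SUFFIXES:
        if met_id.endswith("_" + suffix):
            return suffix, False
    return DEFAULT_COMPARTMENT, False


def _parse_side(text: str, lineno: int) -> dict[str, Fraction]:
    terms: dict[str, Fraction] = {}
    text = text.strip()
    if not text:
        return terms
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise ModelSyntaxError("empty term", lineno)
        m = _TERM_RE.match(chunk)
        if m is None:
            raise ModelSyntaxError(f"cannot parse term {chunk!r}", lineno)
        coef_text, species = m.groups()
        coef = Fraction(coef_text) if coef_text else Fraction(1)
        if coef <= 0:
            raise ModelSyntaxError(f"non-positive coefficient in {chunk!r}", lineno)
        terms[species] = terms.get(species, Fraction(0)) + coef
    return terms


def loads(text: str, strict: bool = True) -> MetabolicNetwork:
    """Parse the reaction-list dialect from a string."""
    net = MetabolicNetwork()
    tag_map: dict[str, set[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#@"):
            body = line[2:].strip()
            if ":" not in body:
                raise ModelSyntaxError("tag directive needs 'Id: tags'", lineno)
            rxn_id, tags = body.split(":", 1)
            tag_map.setdefault(rxn_id.strip(), set()).update(
                t.strip() for t in tags.split(",") if t.strip()
            )
            continue
        if line.startswith("#"):
            continue
        if ":" not in line:
            raise ModelSyntaxError("expected 'Id: LHS -> RHS'", lineno)
        rxn_id, body = line.split(":", 1)
        rxn_id = rxn_id.strip()
        if net.has_reaction(rxn_id):
            raise ModelSyntaxError(f"duplicate reaction id {rxn_id!r}", lineno)
        arrow = None
        for a in _ARROWS:
            if a in body:
                arrow = a
                break
        if arrow is None:
            raise ModelSyntaxError("missing arrow ('->' or '<>')", lineno)
        lhs_text, rhs_text = body.split(arrow, 1)
        lhs = _parse_side(lhs_text, lineno)
        rhs = _parse_side(rhs_text, lineno)
        stoich: dict[str, Fraction] = {m: -c for m, c in lhs.items()}
        for m, c in rhs.items():
            stoich[m] = stoich.get(m, Fraction(0)) + c
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise ModelSyntaxError("reaction cancels to nothing", lineno)
        tags: set[str] = set()
        for met_id in stoich:
            if not net.has_metabolite(met_id):
                comp, is_ext = _compartment_of(met_id)
                net.add_metabolite(
                    Metabolite(id=met_id, compartment=comp, is_external=is_ext)
                )
            if net.metabolite(met_id).is_external:
                tags.add("transporter")
        net.add_reaction(
            Reaction(
                id=rxn_id,
                stoichiometry=stoich,
                reversible=_ARROWS[arrow],
                tags=frozenset(tags),
            )
        )
    if tag_map:
        unknown = [r for r in tag_map if not net.has_reaction(r)]
        if unknown:
            raise ModelValidationError(f"tag directives for unknown reactions {unknown}")
        net.set_tags(tag_map)
    return net.validate(strict=strict)


def dumps(net: MetabolicNetwork) -> str:
    """Serialize a network to the reaction-list dialect (round-trips
    stoichiometry, reversibility and tags)."""
    lines: list[str] = []
    auto = {"transporter"}
    for rxn in net.reactions:
        explicit = sorted(set(rxn.tags) - auto)
        if explicit:
            lines.append(f"#@ {rxn.id}: {', '.join(explicit)}")
        lhs = " + ".join(
            _term(met, -c) for met, c in rxn.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(_term(met, c) for met, c in rxn.stoichiometry.items() if c > 0)
        arrow = "<>" if rxn.reversible else "->"
        lines.append(f"{rxn.id}: {lhs} {arrow} {rhs}".rstrip())
    return "\n".join(lines) + "\n"


def _term(met: str, coef: Fraction) -> str:
    return met if coef == 1 else f"{coef} {met}"


def _read_text(source: str | Path | TextIO) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source or "->" in source or "<>" in source or "<sbml" in source:
            return source  # already model text
        return Path(source).read_text()
    return source.read()


def load_model(
    source: str | Path | TextIO, format: str = "scrumpy", strict: bool = True
) -> MetabolicNetwork:
    """Load and validate a model.

    ``format`` is ``"scrumpy"`` (the reaction-list dialect above) or
    ``"sbml"``.  ``source`` may be a path, a text stream, or (for the
    reaction-list dialect) the model text itself.
    """
    if format == "scrumpy":
        return loads(_read_text(source), strict=strict)
    if format == "sbml":
        return _load_sbml(source)
    raise ValueError(f"unknown model format {format!r}")


def _load_sbml(source: str | Path | TextIO) -> MetabolicNetwork:
    import libsbml

    text = _read_text(source)
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelSyntaxError(err.getMessage().strip(), err.getLine())
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError("SBML document contains no model")
    net = MetabolicNetwork()
    for sp in sbml_model.getListOfSpecies():
        comp = sp.getCompartment() or DEFAULT_COMPARTMENT
        is_ext = bool(sp.getBoundaryCondition()) or comp == EXTERNAL_COMPARTMENT
        net.add_metabolite(
            Metabolite(
                id=sp.getId(),
                compartment=EXTERNAL_COMPARTMENT if is_ext else comp,
                is_external=is_ext,
            )
        )
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, Fraction] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(
                ref.getSpecies(), Fraction(0)
            ) - Fraction(ref.getStoichiometry()).limit_denominator(10**6)
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(
                ref.getSpecies(), Fraction(0)
            ) + Fraction(ref.getStoichiometry()).limit_denominator(10**6)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        tags = (
            {"transporter"}
            if any(net.metabolite(m).is_external for m in stoich)
            else set()
        )
        net.add_reaction(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                reversible=bool(rxn.getReversible()),
                tags=frozenset(tags),
            )
        )
    return net.validate()


# -- side tables ---------------------------------------------------------


def read_element_table(source: str | Path | TextIO) -> dict[str, dict[str, int]]:
    """TSV with columns ``metabolite_id  carbon_atoms  nitrogen_atoms``
    (optional ``oxygen_atoms``); returns ``{id: {element: count}}``."""
    import pandas as pd

    if isinstance(source, str) and "\t" in source:
        source = _io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"metabolite_id", "carbon_atoms", "nitrogen_atoms"}
    if not required.issubset(df.columns):
        raise ValueError(f"element table needs columns {sorted(required)}")
    table: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        entry = {
            "carbon": int(row.carbon_atoms),
            "nitrogen": int(row.nitrogen_atoms),
        }
        if hasattr(row, "oxygen_atoms"):
            entry["oxygen"] = int(row.oxygen_atoms)
        table[str(row.metabolite_id)] = entry
    return table


def apply_element_table(
    net: MetabolicNetwork, table: Mapping[str, Mapping[str, int]]
) -> MetabolicNetwork:
    """Attach C/N/O atom counts to metabolites in place; an entry keyed by a
    bare species name also covers its compartment variants and external form
    (``CO2`` covers ``CO2_chl`` and ``x_CO2``)."""
    def lookup(met_id: str):
        if met_id in table:
            return table[met_id]
        base = met_id
        if base.startswith(EXTERNAL_PREFIX):
            base = base[len(EXTERNAL_PREFIX):]
        for suffix in COMPARTMENT_SUFFIXES:
            if base.endswith("_" + suffix):
                base = base[: -len(suffix) - 1]
                break
        return table.get(base)

    for i, met in enumerate(net.metabolites):
        entry = lookup(met.id)
        if entry is not None:
            net.metabolites[i] = replace(
                met,
                carbon_atoms=entry.get("carbon", met.carbon_atoms),
                nitrogen_atoms=entry.get("nitrogen", met.nitrogen_atoms),
                oxygen_atoms=entry.get("oxygen", met.oxygen_atoms),
            )
    return net
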