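"""Output scenarios: composition tables to fixed export-transporter fluxes.

Instead of a lumped biomass equation, the pipeline fixes the flux of one
export transporter per measured constituent, in proportion to the measured
composition.  The phloem scenario is rescaled so that producing 100% phloem
fixes exactly the same net carbon as producing 100% biomass, which makes
the biomass-to-phloem transition axis a controlled comparison: mixtures
``(1-r)*biomass + r*phloem`` fix the same carbon for every r in [0, 1].
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TextIO

from .model import MetabolicNetwork

CARBON_TOL = 1e-12  # relative tolerance on the equal-carbon invariant


@dataclass(frozen=True)
class CompositionTable:
    """Relative molar export rates per unit of output, keyed by the export
    transporter id; ``label`` distinguishes biomass from phloem tables."""

    entries: Mapping[str, float]
    label: str = "biomass"

    def __post_init__(self) -> None:
        entries = {k: float(v) for k, v in self.entries.items()}
        if not entries or all(v == 0 for v in entries.values()):
            raise ValueError(f"{self.label}: composition needs a positive entry")
        if any(v < 0 for v in entries.values()):
            raise ValueError(f"{self.label}: negative composition entry")
        object.__setattr__(self, "entries", entries)

    def validate_against(self, net: MetabolicNetwork) -> "CompositionTable":
        for rxn_id in self.entries:
            if not net.has_reaction(rxn_id):
                raise ValueError(f"{self.label}: unknown transporter {rxn_id!r}")
            if "output_transporter" not in net.reaction(rxn_id).tags:
                raise ValueError(
                    f"{self.label}: {rxn_id!r} is not tagged output_transporter"
                )
        return self


@dataclass(frozen=True)
class OutputScenario:
    """Fixed export fluxes (model units) at one point of the transition axis.

    ``carbon_rate`` is mol C leaving through the fixed transporters per unit
    time; ``r`` is the phloem fraction (0 = pure biomass, 1 = pure phloem).
    """

    fixed_fluxes: Mapping[str, float]
    r: float = 0.0
    carbon_rate: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fixed_fluxes", {k: float(v) for k, v in self.fixed_fluxes.items()}
        )


def _exported_species_carbon(net: MetabolicNetwork, rxn_id: str) -> float:
    """Carbon atoms carried per unit flux of an output transporter: the sum
    of carbon over external product species weighted by stoichiometry."""
    rxn = net.reaction(rxn_id)
    total = 0.0
    found = False
    for met_id, coef in rxn.stoichiometry.items():
        met = net.metabolite(met_id)
        if met.is_external and coef > 0:
            if met.carbon_atoms is None:
                raise ValueError(
                    f"carbon content unknown for exported species {met_id!r} "
                    f"(transporter {rxn_id!r}); supply it in the element table"
                )
            total += float(coef) * met.carbon_atoms
            found = True
    if not found:
        raise ValueError(f"transporter {rxn_id!r} exports no external species")
    return total


def scenario_carbon_rate(net: MetabolicNetwork, fluxes: Mapping[str, float]) -> float:
    return sum(
        flux * _exported_species_carbon(net, rxn_id)
        for rxn_id, flux in fluxes.items()
    )


def composition_to_fluxes(
    net: MetabolicNetwork,
    table: CompositionTable,
    rate: float = 1.0,
) -> OutputScenario:
    """Turn a relative composition into fixed export fluxes at ``rate`` units
    of output per unit time, with the implied carbon fixation rate."""
    if rate <= 0:
        raise ValueError("output rate must be positive")
    table.validate_against(net)
    fluxes = {rxn_id: rate * rel for rxn_id, rel in table.entries.items()}
    # the mix fully specifies the cell's output: every other export
    # transporter is closed, otherwise the LP can dump surplus carbon
    # through an unconstrained sink
    for rxn in net.reactions_with_tag("output_transporter"):
        fluxes.setdefault(rxn.id, 0.0)
    return OutputScenario(
        fixed_fluxes=fluxes,
        r=1.0 if table.label == "phloem" else 0.0,
        carbon_rate=scenario_carbon_rate(net, fluxes),
        label=table.label,
    )


def scale_to_equal_carbon(
    phloem: OutputScenario, biomass: OutputScenario
) -> OutputScenario:
    """Rescale the phloem scenario so both fix the same net carbon."""
    if phloem.carbon_rate <= 0:
        raise ValueError("phloem scenario has zero carbon export")
    if biomass.carbon_rate <= 0:
        raise ValueError("biomass scenario has zero carbon export")
    factor = biomass.carbon_rate / phloem.carbon_rate
    return OutputScenario(
        fixed_fluxes={k: v * factor for k, v in phloem.fixed_fluxes.items()},
        r=1.0,
        carbon_rate=phloem.carbon_rate * factor,
        label=phloem.label,
    )


def mix_outputs(
    biomass: OutputScenario, phloem: OutputScenario, r: float
) -> OutputScenario:
    """Componentwise convex combination ``(1-r)*biomass + r*phloem``.

    Requires the phloem scenario to be equal-carbon scaled so carbon
    fixation is invariant along the transition axis.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"phloem fraction r={r} outside [0, 1]")
    rel = abs(phloem.carbon_rate - biomass.carbon_rate) / max(
        biomass.carbon_rate, 1e-300
    )
    if rel > 1e-9:
        raise ValueError(
            "phloem scenario is not equal-carbon scaled "
            f"(relative carbon mismatch {rel:.3g}); call scale_to_equal_carbon first"
        )
    keys = set(biomass.fixed_fluxes) | set(phloem.fixed_fluxes)
    mixed = {
        k: (1.0 - r) * biomass.fixed_fluxes.get(k, 0.0)
        + r * phloem.fixed_fluxes.get(k, 0.0)
        for k in keys
    }
    return OutputScenario(
        fixed_fluxes=mixed,
        r=r,
        carbon_rate=(1.0 - r) * biomass.carbon_rate + r * phloem.carbon_rate,
        label=f"mix(r={r:g})",
    )


def read_composition_table(
    source: str | Path | TextIO, label: str
) -> CompositionTable:
    """TSV with columns ``transporter_id  relative_rate``."""
    import pandas as pd

    if isinstance(source, str) and "\t" in source:
        source = _io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#")
    if not {"transporter_id", "relative_rate"}.issubset(df.columns):
        raise ValueError("composition table needs columns transporter_id, relative_rate")
    return CompositionTable(
        entries={
            str(row.transporter_id): float(row.relative_rate)
            for row in df.itertuples(index=False)
        },
        label=label,
    )


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    lines = ["transporter_id\trelative_rate"]
    for rxn_id, rel in table.entries.items():
        lines.append(f"{rxn_id}\t{rel:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
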