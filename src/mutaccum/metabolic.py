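"""Oxygen-uptake (metabolic-rate) computations and mutation-per-energy ratios.

Headspace O2 readings taken before and after growing colonies in an
airtight container are converted to moles of O2 via the ideal gas law at
the assay temperature and pressure. The oxygen uptake rate (OUR) is
expressed per cell division: a colony of N cells represents N - 1
divisions. Dividing the mutation rate (per nucleotide per generation) by
the OUR (mol O2 per division) gives mutations per nucleotide per mol O2,
using the identification one generation = one division per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rates import RateEstimate, rate_summary

#: ideal gas constant in L*atm/(K*mol)
R_L_ATM_PER_K_MOL = 0.0820574


@dataclass(frozen=True)
class MetabolicAssay:
    """One airtight-container O2 assay of colonies on an agar plate."""

    assay_id: str
    group: str
    o2_fraction_before: float
    o2_fraction_after: float
    gas_volume_l: float
    temperature_k: float
    pressure_atm: float = 1.0
    colony_count: int = 0
    cells_per_colony: float = 0.0
    qc_discard: bool = False

    def __post_init__(self) -> None:
        for name in ("o2_fraction_before", "o2_fraction_after"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be a volume fraction in [0, 1]")
        if self.gas_volume_l <= 0:
            raise ValueError("gas_volume_l must be > 0")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be > 0")
        if self.colony_count < 1:
            raise ValueError("colony_count must be >= 1")


def moles_o2_consumed(assay: MetabolicAssay) -> float:
    """Moles of O2 removed from the headspace, by the ideal gas law.

    n = P * V * (f_before - f_after) / (R * T).
    """
    delta = assay.o2_fraction_before - assay.o2_fraction_after
    if delta < 0:
        raise ValueError(
            "O2 fraction increased during incubation; net O2 production is "
            "inconsistent with aerobic uptake"
        )
    return assay.pressure_atm * assay.gas_volume_l * delta / (
        R_L_ATM_PER_K_MOL * assay.temperature_k
    )


def oxygen_uptake_rate(mol_o2: float, colony_count: int, cells_per_colony: float) -> float:
    """Mol O2 per cell division: a colony of N cells is N - 1 divisions."""
    if mol_o2 < 0:
        raise ValueError("mol_o2 must be >= 0")
    divisions = colony_count * (cells_per_colony - 1)
    if divisions <= 0:
        raise ValueError("total cell divisions must be > 0")
    return mol_o2 / divisions


def assay_our(assay: MetabolicAssay) -> float:
    """OUR of one assay from its O2 readings and colony census."""
    return oxygen_uptake_rate(
        moles_o2_consumed(assay), assay.colony_count, assay.cells_per_colony
    )


def mutation_per_energy(mu: float, our: float) -> float:
    """Mutations per nucleotide per mol O2 consumed: mu / OUR."""
    if our <= 0:
        raise ValueError("OUR must be > 0")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    return mu / our


def summarize_our(assays: list[MetabolicAssay]) -> dict[str, RateEstimate]:
    """Per-group mean OUR +/- 95% CL, excluding QC-discarded assays."""
    groups: dict[str, list[float]] = {}
    for a in assays:
        if a.qc_discard:
            continue
        groups.setdefault(a.group, []).append(assay_our(a))
    return {g: rate_summary(vals, category="OUR") for g, vals in groups.items()}
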