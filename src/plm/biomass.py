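"""Condition- and accession-specific biomass reactions.

Biomass coefficients (mmol/gDW) are assembled from a composition table
holding, per component, an absolute amount measured in control plants and
relative abundances per (accession, condition).  Condition-specific
components are scaled by the ratio-to-absolute rule

    absolute = control_absolute * relative_condition / relative_control,

condition-unspecific components (cell wall, nucleic acids) enter at their
control value, and the lipidome enters as a drain of the SLIME lipid pool
carrying the profile's total lipid mass.  Coefficients are finally rescaled
so that total dry mass closes to exactly 1 g/gDW, which makes the biomass
flux a relative growth rate (gDW gDW^-1 phase^-1) and accessions directly
comparable.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from .model_core import LARGE_BOUND, ModelError, ReactionRecord
from .slime import LIPID_POOL_ID, LipidProfile

logger = logging.getLogger("plm")

COMPONENT_GROUPS = frozenset({
    "protein_bound_aa", "free_aa", "sugar", "organic_acid", "starch",
    "cell_wall", "nucleic_acid", "lipid", "other",
})

#: Groups for which condition/accession-specific data cannot be measured;
#: they enter at the control value.
CONDITION_UNSPECIFIC_GROUPS = frozenset({"cell_wall", "nucleic_acid"})

#: Supported units for control_absolute values.
UNITS = ("mmol/gDW", "umol/gDW", "g/gDW", "mg/gDW")


class BiomassError(ValueError):
    pass


def scale_to_absolute(control_absolute: float, relative_condition: float,
                      relative_control: float) -> float:
    """Ratio-to-absolute scaling: control value times the condition/control
    relative-abundance ratio."""
    if relative_control == 0:
        raise BiomassError("relative_control is zero: ratio undefined")
    if control_absolute < 0 or relative_condition < 0 or relative_control < 0:
        raise BiomassError("negative inputs to ratio scaling")
    return control_absolute * (relative_condition / relative_control)


def to_mmol_per_gdw(amount: float, unit: str, molar_mass: float | None) -> float:
    """Convert a declared-unit amount to mmol/gDW (mass units need g/mmol)."""
    if unit == "mmol/gDW":
        return amount
    if unit == "umol/gDW":
        return amount / 1000.0
    if unit in ("g/gDW", "mg/gDW"):
        if molar_mass is None or molar_mass <= 0:
            raise BiomassError(f"unit {unit} requires a molar mass")
        grams = amount if unit == "g/gDW" else amount / 1000.0
        return grams / molar_mass
    raise BiomassError(f"unknown unit {unit!r} (supported: {UNITS})")


@dataclass
class CompositionRow:
    component_id: str
    metabolite_id: str
    group: str
    unit: str
    control_absolute: float
    molar_mass: float  # g/mmol
    relative: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in COMPONENT_GROUPS:
            raise BiomassError(
                f"{self.component_id}: unknown component group {self.group!r}"
            )
        if self.control_absolute < 0:
            raise BiomassError(f"{self.component_id}: negative control value")
        if any(v < 0 for v in self.relative.values()):
            raise BiomassError(f"{self.component_id}: negative relative value")


@dataclass
class CompositionTable:
    rows: list[CompositionRow]

    @property
    def accession_conditions(self) -> set[tuple[str, str]]:
        keys: set[tuple[str, str]] = set()
        for row in self.rows:
            keys |= set(row.relative)
        return keys

    @staticmethod
    def from_tsv(path) -> "CompositionTable":
        """Read the composition TSV: fixed columns component_id,
        metabolite_id, group, unit, molar_mass, control_absolute, then one
        ``accession:condition`` column per relative value."""
        rows = []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            fixed = {"component_id", "metabolite_id", "group", "unit",
                     "molar_mass", "control_absolute"}
            rel_cols = [c for c in reader.fieldnames if c not in fixed]
            for rec in reader:
                relative = {}
                for col in rel_cols:
                    if rec[col] != "":
                        acc, cond = col.split(":", 1)
                        relative[(acc, cond)] = float(rec[col])
                rows.append(CompositionRow(
                    component_id=rec["component_id"],
                    metabolite_id=rec["metabolite_id"],
                    group=rec["group"], unit=rec["unit"],
                    control_absolute=float(rec["control_absolute"]),
                    molar_mass=float(rec["molar_mass"]),
                    relative=relative,
                ))
        return CompositionTable(rows)

    def to_tsv(self, path):
        rel_cols = sorted({f"{a}:{c}" for a, c in self.accession_conditions})
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["component_id", "metabolite_id", "group", "unit",
                        "molar_mass", "control_absolute"] + rel_cols)
            for row in self.rows:
                rel = {f"{a}:{c}": v for (a, c), v in row.relative.items()}
                w.writerow(
                    [row.component_id, row.metabolite_id, row.group, row.unit,
                     repr(row.molar_mass), repr(row.control_absolute)]
                    + [repr(rel[c]) if c in rel else "" for c in rel_cols]
                )


@dataclass
class BiomassSpec:
    """Stoichiometric biomass coefficients for one accession x condition."""
    accession: str
    condition: str
    coefficients: dict[str, float]   # metabolite id -> mmol/gDW
    masses: dict[str, float]         # metabolite id -> g/mmol

    def __post_init__(self):
        neg = [m for m, v in self.coefficients.items() if v < 0]
        if neg:
            raise BiomassError(f"negative biomass coefficients: {neg}")

    @property
    def mass_closure(self) -> float:
        """Total dry mass accounted for, g/gDW."""
        return sum(v * self.masses[m] for m, v in self.coefficients.items())


def normalize_biomass(spec: BiomassSpec) -> BiomassSpec:
    """Proportionally rescale coefficients so mass closure is exactly 1."""
    closure = spec.mass_closure
    if closure <= 0:
        raise BiomassError("cannot normalize: zero mass closure")
    return replace(
        spec,
        coefficients={m: v / closure for m, v in spec.coefficients.items()},
        masses=dict(spec.masses),
    )


def amino_acid_coefficients(protein_fractions: dict[str, float],
                            total_protein: float,
                            free_aa: dict[str, float],
                            molar_masses: dict[str, float]) -> dict[str, float]:
    """Combine protein-bound and free amino acid pools into mmol/gDW.

    ``protein_fractions`` are mass fractions (must sum to 1 within 1e-3),
    ``total_protein`` is g/gDW, ``free_aa`` is mmol/gDW, ``molar_masses``
    g/mmol.  Per amino acid: bound = fraction*total/molar_mass, plus free.
    """
    if total_protein < 0 or any(v < 0 for v in protein_fractions.values()) \
            or any(v < 0 for v in free_aa.values()):
        raise BiomassError("negative inputs to amino acid combination")
    if total_protein > 0:
        s = sum(protein_fractions.values())
        if abs(s - 1.0) > 1e-3:
            raise BiomassError(f"protein mass fractions sum to {s:.4f}, not 1")
    out: dict[str, float] = {}
    for aa in set(protein_fractions) | set(free_aa):
        bound = 0.0
        if total_protein > 0 and protein_fractions.get(aa, 0.0) > 0:
            mm = molar_masses.get(aa)
            if mm is None or mm <= 0:
                raise BiomassError(f"missing molar mass for {aa}")
            bound = protein_fractions[aa] * total_protein / mm
        out[aa] = bound + free_aa.get(aa, 0.0)
    return out


def assemble_biomass(
    composition: CompositionTable,
    profile: LipidProfile | None,
    accession: str,
    condition: str,
    control_condition: str = "control",
    invariant_components: dict[str, tuple[float, float]] | None = None,
    normalize: bool = True,
) -> tuple[BiomassSpec, ReactionRecord]:
    """Build the biomass spec and reaction for one accession x condition.

    Condition-specific rows are scaled by their relative-abundance ratio
    against the same accession's control; cell wall and nucleic acids enter
    condition-unspecifically; the lipid pool is drained at one unit carrying
    the profile's total lipid mass.  ``invariant_components`` adds fixed
    entries as metabolite -> (mmol/gDW, g/mmol), e.g. a growth-associated
    maintenance component.  Rows whose control relative abundance is zero
    are dropped with a warning.
    """
    coefficients: dict[str, float] = {}
    masses: dict[str, float] = {}
    for row in composition.rows:
        if row.molar_mass is None or row.molar_mass <= 0:
            raise BiomassError(f"{row.component_id}: missing molar mass")
        if row.group in CONDITION_UNSPECIFIC_GROUPS or condition == control_condition:
            absolute = row.control_absolute
        else:
            rel_cond = row.relative.get((accession, condition))
            rel_ctrl = row.relative.get((accession, control_condition))
            if rel_cond is None or rel_ctrl is None:
                raise BiomassError(
                    f"{row.component_id}: no relative abundance for "
                    f"({accession}, {condition}) or its control"
                )
            if rel_ctrl == 0:
                logger.warning(
                    "%s: control relative abundance is zero for %s; row skipped",
                    row.component_id, accession,
                )
                continue
            absolute = scale_to_absolute(row.control_absolute, rel_cond, rel_ctrl)
        mmol = to_mmol_per_gdw(absolute, row.unit, row.molar_mass)
        coefficients[row.metabolite_id] = \
            coefficients.get(row.metabolite_id, 0.0) + mmol
        masses[row.metabolite_id] = row.molar_mass

    if profile is not None:
        total_lipid = profile.total_mass
        if total_lipid <= 0:
            raise BiomassError("lipid profile has zero total mass")
        # one pool unit per gDW; the pool species carries the total lipid mass
        coefficients[LIPID_POOL_ID] = 1.0
        masses[LIPID_POOL_ID] = total_lipid

    for met, (mmol, g_per_mmol) in (invariant_components or {}).items():
        coefficients[met] = coefficients.get(met, 0.0) + mmol
        masses[met] = g_per_mmol

    spec = BiomassSpec(accession, condition, coefficients, masses)
    if normalize:
        spec = normalize_biomass(spec)
    rxn = ReactionRecord(
        id=f"biomass_{accession}_{condition}",
        name=f"biomass ({accession}, {condition})",
        stoichiometry={m: -v for m, v in spec.coefficients.items() if v > 0},
        lower_bound=0.0, upper_bound=LARGE_BOUND,
        subsystem="Biomass", flags=frozenset({"biomass"}),
    )
    return spec, rxn
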