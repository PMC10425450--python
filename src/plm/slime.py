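"""SLIME (Split Lipids Into Measurable Entities) pseudo-reactions.

Measured lipidomes constrain a metabolic model at two levels: the mass
distribution over lipid *classes* (PC, MGDG, TG, ...) and the mass
distribution over *acyl chains* (16:0, 18:2, ...).  Each measured species
gets one SLIME reaction splitting it into a class-specific backbone
pseudo-metabolite and per-chain pseudo-metabolites, with coefficients equal
to the moiety molar masses (g/mmol), so pseudo-metabolite units are grams.

Moiety convention: the chain moiety is the acyl group (fatty acid minus
OH) and the backbone moiety is the remainder of the species formula, so
moiety masses sum exactly to the species molar mass and every SLIME
reaction is mass conserving.  Single-moiety lipids (wax monomers,
pigments) get a backbone-only split.

Two pool pseudo-reactions then collect the pseudo-metabolites: the
backbone pool consumes each class's backbone at the measured class total
(g/gDW) and produces one unit of the lipid pool species (drained by the
biomass reaction); the chain pool consumes each chain pseudo-metabolite at
the chain total and produces one unit of a chain-pool species (drained by
a free demand so acyl ratios are enforced without double-counting lipid
mass in the biomass).  Chain totals are scaled by the backbone mass of the
carrying species (``abundance * chain_mass / backbone_mass``) so that the
class and chain constraints are simultaneously satisfiable at steady state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import (
    LARGE_BOUND,
    MetabolicModel,
    MetaboliteRecord,
    ModelError,
    ReactionRecord,
    molar_mass,
)

LIPID_POOL_ID = "lipid_pool"
CHAIN_POOL_ID = "lipid_chain_pool"
BACKBONE_POOL_RXN = "slime_backbone_pool"
CHAIN_POOL_RXN = "slime_chain_pool"


def backbone_pseudo_id(lipid_class: str) -> str:
    return f"slime_backbone_{lipid_class}"

def chain_pseudo_id(chain: str) -> str:
    return f"slime_chain_{chain.replace(':', '_')}"


@dataclass
class LipidSpecies:
    """One measured lipid species with its moiety decomposition."""
    id: str
    lipid_class: str
    backbone_name: str
    backbone_formula: str
    chains: list[tuple[str, str]] = field(default_factory=list)  # (descriptor, formula)
    compartment: str = "c"
    abundance: float | None = None  # g/gDW

    @property
    def backbone_mass(self) -> float:
        return molar_mass(self.backbone_formula)

    @property
    def chain_masses(self) -> dict[str, float]:
        """Total acyl mass per chain descriptor (repeated chains summed)."""
        masses: dict[str, float] = {}
        for desc, formula in self.chains:
            masses[desc] = masses.get(desc, 0.0) + molar_mass(formula)
        return masses

    @property
    def species_mass(self) -> float:
        """Molar mass of the full species (g/mmol): backbone + chains."""
        return self.backbone_mass + sum(self.chain_masses.values())


@dataclass
class LipidProfile:
    """A measured lipid profile for one sample (accession x condition)."""
    species: list[LipidSpecies]

    def __post_init__(self):
        for sp in self.species:
            if sp.abundance is not None and sp.abundance < 0:
                raise ValueError(f"negative abundance for {sp.id}")

    @property
    def total_mass(self) -> float:
        """Total lipid content, g/gDW."""
        return sum(sp.abundance or 0.0 for sp in self.species)

    @property
    def class_totals(self) -> dict[str, float]:
        """Measured mass per lipid class (g/gDW): sum of species abundances."""
        totals: dict[str, float] = {}
        for sp in self.species:
            totals[sp.lipid_class] = totals.get(sp.lipid_class, 0.0) \
                + (sp.abundance or 0.0)
        return totals

    @property
    def chain_totals(self) -> dict[str, float]:
        """Chain pool coefficients (g/gDW), backbone-normalized.

        ``sum_i abundance_i * chain_mass / backbone_mass_i``; with this
        scaling the molar SLIME fluxes ``abundance_i / backbone_mass_i`` per
        unit pool drain satisfy the class and chain constraints exactly.
        """
        totals: dict[str, float] = {}
        for sp in self.species:
            a = sp.abundance or 0.0
            if a == 0.0:
                continue
            bb = sp.backbone_mass
            for desc, mass in sp.chain_masses.items():
                totals[desc] = totals.get(desc, 0.0) + a * mass / bb
        return totals

    @property
    def classes(self) -> list[str]:
        return sorted({sp.lipid_class for sp in self.species})


def slime_reaction_id(species_id: str) -> str:
    return f"slime_{species_id}"


def build_slime_reaction(species: LipidSpecies) -> ReactionRecord:
    """Irreversible split of one species into backbone + chain pseudo-mets.

    Product coefficients are the moiety molar masses in g/mmol, so the
    coefficients sum to the species molar mass (mass conservation).
    """
    if not species.backbone_formula:
        raise ModelError(f"species {species.id}: missing backbone formula")
    for desc, formula in species.chains:
        if not formula:
            raise ModelError(f"species {species.id}: chain {desc} missing formula")
    stoich: dict[str, float] = {species.id: -1.0}
    stoich[backbone_pseudo_id(species.lipid_class)] = species.backbone_mass
    for desc, mass in species.chain_masses.items():
        stoich[chain_pseudo_id(desc)] = mass
    return ReactionRecord(
        id=slime_reaction_id(species.id),
        name=f"SLIME split of {species.id}",
        stoichiometry=stoich,
        lower_bound=0.0, upper_bound=LARGE_BOUND,
        subsystem="SLIME", flags=frozenset({"slime"}),
    )


def build_pool_reactions(profile: LipidProfile) \
        -> tuple[ReactionRecord, ReactionRecord]:
    """Backbone-pool and chain-pool pseudo-reactions for a profile.

    Classes/chains with zero measured abundance are omitted.  The backbone
    pool produces one unit of the lipid pool species (carrying the total
    lipid mass), the chain pool one unit of the chain-pool species.
    """
    if profile.total_mass <= 0:
        raise ModelError("profile has zero total lipid mass")
    bb_stoich: dict[str, float] = {}
    for cls, total in sorted(profile.class_totals.items()):
        if total > 0:
            bb_stoich[backbone_pseudo_id(cls)] = -total
    bb_stoich[LIPID_POOL_ID] = 1.0
    backbone_pool = ReactionRecord(
        id=BACKBONE_POOL_RXN, name="lipid backbone pool",
        stoichiometry=bb_stoich, lower_bound=0.0, upper_bound=LARGE_BOUND,
        subsystem="SLIME", flags=frozenset({"slime"}),
    )
    ch_stoich: dict[str, float] = {}
    for desc, total in sorted(profile.chain_totals.items()):
        if total > 0:
            ch_stoich[chain_pseudo_id(desc)] = -total
    ch_stoich[CHAIN_POOL_ID] = 1.0
    chain_pool = ReactionRecord(
        id=CHAIN_POOL_RXN, name="lipid acyl-chain pool",
        stoichiometry=ch_stoich, lower_bound=0.0, upper_bound=LARGE_BOUND,
        subsystem="SLIME", flags=frozenset({"slime"}),
    )
    return backbone_pool, chain_pool


def pseudo_metabolites(profile: LipidProfile,
                       compartment: str = "c") -> list[MetaboliteRecord]:
    """Pseudo-metabolite records needed by a profile's SLIME set.

    Pseudo-metabolites carry gram units (no formula); the two pool species
    are dimensionless bookkeeping units.
    """
    mets = [
        MetaboliteRecord(backbone_pseudo_id(cls),
                         name=f"{cls} backbone pseudo-metabolite [g]",
                         compartment=compartment)
        for cls in profile.classes
    ]
    chains = sorted({d for sp in profile.species for d, _ in sp.chains})
    mets += [
        MetaboliteRecord(chain_pseudo_id(d),
                         name=f"{d} acyl-chain pseudo-metabolite [g]",
                         compartment=compartment)
        for d in chains
    ]
    mets.append(MetaboliteRecord(LIPID_POOL_ID, name="lipid pool [unit]",
                                 compartment=compartment))
    mets.append(MetaboliteRecord(CHAIN_POOL_ID, name="acyl-chain pool [unit]",
                                 compartment=compartment))
    return mets


def add_slime_constraints(model: MetabolicModel, profile: LipidProfile,
                          pseudo_compartment: str = "c") -> MetabolicModel:
    """Return a copy of ``model`` extended with the full SLIME set.

    Adds pseudo-metabolites, one SLIME reaction per measured species, the
    two pool reactions, and a free demand on the chain-pool species.  Every
    measured species must already exist as a metabolite in the model.
    """
    missing = [sp.id for sp in profile.species if not model.has_metabolite(sp.id)]
    if missing:
        raise ModelError(f"lipid species not in model: {missing}")
    out = model.copy()
    if pseudo_compartment not in out.compartments:
        out.compartments[pseudo_compartment] = "SLIME pseudo-compartment"
    for met in pseudo_metabolites(profile, pseudo_compartment):
        if not out.has_metabolite(met.id):
            out.add_metabolite(met)
    for sp in profile.species:
        rxn = build_slime_reaction(sp)
        if not out.has_reaction(rxn.id):
            out.add_reaction(rxn)
    bb_pool, ch_pool = build_pool_reactions(profile)
    for rxn in (bb_pool, ch_pool):
        if out.has_reaction(rxn.id):
            out.reaction(rxn.id).stoichiometry = dict(rxn.stoichiometry)
        else:
            out.add_reaction(rxn)
    return add_cofactor_demands(out, [CHAIN_POOL_ID])


def read_lipid_profile(path) -> LipidProfile:
    """Read a lipid profile TSV.

    Columns: species_id, class, backbone_name, backbone_formula, chains
    (semicolon-separated ``descriptor:formula`` entries, may be empty),
    compartment, abundance_g_per_gDW.
    """
    import csv

    species = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chains = []
            for entry in (row.get("chains") or "").split(";"):
                entry = entry.strip()
                if entry:
                    # descriptors themselves contain ':' (e.g. 16:0), so the
                    # formula is everything after the last colon
                    desc, formula = entry.rsplit(":", 1)
                    chains.append((desc, formula))
            ab = row.get("abundance_g_per_gDW", "")
            species.append(LipidSpecies(
                id=row["species_id"], lipid_class=row["class"],
                backbone_name=row.get("backbone_name", ""),
                backbone_formula=row["backbone_formula"],
                chains=chains, compartment=row.get("compartment", "c"),
                abundance=float(ab) if ab else None,
            ))
    return LipidProfile(species)


def write_lipid_profile(profile: LipidProfile, path):
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["species_id", "class", "backbone_name", "backbone_formula",
                    "chains", "compartment", "abundance_g_per_gDW"])
        for sp in profile.species:
            chains = ";".join(f"{d}:{f}" for d, f in sp.chains)
            w.writerow([sp.id, sp.lipid_class, sp.backbone_name,
                        sp.backbone_formula, chains, sp.compartment,
                        "" if sp.abundance is None else repr(sp.abundance)])


def update_slime_coefficients(model: MetabolicModel,
                              profile: LipidProfile) -> MetabolicModel:
    """Re-parameterize the pool reactions from a new profile.

    Only pool coefficients change; topology (reaction and metabolite sets)
    stays identical.  The profile must expose exactly the classes and chain
    types already present in the model's pool reactions.
    """
    out = model.copy()
    for rxn_id, pool_met, totals, label in (
        (BACKBONE_POOL_RXN, LIPID_POOL_ID,
         {k: v for k, v in profile.class_totals.items() if v > 0}, "class"),
        (CHAIN_POOL_RXN, CHAIN_POOL_ID,
         {k: v for k, v in profile.chain_totals.items() if v > 0}, "chain"),
    ):
        if not out.has_reaction(rxn_id):
            raise ModelError(f"model has no SLIME pool reaction {rxn_id!r}")
        rxn = out.reaction(rxn_id)
        pseudo = backbone_pseudo_id if label == "class" else chain_pseudo_id
        model_keys = {m for m in rxn.stoichiometry if m != pool_met}
        profile_keys = {pseudo(k) for k in totals}
        missing = profile_keys - model_keys
        if missing:
            raise ModelError(
                f"profile {label} pseudo-metabolites absent from model pool: "
                f"{sorted(missing)}"
            )
        extra = model_keys - profile_keys
        if extra:
            raise ModelError(
                f"model pool {label} pseudo-metabolites missing from profile: "
                f"{sorted(extra)}"
            )
        rxn.stoichiometry = {pseudo(k): -v for k, v in totals.items()}
        rxn.stoichiometry[pool_met] = 1.0
    return out


def add_cofactor_demands(model: MetabolicModel,
                         cofactor_ids: list[str]) -> MetabolicModel:
    """Add one irreversible demand reaction per cofactor (idempotent).

    Demand reactions relieve the coenzyme pseudo-gap problem: cofactors
    that only cycle through otherwise-blocked loops get a drain so the
    loop can carry flux.  Demand-flagged reactions are excluded from
    lethality analysis.
    """
    out = model.copy()
    for met_id in cofactor_ids:
        if not out.has_metabolite(met_id):
            raise ModelError(f"unknown metabolite {met_id!r} for demand")
        rxn_id = f"DM_{met_id}"
        if out.has_reaction(rxn_id):
            continue
        out.add_reaction(ReactionRecord(
            id=rxn_id, name=f"demand for {met_id}",
            stoichiometry={met_id: -1.0},
            lower_bound=0.0, upper_bound=LARGE_BOUND,
            subsystem="Demand", flags=frozenset({"demand"}),
        ))
    return out
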