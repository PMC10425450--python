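"""Seeded generators for every input the pipeline consumes.

These generators build a self-consistent toy world at desk scale: a small
photoautotrophic template model (photon/CO2 uptake, a RuBisCO
carboxylation/oxygenation pair, sugar, starch, organic-acid and amino-acid
metabolism, biomass), a lipid module sharing part of its metabolism with
the template, measured-style lipid profiles and biomass composition tables
for a panel of accessions and conditions (control / 3 and 6 days extended
darkness), transcript tables with a planted flux-concordance rate, a
structured genotype panel with one causal SNP planted inside a lipid-gene
interval, and mutant-phenotype evidence tables.

All generators are pure functions of their configuration: the same seed
reproduces the same bytes.  Random streams are derived per generator from
the root seed so adding a generator never perturbs existing fixtures.

What the toy world does *not* emulate: realistic genome coordinates or
linkage disequilibrium, elementally balanced lipid biochemistry, and the
size of genome-scale reconstructions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import CompositionRow, CompositionTable, assemble_biomass
from .integration import integrate_module
from .lethality import LethalityResult, EvidenceRow, EvidenceTable
from .model_core import (
    LARGE_BOUND,
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    parse_gpr,
)
from .simulation import pfba, set_rubisco_coupling
from .slime import LipidProfile, LipidSpecies, add_slime_constraints
from .fgwa import GenotypeMatrix, TraitVector

# fixed per-generator stream ids (never renumber)
_STREAMS = {
    "template": 1, "module": 2, "panel": 3, "transcripts": 4,
    "genotypes": 5, "evidence": 6, "lethality_models": 7, "traits": 8,
}


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, _STREAMS[stream]])


@dataclass
class FixtureConfig:
    seed: int = 7
    n_accessions: int = 200
    n_snps: int = 5000
    n_template_reactions: int = 28
    n_shared_reactions: int = 3
    lipid_classes: tuple[str, ...] = ("PC", "MGDG", "TG", "WAX")
    chains: tuple[str, ...] = ("16:0", "18:2")
    causal_gene: str = "LPCAT1"
    causal_variance: float = 0.25
    concordance_rate: float = 0.75
    accession_noise: float = 0.10
    condition_noise: float = 0.05
    conditions: tuple[str, ...] = ("control", "3DD", "6DD")

    def __post_init__(self):
        if not (0 <= self.causal_variance < 1):
            raise ValueError("causal variance must be in [0, 1)")


CHAIN_FORMULAS = {"16:0": "C16H30O", "18:2": "C18H30O", "18:1": "C18H32O"}

# class -> (backbone name, backbone formula, chain multiset)
LIPID_CLASS_DEFS = {
    "PC": ("glycerophosphocholine", "C8H20NO6P", ("16:0", "18:2")),
    "MGDG": ("monogalactosylglycerol", "C9H18O8", ("16:0", "18:2")),
    "TG": ("glycerol", "C3H8O3", ("16:0", "16:0", "18:2")),
    "WAX": ("nonacosane", "C29H60", ()),
}

BASE_LIPID_ABUNDANCE = {"PC": 0.004, "MGDG": 0.006, "TG": 0.003, "WAX": 0.001}

# multiplicative class effects of extended darkness on lipid abundance:
# membrane lipids decline, storage TG accumulates
LIPID_CONDITION_EFFECT = {
    "control": {"PC": 1.0, "MGDG": 1.0, "TG": 1.0, "WAX": 1.0},
    "3DD": {"PC": 0.7, "MGDG": 0.6, "TG": 2.0, "WAX": 1.0},
    "6DD": {"PC": 0.5, "MGDG": 0.4, "TG": 3.0, "WAX": 1.0},
}

STORAGE_IDS = ("starch_h", "sucrose_c", "ala_c")
PHOTON_EXCHANGE = "EX_photon"
CARBOXYLATION = "RBC"
OXYGENATION = "RBO"


# ---------------------------------------------------------------------------
# Template model
# ---------------------------------------------------------------------------

def make_template_model(cfg: FixtureConfig | None = None) -> MetabolicModel:
    """Small feasible photoautotrophic template with isoenzyme and complex
    GPRs, subsystem labels and a positive biomass optimum.

    The deterministic core has 26 reactions; ``cfg.n_template_reactions``
    beyond that adds seeded accessory branches (each one reaction plus a
    demand).  Lumped sugar, organic-acid and amino-acid chemistry is
    element-balanced (water, ammonia and O2 carry the balance); photons and
    polymer pools are formula-less, so validation reports the reactions
    touching them as unchecked rather than unbalanced.
    """
    cfg = cfg or FixtureConfig()
    m = MetabolicModel(id="toy_template",
                       compartments={"c": "cytosol", "h": "chloroplast"})

    def met(mid, comp, formula="", kegg=None, name=""):
        ann = {"kegg": kegg} if kegg else {}
        m.add_metabolite(MetaboliteRecord(mid, name=name or mid,
                                          compartment=comp, formula=formula,
                                          annotations=ann))

    met("photon_h", "h", name="photon")
    met("co2_h", "h", "CO2", "C00011")
    met("o2_h", "h", "O2", "C00007")
    met("rubp_h", "h")
    met("pga_h", "h")
    met("g3p_h", "h")
    met("glycolate_h", "h")
    met("g3p_c", "c")
    met("h2o_c", "c", "H2O", "C00001")
    met("nh3_c", "c", "NH3", "C00014")
    met("hexose_c", "c", "C6H12O6", "C00031")
    met("sucrose_c", "c", "C12H22O11", "C00089")
    met("starch_h", "h", "C6H10O5", "C00369")
    met("maltose_c", "c", "", "C00208")
    met("acetyl_c", "c", "C2H4O2", "C00033")
    met("malate_c", "c", "C4H6O5", "C00149")
    met("ala_c", "c", "C3H7NO2", "C00041")
    met("glu_c", "c", "C5H9NO4", "C00025")
    met("cellwall_c", "c")
    met("nucleotide_c", "c")

    def rxn(rid, stoich, gpr="", subsystem="", lb=0.0, ub=LARGE_BOUND,
            flags=()):
        m.add_reaction(ReactionRecord(
            id=rid, name=rid, stoichiometry=stoich, lower_bound=lb,
            upper_bound=ub, gpr=parse_gpr(gpr), subsystem=subsystem,
            flags=frozenset(flags)))

    rxn(PHOTON_EXCHANGE, {"photon_h": -1.0}, lb=-100.0, ub=0.0,
        subsystem="Exchange", flags=("exchange",))
    rxn("EX_co2", {"co2_h": -1.0}, lb=-20.0, ub=LARGE_BOUND,
        subsystem="Exchange", flags=("exchange",))
    rxn("EX_o2", {"o2_h": -1.0}, lb=-LARGE_BOUND, ub=LARGE_BOUND,
        subsystem="Exchange", flags=("exchange",))
    rxn("EX_h2o", {"h2o_c": -1.0}, lb=-LARGE_BOUND, ub=LARGE_BOUND,
        subsystem="Exchange", flags=("exchange",))
    rxn("EX_nh3", {"nh3_c": -1.0}, lb=-50.0, ub=LARGE_BOUND,
        subsystem="Exchange", flags=("exchange",))
    rxn(CARBOXYLATION, {"rubp_h": -1.0, "co2_h": -1.0, "pga_h": 2.0},
        "RBCL and (RBCS1 or RBCS2)", "Calvin cycle")
    rxn(OXYGENATION, {"rubp_h": -1.0, "o2_h": -1.0, "pga_h": 1.0,
                      "glycolate_h": 1.0},
        "RBCL and (RBCS1 or RBCS2)", "Photorespiration")
    rxn("GLYC_SALVAGE", {"glycolate_h": -2.0, "pga_h": 1.0, "co2_h": 1.0},
        "GGT1", "Photorespiration")
    rxn("PGA_RED", {"pga_h": -1.0, "photon_h": -2.0, "g3p_h": 1.0},
        "GAPDH1 or GAPDH2", "Calvin cycle")
    rxn("RUBP_REGEN", {"g3p_h": -5.0, "rubp_h": 3.0}, "PRK1", "Calvin cycle")
    rxn("TPT", {"g3p_h": -1.0, "g3p_c": 1.0}, "TPT1", "Transport",
        lb=-LARGE_BOUND, flags=("transport",))
    rxn("HEX_SYN", {"g3p_c": -2.0, "hexose_c": 1.0}, "FBA1 and FBP1",
        "Sugar metabolism")
    rxn("SUC_SYN", {"hexose_c": -2.0, "sucrose_c": 1.0, "h2o_c": 1.0},
        "SPS1 or SPS2", "Sugar metabolism")
    rxn("SUC_DEG", {"sucrose_c": -1.0, "h2o_c": -1.0, "hexose_c": 2.0},
        "INV1", "Sugar metabolism")
    rxn("STARCH_SYN", {"hexose_c": -1.0, "starch_h": 1.0, "h2o_c": 1.0},
        "AGP1 and SS1", "Starch metabolism")
    rxn("STARCH_DEG", {"starch_h": -2.0, "maltose_c": 1.0}, "BAM1 or BAM3",
        "Starch metabolism")
    rxn("MALT_DEG", {"maltose_c": -1.0, "hexose_c": 2.0}, "DPE2",
        "Starch metabolism")
    rxn("ACETYL_SYN", {"hexose_c": -1.0, "acetyl_c": 3.0}, "PDH1",
        "Central carbon")
    rxn("MAL_SYN", {"hexose_c": -1.0, "o2_h": -3.0, "malate_c": 1.0,
                    "co2_h": 2.0, "h2o_c": 3.0}, "PEPC1", "Organic acids")
    rxn("ALA_SYN", {"hexose_c": -1.0, "nh3_c": -2.0, "ala_c": 2.0,
                    "h2o_c": 2.0}, "ALAT1", "Amino acid synthesis")
    rxn("GLU_SYN", {"hexose_c": -1.0, "malate_c": -1.0, "nh3_c": -2.0,
                    "glu_c": 2.0, "h2o_c": 3.0}, "GDH1 or GDH2",
        "Amino acid synthesis")
    rxn("CW_SYN", {"hexose_c": -1.0, "cellwall_c": 1.0}, "CESA1 and CESA3",
        "Cell wall")
    rxn("NUC_SYN", {"hexose_c": -1.0, "glu_c": -1.0, "nucleotide_c": 1.0},
        "PYR1", "Nucleotide synthesis")
    rxn("NGAM", {"hexose_c": -1.0, "o2_h": -6.0, "co2_h": 6.0, "h2o_c": 6.0},
        "", "Maintenance", flags=("maintenance",))
    rxn("biomass_template", CONTROL_BIOMASS_STOICH.copy(), "", "Biomass",
        flags=("biomass",))

    rng = _rng(cfg.seed, "template")
    n_extra = max(0, cfg.n_template_reactions - 26)
    for i in range(n_extra):
        mid = f"acc{i}_c"
        met(mid, "c")
        genes = [f"EXG{i}A", f"EXG{i}B"]
        gpr = genes[0] if rng.random() < 0.5 \
            else f"{genes[0]} {'or' if rng.random() < 0.5 else 'and'} {genes[1]}"
        rxn(f"ACC{i}", {"hexose_c": -1.0, mid: float(rng.integers(1, 4))},
            gpr, "Accessory")
        rxn(f"DM_{mid}", {mid: -1.0}, "", "Demand", flags=("demand",))

    m.set_objective("biomass_template", "max")
    return m


# control biomass coefficients (mmol/gDW drains)
CONTROL_BIOMASS_STOICH = {
    "ala_c": -0.4, "glu_c": -0.3, "sucrose_c": -0.5, "starch_h": -1.2,
    "cellwall_c": -2.0, "nucleotide_c": -0.1, "malate_c": -0.2,
}


# ---------------------------------------------------------------------------
# Lipid module + profile
# ---------------------------------------------------------------------------

def base_lipid_profile(cfg: FixtureConfig | None = None) -> LipidProfile:
    """The control (Col-0-style) lipid profile of the toy world."""
    cfg = cfg or FixtureConfig()
    species = []
    for cls in cfg.lipid_classes:
        name, backbone, chains = LIPID_CLASS_DEFS[cls]
        species.append(LipidSpecies(
            id=f"lip_{cls}_r", lipid_class=cls, backbone_name=name,
            backbone_formula=backbone,
            chains=[(c, CHAIN_FORMULAS[c]) for c in chains],
            compartment="r", abundance=BASE_LIPID_ABUNDANCE[cls],
        ))
    return LipidProfile(species)


def make_lipid_module(cfg: FixtureConfig | None = None) \
        -> tuple[MetabolicModel, LipidProfile]:
    """Toy lipid module: two compartments (shared cytosol + a new ER-like
    compartment), lipid synthesis and degradation reactions, and exactly
    ``cfg.n_shared_reactions`` reactions duplicating template content via
    KEGG-shared metabolites."""
    cfg = cfg or FixtureConfig()
    profile = base_lipid_profile(cfg)
    from .model_core import add_formulas

    m = MetabolicModel(id="toy_lipid_module",
                       compartments={"c": "cytosol", "r": "endoplasmic reticulum"})

    def met(mid, comp, formula="", kegg=None):
        # names left empty: shared metabolites adopt the template's name
        ann = {"kegg": kegg} if kegg else {}
        m.add_metabolite(MetaboliteRecord(mid, compartment=comp,
                                          formula=formula, annotations=ann))

    met("hexose_m", "c", "C6H12O6", "C00031")
    met("sucrose_m", "c", "C12H22O11", "C00089")
    met("h2o_m", "c", "H2O", "C00001")
    met("acetyl_m", "c", "C2H4O2", "C00033")
    met("glycerol3p_r", "r", "C3H9O6P")
    met("fa160_r", "r", "C16H32O2", "C00249")
    met("fa182_r", "r", "C18H32O2", "C01595")
    for sp in profile.species:
        met(sp.id, "r", add_formulas(sp.backbone_formula,
                                     *(f for _, f in sp.chains)))

    def rxn(rid, stoich, gpr, subsystem, lb=0.0, ub=LARGE_BOUND):
        m.add_reaction(ReactionRecord(
            id=rid, name=rid, stoichiometry=stoich, lower_bound=lb,
            upper_bound=ub, gpr=parse_gpr(gpr), subsystem=subsystem))

    # lipid biochemistry (new content)
    rxn("G3P_SYN_L", {"hexose_m": -1.0, "glycerol3p_r": 2.0}, "LIPG1",
        "Lipid precursors")
    rxn("FA160_SYN", {"acetyl_m": -8.0, "fa160_r": 1.0}, "FAB1 and FAB2",
        "FA synthesis")
    rxn("FA182_SYN", {"acetyl_m": -9.0, "fa182_r": 1.0}, "FAD2",
        "FA synthesis")
    rxn("PC_SYN", {"glycerol3p_r": -1.0, "fa160_r": -1.0, "fa182_r": -1.0,
                   "lip_PC_r": 1.0}, "LPCAT1 or LPCAT2",
        "Phospholipid synthesis")
    rxn("MGDG_SYN", {"glycerol3p_r": -1.0, "fa160_r": -1.0, "fa182_r": -1.0,
                     "lip_MGDG_r": 1.0}, "MGD1", "Galactolipid synthesis")
    rxn("TG_SYN", {"glycerol3p_r": -1.0, "fa160_r": -2.0, "fa182_r": -1.0,
                   "lip_TG_r": 1.0}, "DGAT1 or PDAT1", "TG synthesis")
    rxn("WAX_SYN", {"fa160_r": -2.0, "lip_WAX_r": 1.0}, "CER1 and CER3",
        "Wax synthesis")
    rxn("PC_DEG", {"lip_PC_r": -1.0, "fa160_r": 1.0, "fa182_r": 1.0,
                   "glycerol3p_r": 1.0}, "PLA1", "Lipid degradation")
    rxn("TG_DEG", {"lip_TG_r": -1.0, "fa160_r": 2.0, "fa182_r": 1.0,
                   "glycerol3p_r": 1.0}, "SDP1", "TG hydrolysis")

    # content duplicating the template (matched via shared KEGG ids)
    shared = [
        ("SUC_SYN_L", {"hexose_m": -2.0, "sucrose_m": 1.0, "h2o_m": 1.0},
         "SPS3", "Sugar metabolism"),
        ("SUC_DEG_L", {"sucrose_m": -1.0, "h2o_m": -1.0, "hexose_m": 2.0},
         "INV2", "Sugar metabolism"),
        ("ACETYL_SYN_L", {"hexose_m": -1.0, "acetyl_m": 3.0}, "PDH2",
         "Central carbon"),
    ]
    for rid, stoich, gpr, sub in shared[:cfg.n_shared_reactions]:
        rxn(rid, stoich, gpr, sub)
    return m, profile


def make_study_model(cfg: FixtureConfig | None = None,
                     profile: LipidProfile | None = None) -> MetabolicModel:
    """Template + lipid module + SLIME constraints + control biomass with a
    lipid-pool drain + RuBisCO coupling: the reference model every analysis
    stage runs on."""
    cfg = cfg or FixtureConfig()
    template = make_template_model(cfg)
    module, base_profile = make_lipid_module(cfg)
    profile = profile or base_profile
    merged, _ = integrate_module(template, module)
    merged = add_slime_constraints(merged, profile, pseudo_compartment="c")
    composition = control_composition_table()
    spec, biomass_rxn = assemble_biomass(
        composition, profile, accession="Col0", condition="control")
    merged.add_reaction(biomass_rxn)
    merged.set_objective(biomass_rxn.id, "max")
    merged = set_rubisco_coupling(merged, CARBOXYLATION, OXYGENATION)
    return merged


# ---------------------------------------------------------------------------
# Composition panel
# ---------------------------------------------------------------------------

_COMPOSITION_BASE = [
    # component, metabolite, group, unit, control_absolute, molar mass g/mmol
    ("ala", "ala_c", "free_aa", "umol/gDW", 4.0, 0.089093),
    ("glu", "glu_c", "free_aa", "umol/gDW", 6.0, 0.147129),
    ("sucrose", "sucrose_c", "sugar", "umol/gDW", 30.0, 0.342297),
    ("malate", "malate_c", "organic_acid", "umol/gDW", 8.0, 0.134087),
    ("starch", "starch_h", "starch", "g/gDW", 0.080, 0.162141),
    ("cellwall", "cellwall_c", "cell_wall", "g/gDW", 0.350, 0.162141),
    ("nucleic", "nucleotide_c", "nucleic_acid", "g/gDW", 0.050, 0.330),
]

# multiplicative condition effects on relative abundances by component group
_GROUP_CONDITION_EFFECT = {
    "free_aa": {"control": 1.0, "3DD": 1.6, "6DD": 2.2},
    "sugar": {"control": 1.0, "3DD": 0.5, "6DD": 0.3},
    "organic_acid": {"control": 1.0, "3DD": 0.8, "6DD": 0.6},
    "starch": {"control": 1.0, "3DD": 0.3, "6DD": 0.1},
    "cell_wall": {"control": 1.0, "3DD": 1.0, "6DD": 1.0},
    "nucleic_acid": {"control": 1.0, "3DD": 1.0, "6DD": 1.0},
}


def control_composition_table() -> CompositionTable:
    """Composition table holding only the Col-0 control (all ratios 1)."""
    rows = []
    for comp, met, group, unit, absolute, mm in _COMPOSITION_BASE:
        rows.append(CompositionRow(
            component_id=comp, metabolite_id=met, group=group, unit=unit,
            control_absolute=absolute, molar_mass=mm,
            relative={("Col0", "control"): 1.0},
        ))
    return CompositionTable(rows)


def make_accession_panel(cfg: FixtureConfig | None = None) \
        -> tuple[CompositionTable, dict[tuple[str, str], LipidProfile]]:
    """Composition table and lipid profiles for n accessions x 3 conditions.

    Relative abundances are log-normal around the condition means (darkness
    shifts sugars and starch down, free amino acids up; membrane lipids
    decline while TG accumulates).  Every generated accession assembles and
    normalizes to a valid biomass.
    """
    cfg = cfg or FixtureConfig()
    rng = _rng(cfg.seed, "panel")
    accessions = [f"acc{i:04d}" for i in range(cfg.n_accessions)]

    rows = []
    for comp, met, group, unit, absolute, mm in _COMPOSITION_BASE:
        relative: dict[tuple[str, str], float] = {}
        for acc in accessions:
            base = float(np.exp(rng.normal(0.0, cfg.accession_noise)))
            for cond in cfg.conditions:
                eff = _GROUP_CONDITION_EFFECT[group][cond]
                noise = float(np.exp(rng.normal(0.0, cfg.condition_noise))) \
                    if cond != "control" else 1.0
                relative[(acc, cond)] = base * eff * noise
        rows.append(CompositionRow(
            component_id=comp, metabolite_id=met, group=group, unit=unit,
            control_absolute=absolute, molar_mass=mm, relative=relative,
        ))
    composition = CompositionTable(rows)

    base = base_lipid_profile(cfg)
    profiles: dict[tuple[str, str], LipidProfile] = {}
    for acc in accessions:
        acc_factor = {sp.id: float(np.exp(rng.normal(0.0, cfg.accession_noise)))
                      for sp in base.species}
        for cond in cfg.conditions:
            species = []
            for sp in base.species:
                eff = LIPID_CONDITION_EFFECT[cond][sp.lipid_class]
                noise = float(np.exp(rng.normal(0.0, cfg.condition_noise))) \
                    if cond != "control" else 1.0
                species.append(LipidSpecies(
                    id=sp.id, lipid_class=sp.lipid_class,
                    backbone_name=sp.backbone_name,
                    backbone_formula=sp.backbone_formula,
                    chains=list(sp.chains), compartment=sp.compartment,
                    abundance=sp.abundance * acc_factor[sp.id] * eff * noise,
                ))
            profiles[(acc, cond)] = LipidProfile(species)
    return composition, profiles


# ---------------------------------------------------------------------------
# Transcript tables
# ---------------------------------------------------------------------------

def make_transcript_tables(model: MetabolicModel, flux_control, flux_dark,
                           cfg: FixtureConfig | None = None) \
        -> list[tuple[dict[str, float], dict[str, float]]]:
    """Two transcript tables (control, dark) with a planted fraction
    (``cfg.concordance_rate``) of GPR-bearing reactions whose transcript
    log2 FC sign matches the flux log2 FC sign.

    Genes serving several reactions keep their first assignment, so the
    realized rate can drift by about one reaction from the planted one.
    """
    cfg = cfg or FixtureConfig()
    rng = _rng(cfg.seed, "transcripts")
    eps = 1e-9
    scored = []
    for r in model.reactions:
        if r.gpr.is_empty():
            continue
        v0 = abs(flux_control.fluxes.get(r.id, 0.0))
        v1 = abs(flux_dark.fluxes.get(r.id, 0.0))
        if abs(v1 - v0) <= eps * max(1.0, v0, v1):
            continue  # no flux change; not plantable
        scored.append((r, 1 if v1 > v0 else -1))

    tables = []
    for _ in range(2):
        order = list(range(len(scored)))
        rng.shuffle(order)
        quota = round(cfg.concordance_rate * len(scored))
        ctrl: dict[str, float] = {}
        dark: dict[str, float] = {}
        for rank, k in enumerate(order):
            r, flux_sign = scored[k]
            concordant = rank < quota
            sign = flux_sign if concordant else -flux_sign
            for g in sorted(r.gpr.genes()):
                if g in ctrl:
                    continue  # gene shared with an earlier rule: keep it
                base = float(rng.uniform(5.0, 50.0))
                delta = float(rng.uniform(0.5, 2.0))
                ctrl[g] = base
                dark[g] = base * 2.0 ** (sign * delta)
        tables.append((ctrl, dark))
    return tables


# ---------------------------------------------------------------------------
# Genotype panel and flux traits
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    geno: GenotypeMatrix
    annotation: pd.DataFrame
    causal_snp: str
    causal_gene: str
    accessions: list[str]


def make_genotype_panel(cfg: FixtureConfig | None = None) -> GenotypePanel:
    """Structured genotype panel: two subpopulations, SNPs on two
    chromosomes, genes tiled along them, and the causal gene's interval
    placed around a common SNP on chromosome 1."""
    cfg = cfg or FixtureConfig()
    rng = _rng(cfg.seed, "genotypes")
    n, m = cfg.n_accessions, cfg.n_snps
    accessions = [f"acc{i:04d}" for i in range(n)]
    half = n // 2

    # allele frequencies diverge between the two subpopulations
    p_anc = rng.uniform(0.05, 0.95, size=m)
    shift = rng.normal(0.0, 0.12, size=m)
    p1 = np.clip(p_anc + shift, 0.02, 0.98)
    p2 = np.clip(p_anc - shift, 0.02, 0.98)
    dosage = np.empty((n, m))
    dosage[:half] = rng.binomial(2, p1, size=(half, m))
    dosage[half:] = rng.binomial(2, p2, size=(n - half, m))

    per_chrom = m // 2
    positions = []
    chroms = []
    for chrom, count in (("1", per_chrom), ("2", m - per_chrom)):
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=count,
                                 replace=False))
        positions.extend(int(x) for x in pos)
        chroms.extend([chrom] * count)
    snp_ids = [f"snp{chrom}_{pos}" for chrom, pos in zip(chroms, positions)]
    ref = rng.choice(list("ACGT"), size=m)
    alt = rng.choice(list("ACGT"), size=m)
    snps = pd.DataFrame({"chrom": chroms, "pos": positions, "id": snp_ids,
                         "ref": ref, "alt": alt})
    geno = GenotypeMatrix(accessions, snps, dosage)

    # causal SNP: a chromosome-1 SNP with healthy MAF
    maf = geno.maf()
    chr1 = np.where((np.asarray(chroms) == "1") & (maf > 0.2))[0]
    causal_idx = int(chr1[len(chr1) // 2])
    causal_snp = snp_ids[causal_idx]
    causal_pos = positions[causal_idx]

    # genes tiled every 15 kb (3 kb long) on both chromosomes; the tile
    # containing the causal SNP is named after the causal gene
    records = []
    gi = 0
    for chrom in ("1", "2"):
        for start in range(1, 20_000_000, 15_000):
            end = start + 3_000
            if chrom == "1" and start <= causal_pos <= end:
                gid = cfg.causal_gene
            else:
                gid = f"GENE{gi:05d}"
            gi += 1
            records.append((chrom, start, end, gid))
    # make sure the causal SNP actually falls inside its gene's tile
    if not any(r[3] == cfg.causal_gene for r in records):
        records.append(("1", causal_pos - 1_000, causal_pos + 1_000,
                        cfg.causal_gene))
    annotation = pd.DataFrame(records,
                              columns=["chrom", "start", "end", "gene_id"])
    annotation = annotation.sort_values(["chrom", "start"]).reset_index(drop=True)
    return GenotypePanel(geno, annotation, causal_snp, cfg.causal_gene,
                         accessions)


def make_flux_traits(model: MetabolicModel, panel: GenotypePanel,
                     cfg: FixtureConfig | None = None,
                     trait_reaction: str = "PC_SYN") -> TraitVector:
    """Accession flux traits from genotype-perturbed models.

    Each accession's CO2 uptake bound is scaled by a standardized score
    z = sqrt(R2) * standardized causal dosage + sqrt(1-R2) * noise, and the
    trait is the pFBA flux of ``trait_reaction``; because the CO2 bound is
    the binding constraint, the flux is linear in the score and the causal
    SNP explains the configured variance fraction.
    """
    cfg = cfg or FixtureConfig()
    rng = _rng(cfg.seed, "traits")
    idx = panel.geno.snps.index[panel.geno.snps["id"] == panel.causal_snp][0]
    dos = panel.geno.dosage[:, idx].astype(float)
    sd = dos.std()
    z_gene = (dos - dos.mean()) / (sd if sd > 0 else 1.0)
    noise = rng.normal(0.0, 1.0, size=len(dos))
    r2 = cfg.causal_variance
    z = np.sqrt(r2) * z_gene + np.sqrt(1.0 - r2) * noise

    co2_base = 10.0
    values: dict[str, float] = {}
    base_model = model.copy()
    for acc, zi in zip(panel.accessions, z):
        r = base_model.reaction("EX_co2")
        r.lower_bound = -co2_base * (1.0 + 0.05 * float(zi))
        sol = pfba(base_model)
        values[acc] = sol.fluxes[trait_reaction]
    return TraitVector(trait_id=f"{trait_reaction}:control", values=values)


# ---------------------------------------------------------------------------
# Lethality fixtures
# ---------------------------------------------------------------------------

def make_random_lethality_model(seed: int, n_genes: int = 30,
                                n_reactions: int = 50) -> MetabolicModel:
    """Random feasible toy network for lethality screening.

    A substrate uptake feeds a layered chain to the biomass precursor;
    random parallel edges create isoenzyme-style redundancy, random GPRs
    (single genes, pairs under AND/OR) create complexes and shared genes.
    Wild-type biomass is positive by construction.
    """
    rng = np.random.default_rng([seed, _STREAMS["lethality_models"]])
    n_mets = max(4, n_reactions // 2)
    m = MetabolicModel(id=f"lethal_toy_{seed}", compartments={"c": "cytosol"})
    mets = [f"m{i}" for i in range(n_mets)]
    for mid in mets:
        m.add_metabolite(MetaboliteRecord(mid, compartment="c"))
    genes = [f"g{i:02d}" for i in range(n_genes)]

    def random_gpr() -> str:
        u = rng.random()
        if u < 0.25:
            return ""
        if u < 0.65:
            return str(rng.choice(genes))
        a, b = rng.choice(genes, size=2, replace=False)
        op = "or" if rng.random() < 0.5 else "and"
        return f"{a} {op} {b}"

    m.add_reaction(ReactionRecord(
        id="EX_sub", stoichiometry={mets[0]: -1.0}, lower_bound=-10.0,
        upper_bound=0.0, flags=frozenset({"exchange"}), subsystem="Exchange"))
    # backbone chain guarantees feasibility; some links get a parallel
    # isoenzyme-style alternative (double-lethal material), uncovered links
    # with closable rules yield single lethals
    n_alt_budget = max(0, n_reactions - n_mets - 1)
    n_alts = 0
    for i in range(n_mets - 1):
        m.add_reaction(ReactionRecord(
            id=f"chain_{i}", stoichiometry={mets[i]: -1.0, mets[i + 1]: 1.0},
            lower_bound=0.0, upper_bound=10.0, gpr=parse_gpr(random_gpr()),
            subsystem="Chain"))
        if n_alts < n_alt_budget and rng.random() < 0.45:
            span = int(rng.integers(i + 1, min(i + 3, n_mets)))
            m.add_reaction(ReactionRecord(
                id=f"alt_{i}", stoichiometry={mets[i]: -1.0, mets[span]: 1.0},
                lower_bound=0.0, upper_bound=10.0, gpr=parse_gpr(random_gpr()),
                subsystem="Alternative"))
            n_alts += 1
    m.add_reaction(ReactionRecord(
        id="biomass", stoichiometry={mets[-1]: -1.0}, lower_bound=0.0,
        upper_bound=LARGE_BOUND, flags=frozenset({"biomass"}),
        subsystem="Biomass"))
    m.set_objective("biomass", "max")
    return m


def make_evidence_table(truth: LethalityResult, flip_rate: float,
                        seed: int) -> EvidenceTable:
    """Evidence equal to the truth with labels flipped at ``flip_rate``."""
    if not (0.0 <= flip_rate < 1.0):
        raise ValueError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, _STREAMS["evidence"]])
    rows = []
    for gene in sorted(truth.single_lethal | truth.non_lethal):
        observed = gene in truth.single_lethal
        if rng.random() < flip_rate:
            observed = not observed
        rows.append(EvidenceRow(gene, "lethal" if observed else "viable",
                                "synthetic"))
    return EvidenceTable(rows)
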