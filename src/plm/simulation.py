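"""Flux balance analysis, pFBA, RuBisCO coupling, diel models and scenarios.

FBA solves max/min c'v subject to S v = 0 and lb <= v <= ub with the HiGHS
LP solver (scipy.optimize.linprog).  pFBA fixes the objective at its FBA
optimum and minimizes total absolute flux using the standard split-variable
linearization v = p - n, p, n >= 0.

A diel model duplicates every reaction and metabolite into a light and a
dark phase coupled only by irreversible linker reactions that carry storage
compounds (starch, sucrose, free amino acids, ...) from the light into the
dark phase; the dark-phase photon influx is fixed to zero.  Scenarios:
``control`` (light photons open), and ``3DD``/``6DD`` (extended darkness:
photons closed in both phases, dark metabolism runs on a bounded storage
budget, biomass maximized in the dark phase).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model_core import (
    FLUX_SUPPORT_TOL,
    LARGE_BOUND,
    FluxDistribution,
    MetabolicModel,
    MetaboliteRecord,
    ModelError,
    ReactionRecord,
)

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


class InfeasibleError(RuntimeError):
    """LP was infeasible or unbounded; statuses are never silently zeroed."""

    def __init__(self, status: str):
        super().__init__(f"optimization failed with status {status!r}")
        self.status = status


def _lp_arrays(model: MetabolicModel):
    met_idx = {m.id: i for i, m in enumerate(model.metabolites)}
    n_m, n_r = len(model.metabolites), len(model.reactions)
    S = lil_matrix((n_m, n_r))
    lb = np.empty(n_r)
    ub = np.empty(n_r)
    for j, r in enumerate(model.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for mid, coef in r.stoichiometry.items():
            S[met_idx[mid], j] = coef
    return S.tocsr(), lb, ub


def _objective_vector(model: MetabolicModel,
                      objective: str | dict[str, float] | None) -> np.ndarray:
    if objective is None:
        objective = model.objective
    if not objective:
        raise ModelError("no objective set")
    if isinstance(objective, str):
        objective = {objective: 1.0}
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    c = np.zeros(len(model.reactions))
    for rid, coef in objective.items():
        if rid not in idx:
            raise ModelError(f"objective reaction {rid!r} not in model")
        c[idx[rid]] = coef
    return c


def fba(model: MetabolicModel,
        objective: str | dict[str, float] | None = None,
        direction: str | None = None) -> FluxDistribution:
    """Maximize (or minimize) the objective flux at steady state."""
    S, lb, ub = _lp_arrays(model)
    c = _objective_vector(model, objective)
    direction = direction or model.objective_direction
    sign = -1.0 if direction == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        raise InfeasibleError(status)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxDistribution(fluxes, float(c @ res.x), "optimal")


def pfba(model: MetabolicModel,
         objective: str | dict[str, float] | None = None,
         direction: str | None = None) -> FluxDistribution:
    """Parsimonious FBA: fix the objective at its optimum, minimize sum |v|.

    The returned distribution achieves the FBA objective within 1e-9
    relative and the minimal total absolute flux among such optima.
    """
    opt = fba(model, objective, direction)
    S, lb, ub = _lp_arrays(model)
    c = _objective_vector(model, objective)
    direction = direction or model.objective_direction
    n_m, n_r = S.shape
    z = float(opt.objective_value)

    # variables x = [p; n], v = p - n
    A_steady = lil_matrix((n_m, 2 * n_r))
    A_steady[:, :n_r] = S
    A_steady[:, n_r:] = -S
    A_steady = A_steady.tocsr()
    crow = np.concatenate([c, -c])
    # original bounds lb <= p - n <= ub
    eye = np.eye(n_r)
    V = np.hstack([eye, -eye])
    bound_rows = np.vstack([V, -V])
    bound_rhs = np.concatenate([ub, -lb])
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    cost = np.ones(2 * n_r)

    def solve(fix_exact: bool):
        if fix_exact:
            # HiGHS returns vertex solutions, so pinning the objective with
            # an equality row is normally feasible
            from scipy.sparse import vstack as sp_vstack, csr_matrix
            A_eq = sp_vstack([A_steady, csr_matrix(crow)])
            b_eq = np.concatenate([np.zeros(n_m), [z]])
            return linprog(cost, A_eq=A_eq, b_eq=b_eq, A_ub=bound_rows,
                           b_ub=bound_rhs, bounds=bounds, method="highs")
        slack = 1e-9 * max(1.0, abs(z))
        if direction == "max":
            A_ub = np.vstack([-crow[None, :], bound_rows])
            b_ub = np.concatenate([[-(z - slack)], bound_rhs])
        else:
            A_ub = np.vstack([crow[None, :], bound_rows])
            b_ub = np.concatenate([[z + slack], bound_rhs])
        return linprog(cost, A_eq=A_steady, b_eq=np.zeros(n_m), A_ub=A_ub,
                       b_ub=b_ub, bounds=bounds, method="highs")

    res = solve(fix_exact=True)
    if res.status != 0:
        res = solve(fix_exact=False)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        raise InfeasibleError(status)
    v = res.x[:n_r] - res.x[n_r:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxDistribution(fluxes, float(c @ v), "optimal")


# ---------------------------------------------------------------------------
# RuBisCO carboxylation/oxygenation coupling
# ---------------------------------------------------------------------------

RUBISCO_PSEUDO_MET = "rubisco_coupling_pseudo"
DEFAULT_RUBISCO_RATIO = 2.88


def set_rubisco_coupling(model: MetabolicModel, carboxylation_id: str,
                         oxygenation_id: str,
                         ratio: float = DEFAULT_RUBISCO_RATIO) -> MetabolicModel:
    """Constrain v_carboxylation = ratio * v_oxygenation.

    Implemented with a dimensionless coupling pseudo-metabolite produced by
    carboxylation (+1) and consumed by oxygenation (-ratio); steady state
    then forces the flux ratio exactly.
    """
    if ratio <= 0:
        raise ModelError("rubisco ratio must be positive")
    out = model.copy()
    carb = out.reaction(carboxylation_id)
    oxy = out.reaction(oxygenation_id)
    if out.has_metabolite(RUBISCO_PSEUDO_MET):
        out = remove_rubisco_coupling(out)
        carb = out.reaction(carboxylation_id)
        oxy = out.reaction(oxygenation_id)
    comp = next(iter(out.compartments))
    out.add_metabolite(MetaboliteRecord(
        RUBISCO_PSEUDO_MET, name="RuBisCO coupling pseudo-metabolite",
        compartment=comp,
    ))
    carb.stoichiometry[RUBISCO_PSEUDO_MET] = 1.0
    oxy.stoichiometry[RUBISCO_PSEUDO_MET] = -float(ratio)
    return out


def remove_rubisco_coupling(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for r in out.reactions:
        r.stoichiometry.pop(RUBISCO_PSEUDO_MET, None)
    out.metabolites = [m for m in out.metabolites if m.id != RUBISCO_PSEUDO_MET]
    return out


# ---------------------------------------------------------------------------
# Diel model
# ---------------------------------------------------------------------------

PHASES = ("light", "dark")


def phase_id(base_id: str, phase: str) -> str:
    return f"{base_id}__{phase}"


@dataclass
class DielModel:
    """Two phase-suffixed copies of a model joined by storage linkers."""
    model: MetabolicModel
    phase_of: dict[str, str]          # reaction id -> light | dark
    linker_ids: list[str]
    photon_exchange: dict[str, str]   # phase -> photon exchange reaction id
    storage_ids: list[str]            # base (unsuffixed) storage metabolites

    def biomass_reaction(self, phase: str) -> str:
        for rid, ph in self.phase_of.items():
            if ph == phase and "biomass" in self.model.reaction(rid).flags:
                return rid
        raise ModelError(f"no biomass reaction in phase {phase!r}")


def build_diel_model(model: MetabolicModel, storage_ids: list[str],
                     photon_exchange_id: str) -> DielModel:
    """Duplicate the model into light/dark phases with storage linkers.

    Every reaction and metabolite is copied twice with ``__light`` and
    ``__dark`` suffixes; one irreversible linker per storage metabolite
    carries it from the light into the dark phase; the dark-phase photon
    exchange is fixed to [0, 0] (no photon influx in darkness).
    """
    for sid in storage_ids:
        if not model.has_metabolite(sid):
            raise ModelError(f"storage metabolite {sid!r} not in model")
    if not model.has_reaction(photon_exchange_id):
        raise ModelError(f"photon exchange {photon_exchange_id!r} not in model")

    diel = MetabolicModel(id=f"{model.id}_diel",
                          compartments=dict(model.compartments))
    phase_of: dict[str, str] = {}
    for phase in PHASES:
        for m in model.metabolites:
            mm = m.copy()
            mm.id = phase_id(m.id, phase)
            diel.add_metabolite(mm)
        for r in model.reactions:
            rr = r.copy()
            rr.id = phase_id(r.id, phase)
            rr.stoichiometry = {phase_id(mid, phase): v
                                for mid, v in r.stoichiometry.items()}
            if phase == "dark" and r.id == photon_exchange_id:
                rr.lower_bound = 0.0
                rr.upper_bound = 0.0
            diel.add_reaction(rr)
            phase_of[rr.id] = phase

    linkers = []
    for sid in storage_ids:
        rid = f"linker_{sid}"
        diel.add_reaction(ReactionRecord(
            id=rid, name=f"storage linker for {sid} (light to dark)",
            stoichiometry={phase_id(sid, "light"): -1.0,
                           phase_id(sid, "dark"): 1.0},
            lower_bound=0.0, upper_bound=LARGE_BOUND,
            subsystem="Storage linkers", flags=frozenset({"linker"}),
        ))
        linkers.append(rid)

    if model.objective:
        diel.set_objective(
            {phase_id(rid, ph): coef
             for rid, coef in model.objective.items() for ph in PHASES},
            model.objective_direction,
        )
    return DielModel(
        model=diel, phase_of=phase_of, linker_ids=linkers,
        photon_exchange={ph: phase_id(photon_exchange_id, ph) for ph in PHASES},
        storage_ids=list(storage_ids),
    )


@dataclass
class ScenarioConfig:
    """Bounds and objective weights defining one simulated condition."""
    scenario: str = "control"  # control | 3DD | 6DD
    photon_uptake: float = 100.0          # light-phase photon influx cap
    rubisco_ratio: float = DEFAULT_RUBISCO_RATIO
    objective_weights: dict[str, float] = field(
        default_factory=lambda: {"light": 1.0, "dark": 1.0})
    # storage available to dark metabolism under extended darkness
    # (mmol/gDW/phase); either one budget for all storage species or a
    # per-species map
    storage_budget: float | dict[str, float] = 10.0
    maltose_uptake_bound: float | None = None
    maltose_exchange_id: str | None = None

    def __post_init__(self):
        if self.scenario not in ("control", "3DD", "6DD"):
            raise ModelError(f"unknown scenario {self.scenario!r}")
        if self.photon_uptake < 0:
            raise ModelError("photon bound must be nonnegative")
        if self.rubisco_ratio <= 0:
            raise ModelError("rubisco ratio must be positive")

    def budget_for(self, storage_id: str) -> float:
        if isinstance(self.storage_budget, dict):
            return float(self.storage_budget.get(storage_id, 0.0))
        return float(self.storage_budget)


def apply_scenario(diel: DielModel, cfg: ScenarioConfig) -> MetabolicModel:
    """Instantiate the diel model for one scenario (deterministic in cfg).

    control: light-phase photon influx capped at cfg.photon_uptake,
    objective is the weighted sum of the phase biomass reactions.
    3DD/6DD: photons closed in both phases; each storage species gets a
    bounded light-phase source emulating pre-darkness accumulation; the
    objective is dark-phase biomass.
    """
    model = diel.model.copy()
    light_photon = model.reaction(diel.photon_exchange["light"])
    if cfg.scenario == "control":
        # exchange written one-sided (met -> nothing): uptake is negative flux
        light_photon.lower_bound = -cfg.photon_uptake
        weights = {}
        for phase, w in cfg.objective_weights.items():
            if w:
                weights[diel.biomass_reaction(phase)] = w
        model.set_objective(weights, "max")
    else:
        light_photon.lower_bound = 0.0
        light_photon.upper_bound = 0.0
        for sid in diel.storage_ids:
            rid = f"storage_src_{sid}__light"
            budget = cfg.budget_for(sid)
            src = ReactionRecord(
                id=rid, name=f"pre-darkness storage of {sid}",
                stoichiometry={phase_id(sid, "light"): -1.0},
                lower_bound=-budget, upper_bound=0.0,
                subsystem="Storage source", flags=frozenset({"exchange"}),
            )
            if model.has_reaction(rid):
                r = model.reaction(rid)
                r.lower_bound, r.upper_bound = src.lower_bound, src.upper_bound
            else:
                model.add_reaction(src)
        model.set_objective({diel.biomass_reaction("dark"): 1.0}, "max")

    if cfg.maltose_uptake_bound is not None and cfg.maltose_exchange_id:
        for phase in PHASES:
            rid = phase_id(cfg.maltose_exchange_id, phase)
            if model.has_reaction(rid):
                r = model.reaction(rid)
                r.lower_bound = max(r.lower_bound, -cfg.maltose_uptake_bound)
    return model


# ---------------------------------------------------------------------------
# Subsystem summaries
# ---------------------------------------------------------------------------

DEFAULT_OUTLIER_CAP = 500.0  # mmol/gDW/phase; larger |v| treated as artifacts


@dataclass
class SubsystemRow:
    subsystem: str
    proportion_active: float | None
    mean_flux_centered: float | None
    n_fluxes: int
    cv: float | None


@dataclass
class SubsystemSummary:
    rows: dict[str, SubsystemRow]
    missing: list[str]  # subsystems with no surviving fluxes

    def __getitem__(self, subsystem: str) -> SubsystemRow:
        return self.rows[subsystem]


def _by_subsystem(model: MetabolicModel) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for r in model.reactions:
        groups.setdefault(r.subsystem or "(none)", []).append(r.id)
    return groups


def subsystem_activity(flux: FluxDistribution, model: MetabolicModel,
                       tol: float = FLUX_SUPPORT_TOL) -> SubsystemSummary:
    """Proportion of reactions per subsystem carrying |v| > tol."""
    rows = {}
    for sub, rxns in _by_subsystem(model).items():
        vals = [abs(flux.fluxes.get(r, 0.0)) for r in rxns]
        active = sum(1 for v in vals if v > tol)
        mean = float(np.mean(vals)) if vals else 0.0
        cv = float(np.std(vals) / mean) if mean > 0 else None
        rows[sub] = SubsystemRow(sub, active / len(rxns), None, len(rxns), cv)
    return SubsystemSummary(rows, [])


def subsystem_mean_flux(flux: FluxDistribution, model: MetabolicModel,
                        outlier_cap: float = DEFAULT_OUTLIER_CAP) -> SubsystemSummary:
    """Mean |v| per subsystem after dropping physiologically meaningless
    fluxes (|v| > outlier_cap), mean-centered across subsystems.

    Subsystems with no surviving fluxes are reported as missing, not zero.
    """
    raw_means: dict[str, float] = {}
    extras: dict[str, tuple[int, float | None]] = {}
    missing: list[str] = []
    for sub, rxns in _by_subsystem(model).items():
        vals = [abs(flux.fluxes.get(r, 0.0)) for r in rxns
                if abs(flux.fluxes.get(r, 0.0)) <= outlier_cap]
        if not vals:
            missing.append(sub)
            continue
        mean = float(np.mean(vals))
        cv = float(np.std(vals) / mean) if mean > 0 else None
        raw_means[sub] = mean
        extras[sub] = (len(vals), cv)
    grand = float(np.mean(list(raw_means.values()))) if raw_means else 0.0
    rows = {
        sub: SubsystemRow(sub, None, mean - grand, extras[sub][0], extras[sub][1])
        for sub, mean in raw_means.items()
    }
    return SubsystemSummary(rows, sorted(missing))
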