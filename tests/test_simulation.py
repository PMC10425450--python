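"""FBA/pFBA solving, RuBisCO coupling, diel construction and summaries."""
import numpy as np
import pytest

from plm.fixtures import (
    PHOTON_EXCHANGE,
    STORAGE_IDS,
    make_random_lethality_model,
)
from plm.model_core import FluxDistribution, ModelError
from plm.simulation import (
    DEFAULT_RUBISCO_RATIO,
    InfeasibleError,
    ScenarioConfig,
    apply_scenario,
    build_diel_model,
    fba,
    pfba,
    phase_id,
    remove_rubisco_coupling,
    set_rubisco_coupling,
    subsystem_activity,
    subsystem_mean_flux,
)

from conftest import toy_model


def _chain_model(uptake=10.0):
    return toy_model([
        ("EX_a", {"a_c": -1.0}, -uptake, 0.0, "", ("exchange",)),
        ("r1", {"a_c": -1.0, "b_c": 1.0}),
        ("sink", {"b_c": -1.0}),
    ], objective="sink")


def test_fba_linear_chain_optimum_by_inspection():
    sol = fba(_chain_model())
    assert sol.objective_value == pytest.approx(10.0, rel=1e-9)
    assert sol.status == "optimal"


def test_fba_blocked_model_zero_optimum():
    m = _chain_model(uptake=0.0)
    assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_unbounded_propagated():
    inf = float("inf")
    m = toy_model([("cycle_f", {"a_c": -1.0, "b_c": 1.0}, -inf, inf),
                   ("cycle_b", {"b_c": -1.0, "a_c": 1.0}, -inf, inf)],
                  objective="cycle_f")
    with pytest.raises(InfeasibleError):
        fba(m)


def test_fba_steady_state_and_bounds(study_model):
    sol = fba(study_model)
    balance = {m.id: 0.0 for m in study_model.metabolites}
    for r in study_model.reactions:
        v = sol.fluxes[r.id]
        assert r.lower_bound - 1e-7 <= v <= r.upper_bound + 1e-7
        for mid, coef in r.stoichiometry.items():
            balance[mid] += coef * v
    assert max(abs(x) for x in balance.values()) <= 1e-6


def test_fba_matches_cobra_oracle_on_random_models():
    """Independent LP route: the same model solved through COBRApy/optlang
    must give the same optimum."""
    import cobra
    from plm.model_core import to_cobra

    for seed in range(20):
        m = make_random_lethality_model(seed, n_genes=10, n_reactions=25)
        ours = fba(m).objective_value
        cm = to_cobra(m)
        sol = cm.optimize()
        assert sol.status == "optimal"
        assert ours == pytest.approx(sol.objective_value, rel=1e-6, abs=1e-8)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def _parallel_path_model():
    return toy_model([
        ("EX_a", {"a_c": -1.0}, -10.0, 0.0, "", ("exchange",)),
        ("direct", {"a_c": -1.0, "b_c": 1.0}),
        ("via_x1", {"a_c": -1.0, "x_c": 1.0}),
        ("via_x2", {"x_c": -1.0, "b_c": 1.0}),
        ("sink", {"b_c": -1.0}),
    ], objective="sink")


def test_pfba_prefers_shorter_route():
    m = _parallel_path_model()
    sol = pfba(m)
    assert sol.objective_value == pytest.approx(10.0, rel=1e-9)
    assert sol.fluxes["direct"] == pytest.approx(10.0, rel=1e-6)
    assert abs(sol.fluxes["via_x1"]) < 1e-9
    # total |v|: 10 (exchange) + 10 (direct) + 10 (sink) = 30, not 40
    assert sol.total_absolute_flux == pytest.approx(30.0, rel=1e-6)


def test_pfba_objective_equals_fba_objective(study_model):
    f = fba(study_model)
    p = pfba(study_model)
    assert p.objective_value == pytest.approx(f.objective_value, rel=1e-9)


def test_pfba_total_flux_not_above_fba_solution(study_model):
    assert pfba(study_model).total_absolute_flux \
        <= fba(study_model).total_absolute_flux + 1e-6


def test_pfba_matches_cobra_pfba_oracle(study_model):
    """COBRApy's pFBA is an independent implementation of the same
    minimization; total absolute flux must agree."""
    import cobra.flux_analysis
    from plm.model_core import to_cobra

    ours = pfba(study_model)
    cm = to_cobra(study_model)
    theirs = cobra.flux_analysis.pfba(cm)
    total_theirs = float(np.abs(theirs.fluxes).sum())
    assert ours.total_absolute_flux == pytest.approx(total_theirs, rel=1e-5)


# ---------------------------------------------------------------------------
# RuBisCO coupling
# ---------------------------------------------------------------------------

def _photorespiration_model():
    return toy_model([
        ("EX_s", {"s_c": -1.0}, -10.0, 0.0, "", ("exchange",)),
        ("carb", {"s_c": -1.0, "p_c": 2.0}),
        ("oxy", {"s_c": -1.0, "p_c": 1.0}),
        ("sink", {"p_c": -1.0}),
    ], objective="sink")


def test_coupled_fluxes_satisfy_ratio():
    m = set_rubisco_coupling(_photorespiration_model(), "carb", "oxy")
    sol = fba(m)
    assert sol.fluxes["oxy"] > 1e-6
    assert sol.fluxes["carb"] == pytest.approx(
        DEFAULT_RUBISCO_RATIO * sol.fluxes["oxy"], abs=1e-9)


def test_zero_oxygenation_forces_zero_carboxylation():
    m = set_rubisco_coupling(_photorespiration_model(), "carb", "oxy")
    m.reaction("oxy").upper_bound = 0.0
    sol = fba(m)
    assert abs(sol.fluxes["carb"]) < 1e-9


def test_removing_coupling_restores_original_optimum():
    base = _photorespiration_model()
    before = fba(base).objective_value
    coupled = set_rubisco_coupling(base, "carb", "oxy")
    assert fba(coupled).objective_value < before  # oxygenation wastes carbon
    restored = remove_rubisco_coupling(coupled)
    assert fba(restored).objective_value == pytest.approx(before, rel=1e-9)


def test_missing_reaction_errors():
    with pytest.raises(KeyError):
        set_rubisco_coupling(_photorespiration_model(), "carb", "ghost")


# ---------------------------------------------------------------------------
# Diel model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def diel(study_model):
    return build_diel_model(study_model, list(STORAGE_IDS), PHOTON_EXCHANGE)


def test_diel_counts_double_plus_linkers(study_model, diel):
    assert len(diel.model.reactions) \
        == 2 * len(study_model.reactions) + len(STORAGE_IDS)
    assert len(diel.model.metabolites) == 2 * len(study_model.metabolites)


def test_dark_photon_exchange_fixed_to_zero(diel):
    dark = diel.model.reaction(diel.photon_exchange["dark"])
    assert dark.lower_bound == 0.0
    assert dark.upper_bound == 0.0


def test_linkers_irreversible_and_flagged(diel):
    for rid in diel.linker_ids:
        r = diel.model.reaction(rid)
        assert r.lower_bound == 0.0
        assert "linker" in r.flags


def test_single_phase_solution_embeds_with_zero_linkers(study_model, diel):
    sol = fba(study_model)
    v = {r.id: 0.0 for r in diel.model.reactions}
    for rid, flux in sol.fluxes.items():
        v[phase_id(rid, "light")] = flux
    balance = {m.id: 0.0 for m in diel.model.metabolites}
    for r in diel.model.reactions:
        assert r.lower_bound - 1e-9 <= v[r.id] <= r.upper_bound + 1e-9
        for mid, coef in r.stoichiometry.items():
            balance[mid] += coef * v[r.id]
    assert max(abs(x) for x in balance.values()) <= 1e-6


def test_missing_storage_id_errors(study_model):
    with pytest.raises(ModelError):
        build_diel_model(study_model, ["ghost_c"], PHOTON_EXCHANGE)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def test_control_scenario_opens_light_photons(diel):
    m = apply_scenario(diel, ScenarioConfig(scenario="control",
                                            photon_uptake=100.0))
    light = m.reaction(diel.photon_exchange["light"])
    assert light.lower_bound == -100.0
    assert fba(m).objective_value > 0


def test_extended_darkness_closes_photons_and_runs_on_storage(diel):
    m = apply_scenario(diel, ScenarioConfig(scenario="3DD", storage_budget=5.0))
    light = m.reaction(diel.photon_exchange["light"])
    assert light.upper_bound == 0.0 and light.lower_bound == 0.0
    assert fba(m).objective_value > 0


def test_zero_storage_means_zero_dark_biomass(diel):
    m = apply_scenario(diel, ScenarioConfig(scenario="3DD", storage_budget=0.0))
    assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)


def test_nested_storage_budgets_give_monotone_optima(diel):
    opt3 = fba(apply_scenario(
        diel, ScenarioConfig(scenario="3DD", storage_budget=5.0))).objective_value
    opt6 = fba(apply_scenario(
        diel, ScenarioConfig(scenario="6DD", storage_budget=2.0))).objective_value
    assert opt3 >= opt6 - 1e-9
    assert opt6 > 0


def test_scenario_deterministic(diel):
    cfg = ScenarioConfig(scenario="6DD", storage_budget=2.0)
    assert apply_scenario(diel, cfg) == apply_scenario(diel, cfg)


# ---------------------------------------------------------------------------
# Subsystem summaries
# ---------------------------------------------------------------------------

def _flux(d):
    return FluxDistribution(dict(d), 0.0, "optimal")


def _labeled_model(assignment):
    specs = [(rid, {"a_c": -1.0, "b_c": 1.0}, -1000, 1000) for rid in assignment]
    m = toy_model(specs)
    for rid, sub in assignment.items():
        m.reaction(rid).subsystem = sub
    return m


def test_activity_counts_above_tolerance():
    m = _labeled_model({"r1": "S", "r2": "S", "r3": "S"})
    summary = subsystem_activity(_flux({"r1": 1e-9, "r2": 0.5, "r3": 0.0}), m)
    assert summary["S"].proportion_active == pytest.approx(1 / 3)


def test_all_zero_fluxes_give_zero_proportions():
    m = _labeled_model({"r1": "S", "r2": "T"})
    summary = subsystem_activity(_flux({"r1": 0.0, "r2": 0.0}), m)
    assert all(row.proportion_active == 0.0 for row in summary.rows.values())


def test_activity_matches_counting_oracle():
    rng = np.random.default_rng(0)
    assignment = {f"r{i}": f"S{rng.integers(3)}" for i in range(30)}
    m = _labeled_model(assignment)
    fluxes = {rid: float(rng.choice([0.0, 1e-8, 0.3, -2.0])) for rid in assignment}
    summary = subsystem_activity(_flux(fluxes), m, tol=1e-6)
    for sub in {v for v in assignment.values()}:
        rxns = [r for r, s in assignment.items() if s == sub]
        expected = sum(1 for r in rxns if abs(fluxes[r]) > 1e-6) / len(rxns)
        assert summary[sub].proportion_active == pytest.approx(expected)


def test_mean_flux_centering():
    m = _labeled_model({"r1": "A", "r2": "B", "r3": "C"})
    summary = subsystem_mean_flux(_flux({"r1": 2.0, "r2": 4.0, "r3": 6.0}), m)
    got = {s: summary[s].mean_flux_centered for s in "ABC"}
    assert got == pytest.approx({"A": -2.0, "B": 0.0, "C": 2.0})


def test_outlier_cap_excludes_meaningless_fluxes():
    m = _labeled_model({"r1": "A", "r2": "A", "r3": "B"})
    summary = subsystem_mean_flux(
        _flux({"r1": 2.0, "r2": 900.0, "r3": 2.0}), m, outlier_cap=500.0)
    # r2 dropped: subsystem A mean is 2.0, equal to B, centered means 0
    assert summary["A"].mean_flux_centered == pytest.approx(0.0)
    assert summary["A"].n_fluxes == 1


def test_subsystem_with_no_surviving_fluxes_reported_missing():
    m = _labeled_model({"r1": "A", "r2": "B"})
    summary = subsystem_mean_flux(_flux({"r1": 2.0, "r2": 900.0}), m,
                                  outlier_cap=500.0)
    assert summary.missing == ["B"]
    assert "B" not in summary.rows


def test_centering_preserves_pairwise_differences():
    rng = np.random.default_rng(4)
    assignment = {f"r{i}": f"S{i % 4}" for i in range(20)}
    m = _labeled_model(assignment)
    fluxes = {rid: float(rng.uniform(-3, 3)) for rid in assignment}
    summary = subsystem_mean_flux(_flux(fluxes), m)
    raw = {}
    for sub in {v for v in assignment.values()}:
        vals = [abs(fluxes[r]) for r, s in assignment.items() if s == sub]
        raw[sub] = float(np.mean(vals))
    subs = sorted(raw)
    for a in subs:
        for b in subs:
            assert (summary[a].mean_flux_centered - summary[b].mean_flux_centered) \
                == pytest.approx(raw[a] - raw[b], abs=1e-12)
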