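"""Single and double synthetic-lethal gene identification (Fast-SL).

A gene (or gene pair) is lethal when its deletion drops the biomass
optimum below ``cutoff_rel`` times the wild-type optimum.  Exhaustive
screening of all single and pair deletions is quadratic in genes; Fast-SL
prunes the search using parsimonious reference flux distributions:

* a gene whose closable reactions carry no flux in the wild-type pFBA
  solution cannot be singly lethal (that solution survives the knockout);
* a pair can only be lethal if at least one member is supported in the
  wild-type pFBA solution, and its partner is supported in the pFBA
  solution of the first member's knockout model.

Both prunings are exact, so Fast-SL provably returns the same sets as the
exhaustive screen (asserted against :func:`exhaustive_lethals` in tests).

Demand, exchange, maintenance and SLIME pseudo-reactions are excluded from
the analysis scope; the gene universe is the genes appearing in the GPR
rules of the remaining reactions.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .model_core import (
    FLUX_SUPPORT_TOL,
    FluxDistribution,
    MetabolicModel,
    ModelError,
)
from .simulation import InfeasibleError, fba, pfba

DEFAULT_CUTOFF_REL = 1e-3
SCOPE_EXCLUDED_FLAGS = frozenset({"demand", "exchange", "maintenance", "slime"})


def knockout(model: MetabolicModel, genes: set[str]) -> MetabolicModel:
    """Close (bounds [0,0]) every reaction whose GPR evaluates false under
    the knockout; reactions without a GPR rule are untouched."""
    unknown = set(genes) - set(model.genes)
    if unknown:
        raise ModelError(f"unknown genes: {sorted(unknown)}")
    out = model.copy()
    for r in out.reactions:
        if not r.gpr.is_empty() and not r.gpr.evaluate(genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def analysis_scope(model: MetabolicModel) -> tuple[set[str], set[str]]:
    """(reaction ids, gene universe) analyzed for lethality.

    Reactions flagged demand/exchange/maintenance/slime are excluded; the
    gene universe is the union of GPR genes over the surviving reactions.
    """
    rxns = {r.id for r in model.reactions if not (r.flags & SCOPE_EXCLUDED_FLAGS)}
    genes: set[str] = set()
    for r in model.reactions:
        if r.id in rxns:
            genes |= r.gpr.genes()
    return rxns, genes


@dataclass
class LethalityResult:
    single_lethal: set[str]
    double_lethal: set[frozenset[str]]
    non_lethal: set[str]
    wild_type_biomass: float
    cutoff_rel: float

    @property
    def double_lethal_genes(self) -> set[str]:
        out: set[str] = set()
        for pair in self.double_lethal:
            out |= pair
        return out

    @property
    def pairs_sorted(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.double_lethal)


class _KnockoutSolver:
    """Shared machinery: maps genes to closable reactions and evaluates
    knockout optima without copying the model each time."""

    def __init__(self, model: MetabolicModel,
                 objective: str | dict[str, float] | None = None):
        self.model = model
        self.objective = objective
        self.scope_rxns, self.genes = analysis_scope(model)
        # reactions closable by each gene (GPR false under single KO is not
        # enough for pairs; reevaluate per KO set)
        self.gpr_rxns = [r for r in model.reactions if not r.gpr.is_empty()]

    def closed_reactions(self, ko: set[str]) -> set[str]:
        return {r.id for r in self.gpr_rxns if not r.gpr.evaluate(ko)}

    def optimum(self, ko: set[str]) -> float:
        closed = self.closed_reactions(ko)
        if not closed:
            return self._wild_type
        m = self.model.copy()
        for r in m.reactions:
            if r.id in closed:
                r.lower_bound = 0.0
                r.upper_bound = 0.0
        try:
            return fba(m, self.objective).objective_value
        except InfeasibleError:
            return 0.0

    def pfba_solution(self, ko: set[str]) -> FluxDistribution | None:
        closed = self.closed_reactions(ko)
        m = self.model.copy()
        for r in m.reactions:
            if r.id in closed:
                r.lower_bound = 0.0
                r.upper_bound = 0.0
        try:
            return pfba(m, self.objective)
        except InfeasibleError:
            return None

    def supported_genes(self, flux: FluxDistribution,
                        tol: float = FLUX_SUPPORT_TOL) -> set[str]:
        """Analyzed genes whose reactions carry flux in a solution.

        Support is taken over *all* GPR-bearing reactions (a gene from the
        analysis universe may also close an excluded-flag reaction), which
        keeps the pruning argument exact.
        """
        active = flux.supported_reactions(tol)
        genes: set[str] = set()
        ridx = self.model.reaction_index
        for rid in active:
            genes |= ridx[rid].gpr.genes()
        return genes & self.genes

    @property
    def _wild_type(self) -> float:
        if not hasattr(self, "_wt"):
            self._wt = fba(self.model, self.objective).objective_value
        return self._wt


def single_lethals(model: MetabolicModel,
                   cutoff_rel: float = DEFAULT_CUTOFF_REL,
                   objective: str | dict[str, float] | None = None,
                   _solver: _KnockoutSolver | None = None) -> set[str]:
    """Genes whose single deletion abolishes biomass production.

    Fast-SL pruning: only genes supported in the wild-type pFBA reference
    are tested; the rest provably keep the reference optimum feasible.
    """
    solver = _solver or _KnockoutSolver(model, objective)
    wt = solver._wild_type
    if wt <= 0:
        raise ModelError("wild-type biomass is not positive")
    reference = solver.pfba_solution(set())
    candidates = solver.supported_genes(reference)
    cutoff = cutoff_rel * wt
    return {g for g in sorted(candidates) if solver.optimum({g}) < cutoff}


def double_lethals(model: MetabolicModel, single_lethal_set: set[str],
                   cutoff_rel: float = DEFAULT_CUTOFF_REL,
                   objective: str | dict[str, float] | None = None,
                   _solver: _KnockoutSolver | None = None) -> set[frozenset[str]]:
    """Unordered pairs of non-single-lethal genes whose joint deletion
    abolishes biomass production.

    Fast-SL pruning: a lethal pair must have a member supported in the
    wild-type pFBA solution, and its partner supported in the pFBA solution
    of that member's knockout; enumeration is canonical (sorted gene ids)
    so results are deterministic.
    """
    solver = _solver or _KnockoutSolver(model, objective)
    wt = solver._wild_type
    if wt <= 0:
        raise ModelError("wild-type biomass is not positive")
    cutoff = cutoff_rel * wt
    reference = solver.pfba_solution(set())
    anchors = sorted(solver.supported_genes(reference) - single_lethal_set)

    pairs: set[frozenset[str]] = set()
    tested: set[frozenset[str]] = set()
    for gi in anchors:
        sol_i = solver.pfba_solution({gi})
        if sol_i is None or sol_i.objective_value < cutoff:
            continue  # would be single lethal; not a pair anchor
        partners = sorted(solver.supported_genes(sol_i) - single_lethal_set)
        for gj in partners:
            if gj == gi:
                continue
            pair = frozenset((gi, gj))
            if pair in tested:
                continue
            tested.add(pair)
            if solver.optimum({gi, gj}) < cutoff:
                pairs.add(pair)
    return pairs


def exhaustive_lethals(model: MetabolicModel,
                       cutoff_rel: float = DEFAULT_CUTOFF_REL,
                       order: int = 2,
                       objective: str | dict[str, float] | None = None,
                       max_genes: int = 60) -> LethalityResult:
    """Brute-force screen of all single (and pair) deletions; test oracle.

    Guarded to small models (<= ``max_genes`` analyzed genes).
    """
    solver = _KnockoutSolver(model, objective)
    genes = sorted(solver.genes)
    if len(genes) > max_genes:
        raise ModelError(
            f"{len(genes)} genes exceed the exhaustive-screen guard "
            f"({max_genes})"
        )
    wt = solver._wild_type
    if wt <= 0:
        raise ModelError("wild-type biomass is not positive")
    cutoff = cutoff_rel * wt
    singles = {g for g in genes if solver.optimum({g}) < cutoff}
    doubles: set[frozenset[str]] = set()
    if order >= 2:
        survivors = [g for g in genes if g not in singles]
        for gi, gj in combinations(survivors, 2):
            if solver.optimum({gi, gj}) < cutoff:
                doubles.add(frozenset((gi, gj)))
    dl_genes = set().union(*doubles) if doubles else set()
    non_lethal = set(genes) - singles - dl_genes
    return LethalityResult(singles, doubles, non_lethal, wt, cutoff_rel)


def fastsl_lethals(model: MetabolicModel,
                   cutoff_rel: float = DEFAULT_CUTOFF_REL,
                   objective: str | dict[str, float] | None = None) -> LethalityResult:
    """Full Fast-SL analysis bundled into a LethalityResult."""
    solver = _KnockoutSolver(model, objective)
    singles = single_lethals(model, cutoff_rel, objective, _solver=solver)
    doubles = double_lethals(model, singles, cutoff_rel, objective,
                             _solver=solver)
    dl_genes = set().union(*doubles) if doubles else set()
    non_lethal = set(solver.genes) - singles - dl_genes
    return LethalityResult(singles, doubles, non_lethal,
                           solver._wild_type, cutoff_rel)


# ---------------------------------------------------------------------------
# Evidence scoring
# ---------------------------------------------------------------------------

@dataclass
class EvidenceRow:
    gene_id: str
    observed_phenotype: str  # lethal | viable
    source: str = ""


@dataclass
class EvidenceTable:
    rows: list[EvidenceRow]

    def __post_init__(self):
        seen = set()
        for row in self.rows:
            if row.observed_phenotype not in ("lethal", "viable"):
                raise ValueError(
                    f"{row.gene_id}: phenotype must be lethal/viable"
                )
            key = (row.gene_id, row.source)
            if key in seen:
                raise ValueError(f"duplicate evidence row {key}")
            seen.add(key)

    @staticmethod
    def from_tsv(path) -> "EvidenceTable":
        import csv
        with open(path) as fh:
            return EvidenceTable([
                EvidenceRow(r["gene_id"], r["phenotype"], r.get("source", ""))
                for r in csv.DictReader(fh, delimiter="\t")
            ])


@dataclass
class AccuracyReport:
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int
    verdicts: dict[str, str]  # gene -> TP/FP/TN/FN

    @property
    def n_scored(self) -> int:
        return (self.true_positive + self.false_positive
                + self.true_negative + self.false_negative)

    @property
    def accuracy(self) -> float:
        n = self.n_scored
        return (self.true_positive + self.true_negative) / n if n else float("nan")

    @property
    def false_positive_rate(self) -> float:
        n = self.n_scored
        return self.false_positive / n if n else float("nan")


def score_against_evidence(result: LethalityResult,
                           evidence: EvidenceTable) -> AccuracyReport:
    """Confusion matrix of predicted single-lethal vs observed phenotypes.

    Only evidence genes classified single-lethal or non-lethal are scored;
    genes in double-lethal pairs are excluded (a pair phenotype cannot be
    read off a single mutant).
    """
    scored_universe = result.single_lethal | result.non_lethal
    tp = fp = tn = fn = 0
    verdicts: dict[str, str] = {}
    for row in evidence.rows:
        if row.gene_id not in scored_universe:
            continue
        predicted_lethal = row.gene_id in result.single_lethal
        observed_lethal = row.observed_phenotype == "lethal"
        if predicted_lethal and observed_lethal:
            tp += 1
            verdicts[row.gene_id] = "TP"
        elif predicted_lethal:
            fp += 1
            verdicts[row.gene_id] = "FP"
        elif observed_lethal:
            fn += 1
            verdicts[row.gene_id] = "FN"
        else:
            tn += 1
            verdicts[row.gene_id] = "TN"
    return AccuracyReport(tp, fp, tn, fn, verdicts)
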