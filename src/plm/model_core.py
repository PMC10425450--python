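"""Core data model for compartmentalized constraint-based metabolic models.

Provides the in-memory representation used by every other stage of the
toolkit: metabolites with elemental formulas and database annotations,
reactions with stoichiometry, flux bounds, gene-protein-reaction (GPR)
rules and role flags, plus readers/writers for SBML Level 3 (fbc) and a
JSON dialect (documented in ``docs/model_format.md``).

GPR rules are Boolean trees over gene identifiers (AND for protein
complexes, OR for isoenzymes).  The same trees are reused quantitatively
to map transcript abundance onto reactions: OR sums isoenzyme abundances,
AND takes the minimum over complex subunits.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger("plm")

# Solver / numerical defaults shared across the package.
LARGE_BOUND = 1e6
FEASIBILITY_TOL = 1e-9
STEADY_STATE_TOL = 1e-6
FLUX_SUPPORT_TOL = 1e-6

#: Valid reaction role flags.
REACTION_FLAGS = frozenset(
    {"exchange", "demand", "maintenance", "transport", "slime", "biomass", "linker"}
)


class ModelError(ValueError):
    """Structural problem in a metabolic model or its serialization."""


class GprParseError(ValueError):
    """Malformed GPR rule string; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class NoGprRuleError(ValueError):
    """Raised when a quantitative value is requested from an empty GPR."""


class FormulaError(ValueError):
    """Invalid elemental formula string."""


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

# Standard atomic weights (g/mol), conventional values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794, "He": 4.002602, "Li": 6.941, "B": 10.811, "C": 12.0107,
    "N": 14.0067, "O": 15.9994, "F": 18.9984032, "Na": 22.98977,
    "Mg": 24.305, "Al": 26.981538, "Si": 28.0855, "P": 30.973761,
    "S": 32.065, "Cl": 35.453, "K": 39.0983, "Ca": 40.078, "Mn": 54.938049,
    "Fe": 55.845, "Co": 58.9332, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.409,
    "Se": 78.96, "Br": 79.904, "Mo": 95.94, "I": 126.90447, "W": 183.84,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style element-count string into an element->count map.

    Counts are integers; "R" pseudo-groups and charges are rejected.
    """
    if not formula:
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"invalid formula {formula!r}: unparsable at position {pos}"
            )
        elem, num = m.group(1), m.group(2)
        if elem == "R":
            raise FormulaError(f"invalid formula {formula!r}: R groups not supported")
        if elem not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"invalid formula {formula!r}: trailing {formula[pos:]!r}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass of an elemental formula in g/mmol.

    >>> round(molar_mass("H2O"), 6)
    0.018015
    """
    counts = parse_formula(formula)
    grams_per_mol = sum(ATOMIC_WEIGHTS[e] * n for e, n in counts.items())
    return grams_per_mol / 1000.0


def add_formulas(*formulas: str) -> str:
    """Elementwise sum of formulas, rendered in Hill order (C, H, then abc)."""
    total: dict[str, int] = {}
    for f in formulas:
        for e, n in parse_formula(f).items():
            total[e] = total.get(e, 0) + n
    return format_formula(total)


def format_formula(counts: dict[str, int]) -> str:
    def key(e: str) -> tuple:
        return {"C": (0,), "H": (1,)}.get(e, (2, e))

    parts = []
    for e in sorted((e for e, n in counts.items() if n), key=key):
        n = counts[e]
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GprExpression:
    """Boolean gene-protein-reaction rule: a tree of gene leaves under
    AND/OR nodes.  An empty expression means "no rule" (always catalyzable,
    but with no defined transcript abundance).

    Instances are immutable; equality is structural on the canonical form
    (operands flattened and sorted), so ``(a and b)`` == ``(b and a)``.
    """

    __slots__ = ("op", "gene", "operands")

    def __init__(self, op: str, gene: str | None = None,
                 operands: tuple["GprExpression", ...] = ()):
        if op not in ("", "gene", "and", "or"):
            raise ValueError(f"invalid GPR node op {op!r}")
        if op == "gene" and not gene:
            raise ValueError("gene leaf requires a non-empty gene id")
        if op in ("and", "or") and len(operands) < 2:
            raise ValueError(f"{op!r} node requires at least two operands")
        object.__setattr__(self, "op", op)
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "operands", operands)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("GprExpression is immutable")

    # -- constructors -------------------------------------------------
    @staticmethod
    def empty() -> "GprExpression":
        return _EMPTY_GPR

    @staticmethod
    def leaf(gene: str) -> "GprExpression":
        return GprExpression("gene", gene=gene)

    @staticmethod
    def all_of(*ops: "GprExpression") -> "GprExpression":
        return GprExpression._combine("and", ops)

    @staticmethod
    def any_of(*ops: "GprExpression") -> "GprExpression":
        return GprExpression._combine("or", ops)

    @staticmethod
    def _combine(op: str, ops) -> "GprExpression":
        flat: list[GprExpression] = []
        seen = set()
        for o in ops:
            if o.is_empty():
                continue
            parts = o.operands if o.op == op else (o,)
            for p in parts:
                c = p._canonical()
                if c not in seen:
                    seen.add(c)
                    flat.append(p)
        if not flat:
            return _EMPTY_GPR
        if len(flat) == 1:
            return flat[0]
        return GprExpression(op, operands=tuple(flat))

    # -- queries ------------------------------------------------------
    def is_empty(self) -> bool:
        return self.op == ""

    def genes(self) -> frozenset[str]:
        if self.op == "":
            return frozenset()
        if self.op == "gene":
            return frozenset((self.gene,))
        return frozenset().union(*(o.genes() for o in self.operands))

    def evaluate(self, knocked_out: set[str] | frozenset[str]) -> bool:
        """True iff the reaction remains catalyzable under the knockout."""
        if self.op == "":
            return True
        if self.op == "gene":
            return self.gene not in knocked_out
        vals = (o.evaluate(knocked_out) for o in self.operands)
        return all(vals) if self.op == "and" else any(vals)

    def abundance(self, table: dict[str, float]) -> float:
        """Map gene abundances onto the rule: OR sums, AND takes the min.

        Genes absent from ``table`` contribute 0 under OR and are skipped
        under AND (absent evidence must not zero out a complex).  Raises
        :class:`NoGprRuleError` on an empty expression so that "no rule"
        stays distinct from an abundance of 0.
        """
        if self.op == "":
            raise NoGprRuleError("abundance of an empty GPR rule is undefined")
        value = self._abundance(table)
        return 0.0 if value is None else value

    def _abundance(self, table: dict[str, float]) -> float | None:
        if self.op == "gene":
            return table.get(self.gene)
        vals = [o._abundance(table) for o in self.operands]
        known = [v for v in vals if v is not None]
        if self.op == "or":
            # missing isoenzymes contribute 0
            return sum(known) if known else None
        if not known:
            logger.warning("AND node with no measured genes; treated as missing")
            return None
        return min(known)

    # -- serialization ------------------------------------------------
    def to_string(self) -> str:
        return self._render(top=True)

    def _render(self, top: bool = False) -> str:
        if self.op == "":
            return ""
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        inner = sep.join(
            o._render() if o.op == "gene" else f"({o._render()})"
            for o in self.operands
        )
        return inner if top else inner

    def _canonical(self):
        if self.op == "":
            return ("",)
        if self.op == "gene":
            return ("gene", self.gene)
        return (self.op,) + tuple(sorted(o._canonical() for o in self.operands))

    def __eq__(self, other):
        if not isinstance(other, GprExpression):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self):
        return hash(self._canonical())

    def __repr__(self):
        return f"GprExpression({self.to_string()!r})" if not self.is_empty() \
            else "GprExpression(<empty>)"


_EMPTY_GPR = GprExpression("")

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string: gene ids, parentheses, case-insensitive
    ``and`` / ``or`` (``or`` binds loosest, per convention)."""
    if text is None or not text.strip():
        return GprExpression.empty()

    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def parse_or() -> GprExpression:
        nonlocal idx
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            terms.append(parse_and())
        return GprExpression.any_of(*terms)

    def parse_and() -> GprExpression:
        nonlocal idx
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            factors.append(parse_atom())
        return GprExpression.all_of(*factors)

    def parse_atom() -> GprExpression:
        nonlocal idx
        tok = peek()
        if tok is None:
            off = tokens[idx - 1][1] if tokens else 0
            raise GprParseError("unexpected end of rule, operand expected", off)
        off = tokens[idx][1]
        if tok == "(":
            idx += 1
            inner = parse_or()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses, ')' expected", off)
            idx += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"operand expected, got {tok!r}", off)
        idx += 1
        return GprExpression.leaf(tok)

    expr = parse_or()
    if idx != len(tokens):
        raise GprParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return expr


def eval_gpr(expr: GprExpression, knocked_out: set[str]) -> bool:
    """Whether a reaction stays catalyzable given a gene knockout set."""
    return expr.evaluate(knocked_out)


def gpr_abundance(expr: GprExpression, abundance: dict[str, float]) -> float:
    """Reaction-level transcript abundance under the OR=sum / AND=min rule."""
    return expr.abundance(abundance)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteRecord:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: int = 0
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def molar_mass(self) -> float | None:
        """Mass in g/mmol derived from the formula, or None if no formula."""
        if not self.formula:
            return None
        return molar_mass(self.formula)

    def copy(self) -> "MetaboliteRecord":
        return replace(self, annotations=dict(self.annotations))


@dataclass
class ReactionRecord:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -LARGE_BOUND
    upper_bound: float = LARGE_BOUND
    gpr: GprExpression = field(default_factory=GprExpression.empty)
    subsystem: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        self.flags = frozenset(self.flags)
        bad = self.flags - REACTION_FLAGS
        if bad:
            raise ModelError(f"reaction {self.id}: unknown flags {sorted(bad)}")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "ReactionRecord":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class FluxDistribution:
    """Solution of one optimization: reaction->flux (mmol/gDW/phase)."""
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def total_absolute_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())

    def supported_reactions(self, tol: float = FLUX_SUPPORT_TOL) -> set[str]:
        return {r for r, v in self.fluxes.items() if abs(v) > tol}


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    id: str = "model"
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: list[MetaboliteRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    objective_direction: str = "max"
    extra_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self._check_unique_ids()

    # -- indexing -----------------------------------------------------
    def _check_unique_ids(self):
        seen, dup = set(), []
        for m in self.metabolites:
            if m.id in seen:
                dup.append(m.id)
            seen.add(m.id)
        seen2 = set()
        for r in self.reactions:
            if r.id in seen2:
                dup.append(r.id)
            seen2.add(r.id)
        if dup:
            raise ModelError(f"duplicated ids: {sorted(set(dup))}")

    @property
    def metabolite_index(self) -> dict[str, MetaboliteRecord]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_index(self) -> dict[str, ReactionRecord]:
        return {r.id: r for r in self.reactions}

    @property
    def genes(self) -> frozenset[str]:
        gs: set[str] = set(self.extra_genes)
        for r in self.reactions:
            gs |= r.gpr.genes()
        return frozenset(gs)

    def metabolite(self, met_id: str) -> MetaboliteRecord:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- editing ------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective=dict(self.objective),
            objective_direction=self.objective_direction,
            extra_genes=set(self.extra_genes),
        )

    def add_metabolite(self, met: MetaboliteRecord):
        if self.has_metabolite(met.id):
            raise ModelError(f"metabolite id {met.id!r} already present")
        if met.compartment not in self.compartments:
            raise ModelError(
                f"metabolite {met.id}: unknown compartment {met.compartment!r}"
            )
        self.metabolites.append(met)

    def add_reaction(self, rxn: ReactionRecord):
        if self.has_reaction(rxn.id):
            raise ModelError(f"reaction id {rxn.id!r} already present")
        mets = self.metabolite_index
        missing = [m for m in rxn.stoichiometry if m not in mets]
        if missing:
            raise ModelError(f"reaction {rxn.id}: unknown metabolites {missing}")
        self.reactions.append(rxn)

    def set_objective(self, objective: str | dict[str, float],
                      direction: str = "max"):
        if isinstance(objective, str):
            objective = {objective: 1.0}
        for rid in objective:
            if not self.has_reaction(rid):
                raise ModelError(f"objective reaction {rid!r} not in model")
        if direction not in ("max", "min"):
            raise ModelError(f"invalid objective direction {direction!r}")
        self.objective = dict(objective)
        self.objective_direction = direction

    def check_structure(self):
        """Raise ModelError on broken referential invariants."""
        self._check_unique_ids()
        mets = self.metabolite_index
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {m.id}: compartment {m.compartment!r} missing"
                )
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in mets:
                    raise ModelError(f"reaction {r.id}: unknown metabolite {mid!r}")
        for rid in self.objective:
            if not self.has_reaction(rid):
                raise ModelError(f"objective reaction {rid!r} missing")

    def __eq__(self, other):
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return _model_signature(self) == _model_signature(other)


def models_equivalent(a: MetabolicModel, b: MetabolicModel,
                      rtol: float = 1e-12) -> bool:
    """Equality up to a relative tolerance on numeric fields.

    SBML serializes doubles at 15 significant digits, so a written-and-read
    model can differ from the original in the last bit of a coefficient;
    the JSON dialect round-trips exactly.
    """
    sa, sb = _model_signature(a), _model_signature(b)

    def close(x, y):
        if isinstance(x, float) and isinstance(y, float):
            return math.isclose(x, y, rel_tol=rtol, abs_tol=rtol)
        if isinstance(x, tuple) and isinstance(y, tuple):
            return len(x) == len(y) and all(close(u, v) for u, v in zip(x, y))
        return x == y

    return close(sa, sb)


def _model_signature(m: MetabolicModel):
    mets = tuple(sorted(
        (x.id, x.name, x.compartment, x.formula, x.charge,
         tuple(sorted(x.annotations.items())))
        for x in m.metabolites
    ))
    rxns = tuple(sorted(
        (r.id, r.name, tuple(sorted(r.stoichiometry.items())),
         r.lower_bound, r.upper_bound, r.gpr._canonical(), r.subsystem,
         tuple(sorted(r.flags)))
        for r in m.reactions
    ))
    return (tuple(sorted(m.compartments.items())), mets, rxns,
            tuple(sorted(m.objective.items())), m.objective_direction)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

#: Flags exempt from mass/charge balance checks (boundary pseudo-reactions).
BALANCE_EXEMPT_FLAGS = frozenset({"exchange", "demand", "biomass", "slime"})


@dataclass
class ValidationReport:
    unbalanced_reactions: dict[str, dict[str, float]]  # rxn -> element deltas
    charge_imbalanced: dict[str, float]
    orphan_metabolites: list[str]
    blocked_bound_reactions: list[str]
    unchecked_reactions: list[str]  # missing formulas prevented the check
    warnings: list[str]

    @property
    def n_problems(self) -> int:
        return (len(self.unbalanced_reactions) + len(self.orphan_metabolites)
                + len(self.blocked_bound_reactions))


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Report element/charge-unbalanced reactions, orphan metabolites and
    reactions whose bounds pin the flux to zero.

    Exchange, demand, biomass and SLIME pseudo-reactions are exempt from
    balance checks; reactions touching a metabolite with no formula are
    reported as unchecked rather than unbalanced.
    """
    model.check_structure()
    mets = model.metabolite_index
    unbalanced: dict[str, dict[str, float]] = {}
    charge_bad: dict[str, float] = {}
    unchecked: list[str] = []
    warnings: list[str] = []

    for r in model.reactions:
        if r.flags & BALANCE_EXEMPT_FLAGS:
            continue
        if any(not mets[m].formula for m in r.stoichiometry):
            unchecked.append(r.id)
            continue
        deltas: dict[str, float] = {}
        charge_delta = 0.0
        for mid, coef in r.stoichiometry.items():
            for e, n in parse_formula(mets[mid].formula).items():
                deltas[e] = deltas.get(e, 0.0) + coef * n
            charge_delta += coef * mets[mid].charge
        deltas = {e: d for e, d in deltas.items() if abs(d) > 1e-9}
        if deltas:
            unbalanced[r.id] = deltas
        if abs(charge_delta) > 1e-9:
            charge_bad[r.id] = charge_delta

    used = set()
    for r in model.reactions:
        used.update(r.stoichiometry)
    orphans = sorted(m.id for m in model.metabolites if m.id not in used)

    blocked = sorted(
        r.id for r in model.reactions
        if r.lower_bound == 0.0 and r.upper_bound == 0.0
    )
    for r in model.reactions:
        if "exchange" in r.flags and len(r.stoichiometry) != 1:
            warnings.append(
                f"exchange reaction {r.id} touches {len(r.stoichiometry)} "
                "metabolites (expected exactly one)"
            )
    return ValidationReport(unbalanced, charge_bad, orphans, blocked,
                            unchecked, warnings)


# ---------------------------------------------------------------------------
# Serialization: JSON dialect
# ---------------------------------------------------------------------------

JSON_FORMAT_VERSION = 1


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "format": "plm-model",
        "version": JSON_FORMAT_VERSION,
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                "formula": m.formula, "charge": m.charge,
                "annotations": dict(m.annotations),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(), "subsystem": r.subsystem,
                "flags": sorted(r.flags),
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": {
            "reactions": dict(model.objective),
            "direction": model.objective_direction,
        },
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if data.get("format") != "plm-model":
        raise ModelError("not a plm-model JSON document")
    model = MetabolicModel(
        id=data.get("id", "model"),
        compartments=dict(data["compartments"]),
    )
    for m in data["metabolites"]:
        model.add_metabolite(MetaboliteRecord(
            id=m["id"], name=m.get("name", ""),
            compartment=m["compartment"], formula=m.get("formula", ""),
            charge=int(m.get("charge", 0)),
            annotations=dict(m.get("annotations", {})),
        ))
    for r in data["reactions"]:
        model.add_reaction(ReactionRecord(
            id=r["id"], name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gpr=parse_gpr(r.get("gpr", "")),
            subsystem=r.get("subsystem", ""),
            flags=frozenset(r.get("flags", [])),
        ))
    obj = data.get("objective") or {}
    if obj.get("reactions"):
        model.set_objective({k: float(v) for k, v in obj["reactions"].items()},
                            obj.get("direction", "max"))
    declared = set(data.get("genes", []))
    model.extra_genes = declared - set(model.genes)
    model.check_structure()
    return model


# ---------------------------------------------------------------------------
# Serialization: SBML L3 + fbc via COBRApy
# ---------------------------------------------------------------------------

# Annotation namespace mapping between this package and identifiers.org
# prefixes used by COBRApy/SBML CV terms.
_ANNOTATION_OUT = {"kegg": "kegg.compound", "chebi": "chebi"}
_ANNOTATION_IN = {v: k for k, v in _ANNOTATION_OUT.items()}


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (flags and subsystem carried in notes)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.compartments = dict(model.compartments)
    cobra_mets = {}
    for m in model.metabolites:
        c = cobra.Metabolite(
            m.id, formula=m.formula or None, name=m.name,
            compartment=m.compartment, charge=m.charge,
        )
        for ns, val in m.annotations.items():
            c.annotation[_ANNOTATION_OUT.get(ns, ns)] = val
        cobra_mets[m.id] = c
    cm.add_metabolites(list(cobra_mets.values()))

    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({cobra_mets[m]: v for m, v in r.stoichiometry.items()})
        cr.gene_reaction_rule = r.gpr.to_string()
        cr.subsystem = r.subsystem
        notes = {}
        if r.flags:
            notes["plm_flags"] = ";".join(sorted(r.flags))
        if r.subsystem:
            notes["plm_subsystem"] = r.subsystem
        cr.notes = notes
    if model.objective:
        cm.objective = {cm.reactions.get_by_id(rid): coef
                        for rid, coef in model.objective.items()}
        cm.objective_direction = model.objective_direction
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model into the package's data model."""
    from cobra.util.solver import linear_reaction_coefficients

    model = MetabolicModel(id=cm.id or "model",
                           compartments=dict(cm.compartments))
    for c in cm.metabolites:
        ann: dict[str, str] = {}
        for ns, val in c.annotation.items():
            if isinstance(val, (list, tuple)):
                val = val[0] if val else ""
            ann[_ANNOTATION_IN.get(ns, ns)] = str(val)
        if c.compartment not in model.compartments:
            model.compartments[c.compartment] = c.compartment
        model.add_metabolite(MetaboliteRecord(
            id=c.id, name=c.name or "", compartment=c.compartment,
            formula=c.formula or "", charge=int(c.charge or 0),
            annotations=ann,
        ))
    for cr in cm.reactions:
        notes = cr.notes or {}
        flags = frozenset(
            f for f in str(notes.get("plm_flags", "")).split(";") if f
        )
        subsystem = str(notes.get("plm_subsystem", "") or cr.subsystem or "")
        model.add_reaction(ReactionRecord(
            id=cr.id, name=cr.name or "",
            stoichiometry={m.id: v for m, v in cr.metabolites.items()},
            lower_bound=cr.lower_bound, upper_bound=cr.upper_bound,
            gpr=parse_gpr(cr.gene_reaction_rule or ""),
            subsystem=subsystem, flags=flags,
        ))
    coefs = linear_reaction_coefficients(cm)
    if coefs:
        model.set_objective({r.id: float(v) for r, v in coefs.items()},
                            cm.objective_direction or "max")
    return model


def _assert_sbml_has_fbc(path: str):
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"{path}: not a readable SBML document")
    if doc.getPlugin("fbc") is None and sbml_model.getPlugin("fbc") is None:
        raise ModelError(
            f"{path}: SBML document lacks the flux-bounds (fbc) extension"
        )


def read_model(path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from SBML (L3+fbc) or the JSON dialect.

    The format is inferred from the file suffix when not given.
    """
    path = str(path)
    fmt = fmt or ("json" if path.endswith(".json") else "sbml")
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if fmt == "sbml":
        _assert_sbml_has_fbc(path)
        import cobra.io
        cm = cobra.io.read_sbml_model(path)
        return from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: str | None = None):
    path = str(path)
    fmt = fmt or ("json" if path.endswith(".json") else "sbml")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        return
    if fmt == "sbml":
        import cobra.io
        cobra.io.write_sbml_model(to_cobra(model), path)
        return
    raise ValueError(f"unknown model format {fmt!r}")
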