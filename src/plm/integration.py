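"""Merging a lipid-metabolism module into a template metabolic model.

The merge follows a four-step procedure: (1) take the template model as-is;
(2) consolidate compartments (exact id, case-insensitive name, or explicit
override; unmatched module compartments are added as new); (3) consolidate
metabolites (match priority: shared KEGG id > shared ChEBI id > identical
formula+charge within a compartment; template attributes win on conflict);
(4) add the module reactions rewritten onto the consolidated namespace and
drop duplicates, OR-merging their GPRs into the template reaction.

Template content is never modified beyond GPR unions on duplicates, so any
template-feasible flux vector (extended with zeros) stays feasible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model_core import (
    GprExpression,
    MetabolicModel,
    MetaboliteRecord,
    ModelError,
    ReactionRecord,
)

logger = logging.getLogger("plm")

NEW = "NEW"


@dataclass
class CompartmentMap:
    """Total map from module compartment ids to template ids or NEW."""
    mapping: dict[str, str]           # module id -> template id or NEW
    new_compartments: list[str]       # module ids mapped to NEW

    def target(self, module_comp: str) -> str:
        """Template-side compartment id a module compartment lands in."""
        t = self.mapping[module_comp]
        return module_comp if t == NEW else t


@dataclass
class MetaboliteMatch:
    module_id: str
    template_id: str          # template metabolite id, or NEW
    match_basis: str          # kegg | chebi | formula+charge | none
    conflicts: list[str] = field(default_factory=list)

    @property
    def is_new(self) -> bool:
        return self.template_id == NEW


@dataclass
class IntegrationReport:
    metabolites_matched: int
    metabolites_added: int
    reactions_added: int
    reactions_deduplicated: int
    matches: list[MetaboliteMatch]
    removed_duplicates: list[tuple[str, str]]  # (module rxn, template rxn)
    warnings: list[str]

    def to_rows(self) -> list[dict]:
        rows = [
            {"record": "metabolite", "module_id": m.module_id,
             "template_id": m.template_id, "basis": m.match_basis,
             "conflicts": "|".join(m.conflicts)}
            for m in self.matches
        ]
        rows += [
            {"record": "duplicate_reaction", "module_id": a, "template_id": b,
             "basis": "stoichiometry", "conflicts": ""}
            for a, b in self.removed_duplicates
        ]
        return rows


def map_compartments(template: MetabolicModel, module: MetabolicModel,
                     overrides: dict[str, str] | None = None) -> CompartmentMap:
    """Map every module compartment onto a template compartment or NEW.

    Explicit overrides take precedence, then exact id match, then
    case-insensitive name match.
    """
    overrides = dict(overrides or {})
    for mc, tc in overrides.items():
        if mc not in module.compartments:
            raise ModelError(f"override names unknown module compartment {mc!r}")
        if tc not in template.compartments:
            raise ModelError(f"override names unknown template compartment {tc!r}")
    by_name = {}
    for cid, cname in template.compartments.items():
        by_name.setdefault(cname.strip().lower(), cid)

    mapping: dict[str, str] = {}
    new: list[str] = []
    for cid, cname in module.compartments.items():
        if cid in overrides:
            mapping[cid] = overrides[cid]
        elif cid in template.compartments:
            mapping[cid] = cid
        elif cname.strip().lower() in by_name:
            mapping[cid] = by_name[cname.strip().lower()]
        else:
            mapping[cid] = NEW
            new.append(cid)
    return CompartmentMap(mapping, new)


def _annotation(met: MetaboliteRecord, ns: str) -> str | None:
    v = met.annotations.get(ns)
    return v if v else None


def match_metabolites(template: MetabolicModel, module: MetabolicModel,
                      cmap: CompartmentMap) -> list[MetaboliteMatch]:
    """Match module metabolites to template metabolites compartment-wise.

    Priority: shared KEGG id > shared ChEBI id > identical (formula, charge).
    Two template metabolites carrying the same KEGG (or ChEBI) id within one
    compartment make the match ambiguous and raise an error.
    """
    # template lookups per compartment
    by_kegg: dict[tuple[str, str], list[str]] = {}
    by_chebi: dict[tuple[str, str], list[str]] = {}
    by_formula: dict[tuple[str, str, int], list[str]] = {}
    for tm in template.metabolites:
        if (k := _annotation(tm, "kegg")):
            by_kegg.setdefault((tm.compartment, k), []).append(tm.id)
        if (c := _annotation(tm, "chebi")):
            by_chebi.setdefault((tm.compartment, c), []).append(tm.id)
        if tm.formula:
            by_formula.setdefault(
                (tm.compartment, tm.formula, tm.charge), []).append(tm.id)

    tmets = template.metabolite_index
    matches: list[MetaboliteMatch] = []
    for mm in module.metabolites:
        target_comp = cmap.mapping[mm.compartment]
        if target_comp == NEW:
            matches.append(MetaboliteMatch(mm.id, NEW, "none"))
            continue

        basis, candidates = "none", []
        if (k := _annotation(mm, "kegg")) and (target_comp, k) in by_kegg:
            basis, candidates = "kegg", by_kegg[(target_comp, k)]
        elif (c := _annotation(mm, "chebi")) and (target_comp, c) in by_chebi:
            basis, candidates = "chebi", by_chebi[(target_comp, c)]
        elif mm.formula and (key := (target_comp, mm.formula, mm.charge)) in by_formula:
            basis, candidates = "formula+charge", by_formula[key]

        if basis == "none":
            matches.append(MetaboliteMatch(mm.id, NEW, "none"))
            continue
        if len(candidates) > 1 and basis in ("kegg", "chebi"):
            raise ModelError(
                f"ambiguous {basis} match for module metabolite {mm.id!r} in "
                f"compartment {target_comp!r}: candidates {sorted(candidates)}"
            )
        tid = sorted(candidates)[0]
        tm = tmets[tid]
        conflicts = []
        for fld in ("name", "formula", "charge"):
            mv, tv = getattr(mm, fld), getattr(tm, fld)
            if mv and tv and mv != tv:
                conflicts.append(f"{fld}: module={mv!r} template={tv!r}")
        matches.append(MetaboliteMatch(mm.id, tid, basis, conflicts))
    return matches


# ---------------------------------------------------------------------------
# Duplicate reactions
# ---------------------------------------------------------------------------

def _normalized_stoichiometry(stoich: dict[str, float]):
    """Canonical (sign-normalized, sorted) form plus the sign applied.

    The sign is chosen so that the lexicographically first metabolite has a
    negative coefficient.  Comparison uses exact coefficient equality: model
    coefficients are curated constants, not measurements.
    """
    items = sorted(stoich.items())
    sign = 1.0 if items[0][1] < 0 else -1.0
    return tuple((m, sign * c) for m, c in items), sign


def _directions_compatible(r1: ReactionRecord, s1: float,
                           r2: ReactionRecord, s2: float) -> bool:
    """Whether two stoichiometrically identical reactions admit a common
    nonzero flux direction once both are expressed in normalized orientation."""
    lo1, hi1 = sorted((s1 * r1.lower_bound, s1 * r1.upper_bound))
    lo2, hi2 = sorted((s2 * r2.lower_bound, s2 * r2.upper_bound))
    lo, hi = max(lo1, lo2), min(hi1, hi2)
    return lo <= hi and not (lo == 0.0 == hi)


def find_duplicate_reactions(model: MetabolicModel) -> list[tuple[str, str]]:
    """Pairs of reactions with identical normalized stoichiometry that can
    carry flux in a common direction (A->B vs B->A both-irreversible are
    not duplicates)."""
    groups: dict[tuple, list[tuple[ReactionRecord, float]]] = {}
    for r in model.reactions:
        key, sign = _normalized_stoichiometry(r.stoichiometry)
        groups.setdefault(key, []).append((r, sign))
    pairs = []
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (r1, s1), (r2, s2) = members[i], members[j]
                if _directions_compatible(r1, s1, r2, s2):
                    pairs.append((r1.id, r2.id))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Full integration
# ---------------------------------------------------------------------------

def integrate_module(
    template: MetabolicModel,
    module: MetabolicModel,
    compartment_overrides: dict[str, str] | None = None,
) -> tuple[MetabolicModel, IntegrationReport]:
    """Merge ``module`` into ``template`` (four-step procedure).

    Returns the merged model and a report.  Template content is unchanged
    except for GPR OR-unions on deduplicated reactions.
    """
    template.check_structure()
    module.check_structure()
    merged = template.copy()
    warnings: list[str] = []

    cmap = map_compartments(template, module, compartment_overrides)
    for cid in cmap.new_compartments:
        merged.compartments[cid] = module.compartments[cid]

    matches = match_metabolites(template, module, cmap)
    id_rewrite: dict[str, str] = {}
    n_matched = n_added = 0
    module_mets = module.metabolite_index
    for match in matches:
        if not match.is_new:
            id_rewrite[match.module_id] = match.template_id
            n_matched += 1
            if match.conflicts:
                warnings.append(
                    f"metabolite {match.module_id} -> {match.template_id}: "
                    f"template attributes kept ({'; '.join(match.conflicts)})"
                )
            continue
        mm = module_mets[match.module_id].copy()
        mm.compartment = cmap.target(mm.compartment)
        new_id = mm.id
        if merged.has_metabolite(new_id):
            new_id = f"{new_id}__mod"
            warnings.append(
                f"metabolite id collision: module {mm.id!r} renamed {new_id!r}"
            )
            mm.id = new_id
        id_rewrite[match.module_id] = new_id
        merged.add_metabolite(mm)
        n_added += 1

    # index template reactions by normalized stoichiometry
    template_norm: dict[tuple, list[tuple[ReactionRecord, float]]] = {}
    for r in merged.reactions:
        key, sign = _normalized_stoichiometry(r.stoichiometry)
        template_norm.setdefault(key, []).append((r, sign))

    removed: list[tuple[str, str]] = []
    n_rxn_added = n_dedup = 0
    for mr in module.reactions:
        stoich = {id_rewrite[m]: c for m, c in mr.stoichiometry.items()}
        key, sign = _normalized_stoichiometry(stoich)
        dup_target = None
        for tr, tsign in template_norm.get(key, []):
            if _directions_compatible(mr, sign, tr, tsign):
                dup_target = tr
                break
        if dup_target is not None:
            # OR-union of gene evidence; an empty rule means "no gene
            # requirement" and must stay empty (TRUE or X = TRUE)
            if not dup_target.gpr.is_empty() and not mr.gpr.is_empty():
                dup_target.gpr = GprExpression.any_of(dup_target.gpr, mr.gpr)
            removed.append((mr.id, dup_target.id))
            n_dedup += 1
            continue
        new = mr.copy()
        new.stoichiometry = stoich
        if merged.has_reaction(new.id):
            renamed = f"{new.id}__mod"
            warnings.append(
                f"reaction id collision: module {new.id!r} renamed {renamed!r}"
            )
            new.id = renamed
        merged.add_reaction(new)
        template_norm.setdefault(key, []).append((new, sign))
        n_rxn_added += 1

    merged.check_structure()
    report = IntegrationReport(
        metabolites_matched=n_matched, metabolites_added=n_added,
        reactions_added=n_rxn_added, reactions_deduplicated=n_dedup,
        matches=matches, removed_duplicates=removed, warnings=warnings,
    )
    for w in warnings:
        logger.warning(w)
    return merged, report
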