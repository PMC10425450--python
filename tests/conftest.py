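import logging

import pytest

from plm.fixtures import (
    FixtureConfig,
    make_lipid_module,
    make_study_model,
    make_template_model,
)
from plm.model_core import (
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    parse_gpr,
)

logging.getLogger("plm").setLevel(logging.ERROR)
logging.getLogger("cobra").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return FixtureConfig()


@pytest.fixture(scope="session")
def template(cfg):
    return make_template_model(cfg)


@pytest.fixture(scope="session")
def lipid_module(cfg):
    return make_lipid_module(cfg)


@pytest.fixture(scope="session")
def study_model(cfg):
    return make_study_model(cfg)


def toy_model(reactions, compartments=None, objective=None, formulas=None,
              annotations=None):
    """Assemble a small model from reaction specs:
    (id, stoich, lb, ub, gpr, flags)."""
    m = MetabolicModel(id="toy", compartments=compartments or {"c": "cytosol"})
    mets = {}
    for spec in reactions:
        for mid in spec[1]:
            mets.setdefault(mid, None)
    formulas = formulas or {}
    annotations = annotations or {}
    for mid in mets:
        comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
        if comp not in m.compartments:
            comp = next(iter(m.compartments))
        m.add_metabolite(MetaboliteRecord(
            mid, compartment=comp, formula=formulas.get(mid, ""),
            annotations=annotations.get(mid, {})))
    for spec in reactions:
        rid, stoich = spec[0], spec[1]
        lb = spec[2] if len(spec) > 2 else 0.0
        ub = spec[3] if len(spec) > 3 else 1000.0
        gpr = spec[4] if len(spec) > 4 else ""
        flags = spec[5] if len(spec) > 5 else ()
        m.add_reaction(ReactionRecord(
            id=rid, stoichiometry=dict(stoich), lower_bound=lb,
            upper_bound=ub, gpr=parse_gpr(gpr), flags=frozenset(flags)))
    if objective:
        m.set_objective(objective, "max")
    return m
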