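"""Flux-transcript log2 fold-change sign concordance and the chi-square
comparison between transcriptomic datasets.

For every GPR-bearing reaction, transcript abundance is mapped onto the
rule (OR = sum over isoenzymes, AND = min over complex subunits) in the
control and the treatment condition; the log2 fold changes of flux
magnitude and of mapped transcript abundance are compared by sign.  Rows
where either change is effectively zero are excluded.  Two concordance
tables are compared with a Pearson chi-square test of independence
(2x2, df=1, no continuity correction) with phi = sqrt(chi2/N) as effect
size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import MetabolicModel, FluxDistribution, NoGprRuleError

DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_EPSILON = 1e-6

EXCLUDED = "excluded"
CONCORDANT = "concordant"
OUTLIER = "outlier"


def log2fc(treated: float, control: float,
           pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float | None:
    """log2((treated+pc)/(control+pc)); None (excluded) when both are zero."""
    if treated < 0 or control < 0:
        raise ValueError("negative abundances")
    if pseudocount < 0:
        raise ValueError("negative pseudocount")
    if treated == 0 and control == 0:
        return None
    if control + pseudocount == 0 or treated + pseudocount == 0:
        return None
    return math.log2((treated + pseudocount) / (control + pseudocount))


def classify_concordance(flux_fc: float | None, transcript_fc: float | None,
                         epsilon: float = DEFAULT_EPSILON) -> str:
    """concordant iff both changes are real (|fc| > epsilon) and same-signed."""
    if flux_fc is None or transcript_fc is None:
        return EXCLUDED
    if abs(flux_fc) <= epsilon or abs(transcript_fc) <= epsilon:
        return EXCLUDED
    return CONCORDANT if (flux_fc > 0) == (transcript_fc > 0) else OUTLIER


@dataclass
class ConcordanceRow:
    reaction_id: str
    flux_log2fc: float | None
    transcript_log2fc: float | None
    klass: str


@dataclass
class ConcordanceTable:
    rows: list[ConcordanceRow]

    @property
    def n_scored(self) -> int:
        return sum(1 for r in self.rows if r.klass != EXCLUDED)

    @property
    def n_concordant(self) -> int:
        return sum(1 for r in self.rows if r.klass == CONCORDANT)

    @property
    def n_outlier(self) -> int:
        return sum(1 for r in self.rows if r.klass == OUTLIER)

    @property
    def percent_concordant(self) -> float:
        n = self.n_scored
        return 100.0 * self.n_concordant / n if n else float("nan")

    @property
    def percent_outlier(self) -> float:
        n = self.n_scored
        return 100.0 * self.n_outlier / n if n else float("nan")


def concordance_table(
    flux_control: FluxDistribution,
    flux_dark: FluxDistribution,
    transcripts_control: dict[str, float],
    transcripts_dark: dict[str, float],
    model: MetabolicModel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epsilon: float = DEFAULT_EPSILON,
) -> ConcordanceTable:
    """Score every GPR-bearing reaction for flux/transcript sign agreement.

    Flux changes use the flux magnitude |v| (reaction activity level), since
    LP fluxes are signed by an arbitrary reaction orientation.
    """
    rows = []
    for r in model.reactions:
        if r.gpr.is_empty():
            continue
        try:
            t_ctrl = r.gpr.abundance(transcripts_control)
            t_dark = r.gpr.abundance(transcripts_dark)
        except NoGprRuleError:  # pragma: no cover - guarded by is_empty
            continue
        v_ctrl = abs(flux_control.fluxes.get(r.id, 0.0))
        v_dark = abs(flux_dark.fluxes.get(r.id, 0.0))
        f_fc = log2fc(v_dark, v_ctrl, pseudocount)
        t_fc = log2fc(t_dark, t_ctrl, pseudocount)
        rows.append(ConcordanceRow(r.id, f_fc, t_fc,
                                   classify_concordance(f_fc, t_fc, epsilon)))
    return ConcordanceTable(rows)


# ---------------------------------------------------------------------------
# Chi-square comparison
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    counts: list[list[int]]
    statistic: float
    df: int
    p_value: float
    phi: float  # effect size sqrt(chi2 / N)

    @property
    def n(self) -> int:
        return int(sum(sum(row) for row in self.counts))


def chi_square_independence(counts, continuity_correction: bool = False) \
        -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 table.

    No Yates correction by default.  Effect size phi = sqrt(chi2/N).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(
        table, correction=continuity_correction)
    n = table.sum()
    return ChiSquareResult(
        counts=[[int(x) for x in row] for row in np.asarray(counts)],
        statistic=float(stat), df=int(dof), p_value=float(p),
        phi=float(np.sqrt(stat / n)),
    )


def counts_from_percent(percent_concordant: float, n: int) -> tuple[int, int]:
    """Reconstruct (concordant, outlier) counts from a printed percentage."""
    conc = round(percent_concordant / 100.0 * n)
    return int(conc), int(n - conc)


def compare_datasets(table_a: ConcordanceTable,
                     table_b: ConcordanceTable) -> ChiSquareResult:
    """Chi-square independence test on the two tables' concordant/outlier
    counts (rows = datasets, columns = concordant/outlier)."""
    counts = [
        [table_a.n_concordant, table_a.n_outlier],
        [table_b.n_concordant, table_b.n_outlier],
    ]
    return chi_square_independence(counts)
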