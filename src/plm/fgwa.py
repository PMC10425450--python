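"""Flux genome-wide association (fGWA) post-processing.

Model-predicted fluxes across a panel of accessions are treated as
quantitative traits.  The stage covers: minor-allele-frequency filtering
(strictly > 0.05 retained), population-structure covariates (top principal
components of the dosage matrix), a per-SNP fixed-effect association scan
(trait ~ intercept + covariates + dosage, two-sided t test on the dosage
coefficient; externally computed p-values can be supplied instead),
significance at the 1/n threshold, transitive 20-kb clumping of significant
SNPs into loci, candidate-gene retrieval around each lead SNP, functional
classification of candidates against the trait reaction's GPR neighborhood
and a transcription-factor list, expression-level categorization, and
mutant lipid fold-change validation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import MetabolicModel

logger = logging.getLogger("plm")

DEFAULT_MIN_MAF = 0.05
DEFAULT_CLUMP_WINDOW_BP = 20_000
DEFAULT_N_PCS = 3


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Accession x SNP dosage matrix (0/1/2, NaN = missing)."""
    accessions: list[str]
    snps: pd.DataFrame  # columns: chrom, pos (1-based), id, ref, alt
    dosage: np.ndarray  # float array, shape (n_accessions, n_snps)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, missing dosages excluded."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            snps=self.snps.loc[np.asarray(mask)].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(mask)],
        )

    @staticmethod
    def from_tsv(path) -> "GenotypeMatrix":
        """Read a delimited dosage matrix: columns chrom, pos, id, ref, alt,
        then one column per accession holding 0/1/2 (empty = missing)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        fixed = ["chrom", "pos", "id", "ref", "alt"]
        acc = [c for c in df.columns if c not in fixed]
        return GenotypeMatrix(
            accessions=acc,
            snps=df[fixed].copy(),
            dosage=df[acc].to_numpy(dtype=float).T,
        )

    @staticmethod
    def from_vcf(path) -> "GenotypeMatrix":
        """Read genotypes from a (plain-text) VCF; dosage = ALT allele count."""
        accessions: list[str] = []
        records = []
        dosages = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    accessions = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], \
                    parts[3], parts[4]
                fmt = parts[8].split(":")
                gt_i = fmt.index("GT")
                row = []
                for sample in parts[9:]:
                    gt = sample.split(":")[gt_i].replace("|", "/")
                    alleles = gt.split("/")
                    if "." in alleles:
                        row.append(np.nan)
                    else:
                        row.append(float(sum(int(a) != 0 for a in alleles)))
                records.append((chrom, pos, vid, ref, alt))
                dosages.append(row)
        snps = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
        return GenotypeMatrix(accessions, snps,
                              np.asarray(dosages, dtype=float).T)


def filter_maf(geno: GenotypeMatrix,
               min_maf: float = DEFAULT_MIN_MAF) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly greater than min_maf."""
    return geno.subset_snps(geno.maf() > min_maf)


def _mean_impute(dosage: np.ndarray) -> np.ndarray:
    filled = dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(filled))
    filled[idx] = col_mean[idx[1]]
    return filled


def pca_covariates(geno: GenotypeMatrix, k: int = DEFAULT_N_PCS) -> np.ndarray:
    """Top-k principal component scores of the mean-imputed, column-centered
    dosage matrix (orthonormal score vectors; the sign of each component is
    fixed by making its largest-magnitude SNP loading positive)."""
    if k == 0:
        return np.zeros((len(geno.accessions), 0))
    if len(geno.accessions) < k + 1:
        raise ValueError(f"need at least {k + 1} accessions for {k} PCs")
    X = _mean_impute(geno.dosage)
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("degenerate (constant) genotype matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = U[:, :k], Vt[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            U[:, j] = -U[:, j]
    return U


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

@dataclass
class TraitVector:
    trait_id: str  # reaction id + condition
    values: dict[str, float]  # accession -> flux value

    def aligned(self, accessions: list[str]) -> tuple[list[str], np.ndarray]:
        present = [a for a in accessions
                   if a in self.values and math.isfinite(self.values[a])]
        missing = set(self.values) - set(accessions)
        if missing:
            raise ValueError(
                f"trait accessions not in genotype panel: {sorted(missing)}"
            )
        return present, np.array([self.values[a] for a in present])


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    lead_snp: str
    lead_pos: int
    lead_p: float
    members: list[str]


@dataclass
class AssociationScan:
    trait_id: str
    snps: pd.DataFrame  # chrom, pos, id, ref, alt, beta, p_value
    threshold: float
    loci: list[Locus] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.snps[self.snps["p_value"] < self.threshold]


def significance_threshold(n_snps: int) -> float:
    """The 1/n genome-wide significance threshold."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    return 1.0 / n_snps


def association_scan(
    geno: GenotypeMatrix,
    trait: TraitVector,
    covariates: np.ndarray | None = None,
    threshold: float | None = None,
    p_values: np.ndarray | None = None,
) -> AssociationScan:
    """Per-SNP fixed-effect scan: trait ~ intercept + covariates + dosage.

    Missing dosages are mean-imputed per SNP.  Covariates (e.g. PCs from
    :func:`pca_covariates`) are projected out of trait and dosages, and the
    dosage coefficient is tested two-sided with the correct residual
    degrees of freedom.  ``p_values`` short-circuits the scan with
    externally computed values (e.g. from a kinship mixed model).
    """
    if p_values is not None:
        snps = geno.snps.copy()
        snps["beta"] = np.nan
        snps["p_value"] = np.asarray(p_values, dtype=float)
        thr = threshold if threshold is not None \
            else significance_threshold(geno.n_snps)
        return AssociationScan(trait.trait_id, snps, thr)

    acc, y = trait.aligned(geno.accessions)
    if len(acc) < 10:
        raise ValueError("need at least 10 accessions with nonmissing trait")
    rows = [geno.accessions.index(a) for a in acc]
    G = _mean_impute(geno.dosage[rows])
    n = len(acc)

    if covariates is None:
        covariates = np.zeros((len(geno.accessions), 0))
    C = np.asarray(covariates)[rows]
    X0 = np.column_stack([np.ones(n), C])
    # project out intercept + covariates (Frisch-Waugh-Lovell)
    Q, _ = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    df = n - X0.shape[1] - 1
    gtg = np.einsum("ij,ij->j", G_r, G_r)
    gty = G_r.T @ y_r
    yty = float(y_r @ y_r)

    beta = np.zeros(geno.n_snps)
    p = np.ones(geno.n_snps)
    if yty <= 1e-12 * max(1.0, float(y @ y)):
        logger.warning("constant trait %s: all p-values set to 1", trait.trait_id)
    else:
        ok = gtg > 1e-12
        beta[ok] = gty[ok] / gtg[ok]
        rss = yty - beta * gty
        rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / df / gtg)
            t = np.where(ok & (se > 0), beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.clip(p, np.finfo(float).tiny, 1.0)

    snps = geno.snps.copy()
    snps["beta"] = beta
    snps["p_value"] = p
    thr = threshold if threshold is not None \
        else significance_threshold(geno.n_snps)
    return AssociationScan(trait.trait_id, snps, thr)


def clump_loci(scan: AssociationScan,
               window_bp: int = DEFAULT_CLUMP_WINDOW_BP) -> list[Locus]:
    """Merge significant SNPs transitively: consecutive significant SNPs on
    one chromosome at most window_bp apart belong to one locus.  The lead
    SNP is the locus minimum p-value (ties: smaller position)."""
    sig = scan.significant.sort_values(["chrom", "pos"], kind="mergesort")
    loci: list[Locus] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        current: list[pd.Series] = []
        last_pos = None
        for _, row in grp.iterrows():
            if last_pos is not None and row["pos"] - last_pos > window_bp:
                loci.append(_make_locus(str(chrom), current))
                current = []
            current.append(row)
            last_pos = row["pos"]
        if current:
            loci.append(_make_locus(str(chrom), current))
    scan.loci = loci
    return loci


def _make_locus(chrom: str, rows: list[pd.Series]) -> Locus:
    lead = min(rows, key=lambda r: (r["p_value"], r["pos"]))
    return Locus(
        chrom=chrom,
        start=int(min(r["pos"] for r in rows)),
        end=int(max(r["pos"] for r in rows)),
        lead_snp=str(lead["id"]), lead_pos=int(lead["pos"]),
        lead_p=float(lead["p_value"]),
        members=[str(r["id"]) for r in rows],
    )


# ---------------------------------------------------------------------------
# Candidate genes
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: chrom, start, end, gene_id (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def candidate_genes(loci: list[Locus], annotation: pd.DataFrame,
                    window_bp: int = DEFAULT_CLUMP_WINDOW_BP) -> dict[str, list[str]]:
    """Genes overlapping the +-window_bp/2 interval around each lead SNP.

    Returns lead SNP id -> sorted gene ids.
    """
    half = window_bp / 2.0
    out: dict[str, list[str]] = {}
    for locus in loci:
        lo, hi = locus.lead_pos - half, locus.lead_pos + half
        hit = annotation[
            (annotation["chrom"].astype(str) == locus.chrom)
            & (annotation["start"] <= hi)
            & (annotation["end"] >= lo)
        ]
        out[locus.lead_snp] = sorted(hit["gene_id"].astype(str))
    return out


CANDIDATE_CATEGORIES = ("exact_gpr", "gpr_upstream", "gpr_downstream",
                        "transcription_factor", "unknown")


@dataclass
class CandidateGene:
    gene_id: str
    locus: str  # lead SNP id
    category: str
    expression_category: str | None = None


def _neighbor_genes(model: MetabolicModel, trait_reaction: str) \
        -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(exact, upstream, downstream) GPR gene sets for a trait reaction.

    Upstream: genes of reactions able to produce a substrate of the trait
    reaction; downstream: genes of reactions able to consume a product.
    Reversible neighbors count on both sides.
    """
    trait = model.reaction(trait_reaction)
    exact = trait.gpr.genes()
    substrates = {m for m, c in trait.stoichiometry.items() if c < 0}
    products = {m for m, c in trait.stoichiometry.items() if c > 0}
    upstream: set[str] = set()
    downstream: set[str] = set()
    for r in model.reactions:
        if r.id == trait_reaction or r.gpr.is_empty():
            continue
        for m, c in r.stoichiometry.items():
            produces = (c > 0 and r.upper_bound > 0) or (c < 0 and r.lower_bound < 0)
            consumes = (c < 0 and r.upper_bound > 0) or (c > 0 and r.lower_bound < 0)
            if m in substrates and produces:
                upstream |= r.gpr.genes()
            if m in products and consumes:
                downstream |= r.gpr.genes()
    return frozenset(exact), frozenset(upstream), frozenset(downstream)


def classify_candidates(
    genes_by_locus: dict[str, list[str]],
    model: MetabolicModel,
    trait_reaction: str,
    tf_list: set[str],
    expression: dict[str, float] | None = None,
) -> list[CandidateGene]:
    """Classify candidate genes for one trait reaction.

    Precedence: exact GPR > GPR upstream > GPR downstream > transcription
    factor > unknown.  ``expression`` optionally supplies normalized
    leaf-expression levels in [0, 1] for categorization.
    """
    exact, upstream, downstream = _neighbor_genes(model, trait_reaction)
    out = []
    for locus, genes in sorted(genes_by_locus.items()):
        for g in genes:
            if g in exact:
                cat = "exact_gpr"
            elif g in upstream:
                cat = "gpr_upstream"
            elif g in downstream:
                cat = "gpr_downstream"
            elif g in tf_list:
                cat = "transcription_factor"
            else:
                cat = "unknown"
            expr_cat = None
            if expression is not None and g in expression:
                expr_cat = classify_expression(expression[g])
            out.append(CandidateGene(g, locus, cat, expr_cat))
    return out


def classify_expression(normalized_level: float) -> str:
    """Leaf expression category from a level normalized to [0, 1]:
    0 -> not_expressed, (0, 0.3) -> low, [0.3, 0.6] -> intermediate,
    (0.6, 1] -> high."""
    if not (0.0 <= normalized_level <= 1.0):
        raise ValueError(f"expression level {normalized_level} outside [0, 1]")
    if normalized_level == 0.0:
        return "not_expressed"
    if normalized_level < 0.3:
        return "low"
    if normalized_level <= 0.6:
        return "intermediate"
    return "high"


# ---------------------------------------------------------------------------
# Mutant validation
# ---------------------------------------------------------------------------

@dataclass
class CandidateValidation:
    gene_id: str
    assessable: bool
    fold_changes: dict[str, float]  # lipid id -> mutant/WT
    supported: bool


def validate_candidates(
    candidates: list[CandidateGene],
    model: MetabolicModel,
    trait_reaction: str,
    mutant_profiles: dict[str, dict[str, float]],
    wild_type_profile: dict[str, float],
    tf_targets: dict[str, set[str]] | None = None,
    log2fc_threshold: float = 1.0,
) -> list[CandidateValidation]:
    """Mutant/wild-type lipid fold changes for each candidate.

    Enzyme-coding candidates are checked on the lipids participating in the
    trait reaction; TF candidates on the lipids of reactions whose GPR genes
    are among the TF's supplied binding targets.  A candidate is supported
    when any |log2 FC| exceeds the threshold; candidates with no mutant
    profile or no measured lipids are reported as not assessable.
    """
    trait = model.reaction(trait_reaction)
    trait_lipids = set(trait.stoichiometry)
    tf_targets = tf_targets or {}
    out = []
    for cand in candidates:
        if cand.category == "transcription_factor":
            targets = tf_targets.get(cand.gene_id, set())
            lipids: set[str] = set()
            for r in model.reactions:
                if not r.gpr.is_empty() and (r.gpr.genes() & targets):
                    lipids |= set(r.stoichiometry)
        else:
            lipids = trait_lipids
        profile = mutant_profiles.get(cand.gene_id)
        if profile is None:
            out.append(CandidateValidation(cand.gene_id, False, {}, False))
            continue
        fcs: dict[str, float] = {}
        for lipid in sorted(lipids):
            if lipid in profile and lipid in wild_type_profile \
                    and wild_type_profile[lipid] > 0:
                fcs[lipid] = profile[lipid] / wild_type_profile[lipid]
        if not fcs:
            out.append(CandidateValidation(cand.gene_id, False, {}, False))
            continue
        supported = any(
            fc > 0 and abs(math.log2(fc)) > log2fc_threshold
            for fc in fcs.values()
        )
        out.append(CandidateValidation(cand.gene_id, True, fcs, supported))
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class FgwaResult:
    scan: AssociationScan
    loci: list[Locus]
    genes_by_locus: dict[str, list[str]]
    candidates: list[CandidateGene]


def run_fgwa(
    geno: GenotypeMatrix,
    trait: TraitVector,
    annotation: pd.DataFrame,
    model: MetabolicModel,
    trait_reaction: str,
    tf_list: set[str] | None = None,
    min_maf: float = DEFAULT_MIN_MAF,
    n_pcs: int = DEFAULT_N_PCS,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    expression: dict[str, float] | None = None,
) -> FgwaResult:
    """MAF filter -> PC covariates -> scan -> 1/n threshold -> 20-kb clumping
    -> candidate genes -> GPR/TF classification."""
    filtered = filter_maf(geno, min_maf)
    covs = pca_covariates(filtered, n_pcs) if n_pcs else None
    scan = association_scan(filtered, trait, covs)
    loci = clump_loci(scan, window_bp)
    genes = candidate_genes(loci, annotation, window_bp)
    cands = classify_candidates(genes, model, trait_reaction,
                                tf_list or set(), expression)
    return FgwaResult(scan, loci, genes, cands)
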