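"""fGWA post-processing: MAF filter, PCs, scan, clumping, classification."""
import numpy as np
import pandas as pd
import pytest

from plm.fgwa import (
    AssociationScan,
    GenotypeMatrix,
    Locus,
    TraitVector,
    association_scan,
    candidate_genes,
    classify_candidates,
    classify_expression,
    clump_loci,
    filter_maf,
    pca_covariates,
    significance_threshold,
    validate_candidates,
)

from conftest import toy_model


def _geno(dosage, positions=None, chroms=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions or list(range(1000, 1000 + 1000 * m, 1000))
    chroms = chroms or ["1"] * m
    snps = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "id": [f"s{i}" for i in range(m)],
        "ref": ["A"] * m, "alt": ["T"] * m,
    })
    return GenotypeMatrix([f"a{i}" for i in range(n)], snps, dosage)


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def test_maf_filter_strict_boundary():
    # col 0: freq 0.03 -> removed; col 1: exactly 0.05 -> removed (strict);
    # col 2: 0.2 -> kept
    n = 100
    d = np.zeros((n, 3))
    d[:3, 0] = 2  # 6/200 = 0.03
    d[:5, 1] = 2  # 10/200 = 0.05
    d[:20, 2] = 2  # 0.2
    geno = _geno(d)
    kept = filter_maf(geno, 0.05)
    assert list(kept.snps["id"]) == ["s2"]


def test_maf_uses_minor_allele_and_ignores_missing():
    d = np.full((10, 2), 2.0)
    d[:1, 0] = 0  # freq 0.9 -> minor 0.1
    d[0, 1] = np.nan
    d[1:, 1] = 2.0  # all alt among observed -> maf 0
    geno = _geno(d)
    assert geno.maf() == pytest.approx([0.1, 0.0])


def test_maf_matches_brute_force_counting():
    rng = np.random.default_rng(0)
    d = rng.choice([0, 1, 2, np.nan], p=[0.3, 0.3, 0.3, 0.1], size=(50, 40))
    geno = _geno(d)
    kept = set(filter_maf(geno, 0.05).snps["id"])
    expected = set()
    for j in range(40):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.sum() / (2 * len(obs))
        if min(freq, 1 - freq) > 0.05:
            expected.add(f"s{j}")
    assert kept == expected


# ---------------------------------------------------------------------------
# PCA covariates
# ---------------------------------------------------------------------------

def test_pca_separates_planted_subpopulations():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(1)
    n, m = 100, 400
    p1, p2 = rng.uniform(0.1, 0.9, m), rng.uniform(0.1, 0.9, m)
    d = np.vstack([rng.binomial(2, p1, size=(50, m)),
                   rng.binomial(2, p2, size=(50, m))]).astype(float)
    covs = pca_covariates(_geno(d), k=3)
    labels = np.repeat([0, 1], 50)
    assert silhouette_score(covs[:, :1], labels) > 0.8


def test_pca_zero_components_and_orthonormality():
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, size=(30, 50)).astype(float)
    assert pca_covariates(_geno(d), k=0).shape == (30, 0)
    covs = pca_covariates(_geno(d), k=4)
    gram = covs.T @ covs
    assert np.allclose(gram, np.eye(4), atol=1e-9)


def test_pca_sign_is_deterministic():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(40, 60)).astype(float)
    a = pca_covariates(_geno(d), k=3)
    b = pca_covariates(_geno(d.copy()), k=3)
    assert np.array_equal(a, b)


def test_pca_constant_matrix_errors():
    with pytest.raises(ValueError):
        pca_covariates(_geno(np.ones((10, 5))), k=2)


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

def test_trait_equal_to_dosage_gives_scan_minimum_at_that_snp():
    rng = np.random.default_rng(4)
    d = rng.integers(0, 3, size=(60, 30)).astype(float)
    geno = _geno(d)
    trait = TraitVector("t", {a: float(d[i, 7])
                              for i, a in enumerate(geno.accessions)})
    scan = association_scan(geno, trait)
    assert scan.snps["p_value"].idxmin() == 7


def test_planted_effect_detected_at_stringent_threshold():
    rng = np.random.default_rng(5)
    n, m = 200, 500
    d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
    geno = _geno(d)
    causal = d[:, 11]
    z = (causal - causal.mean()) / causal.std()
    y = np.sqrt(0.25) * z + np.sqrt(0.75) * rng.normal(size=n)
    trait = TraitVector("t", dict(zip(geno.accessions, y)))
    scan = association_scan(geno, trait, threshold=1.0 / 5000)
    assert scan.snps.loc[11, "p_value"] < 1.0 / 5000


def test_constant_trait_all_p_one():
    rng = np.random.default_rng(6)
    d = rng.integers(0, 3, size=(20, 10)).astype(float)
    geno = _geno(d)
    trait = TraitVector("t", {a: 1.0 for a in geno.accessions})
    scan = association_scan(geno, trait)
    assert (scan.snps["p_value"] == 1.0).all()


def test_external_p_values_short_circuit():
    d = np.zeros((12, 3))
    geno = _geno(d)
    trait = TraitVector("t", {a: 0.0 for a in geno.accessions})
    scan = association_scan(geno, trait, p_values=np.array([0.5, 1e-8, 0.9]),
                            threshold=1e-4)
    assert list(scan.significant["id"]) == ["s1"]


def test_scan_requires_enough_accessions():
    geno = _geno(np.zeros((5, 3)))
    trait = TraitVector("t", {a: 1.0 for a in geno.accessions})
    with pytest.raises(ValueError):
        association_scan(geno, trait)


# ---------------------------------------------------------------------------
# Threshold and clumping
# ---------------------------------------------------------------------------

def test_significance_threshold_is_reciprocal():
    assert significance_threshold(5000) == pytest.approx(2e-4)
    assert significance_threshold(1) == 1.0
    assert float(f"{significance_threshold(1_329_408):.4g}") \
        == pytest.approx(7.522e-7)
    with pytest.raises(ValueError):
        significance_threshold(0)


def _scan_from(positions, pvals, chroms=None, threshold=1e-3):
    m = len(positions)
    snps = pd.DataFrame({
        "chrom": chroms or ["1"] * m, "pos": positions,
        "id": [f"s{i}" for i in range(m)],
        "ref": "A", "alt": "T", "beta": 0.0, "p_value": pvals,
    })
    return AssociationScan("t", snps, threshold)


def test_clump_example_two_loci():
    scan = _scan_from([1_000, 15_000, 40_000], [1e-6, 1e-8, 1e-5])
    loci = clump_loci(scan, window_bp=20_000)
    assert len(loci) == 2
    assert loci[0].lead_pos == 15_000  # most significant of the first pair
    assert loci[1].lead_pos == 40_000
    assert loci[0].members == ["s0", "s1"]


def test_single_snp_single_locus_and_cross_chromosome_split():
    scan = _scan_from([100], [1e-9])
    assert len(clump_loci(scan)) == 1
    scan = _scan_from([100, 5_000], [1e-9, 1e-9], chroms=["1", "2"])
    assert len(clump_loci(scan)) == 2


def test_lead_snp_tie_breaks_to_smaller_position():
    scan = _scan_from([1_000, 2_000], [1e-8, 1e-8])
    assert clump_loci(scan)[0].lead_pos == 1_000


def test_clump_matches_interval_merge_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(10):
        m = 60
        positions = np.sort(rng.choice(np.arange(1, 500_000), m, replace=False))
        pvals = 10 ** rng.uniform(-9, 0, m)
        scan = _scan_from([int(p) for p in positions], pvals)
        loci = clump_loci(scan, window_bp=20_000)
        sig = [(int(p), pv) for p, pv in zip(positions, pvals) if pv < 1e-3]
        groups, current = [], []
        for pos, pv in sig:
            if current and pos - current[-1][0] > 20_000:
                groups.append(current)
                current = []
            current.append((pos, pv))
        if current:
            groups.append(current)
        assert len(loci) == len(groups)
        for locus, grp in zip(loci, groups):
            assert locus.lead_pos == min(grp, key=lambda x: (x[1], x[0]))[0]
            assert (locus.start, locus.end) == (grp[0][0], grp[-1][0])


def test_clumping_idempotent_and_permutation_invariant():
    rng = np.random.default_rng(8)
    positions = np.sort(rng.choice(np.arange(1, 300_000), 40, replace=False))
    pvals = 10 ** rng.uniform(-8, 0, 40)
    scan = _scan_from([int(p) for p in positions], pvals)
    loci1 = clump_loci(scan)
    loci2 = clump_loci(scan)
    assert [(l.lead_snp, l.members) for l in loci1] \
        == [(l.lead_snp, l.members) for l in loci2]
    perm = rng.permutation(40)
    snps = scan.snps.iloc[perm].sort_values(["chrom", "pos"]).reset_index(drop=True)
    loci3 = clump_loci(AssociationScan("t", snps, scan.threshold))
    assert [(l.lead_pos, l.start, l.end) for l in loci1] \
        == [(l.lead_pos, l.start, l.end) for l in loci3]


# ---------------------------------------------------------------------------
# Candidate genes and classification
# ---------------------------------------------------------------------------

def _locus(lead_pos, chrom="1"):
    return Locus(chrom, lead_pos, lead_pos, "lead", lead_pos, 1e-9, ["lead"])


def test_gene_spanning_lead_snp_returned_distant_gene_not():
    ann = pd.DataFrame({
        "chrom": ["1", "1"], "start": [9_000, 60_000],
        "end": [12_000, 63_000], "gene_id": ["near", "far"],
    })
    genes = candidate_genes([_locus(10_000)], ann, window_bp=20_000)
    assert genes["lead"] == ["near"]


def test_candidate_genes_match_brute_force_overlap():
    rng = np.random.default_rng(9)
    starts = np.sort(rng.choice(np.arange(1, 200_000), 50, replace=False))
    ann = pd.DataFrame({
        "chrom": "1", "start": starts, "end": starts + 2_500,
        "gene_id": [f"G{i}" for i in range(50)],
    })
    for lead in (5_000, 77_777, 150_001):
        got = candidate_genes([_locus(lead)], ann, window_bp=20_000)["lead"]
        lo, hi = lead - 10_000, lead + 10_000
        expected = sorted(
            f"G{i}" for i, s in enumerate(starts)
            if s <= hi and s + 2_500 >= lo)
        assert got == expected


def _trait_model():
    return toy_model([
        ("make_sub", {"pre_c": -1.0, "sub_c": 1.0}, 0, 10, "g_up"),
        ("trait", {"sub_c": -1.0, "prod_c": 1.0}, 0, 10, "g_exact"),
        ("use_prod", {"prod_c": -1.0, "post_c": 1.0}, 0, 10, "g_down"),
        ("elsewhere", {"pre_c": -1.0, "post_c": 1.0}, 0, 10, "g_off"),
    ])


def test_candidate_classification_precedence():
    m = _trait_model()
    genes = {"lead": ["g_exact", "g_up", "g_down", "g_tf", "g_nobody"]}
    cands = classify_candidates(genes, m, "trait",
                                tf_list={"g_tf", "g_exact"})
    by_gene = {c.gene_id: c.category for c in cands}
    assert by_gene == {
        "g_exact": "exact_gpr",  # exact beats TF
        "g_up": "gpr_upstream",
        "g_down": "gpr_downstream",
        "g_tf": "transcription_factor",
        "g_nobody": "unknown",
    }


def test_reversible_neighbors_count_both_directions():
    m = toy_model([
        ("rev", {"sub_c": 1.0, "x_c": -1.0}, -10, 10, "g_rev"),
        ("trait", {"sub_c": -1.0, "prod_c": 1.0}, 0, 10, "g_exact"),
    ])
    cands = classify_candidates({"l": ["g_rev"]}, m, "trait", set())
    assert cands[0].category == "gpr_upstream"


def test_classification_matches_adjacency_oracle():
    rng = np.random.default_rng(10)
    mets = [f"x{i}_c" for i in range(8)]
    for rep in range(5):
        specs = []
        for j in range(14):
            pair = rng.choice(mets, size=2, replace=False)
            lb = 0.0 if rng.random() < 0.7 else -10.0
            specs.append((f"r{j}", {pair[0]: -1.0, pair[1]: 1.0}, lb, 10.0,
                          f"gene{j}"))
        m = toy_model(specs)
        trait = m.reaction("r0")
        subs = {k for k, v in trait.stoichiometry.items() if v < 0}
        prods = {k for k, v in trait.stoichiometry.items() if v > 0}
        up, down = set(), set()
        for r in m.reactions:
            if r.id == "r0":
                continue
            for mid, coef in r.stoichiometry.items():
                can_produce = coef > 0 or r.lower_bound < 0
                can_consume = coef < 0 or r.lower_bound < 0
                if mid in subs and can_produce:
                    up |= r.gpr.genes()
                if mid in prods and can_consume:
                    down |= r.gpr.genes()
        genes = [f"gene{j}" for j in range(14)]
        cands = classify_candidates({"l": genes}, m, "r0", set())
        for c in cands:
            if c.gene_id in trait.gpr.genes():
                assert c.category == "exact_gpr"
            elif c.gene_id in up:
                assert c.category == "gpr_upstream"
            elif c.gene_id in down:
                assert c.category == "gpr_downstream"
            else:
                assert c.category == "unknown"


@pytest.mark.parametrize("level,expected", [
    (0.0, "not_expressed"),
    (0.1, "low"),
    (0.3, "intermediate"),
    (0.45, "intermediate"),
    (0.6, "intermediate"),
    (0.61, "high"),
    (1.0, "high"),
])
def test_expression_categories(level, expected):
    assert classify_expression(level) == expected


def test_expression_out_of_range_errors():
    with pytest.raises(ValueError):
        classify_expression(-0.1)
    with pytest.raises(ValueError):
        classify_expression(1.2)


# ---------------------------------------------------------------------------
# Mutant validation
# ---------------------------------------------------------------------------

def test_validate_candidates_fold_changes_and_support():
    from plm.fgwa import CandidateGene

    m = _trait_model()
    cands = [CandidateGene("g_exact", "l", "exact_gpr"),
             CandidateGene("g_absent", "l", "unknown"),
             CandidateGene("g_nolipids", "l", "unknown")]
    wild_type = {"sub_c": 2.0, "prod_c": 4.0}
    mutants = {
        "g_exact": {"sub_c": 1.0, "prod_c": 16.0},  # FC 0.5 and 4.0
        "g_nolipids": {"unrelated": 1.0},
    }
    out = validate_candidates(cands, m, "trait", mutants, wild_type,
                              log2fc_threshold=1.0)
    by_gene = {v.gene_id: v for v in out}
    assert by_gene["g_exact"].fold_changes["sub_c"] == pytest.approx(0.5)
    assert by_gene["g_exact"].supported  # |log2 4.0| = 2 > 1
    assert not by_gene["g_absent"].assessable
    assert not by_gene["g_nolipids"].assessable


def test_planted_twofold_change_not_supported_at_strict_threshold():
    from plm.fgwa import CandidateGene

    m = _trait_model()
    cands = [CandidateGene("g_exact", "l", "exact_gpr")]
    out = validate_candidates(cands, m, "trait", {"g_exact": {"sub_c": 4.0}},
                              {"sub_c": 2.0}, log2fc_threshold=1.5)
    assert not out[0].supported  # |log2 2| = 1 < 1.5


def test_tf_candidates_use_binding_targets():
    from plm.fgwa import CandidateGene

    m = _trait_model()
    cands = [CandidateGene("tf1", "l", "transcription_factor")]
    out = validate_candidates(
        cands, m, "trait", {"tf1": {"post_c": 8.0}}, {"post_c": 2.0},
        tf_targets={"tf1": {"g_down"}}, log2fc_threshold=1.0)
    assert out[0].assessable and out[0].supported


# ---------------------------------------------------------------------------
# Genotype IO
# ---------------------------------------------------------------------------

def test_vcf_and_tsv_readers_agree(tmp_path):
    vcf = """##fileformat=VCFv4.2
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta0\ta1\ta2
1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\tsnp2\tG\tC\t.\t.\t.\tGT\t1|1\t./.\t0/0
2\t50\tsnp3\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\t0/1
"""
    vcf_path = tmp_path / "g.vcf"
    vcf_path.write_text(vcf)
    g = GenotypeMatrix.from_vcf(vcf_path)
    assert g.accessions == ["a0", "a1", "a2"]
    assert g.dosage[:, 0] == pytest.approx([0, 1, 2])
    assert np.isnan(g.dosage[1, 1])

    tsv = tmp_path / "g.tsv"
    df = g.snps.copy()
    for i, acc in enumerate(g.accessions):
        df[acc] = g.dosage[i]
    df.to_csv(tsv, sep="\t", index=False)
    g2 = GenotypeMatrix.from_tsv(tsv)
    assert g2.accessions == g.accessions
    assert np.allclose(g2.dosage, g.dosage, equal_nan=True)
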