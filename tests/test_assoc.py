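"""Association statistics: OLS, genomic control, power, replication."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrqtl.assoc import (
    CHI2_1_MEDIAN,
    PowerSpec,
    fit_additive,
    gc_adjust,
    genomic_lambda,
    load_qtl_catalog,
    load_replication_catalog,
    manhattan_data,
    qq_data,
    qtl_power,
    replication_compare,
    run_gwas,
)
from emrqtl.plink import GenotypeMatrix


def normal_equations_fit(g, y, X=None):
    """Independent oracle: explicit (X'X)^-1 X'y with textbook SE."""
    n = len(y)
    cols = [np.ones(n), np.asarray(g, float)]
    if X is not None:
        X = np.asarray(X, float)
        cols.extend(X[:, j] for j in range(X.shape[1]))
    D = np.column_stack(cols)
    xtx_inv = np.linalg.inv(D.T @ D)
    beta = xtx_inv @ D.T @ y
    resid = y - D @ beta
    df = n - D.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * xtx_inv[1, 1])
    t = beta[1] / se
    return beta[1], se, 2 * stats.t.sf(abs(t), df), t * t / (t * t + df)


def test_exact_fit_recovers_slope():
    g = np.array([0, 1, 2, 0, 1, 2])
    res = fit_additive(g, 2.0 * g)
    assert res.beta == pytest.approx(2.0)
    assert res.r2_partial == pytest.approx(1.0)
    assert res.p < 1e-30


def test_fit_matches_normal_equations_on_random_problems():
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(20, 60))
        k = int(rng.integers(0, 3))
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        if np.ptp(g) == 0:
            continue
        X = rng.normal(size=(n, k)) if k else None
        y = 0.3 * g + rng.normal(size=n)
        res = fit_additive(g, y, X)
        b, se, p, r2 = normal_equations_fit(g, y, X)
        assert res.beta == pytest.approx(b, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)
        assert res.r2_partial == pytest.approx(r2, abs=1e-10)


def test_fit_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 200
    g = rng.binomial(2, 0.3, n).astype(float)
    X = rng.normal(size=(n, 2))
    y = 0.2 * g + X @ [0.5, -0.3] + rng.normal(size=n)
    res = fit_additive(g, y, X)
    model = sm.OLS(y, sm.add_constant(np.column_stack([g, X]))).fit()
    assert res.beta == pytest.approx(model.params[1], abs=1e-10)
    assert res.se == pytest.approx(model.bse[1], abs=1e-10)
    assert res.p == pytest.approx(model.pvalues[1], rel=1e-8)


def test_missing_genotypes_complete_case():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.4, 100).astype(float)
    y = 0.5 * g + rng.normal(size=100)
    g_miss = g.copy()
    g_miss[:10] = -1
    res = fit_additive(g_miss, y)
    ref = fit_additive(g[10:], y[10:])
    assert res.n_used == 90
    assert res.beta == pytest.approx(ref.beta)


def test_constant_genotype_flagged_not_raised():
    res = fit_additive(np.ones(30), np.random.default_rng(0).normal(size=30))
    assert res.flag == "constant-genotype" and np.isnan(res.beta)


def test_collinear_covariates_rejected():
    rng = np.random.default_rng(4)
    g = rng.binomial(2, 0.4, 50).astype(float)
    X = np.column_stack([g, g * 2.0])
    with pytest.raises(ValueError, match="collinear"):
        fit_additive(g, rng.normal(size=50), X)


def _toy_gwas(n=300, m=40, seed=5, missing=False):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, m)[None, :], size=(n, m)).astype(np.int8)
    if missing:
        d[rng.random(d.shape) < 0.02] = -1
    markers = pd.DataFrame(
        {"marker_id": [f"s{j}" for j in range(m)], "chrom": 1,
         "bp": np.arange(m) * 100 + 1, "a1": "A", "a2": "G"}
    )
    G = GenotypeMatrix(dosage=d, samples=[f"P{i}" for i in range(n)], markers=markers)
    pheno = pd.DataFrame(
        {
            "patient_id": G.samples,
            "HGB": rng.normal(14, 1.3, n) + 0.4 * d[:, 3],
            "age": rng.normal(60, 8, n),
            "male": rng.integers(0, 2, n),
            "pad": rng.integers(0, 2, n),
        }
    )
    return G, pheno


def test_run_gwas_fast_path_equals_per_marker_fit():
    G, pheno = _toy_gwas()
    gwas = run_gwas(G, pheno, traits=["HGB"])
    X = pheno[["age", "male", "pad"]].to_numpy(float)
    for j in (0, 3, 17):
        ref = fit_additive(G.dosage[:, j], pheno["HGB"].to_numpy(), X)
        row = gwas.iloc[j]
        assert row["beta"] == pytest.approx(ref.beta, abs=1e-10)
        assert row["se"] == pytest.approx(ref.se, abs=1e-10)
        assert row["p"] == pytest.approx(ref.p, rel=1e-8)


def test_run_gwas_missing_genotype_path():
    G, pheno = _toy_gwas(missing=True)
    gwas = run_gwas(G, pheno, traits=["HGB"])
    X = pheno[["age", "male", "pad"]].to_numpy(float)
    ref = fit_additive(G.dosage[:, 7], pheno["HGB"].to_numpy(), X)
    row = gwas.iloc[7]
    assert row["n_used"] == ref.n_used
    assert row["beta"] == pytest.approx(ref.beta, abs=1e-10)


def test_run_gwas_aligns_by_id_not_order():
    G, pheno = _toy_gwas()
    shuffled = pheno.sample(frac=1.0, random_state=7).reset_index(drop=True)
    a = run_gwas(G, pheno, traits=["HGB"])
    b = run_gwas(G, shuffled, traits=["HGB"])
    pd.testing.assert_frame_equal(a, b)


def test_run_gwas_requires_overlap():
    G, pheno = _toy_gwas()
    pheno["patient_id"] = "X" + pheno["patient_id"]
    with pytest.raises(ValueError, match="overlap"):
        run_gwas(G, pheno, traits=["HGB"])


def test_lambda_definition():
    assert genomic_lambda(np.full(500, CHI2_1_MEDIAN)) == pytest.approx(1.0)
    assert genomic_lambda(np.full(500, 2 * CHI2_1_MEDIAN)) == pytest.approx(2.0)


def test_gc_adjust_identity_and_monotonicity():
    G, pheno = _toy_gwas()
    gwas = run_gwas(G, pheno, traits=["HGB"])
    same = gc_adjust(gwas, 1.0)
    np.testing.assert_allclose(
        same["p_gc"], stats.chi2.sf(gwas["t"] ** 2, 1), rtol=1e-12
    )
    adj = gc_adjust(gwas, 2.0)
    assert (adj["p_gc"] >= same["p_gc"] - 1e-15).all()
    # chi2 29.72 at lambda 2 -> adjusted chi2 14.86
    assert stats.chi2.sf(29.72 / 2.0, 1) == pytest.approx(
        float(
            gc_adjust(
                gwas.assign(t=np.sqrt(29.72)), 2.0
            )["p_gc"].iloc[0]
        )
    )


def test_deflation_never_applied():
    G, pheno = _toy_gwas()
    gwas = run_gwas(G, pheno, traits=["HGB"])
    adj = gc_adjust(gwas, 0.9)
    np.testing.assert_allclose(adj["p_gc"], stats.chi2.sf(gwas["t"] ** 2, 1), rtol=1e-12)


def test_qq_data_single_and_uniform_grid():
    one = qq_data(pd.DataFrame({"p": [0.5]}))
    assert one["expected"].iloc[0] == pytest.approx(np.log10(2))
    assert one["observed"].iloc[0] == pytest.approx(np.log10(2))
    m = 99
    grid = pd.DataFrame({"p": np.arange(1, m + 1) / (m + 1)})
    qq = qq_data(grid)
    np.testing.assert_allclose(qq["expected"], qq["observed"], atol=1e-12)
    assert len(qq) == m


def test_manhattan_length_and_threshold():
    G, pheno = _toy_gwas()
    gwas = run_gwas(G, pheno, traits=["HGB"])
    man = manhattan_data(gwas)
    assert len(man) == np.isfinite(gwas["p"]).sum()
    assert man.attrs["threshold"] == 5e-8


def test_power_null_limit_and_monotonicity():
    small = qtl_power(PowerSpec(n=1000, r2=1e-9, alpha=0.05))
    assert small == pytest.approx(0.05, rel=1e-3)
    grid_n = [qtl_power(PowerSpec(n=n, r2=0.01)) for n in (1000, 2000, 4000)]
    assert grid_n[0] < grid_n[1] < grid_n[2]
    grid_r = [qtl_power(PowerSpec(n=3000, r2=r)) for r in (0.005, 0.01, 0.02)]
    assert grid_r[0] < grid_r[1] < grid_r[2]


def test_power_simulation_agrees_with_analytic():
    spec = PowerSpec(n=800, r2=0.02, alpha=1e-4)
    analytic = qtl_power(spec)
    sim = qtl_power(spec, method="simulation", reps=400, seed=1)
    mc_se = np.sqrt(analytic * (1 - analytic) / 400)
    assert abs(sim - analytic) < 3 * mc_se


def test_power_spec_validation():
    with pytest.raises(ValueError):
        qtl_power(PowerSpec(n=3000, r2=0.0))
    with pytest.raises(ValueError):
        qtl_power(PowerSpec(n=3000, r2=0.01, alpha=1.5))


def _gwas_row(marker, trait, beta, allele, other="G"):
    return pd.DataFrame(
        [{"marker_id": marker, "trait": trait, "effect_allele": allele,
          "other_allele": other, "eaf": 0.3, "beta": beta}]
    )


def test_replication_same_allele_concordant():
    cat = pd.DataFrame(
        [{"snp": "rs855791", "trait": "MCV", "effect_allele": "A",
          "beta": -0.127, "study": "prior"}]
    )
    out = replication_compare(_gwas_row("rs855791", "MCV", -0.620, "A", other="G"), cat)
    assert out["status"].iloc[0] == "matched"
    assert bool(out["concordant"].iloc[0])


def test_replication_flip_on_other_allele():
    # catalog reports the major allele: beta flips sign during harmonization
    cat = pd.DataFrame(
        [{"snp": "rs4895441", "trait": "MCV", "effect_allele": "A",
          "beta": -0.008, "study": "prior"}]
    )
    out = replication_compare(_gwas_row("rs4895441", "MCV", 0.854, "G", other="A"), cat)
    assert out["status"].iloc[0] == "matched-flipped"
    assert out["catalog_beta"].iloc[0] == pytest.approx(0.008)
    assert bool(out["concordant"].iloc[0])


def test_replication_no_match_row_emitted():
    cat = pd.DataFrame(
        [{"snp": "rsX", "trait": "MCV", "effect_allele": "A", "beta": 1.0,
          "study": "prior"}]
    )
    out = replication_compare(_gwas_row("rsY", "MCV", 0.5, "A"), cat)
    assert out["status"].iloc[0] == "no match"


def test_replication_strand_ambiguous_flagged():
    cat = pd.DataFrame(
        [{"snp": "rs1", "trait": "HGB", "effect_allele": "A", "beta": 0.1,
          "study": "prior"}]
    )
    out = replication_compare(_gwas_row("rs1", "HGB", 0.2, "A", other="T"), cat)
    assert "strand-ambiguous" in out["status"].iloc[0]


def test_replication_allele_mismatch_flagged():
    cat = pd.DataFrame(
        [{"snp": "rs1", "trait": "HGB", "effect_allele": "C", "beta": 0.1,
          "study": "prior"}]
    )
    out = replication_compare(_gwas_row("rs1", "HGB", 0.2, "A", other="G"), cat)
    assert out["status"].iloc[0] == "allele mismatch"


def test_bundled_catalogs_are_coherent():
    cat = load_qtl_catalog()
    assert len(cat) == 25
    assert (cat["maf"] <= 0.5).all() and (cat["se"] > 0).all()
    rep = load_replication_catalog()
    # where the same SNP + allele was reported before, directions agree
    same = rep[(rep["snp"] == rep["ref_snp"]) &
               (rep["effect_allele"] == rep["ref_effect_allele"])]
    assert len(same) > 0
    assert (np.sign(same["beta"]) == np.sign(same["ref_beta"])).all()
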