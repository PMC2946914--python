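"""Validation experiments: calibration, recovery and oracle checks.

These harnesses measure the pipeline's statistical behaviour under the
generator's study conditions — null calibration of the GWAS, recovery
of planted QTL effects, agreement of the production filter with the
generator's independent truth labels, and numerical agreement of the
statistics with standalone oracle implementations (log-factorial
enumeration for the exact HWE test, explicit normal equations for OLS).
The oracles here deliberately share no code with the production paths
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .aggregate import aggregate_median
from .assoc import PowerSpec, fit_additive, genomic_lambda, load_qtl_catalog, qtl_power, run_gwas
from .filters import run_filter
from .qc import hwe_exact_test
from .simulate import (
    CausalEffect,
    SimConfig,
    inject_genetic_effects,
    simulate_dataset,
    simulate_genotypes,
    simulate_lab_series,
    simulate_patients,
)
from .traits import TRAITS


def subseeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(int(seed) % (2**31)).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# power

def power_study(seed: int, n: int = 3000, r2: float = 0.015, alpha: float = 5e-8,
                maf: float = 0.05, reps: int = 2000) -> dict:
    """Analytic vs Monte-Carlo power at the study's design point."""
    spec = PowerSpec(n=n, r2=r2, alpha=alpha, maf=maf)
    analytic = qtl_power(spec, "analytic")
    sim = qtl_power(spec, "simulation", reps=reps, seed=seed)
    mc_se = float(np.sqrt(analytic * (1 - analytic) / reps))
    return {"analytic": analytic, "simulation": sim, "mc_se": mc_se, "reps": reps}


# ---------------------------------------------------------------------------
# null calibration

def null_calibration(seed: int, n_patients: int = 3000, m_snps: int = 10000) -> dict:
    """GWAS of all six traits with no causal effects: per-trait
    lambda_GC and the fraction of P < 0.05."""
    cfg = SimConfig(n_patients=n_patients, m_snps=m_snps, seed=seed)
    pats = simulate_patients(cfg)
    genotypes = simulate_genotypes(pats, cfg)
    labs = simulate_lab_series(pats, cfg)
    pheno = aggregate_median(labs, covariates=pats[["patient_id", "age", "male", "pad"]])
    gwas = run_gwas(genotypes, pheno)
    out = {"n_patients": n_patients, "m_snps": m_snps, "lambda": {}, "frac_p05": {}}
    for t in TRAITS:
        sub = gwas[gwas["trait"] == t]
        out["lambda"][t] = genomic_lambda(sub)
        out["frac_p05"][t] = float((sub["p"] < 0.05).mean())
    return out


# ---------------------------------------------------------------------------
# planted-QTL recovery

def planted_recovery(
    seed: int,
    reps: int = 200,
    n_patients: int = 3000,
    r2: float = 0.02,
    trait: str = "HGB",
    alpha: float = 5e-8,
) -> dict:
    """Replicated single-QTL recovery.

    Each replicate: fresh cohort, one marker, effect planted at
    variance fraction ``r2`` of the trait, one lab draw per patient
    (so the analyzed phenotype's variance equals the configured trait
    variance), median aggregation, additive fit with the age/sex/PAD
    covariates in the model (their effects are zero in this design so
    the SNP's partial R^2 estimates exactly ``r2``).
    """
    hits = covered = 0
    r2_hat = []
    for rep, s in enumerate(subseeds(seed, reps)):
        cfg = SimConfig(
            n_patients=n_patients,
            m_snps=1,
            visit_rate=0.0,
            seed=s,
            covariate_effects={},
            causal_spec=[CausalEffect(0, trait, r2)],
        )
        pats = simulate_patients(cfg)
        genotypes = simulate_genotypes(pats, cfg)
        pats, causal = inject_genetic_effects(pats, genotypes, cfg.causal_spec, cfg)
        labs = simulate_lab_series(pats, cfg)
        pheno = aggregate_median(
            labs[labs["trait"] == trait],
            covariates=pats[["patient_id", "age", "male", "pad"]],
        ).set_index("patient_id").loc[genotypes.samples]
        res = fit_additive(
            genotypes.dosage[:, 0],
            pheno[trait].to_numpy(),
            pheno[["age", "male", "pad"]].to_numpy(float),
        )
        true_beta = causal["beta"].iloc[0]
        hits += res.p < alpha
        covered += abs(res.beta - true_beta) <= 2 * res.se
        r2_hat.append(res.r2_partial)
    r2_hat = np.asarray(r2_hat)
    analytic = qtl_power(PowerSpec(n=n_patients, r2=r2, alpha=alpha))
    return {
        "reps": reps,
        "r2": r2,
        "detection_rate": hits / reps,
        "analytic_power": analytic,
        "power_mc_se": float(np.sqrt(analytic * (1 - analytic) / reps)),
        "beta_coverage_2se": covered / reps,
        "mean_r2_hat": float(r2_hat.mean()),
        "se_mean_r2_hat": float(r2_hat.std(ddof=1) / np.sqrt(reps)),
    }


# ---------------------------------------------------------------------------
# filter-vs-truth oracle

def filter_oracle_check(seed: int, n_fixtures: int = 50, n_patients: int = 50) -> dict:
    """Exact agreement of the production filter with the generator's
    independently computed truth labels, over random fixtures."""
    agree = total = 0
    reconciled = True
    seeds = subseeds(seed, n_fixtures)
    for s in seeds:
        ds = simulate_dataset(SimConfig(n_patients=n_patients, m_snps=2, seed=s))
        result, report = run_filter(ds.labs, ds.events, ds.notes)
        dec = (result["decision"] == "exclude").to_numpy()
        truth = ds.truth.values["excluded"].to_numpy()
        agree += int((dec == truth).sum())
        total += len(dec)
        reconciled &= (
            report["values_kept"] + report["values_excluded"] == len(ds.labs)
        )
    return {
        "fixtures": n_fixtures,
        "seeds": seeds,
        "values": total,
        "agreement": agree / total,
        "reconciled": reconciled,
    }


# ---------------------------------------------------------------------------
# HWE oracle

def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Log-factorial enumeration of the Levene–Haldane conditional
    distribution; shares no code with :func:`emrqtl.qc.hwe_exact_test`."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    na, nb = min(na, 2 * n - na), max(na, 2 * n - na)
    hets = np.arange(na % 2, na + 1, 2)
    logp = (
        hets * np.log(2)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((nb - hets) / 2 + 1)
        + gammaln(na + 1)
        + gammaln(nb + 1)
        + gammaln(n + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_sweep(max_total: int = 50) -> dict:
    """Exhaustive comparison with the enumeration oracle over every
    genotype table with total count <= max_total."""
    worst = 0.0
    checked = 0
    for n in range(1, max_total + 1):
        for naa in range(n + 1):
            for nab in range(n - naa + 1):
                nbb = n - naa - nab
                diff = abs(
                    hwe_exact_test(naa, nab, nbb) - hwe_enumeration_oracle(naa, nab, nbb)
                )
                worst = max(worst, diff)
                checked += 1
    return {"tables": checked, "max_abs_diff": worst}


def hwe_rejection_rate(seed: int, m: int = 100000, n: int = 3000,
                       alpha: float = 0.001) -> dict:
    """Empirical size of the exact test under HWE sampling."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 71]))
    maf = rng.uniform(0.05, 0.5, m)
    probs = np.column_stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    counts = rng.multinomial(n, probs)
    pv = np.fromiter(
        (hwe_exact_test(c[0], c[1], c[2]) for c in counts), float, count=m
    )
    frac = float((pv < alpha).mean())
    ci = 2.576 * float(np.sqrt(alpha * (1 - alpha) / m))
    return {"m": m, "n": n, "alpha": alpha, "rejection_rate": frac, "ci99_halfwidth": ci}


# ---------------------------------------------------------------------------
# published-catalog internal consistency

def catalog_consistency() -> dict:
    """For every bundled published association row, the two-sided P
    implied by the printed beta and SE (normal approximation at n~3000)
    against the printed P, on the log10 scale."""
    cat = load_qtl_catalog()
    z = np.abs(cat["beta"]) / cat["se"]
    implied = 2.0 * stats.norm.sf(z)
    gap = np.abs(np.log10(implied) - np.log10(cat["p"]))
    return {
        "rows": len(cat),
        "max_abs_log10_gap": float(gap.max()),
        "all_minor_allele": bool((cat["maf"] <= 0.5).all()),
    }


# ---------------------------------------------------------------------------
# OLS oracle

def _normal_equations(g, y, X=None):
    n = len(y)
    cols = [np.ones(n), np.asarray(g, float)]
    if X is not None:
        X = np.asarray(X, float)
        cols.extend(X[:, j] for j in range(X.shape[1]))
    D = np.column_stack(cols)
    xtx_inv = np.linalg.inv(D.T @ D)
    beta = xtx_inv @ (D.T @ y)
    resid = y - D @ beta
    df = n - D.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * xtx_inv[1, 1])
    return float(beta[1]), float(se)


def ols_oracle_check(seed: int, reps: int = 1000) -> dict:
    """fit_additive vs the explicit normal-equations solution on random
    small problems; reports the worst absolute deviation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 83]))
    worst = 0.0
    done = 0
    while done < reps:
        n = int(rng.integers(15, 60))
        k = int(rng.integers(0, 4))
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        if np.ptp(g) == 0:
            continue
        X = rng.normal(size=(n, k)) if k else None
        y = rng.normal(size=n) + 0.2 * g
        res = fit_additive(g, y, X)
        b, se = _normal_equations(g, y, X)
        worst = max(worst, abs(res.beta - b), abs(res.se - se))
        done += 1
    return {"problems": reps, "max_abs_diff": worst}
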