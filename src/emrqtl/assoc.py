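"""Single-SNP additive association, genomic control, power, replication.

The association model is ordinary least squares of the phenotype on
minor-allele dosage plus covariates (age, sex, disease status):

    y = a + beta * g + X c + e

with the two-sided P from the t distribution at residual df and the
SNP's contribution reported as partial R^2 — the incremental R^2 over
the covariate-only model, equivalently t^2 / (t^2 + df_resid).

Genomic control: lambda_GC = median(chi^2_1 statistics) / 0.4549364;
adjusted chi^2 = chi^2 / lambda (never deflated below lambda = 1).

Power for a QTL explaining variance fraction r^2 at sample size n uses
the noncentral chi^2_1 distribution with noncentrality
n * r^2 / (1 - r^2), or a simulation route through the same model fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .plink import GenotypeMatrix
from .traits import TRAITS

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution
GENOME_WIDE_P = 5e-8

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class AssocResult:
    """Per-SNP additive regression summary (one row of a GWAS table)."""

    marker_id: str
    effect_allele: str
    eaf: float
    n_used: int
    beta: float
    se: float
    t: float
    p: float
    r2_partial: float
    flag: str = ""  # "" | "constant-genotype" | other not-a-result reasons


def fit_additive(
    g,
    y,
    X=None,
    marker_id: str = "",
    effect_allele: str = "",
) -> AssocResult:
    """OLS of y on [1, g, X] with complete-case removal.

    ``X`` is an optional (n, k) covariate array (no intercept column).
    Returns an :class:`AssocResult`; a genotype constant after
    complete-case removal is flagged ``constant-genotype`` with NaN
    statistics rather than raising.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(g) & (g >= 0)
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep &= np.isfinite(X).all(axis=1)
    gk, yk = g[keep], y[keep]
    Xk = X[keep] if X is not None else np.empty((keep.sum(), 0))
    n = len(yk)
    p_cols = 2 + Xk.shape[1]
    if n <= p_cols + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p_cols} parameters")
    eaf = float(gk.mean() / 2.0)
    if np.ptp(gk) == 0:
        return AssocResult(
            marker_id, effect_allele, eaf, n, np.nan, np.nan, np.nan, np.nan, np.nan,
            flag="constant-genotype",
        )
    design = np.column_stack([np.ones(n), gk, Xk])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("collinear design (covariates + genotype)")
    coef, _, _, _ = np.linalg.lstsq(design, yk, rcond=None)
    resid = yk - design @ coef
    df = n - design.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:  # exact fit: residual variance is zero
        return AssocResult(
            marker_id, effect_allele, eaf, n, beta, 0.0, np.inf, 5e-324, 1.0
        )
    t = beta / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    r2_partial = t * t / (t * t + df)
    return AssocResult(
        marker_id, effect_allele, eaf, n, beta, se, t, max(p, 5e-324), r2_partial
    )


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    traits=None,
    covariates=("age", "male", "pad"),
) -> pd.DataFrame:
    """One additive fit per QC-passing marker per trait.

    Samples align by patient id (not row order).  Markers whose genotype
    is constant in the analyzed samples carry NaN statistics with a
    flag — never silently dropped.

    Returns a long table: trait, marker_id, chrom, bp, effect_allele,
    eaf, n_used, beta, se, t, p, r2_partial, flag.
    """
    traits = list(traits) if traits is not None else [t for t in TRAITS if t in phenotypes]
    pheno = phenotypes.set_index("patient_id")
    sample_ids = [s for s in genotypes.samples if s in pheno.index]
    if not sample_ids:
        raise ValueError("no overlapping samples between genotypes and phenotypes")
    keep = np.array([s in pheno.index for s in genotypes.samples])
    g_sub = genotypes.subset(sample_mask=keep)
    pheno = pheno.loc[[s for s in g_sub.samples]]

    covariates = [c for c in covariates if c]
    Xc = pheno[list(covariates)].to_numpy(dtype=float) if covariates else None

    frames = []
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        frames.append(_gwas_one_trait(g_sub, y, Xc, trait))
    return pd.concat(frames, ignore_index=True)


def _gwas_one_trait(g: GenotypeMatrix, y, Xc, trait: str) -> pd.DataFrame:
    """Vectorized per-trait scan (Frisch–Waugh residualization); markers
    with missing genotypes or incomplete phenotypes fall back to
    :func:`fit_additive` marker by marker."""
    n, m = g.n_samples, g.n_markers
    d = g.dosage
    ok_rows = np.isfinite(y)
    if Xc is not None:
        ok_rows &= np.isfinite(Xc).all(axis=1)
    fast = ok_rows.all() and (d >= 0).all()

    out = {
        "trait": trait,
        "marker_id": g.markers["marker_id"].to_numpy(),
        "chrom": g.markers["chrom"].to_numpy(),
        "bp": g.markers["bp"].to_numpy(),
        "effect_allele": g.markers["a1"].to_numpy()
        if "a1" in g.markers
        else np.full(m, ""),
    }
    if fast:
        X = np.ones((n, 1)) if Xc is None else np.column_stack([np.ones(n), Xc])
        # residualize phenotype and genotypes on covariates
        Q, _ = np.linalg.qr(X)
        y_r = y - Q @ (Q.T @ y)
        beta = np.empty(m)
        se = np.empty(m)
        gss = np.empty(m)
        chunk = 2048
        for j0 in range(0, m, chunk):
            G = d[:, j0 : j0 + chunk].astype(float)
            G -= Q @ (Q.T @ G)
            gg = np.einsum("ij,ij->j", G, G)
            gy = G.T @ y_r
            gss[j0 : j0 + chunk] = gg
            with np.errstate(invalid="ignore", divide="ignore"):
                beta[j0 : j0 + chunk] = gy / gg
        df = n - X.shape[1] - 1
        yss = float(y_r @ y_r)
        rss = yss - beta**2 * gss
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(rss / df / gss)
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r2 = t * t / (t * t + df)
        const = gss <= 1e-12
        for arr in (beta, se, t, p, r2):
            arr[const] = np.nan
        out.update(
            {
                "eaf": d.astype(float).mean(axis=0) / 2.0,
                "n_used": np.full(m, n),
                "beta": beta,
                "se": se,
                "t": t,
                "p": np.clip(p, 5e-324, None),
                "r2_partial": r2,
                "flag": np.where(const, "constant-genotype", ""),
            }
        )
        return pd.DataFrame(out)

    results = [
        fit_additive(
            d[:, j],
            y,
            Xc,
            marker_id=g.markers["marker_id"].iloc[j],
            effect_allele=str(out["effect_allele"][j]),
        )
        for j in range(m)
    ]
    out.update(
        {
            "eaf": [r.eaf for r in results],
            "n_used": [r.n_used for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "r2_partial": [r.r2_partial for r in results],
            "flag": [r.flag for r in results],
        }
    )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# genomic control

def genomic_lambda(gwas: pd.DataFrame | np.ndarray) -> float:
    """Inflation factor: median chi^2_1 statistic / 0.4549364.

    Accepts a GWAS table (uses t^2) or an array of chi^2 statistics.
    """
    if isinstance(gwas, pd.DataFrame):
        chi2 = (gwas["t"].to_numpy(dtype=float)) ** 2
    else:
        chi2 = np.asarray(gwas, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if len(chi2) == 0:
        raise ValueError("no finite statistics for lambda")
    if len(chi2) < 100:
        import warnings

        warnings.warn(f"lambda from only {len(chi2)} markers is unstable")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def gc_adjust(gwas: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Add ``p_gc``: P recomputed from chi^2 / lambda (chi^2_1 survival
    function).  Lambda < 1 is never applied (no deflation); statistics
    pass through unchanged with a note column."""
    out = gwas.copy()
    chi2 = out["t"].to_numpy(dtype=float) ** 2
    if lam < 1.0:
        out["p_gc"] = stats.chi2.sf(chi2, 1)
        out.attrs["gc_note"] = f"lambda={lam:.4f} < 1: no deflation applied"
    else:
        out["p_gc"] = stats.chi2.sf(chi2 / lam, 1)
    return out


def qq_data(gwas: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed -log10 P, rank i of m -> -log10(i / (m+1))."""
    p = gwas["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no finite P values")
    obs = -np.log10(np.sort(p))  # descending -log10, smallest p first
    m = len(p)
    exp = -np.log10(np.arange(1, m + 1) / (m + 1.0))
    return pd.DataFrame({"expected": exp, "observed": obs})


def manhattan_data(gwas: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """(chromosome, bp, -log10 P) with the genome-wide line annotated."""
    p = gwas["p"].to_numpy(dtype=float)
    keep = np.isfinite(p)
    out = pd.DataFrame(
        {
            "chrom": gwas["chrom"].to_numpy()[keep],
            "bp": gwas["bp"].to_numpy()[keep],
            "neglog10_p": -np.log10(p[keep]),
            "significant": p[keep] < threshold,
        }
    )
    out.attrs["threshold"] = threshold
    out.attrs["threshold_line"] = -np.log10(threshold)
    return out


# ---------------------------------------------------------------------------
# power

@dataclass
class PowerSpec:
    n: int
    r2: float
    alpha: float = GENOME_WIDE_P
    maf: float = 0.05  # used only by the simulation route

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def qtl_power(
    spec: PowerSpec,
    method: str = "analytic",
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Power to detect a QTL explaining variance fraction r^2.

    analytic
        P(X > q) for X ~ noncentral chi^2_1 with noncentrality
        n * r^2 / (1 - r^2), q the (1 - alpha) quantile of chi^2_1.
    simulation
        fraction of ``reps`` replicates (genotype Binomial(2, maf),
        trait = beta*g + noise at variance fraction r^2, then
        :func:`fit_additive`) reaching P < alpha.
    """
    spec.validate()
    if method == "analytic":
        q = stats.chi2.isf(spec.alpha, 1)
        ncp = spec.n * spec.r2 / (1.0 - spec.r2)
        return float(stats.ncx2.sf(q, 1, ncp))
    if method == "simulation":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 97]))
        hits = 0
        beta = np.sqrt(spec.r2 / (2.0 * spec.maf * (1.0 - spec.maf)))
        resid_sd = np.sqrt(1.0 - spec.r2)
        for _ in range(reps):
            g = rng.binomial(2, spec.maf, size=spec.n)
            y = beta * g + rng.normal(0.0, resid_sd, size=spec.n)
            res = fit_additive(g, y)
            if res.flag == "" and res.p < spec.alpha:
                hits += 1
        return hits / reps
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# replication

def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((str(a1).upper(), str(a2).upper())) in _AMBIGUOUS_PAIRS


def replication_compare(gwas: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Harmonize effect alleles and compare directions against a
    reference catalog.

    ``gwas`` rows need marker_id/effect_allele/beta (+ optionally the
    other allele as ``other_allele`` or via a1/a2 metadata); ``catalog``
    rows need snp, trait, effect_allele, beta.  Matching is on
    (marker id, trait).  If the catalog reports the other allele, its
    beta sign is flipped before comparison.  A/T and C/G markers are
    flagged strand-ambiguous (unresolvable without frequency matching).

    Returns one row per GWAS (marker, trait) with match status,
    harmonized betas and a direction-concordance flag.
    """
    cat = catalog.set_index(["snp", "trait"], drop=False).sort_index()
    rows = []
    for row in gwas.itertuples(index=False):
        key = (getattr(row, "marker_id"), getattr(row, "trait"))
        base = {
            "marker_id": key[0],
            "trait": key[1],
            "effect_allele": getattr(row, "effect_allele"),
            "eaf": getattr(row, "eaf", np.nan),
            "beta": getattr(row, "beta"),
        }
        other = str(getattr(row, "other_allele", "")) or None
        if key not in cat.index:
            rows.append({**base, "status": "no match", "catalog_beta": np.nan,
                         "catalog_study": "", "concordant": None})
            continue
        matches = cat.loc[[key]]
        for crow in matches.itertuples(index=False):
            cat_allele = str(getattr(crow, "effect_allele")).upper()
            eff = str(base["effect_allele"]).upper()
            cat_beta = float(getattr(crow, "beta"))
            status = "matched"
            if cat_allele == eff:
                pass
            elif other is not None and cat_allele == other.upper():
                cat_beta = -cat_beta
                status = "matched-flipped"
            elif other is None:
                cat_beta = -cat_beta
                status = "matched-flipped-assumed"
            else:
                rows.append({**base, "status": "allele mismatch",
                             "catalog_beta": np.nan, "catalog_study":
                             str(getattr(crow, "study", "")), "concordant": None})
                continue
            if other is not None and is_strand_ambiguous(eff, other):
                status += ";strand-ambiguous"
            rows.append(
                {
                    **base,
                    "status": status,
                    "catalog_beta": cat_beta,
                    "catalog_study": str(getattr(crow, "study", "")),
                    "concordant": bool(np.sign(base["beta"]) == np.sign(cat_beta)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled catalogs of previously reported RBC-trait QTL

def _data_path(name: str):
    return resources.files("emrqtl").joinpath("data", name)


def load_qtl_catalog(path=None) -> pd.DataFrame:
    """Published RBC-trait QTL association results (minor-allele beta,
    SE, partial R^2 %, P) used for internal-consistency checks."""
    src = Path(path) if path else _data_path("rbc_qtl_catalog.tsv")
    return pd.read_csv(src, sep="\t")


def load_replication_catalog(path=None) -> pd.DataFrame:
    """Cross-study comparison table: EMR-cohort effects alongside
    previously reported effects at the same loci."""
    src = Path(path) if path else _data_path("rbc_replication_catalog.tsv")
    return pd.read_csv(src, sep="\t")
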