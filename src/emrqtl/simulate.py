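"""Synthetic EMR + genotype generator with known ground truth.

Emulates the data a hospital-biobank GWAS of red-blood-cell traits
consumes: repeated, dated CBC lab draws for a cohort of patients;
hospitalization episodes; coded diagnosis/procedure events; clinical
notes mentioning marrow-suppressing medications; and HWE genotypes with
optional planted additive effects on trait means.

Design notes
------------
* HGB/HCT/RBC are the *primary* simulated quantities. The erythrocyte
  indices (MCV, MCH, MCHC) are derived per draw through the exact
  hematological identities, so the six traits carry the physiological
  dependence structure of a real CBC panel.
* The six target (mean, SD) pairs are over-determined given the exact
  identities: the identities force the derived means to the ratio of the
  primary means. The generator matches the primary means/SDs exactly and
  solves the cross-trait correlations so the derived SDs match their
  targets (delta method); derived means then land within ~1% of target.
* Every value-affecting confounder the generator plants is recorded, and
  each lab value receives a truth label computed by a direct, standalone
  evaluation of the window policies — deliberately *not* by calling the
  production filter, so the filter can be tested against an independent
  oracle.
* All randomness derives from ``(config.seed, stage_tag)`` so each stage
  is reproducible independent of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .traits import (
    DERIVED_TRAITS,
    PRIMARY_TRAITS,
    REPORT_DECIMALS,
    TRAITS,
    derive_indices,
)

# between/within variance split and cohort composition defaults reflect
# a PAD case/control hospital cohort (~3,000 patients, 62% male,
# mean age 63) with six correlated CBC traits
DEFAULT_TRAIT_PARAMS = {
    "HGB": (14.1, 1.3),
    "HCT": (41.0, 3.6),
    "RBC": (4.5, 0.4),
    "MCV": (90.5, 4.2),
    "MCH": (31.1, 1.6),
    "MCHC": (34.3, 0.5),
}

# age is per year centered at the cohort mean age; male/pad are 0/1
# indicators.  PAD coefficients mirror the observed case-control gaps;
# age/sex effects are near-proportional across the primaries so the
# derived indices are only weakly covariate-dependent (as observed:
# MCH barely differs between PAD cases and controls).
DEFAULT_COVARIATE_EFFECTS = {
    "HGB": {"age": -0.010, "male": 1.2, "pad": -0.5},
    "HCT": {"age": -0.030, "male": 3.4, "pad": -1.1},
    "RBC": {"age": -0.0032, "male": 0.36, "pad": -0.10},
}

DEFAULT_EVENT_RATES = {
    "condition": 0.10,
    "transplant": 0.02,
    "medication_code": 0.06,
    "medication_nlp": 0.12,
    "surgery_blood_loss": 0.10,
}

_STAGE_SALTS = {
    "patients": 11,
    "labs": 23,
    "genotypes": 37,
    "confounders": 53,
}


@dataclass
class CausalEffect:
    """One planted additive QTL: ``snp_index`` explains fraction ``r2``
    of the total variance of ``trait``."""

    snp_index: int
    trait: str
    r2: float


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions the pipeline is exercised under:
    a ~3,000-patient PAD case/control cohort, six draws per patient on
    average over a 15-year span, and confounding-event rates that
    exclude a sizeable minority of values.
    """

    n_patients: int = 3012
    seed: int = 0
    visit_rate: float = 6.0  # mean extra draws; draws = 1 + Poisson(rate)
    span_start: str = "1994-01-01"
    span_days: int = 5478  # ~15 years
    trait_params: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_PARAMS))
    icc: float = 0.7  # within-patient intraclass correlation of repeats
    age_mean: float = 63.2
    age_sd: float = 9.5
    p_male: float = 0.62
    p_pad: float = 0.49
    covariate_effects: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    event_rates: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    hospitalization_rate: float = 0.35
    decoy_event_rate: float = 0.5  # benign codes that must NOT trigger exclusion
    m_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    genotype_missing_rate: float = 0.0
    causal_spec: list = field(default_factory=list)
    round_values: bool = True  # round to analyzer reporting precision

    def validate(self) -> list[str]:
        """Return a list of problems; empty means valid."""
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.visit_rate < 0:
            problems.append("visit_rate must be >= 0")
        for t, (mu, sd) in self.trait_params.items():
            if sd <= 0:
                problems.append(f"trait {t}: SD must be > 0")
        for name, rate in list(self.event_rates.items()) + [
            ("hospitalization_rate", self.hospitalization_rate),
            ("p_male", self.p_male),
            ("p_pad", self.p_pad),
        ]:
            if not 0.0 <= rate <= 1.0:
                problems.append(f"rate {name}={rate} outside [0, 1]")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            problems.append(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0.0 < self.icc <= 1.0:
            problems.append("icc must be in (0, 1]")
        per_trait = {}
        for eff in self.causal_spec:
            if not 0.0 < eff.r2 < 1.0:
                problems.append(f"causal r2={eff.r2} outside (0, 1)")
            if eff.trait not in TRAITS:
                problems.append(f"causal trait {eff.trait} unknown")
            if not 0 <= eff.snp_index < self.m_snps:
                problems.append(f"causal snp_index {eff.snp_index} out of range")
            per_trait[eff.trait] = per_trait.get(eff.trait, 0.0) + eff.r2
        for t, tot in per_trait.items():
            if tot >= 1.0:
                problems.append(f"trait {t}: sum of causal r2 = {tot} >= 1")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class TruthLabels:
    """Ground truth attached to one simulated dataset.

    values
        one row per lab value: ``lab_id, patient_id, trait, sample_date,
        inpatient, excluded, reason`` — ``excluded``/``reason`` refer to
        the confounder-window policies; ``inpatient`` is the separate
        hospitalization flag.
    patients
        per-patient latent (noise-free) trait means for all six traits.
    causal
        per planted QTL: marker id, trait, realized allele frequency and
        the true per-minor-allele effect β.
    """

    values: pd.DataFrame
    patients: pd.DataFrame
    causal: pd.DataFrame


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), _STAGE_SALTS[stage]])
    )


# ---------------------------------------------------------------------------
# variance bookkeeping

def _covariate_variance(config: SimConfig, trait: str) -> float:
    """Between-patient variance contributed by the covariate effects."""
    eff = config.covariate_effects.get(trait, {})
    v = 0.0
    v += (eff.get("age", 0.0) * config.age_sd) ** 2
    v += eff.get("male", 0.0) ** 2 * config.p_male * (1 - config.p_male)
    v += eff.get("pad", 0.0) ** 2 * config.p_pad * (1 - config.p_pad)
    return v


def _covariate_covariance(config: SimConfig) -> np.ndarray:
    """3x3 covariance of the covariate-driven shifts of (HGB, HCT, RBC)."""
    cov = np.zeros((3, 3))
    variances = {
        "age": config.age_sd**2,
        "male": config.p_male * (1 - config.p_male),
        "pad": config.p_pad * (1 - config.p_pad),
    }
    for k, var_k in variances.items():
        beta = np.array(
            [config.covariate_effects.get(t, {}).get(k, 0.0) for t in PRIMARY_TRAITS]
        )
        cov += var_k * np.outer(beta, beta)
    return cov


def primary_correlation(config: SimConfig) -> np.ndarray:
    """Correlation of the random (non-covariate) components of the
    primaries, solved so the derived indices hit their target SDs.

    Each derived trait is a ratio of two primaries; by the delta method
    its variance is a linear function of exactly one pairwise
    correlation, giving a closed-form solve.  The resulting matrix is
    clipped to the nearest correlation matrix if the three targets are
    jointly infeasible.
    """
    mu = {t: config.trait_params[t][0] for t in PRIMARY_TRAITS}
    vr = {
        t: config.trait_params[t][1] ** 2 - _covariate_variance(config, t)
        for t in PRIMARY_TRAITS
    }
    for t, v in vr.items():
        if v <= 0:
            raise ValueError(
                f"covariate effects for {t} exceed the configured trait variance"
            )
    cov_c = _covariate_covariance(config)
    h, c, r = mu["HGB"], mu["HCT"], mu["RBC"]
    # gradients of each index wrt its two primaries, evaluated at the mean
    specs = {
        # derived trait: (i, j, grad_i, grad_j)
        "MCV": (1, 2, 10.0 / r, -10.0 * c / r**2),
        "MCH": (0, 2, 10.0 / r, -10.0 * h / r**2),
        "MCHC": (0, 1, 100.0 / c, -100.0 * h / c**2),
    }
    order = list(PRIMARY_TRAITS)
    rho = np.eye(3)
    for dt, (i, j, gi, gj) in specs.items():
        target_var = config.trait_params[dt][1] ** 2
        g = np.zeros(3)
        g[i], g[j] = gi, gj
        cov_contrib = g @ cov_c @ g
        vi, vj = vr[order[i]], vr[order[j]]
        rij = (target_var - cov_contrib - gi**2 * vi - gj**2 * vj) / (
            2.0 * gi * gj * np.sqrt(vi * vj)
        )
        rho[i, j] = rho[j, i] = float(np.clip(rij, -0.999, 0.999))
    # nearest-PSD repair (eigenvalue clip) in case targets are infeasible
    w, v = np.linalg.eigh(rho)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        rho = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(rho))
        rho = rho / np.outer(d, d)
    return rho


# ---------------------------------------------------------------------------
# patients

def simulate_patients(config: SimConfig) -> pd.DataFrame:
    """Draw the cohort: demographics, covariates and the between-patient
    random component of each primary trait.

    Columns: ``patient_id, age, male, pad``, per-primary covariate shift
    ``cov_<T>`` and between-patient deviation ``eps_<T>``, plus zeroed
    genetic-shift columns ``gen_<T>`` for all six traits (filled by
    :func:`inject_genetic_effects`).
    """
    config.require_valid()
    n = config.n_patients
    rng = _rng(config, "patients")
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 18.0, 100.0)
    male = (rng.random(n) < config.p_male).astype(np.int8)
    pad = (rng.random(n) < config.p_pad).astype(np.int8)

    rho = primary_correlation(config)
    chol = np.linalg.cholesky(rho)
    z = rng.standard_normal((n, 3)) @ chol.T

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "age": age,
            "male": male,
            "pad": pad,
        }
    )
    for k, t in enumerate(PRIMARY_TRAITS):
        sigma2 = config.trait_params[t][1] ** 2
        cov_var = _covariate_variance(config, t)
        eps_var = config.icc * sigma2 - cov_var
        if eps_var <= 0:
            raise ValueError(
                f"trait {t}: covariate variance {cov_var:.3f} exceeds the "
                f"between-patient budget icc*sigma^2 = {config.icc * sigma2:.3f}"
            )
        eff = config.covariate_effects.get(t, {})
        shift = (
            eff.get("age", 0.0) * (age - config.age_mean)
            + eff.get("male", 0.0) * (male - config.p_male)
            + eff.get("pad", 0.0) * (pad - config.p_pad)
        )
        df[f"cov_{t}"] = shift
        df[f"eps_{t}"] = np.sqrt(eps_var) * z[:, k]
    for t in TRAITS:
        df[f"gen_{t}"] = 0.0
    return df


def latent_trait_means(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-patient noise-free trait means for all six traits."""
    out = pd.DataFrame({"patient_id": patients["patient_id"]})
    lat = {}
    for t in PRIMARY_TRAITS:
        lat[t] = (
            config.trait_params[t][0]
            + patients[f"cov_{t}"].to_numpy()
            + patients[f"eps_{t}"].to_numpy()
            + patients[f"gen_{t}"].to_numpy()
        )
    mcv, mch, mchc = derive_indices(lat["HGB"], lat["HCT"], lat["RBC"])
    lat["MCV"] = mcv + patients["gen_MCV"].to_numpy()
    lat["MCH"] = mch + patients["gen_MCH"].to_numpy()
    lat["MCHC"] = mchc + patients["gen_MCHC"].to_numpy()
    for t in TRAITS:
        out[t] = lat[t]
    return out


# ---------------------------------------------------------------------------
# lab series

def simulate_lab_series(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate dated CBC draws: ``1 + Poisson(visit_rate)`` per patient.

    Each draw produces all six traits: primaries = patient latent mean +
    within-patient noise (correlation structure shared with the
    between-patient component), indices derived per draw through the
    exact identities, then rounded to analyzer reporting precision
    (``config.round_values``).

    Returns a long table: ``lab_id, patient_id, trait, value,
    sample_date, accession, source``.
    """
    if len(patients) == 0:
        raise ValueError("patient table is empty")
    config.require_valid()
    rng = _rng(config, "labs")
    n = len(patients)
    draws = 1 + rng.poisson(config.visit_rate, size=n)
    total = int(draws.sum())

    pat_idx = np.repeat(np.arange(n), draws)
    day = rng.integers(0, config.span_days, size=total)

    rho = primary_correlation(config)
    chol = np.linalg.cholesky(rho)
    znoise = rng.standard_normal((total, 3)) @ chol.T
    within_sd = np.array(
        [np.sqrt((1.0 - config.icc) * config.trait_params[t][1] ** 2) for t in PRIMARY_TRAITS]
    )

    lat = latent_trait_means(patients, config)
    prim = np.column_stack([lat[t].to_numpy()[pat_idx] for t in PRIMARY_TRAITS])
    prim = prim + znoise * within_sd

    hgb, hct, rbc = prim[:, 0], prim[:, 1], prim[:, 2]
    mcv, mch, mchc = derive_indices(hgb, hct, rbc)
    mcv = mcv + patients["gen_MCV"].to_numpy()[pat_idx]
    mch = mch + patients["gen_MCH"].to_numpy()[pat_idx]
    mchc = mchc + patients["gen_MCHC"].to_numpy()[pat_idx]

    values = {"HGB": hgb, "HCT": hct, "RBC": rbc, "MCV": mcv, "MCH": mch, "MCHC": mchc}
    if config.round_values:
        values = {t: np.round(v, REPORT_DECIMALS[t]) for t, v in values.items()}

    dates = (
        np.datetime64(config.span_start) + day.astype("timedelta64[D]")
    ).astype("datetime64[D]").astype(str)
    pids = patients["patient_id"].to_numpy()[pat_idx]
    accession = np.array([f"A{pid[1:]}-{k}" for pid, k in zip(pids, _draw_counter(pat_idx))])

    frames = []
    for t in TRAITS:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "trait": t,
                    "value": values[t],
                    "sample_date": dates,
                    "accession": accession,
                    "source": "sim_lab",
                }
            )
        )
    labs = pd.concat(frames, ignore_index=True)
    labs.insert(0, "lab_id", [f"L{i:07d}" for i in range(len(labs))])
    return labs


def _draw_counter(pat_idx: np.ndarray) -> np.ndarray:
    """Sequential draw number within each patient (pat_idx is sorted)."""
    if len(pat_idx) == 0:
        return np.zeros(0, dtype=int)
    boundaries = np.flatnonzero(np.diff(pat_idx)) + 1
    starts = np.concatenate([[0], boundaries])
    return np.arange(len(pat_idx)) - np.repeat(starts, np.diff(np.append(starts, len(pat_idx))))


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(patients: pd.DataFrame, config: SimConfig):
    """HWE genotypes: MAF ~ U(maf_range), dosage = two Bernoulli(MAF)
    allele draws; optional missingness. Returns a
    :class:`~emrqtl.plink.GenotypeMatrix`."""
    from .plink import GenotypeMatrix  # local import to avoid cycle

    config.require_valid()
    if config.m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    rng = _rng(config, "genotypes")
    n, m = len(patients), config.m_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosage = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random((n, m)) < config.genotype_missing_rate
        dosage[miss] = -1

    bases = np.array(list("ACGT"))
    a1 = bases[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)  # guarantee a2 != a1
    a2 = bases[(np.searchsorted(bases, a1) + shift) % 4]
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": (np.arange(m) % 22) + 1,
            "bp": 1_000_000 + np.arange(m) * 5_000,
            "a1": a1,  # minor / counted allele
            "a2": a2,
            "maf_true": maf,
        }
    )
    return GenotypeMatrix(
        dosage=dosage, samples=list(patients["patient_id"]), markers=markers
    )


def inject_genetic_effects(
    patients: pd.DataFrame, genotypes, causal_spec: list[CausalEffect], config: SimConfig
):
    """Plant additive QTL effects into the patient latent means.

    For each causal (j, trait, r²):
    ``β = sqrt(r² σ²_trait / (2 p (1−p)))`` with p the realized allele
    frequency; the centered dosage ``β (g − ḡ)`` is added to the latent
    mean (centering keeps the population trait mean at its target).  For
    primary traits, the between-patient deviation is rescaled so the
    total trait variance stays at the configured σ²; for derived traits
    the shift is additive on top of the identity-derived value and the
    total variance grows by the (small) planted fraction.

    Returns ``(patients, causal_truth)`` where ``causal_truth`` has one
    row per planted QTL (marker id, trait, realized freq, true β).
    Call once with the full causal spec.
    """
    patients = patients.copy()
    rows = []
    shrink = {t: 0.0 for t in PRIMARY_TRAITS}  # planted variance per primary
    for eff in causal_spec:
        if not 0.0 < eff.r2 < 1.0:
            raise ValueError(f"causal r2 must be in (0, 1), got {eff.r2}")
        g = genotypes.dosage[:, eff.snp_index].astype(float)
        called = g >= 0
        p = g[called].sum() / (2.0 * called.sum())
        sigma2 = config.trait_params[eff.trait][1] ** 2
        beta = float(np.sqrt(eff.r2 * sigma2 / (2.0 * p * (1.0 - p))))
        gc = np.where(called, g, 2.0 * p) - 2.0 * p
        patients[f"gen_{eff.trait}"] = patients[f"gen_{eff.trait}"] + beta * gc
        if eff.trait in PRIMARY_TRAITS:
            shrink[eff.trait] += beta**2 * float(np.var(gc))
        rows.append(
            {
                "marker_id": genotypes.markers["marker_id"].iloc[eff.snp_index],
                "trait": eff.trait,
                "freq": p,
                "beta": beta,
                "r2": eff.r2,
            }
        )
    for t, gvar in shrink.items():
        if gvar > 0:
            sigma2 = config.trait_params[t][1] ** 2
            eps_var = config.icc * sigma2 - _covariate_variance(config, t)
            factor = np.sqrt(max(eps_var - gvar, 0.0) / eps_var)
            patients[f"eps_{t}"] = patients[f"eps_{t}"] * factor
    causal = pd.DataFrame(rows, columns=["marker_id", "trait", "freq", "beta", "r2"])
    return patients, causal


# ---------------------------------------------------------------------------
# confounders + truth labels

def simulate_confounders(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    registry,
    lexicon,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Plant coded events, hospitalizations and medication notes; label
    every lab value with ground truth.

    Confounding events are anchored near actual draw dates (clinically,
    CBCs cluster around the encounters that generate codes), so finite
    windows genuinely cover draws.  Truth labels are computed by a
    direct evaluation of each planted event's window policy against each
    lab date — an independent code path from the production filter.

    Returns ``(events, episodes, notes, truth)``; the note table contains
    both medication-mention notes and decoy notes without mentions.
    """
    if len(registry.entries) == 0:
        raise ValueError("registry is empty")
    config.require_valid()
    rng = _rng(config, "confounders")
    start = date.fromisoformat(config.span_start)

    lab_days = {}  # patient_id -> sorted array of draw day offsets
    d0 = pd.to_datetime(labs["sample_date"])
    day_off = (d0 - pd.Timestamp(start)).dt.days.to_numpy()
    for pid, grp in pd.DataFrame(
        {"patient_id": labs["patient_id"], "day": day_off}
    ).groupby("patient_id", sort=False):
        lab_days[pid] = np.unique(grp["day"].to_numpy())

    by_cat = {}
    for entry in registry.entries:
        by_cat.setdefault(entry.category, []).append(entry)

    events, episodes, notes = [], [], []
    # (patient_id, category, day, lookback, duration or None=chronic)
    planted_windows = []
    eid = 0
    for _, pat in patients.iterrows():
        pid = pat["patient_id"]
        days = lab_days.get(pid, np.array([config.span_days // 2]))

        def _anchor_day():
            base = int(days[rng.integers(0, len(days))])
            return int(np.clip(base + rng.integers(-30, 31), 0, config.span_days - 1))

        for category, rate in config.event_rates.items():
            if rng.random() >= rate:
                continue
            n_ev = 1 + rng.poisson(1.0)
            for _ in range(n_ev):
                ev_day = _anchor_day()
                ev_date = (start + timedelta(days=ev_day)).isoformat()
                if category == "medication_nlp":
                    term = lexicon.terms[rng.integers(0, len(lexicon.terms))]
                    notes.append(
                        {
                            "note_id": f"N{eid:06d}",
                            "patient_id": pid,
                            "note_date": ev_date,
                            "text": (
                                f"Follow-up visit. Patient started on {term.name} "
                                "with stable course; continue current regimen."
                            ),
                        }
                    )
                    policy = registry.policy_for_category("medication_code")
                else:
                    entry = by_cat[category][rng.integers(0, len(by_cat[category]))]
                    code = entry.concrete_code(rng)
                    events.append(
                        {
                            "event_id": f"E{eid:06d}",
                            "patient_id": pid,
                            "code_system": entry.code_system,
                            "code": code,
                            "event_date": ev_date,
                        }
                    )
                    policy = registry.policy_for(entry)
                planted_windows.append(
                    (
                        pid,
                        "medication_nlp" if category == "medication_nlp" else category,
                        ev_day,
                        policy.lookback_days,
                        None if policy.chronic else policy.duration_days,
                    )
                )
                eid += 1

        if rng.random() < config.decoy_event_rate:
            for _ in range(1 + rng.poisson(1.0)):
                benign = ["401.9", "250.00", "715.90", "530.81", "272.4"]
                events.append(
                    {
                        "event_id": f"E{eid:06d}",
                        "patient_id": pid,
                        "code_system": "ICD9CM",
                        "code": benign[rng.integers(0, len(benign))],
                        "event_date": (start + timedelta(days=_anchor_day())).isoformat(),
                    }
                )
                eid += 1
            notes.append(
                {
                    "note_id": f"N{eid:06d}",
                    "patient_id": pid,
                    "note_date": (start + timedelta(days=_anchor_day())).isoformat(),
                    "text": "Routine visit. Medication list reviewed, no changes.",
                }
            )
            eid += 1

        if rng.random() < config.hospitalization_rate:
            for _ in range(1 + rng.poisson(0.3)):
                anchor = int(days[rng.integers(0, len(days))])
                admit = max(0, anchor - int(rng.integers(0, 4)))
                discharge = min(config.span_days - 1, admit + int(rng.integers(1, 15)))
                episodes.append(
                    {
                        "patient_id": pid,
                        "admit_date": (start + timedelta(days=admit)).isoformat(),
                        "discharge_date": (start + timedelta(days=discharge)).isoformat(),
                    }
                )

    events_df = pd.DataFrame(
        events, columns=["event_id", "patient_id", "code_system", "code", "event_date"]
    )
    episodes_df = pd.DataFrame(
        episodes, columns=["patient_id", "admit_date", "discharge_date"]
    )
    notes_df = pd.DataFrame(notes, columns=["note_id", "patient_id", "note_date", "text"])

    truth_values = _evaluate_truth(labs, day_off, planted_windows, episodes_df, start)
    truth = TruthLabels(
        values=truth_values,
        patients=latent_trait_means(patients, config),
        causal=pd.DataFrame(columns=["marker_id", "trait", "freq", "beta", "r2"]),
    )
    return events_df, episodes_df, notes_df, truth


def _evaluate_truth(labs, day_off, planted_windows, episodes_df, start):
    """Direct per-value window evaluation (the oracle path)."""
    win_by_pid = {}
    for pid, cat, day, lookback, dur in planted_windows:
        lo = day - lookback
        hi = np.inf if dur is None else day + dur
        win_by_pid.setdefault(pid, []).append((lo, hi, cat))

    epi_by_pid = {}
    for _, row in episodes_df.iterrows():
        a = (date.fromisoformat(row["admit_date"]) - start).days
        d = (date.fromisoformat(row["discharge_date"]) - start).days
        epi_by_pid.setdefault(row["patient_id"], []).append((a, d))

    excluded = np.zeros(len(labs), dtype=bool)
    inpatient = np.zeros(len(labs), dtype=bool)
    reasons = [""] * len(labs)
    pids = labs["patient_id"].to_numpy()
    for i in range(len(labs)):
        d = int(day_off[i])
        cats = []
        for lo, hi, cat in win_by_pid.get(pids[i], ()):
            if lo <= d <= hi and cat not in cats:
                cats.append(cat)
        if cats:
            excluded[i] = True
            reasons[i] = ";".join(sorted(cats))
        for a, dd in epi_by_pid.get(pids[i], ()):
            if a <= d <= dd:
                inpatient[i] = True
                break
    return pd.DataFrame(
        {
            "lab_id": labs["lab_id"].to_numpy(),
            "patient_id": pids,
            "trait": labs["trait"].to_numpy(),
            "sample_date": labs["sample_date"].to_numpy(),
            "inpatient": inpatient,
            "excluded": excluded,
            "reason": reasons,
        }
    )


# ---------------------------------------------------------------------------
# one-call dataset + disk output

@dataclass
class SyntheticDataset:
    patients: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    episodes: pd.DataFrame
    notes: pd.DataFrame
    genotypes: object
    truth: TruthLabels
    config: SimConfig


def simulate_dataset(config: SimConfig, registry=None, lexicon=None) -> SyntheticDataset:
    """Run every generator stage in order and bundle the results."""
    from .filters import default_lexicon, default_registry

    registry = registry if registry is not None else default_registry()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    patients = simulate_patients(config)
    genotypes = simulate_genotypes(patients, config)
    patients, causal = inject_genetic_effects(patients, genotypes, config.causal_spec, config)
    labs = simulate_lab_series(patients, config)
    events, episodes, notes, truth = simulate_confounders(
        patients, labs, registry, lexicon, config
    )
    truth.causal = causal
    return SyntheticDataset(
        patients=patients,
        labs=labs,
        events=events,
        episodes=episodes,
        notes=notes,
        genotypes=genotypes,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the dataset as plain-text tables + PLINK PED/MAP."""
    import json
    from pathlib import Path

    from .plink import write_ped_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covars = ds.patients[["patient_id", "age", "male", "pad"]]
    covars.to_csv(out / "patients.tsv", sep="\t", index=False)
    ds.labs.to_csv(out / "labs.tsv", sep="\t", index=False)
    ds.events.to_csv(out / "events.tsv", sep="\t", index=False)
    ds.episodes.to_csv(out / "episodes.tsv", sep="\t", index=False)
    ds.notes.to_csv(out / "notes.tsv", sep="\t", index=False)
    ds.truth.values.to_csv(out / "truth.tsv", sep="\t", index=False)
    ds.truth.causal.to_csv(out / "truth_causal.tsv", sep="\t", index=False)
    write_ped_map(ds.genotypes, out / "genotypes")
    cfg = dataclasses.asdict(ds.config)
    cfg["causal_spec"] = [dataclasses.asdict(e) for e in ds.config.causal_spec]
    cfg["maf_range"] = list(ds.config.maf_range)
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
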