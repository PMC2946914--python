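"""Generator: determinism, trait structure, truth-label conservation."""

import numpy as np
import pandas as pd
import pytest

from emrqtl.simulate import (
    CausalEffect,
    SimConfig,
    inject_genetic_effects,
    simulate_dataset,
    simulate_genotypes,
    simulate_lab_series,
    simulate_patients,
)
from emrqtl.traits import DERIVED_TRAITS, PRIMARY_TRAITS, TRAITS, derive_indices


def test_derive_indices_identity_values():
    mcv, mch, mchc = derive_indices(15.0, 45.0, 5.0)
    assert mcv == pytest.approx(90.0)
    assert mch == pytest.approx(30.0)
    assert mchc == pytest.approx(100.0 / 3.0)


def test_patient_cohort_statistics():
    cfg = SimConfig(n_patients=3012, seed=5)
    pats = simulate_patients(cfg)
    se_age = cfg.age_sd / np.sqrt(cfg.n_patients)
    assert abs(pats["age"].mean() - cfg.age_mean) < 3 * se_age
    assert pats["age"].between(18, 100).all()
    se_male = np.sqrt(cfg.p_male * (1 - cfg.p_male) / cfg.n_patients)
    assert abs(pats["male"].mean() - cfg.p_male) < 3 * se_male


def test_degenerate_sex_rate_yields_no_males():
    pats = simulate_patients(SimConfig(n_patients=2000, p_male=0.0, seed=1))
    assert pats["male"].sum() == 0


def test_nonpositive_patient_count_rejected():
    with pytest.raises(ValueError):
        simulate_patients(SimConfig(n_patients=0))


def test_generator_is_deterministic():
    a = simulate_dataset(SimConfig(n_patients=40, m_snps=10, seed=9))
    b = simulate_dataset(SimConfig(n_patients=40, m_snps=10, seed=9))
    pd.testing.assert_frame_equal(a.labs, b.labs)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.truth.values, b.truth.values)
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)


def test_visit_rate_zero_gives_single_draw():
    cfg = SimConfig(n_patients=50, visit_rate=0.0, seed=2)
    labs = simulate_lab_series(simulate_patients(cfg), cfg)
    per = labs.groupby(["patient_id", "trait"]).size()
    assert (per == 1).all()


def test_identities_hold_per_draw_without_rounding():
    cfg = SimConfig(n_patients=60, seed=3, round_values=False)
    labs = simulate_lab_series(simulate_patients(cfg), cfg)
    wide = labs.pivot_table(index="accession", columns="trait", values="value")
    np.testing.assert_allclose(wide["MCV"], 10 * wide["HCT"] / wide["RBC"], rtol=1e-12)
    np.testing.assert_allclose(wide["MCH"], 10 * wide["HGB"] / wide["RBC"], rtol=1e-12)
    np.testing.assert_allclose(
        wide["MCHC"], wide["MCH"] / wide["MCV"] * 100.0, rtol=1e-12
    )


def test_pooled_trait_means_and_sds_match_targets():
    """Primaries match their configured means to 3 SE; the derived
    indices (whose means are pinned by the identities to the ratio of
    the primary means) match to 1% and their SDs to 5%."""
    cfg = SimConfig(n_patients=3000, seed=4)
    pats = simulate_patients(cfg)
    labs = simulate_lab_series(pats, cfg)
    g = labs.groupby("trait")["value"]
    means, sds = g.mean(), g.std()
    n_draws = labs["accession"].nunique()
    for t in PRIMARY_TRAITS:
        mu, sd = cfg.trait_params[t]
        # repeats within a patient are ICC-correlated
        se = sd * np.sqrt(cfg.icc / cfg.n_patients + (1 - cfg.icc) / n_draws)
        assert abs(means[t] - mu) < 3 * se
    for t in TRAITS:
        mu, sd = cfg.trait_params[t]
        assert abs(means[t] - mu) / mu < 0.01
        assert abs(sds[t] - sd) / sd < 0.05


def test_no_confounders_means_all_kept(registry, lexicon):
    cfg = SimConfig(
        n_patients=40,
        seed=6,
        event_rates={k: 0.0 for k in SimConfig().event_rates},
        hospitalization_rate=0.0,
        decoy_event_rate=0.0,
    )
    ds = simulate_dataset(cfg, registry=registry, lexicon=lexicon)
    assert not ds.truth.values["excluded"].any()
    assert not ds.truth.values["inpatient"].any()
    assert len(ds.events) == 0 and len(ds.episodes) == 0


def test_chronic_condition_excludes_values(registry, lexicon):
    rates = {k: 0.0 for k in SimConfig().event_rates}
    rates["condition"] = 1.0
    cfg = SimConfig(
        n_patients=5, seed=7, event_rates=rates, hospitalization_rate=0.0,
        decoy_event_rate=0.0,
    )
    ds = simulate_dataset(cfg, registry=registry, lexicon=lexicon)
    # chronic windows anchored near a draw must cover at least that draw
    per_patient = ds.truth.values.groupby("patient_id")["excluded"].any()
    assert per_patient.all()
    assert (ds.truth.values.loc[ds.truth.values["excluded"], "reason"] == "condition").all()


def test_truth_labels_cover_every_lab_value(small_dataset):
    assert sorted(small_dataset.truth.values["lab_id"]) == sorted(
        small_dataset.labs["lab_id"]
    )
    assert not small_dataset.truth.values["lab_id"].duplicated().any()


def test_genotypes_hwe_and_missingness():
    cfg = SimConfig(n_patients=4000, m_snps=200, maf_range=(0.5, 0.5), seed=8)
    pats = simulate_patients(cfg)
    g = simulate_genotypes(pats, cfg)
    het = (g.dosage == 1).mean(axis=0)
    se = np.sqrt(0.5 * 0.5 / cfg.n_patients)
    assert (np.abs(het - 0.5) < 4 * se).mean() > 0.97  # 2pq = 0.5 at MAF 0.5
    assert (g.dosage >= 0).all()  # no missingness by default


def test_genotype_missingness_rate_applied():
    cfg = SimConfig(n_patients=500, m_snps=100, genotype_missing_rate=0.1, seed=8)
    g = simulate_genotypes(simulate_patients(cfg), cfg)
    miss = (g.dosage < 0).mean()
    assert abs(miss - 0.1) < 0.01


def test_bad_maf_range_rejected():
    with pytest.raises(ValueError):
        simulate_patients(SimConfig(n_patients=5, maf_range=(0.0, 0.6)))


def test_injected_effect_matches_closed_form():
    cfg = SimConfig(
        n_patients=2000,
        m_snps=3,
        seed=9,
        trait_params={**SimConfig().trait_params, "HGB": (14.1, 1.0)},
        causal_spec=[CausalEffect(1, "HGB", 0.015)],
    )
    pats = simulate_patients(cfg)
    g = simulate_genotypes(pats, cfg)
    pats2, causal = inject_genetic_effects(pats, g, cfg.causal_spec, cfg)
    p = causal["freq"].iloc[0]
    expected = np.sqrt(0.015 * 1.0 / (2 * p * (1 - p)))
    assert causal["beta"].iloc[0] == pytest.approx(expected, rel=1e-12)
    # r2 = 0 case: empty spec leaves latents untouched
    pats3, _ = inject_genetic_effects(pats, g, [], cfg)
    pd.testing.assert_frame_equal(pats3, pats)


def test_injection_preserves_total_variance():
    cfg = SimConfig(
        n_patients=5000, m_snps=2, seed=10, visit_rate=0.0,
        causal_spec=[CausalEffect(0, "HGB", 0.1)],
    )
    pats = simulate_patients(cfg)
    g = simulate_genotypes(pats, cfg)
    pats, _ = inject_genetic_effects(pats, g, cfg.causal_spec, cfg)
    labs = simulate_lab_series(pats, cfg)
    sd = labs.loc[labs["trait"] == "HGB", "value"].std()
    target = cfg.trait_params["HGB"][1]
    assert abs(sd - target) / target < 0.05


def test_invalid_causal_r2_rejected():
    cfg = SimConfig(n_patients=5, m_snps=2, causal_spec=[CausalEffect(0, "HGB", 1.5)])
    assert any("r2" in p for p in cfg.validate())
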