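"""Exclusion windows, medication NLP, and the truth-label oracle."""

import math
from datetime import date

import pandas as pd
import pytest

from emrqtl.filters import (
    CodeRegistry,
    LexiconTerm,
    MedicationLexicon,
    RegistryEntry,
    WindowPolicy,
    build_exclusion_windows,
    detect_medication_mentions,
    drop_empty_patients,
    exclude_values,
    run_filter,
)
from emrqtl.simulate import SimConfig, simulate_dataset

DAY0 = date(2000, 1, 1).toordinal()


def _registry():
    policies = {
        "surgery": WindowPolicy("surgery", lookback_days=0, duration_days=90),
        "chronic": WindowPolicy("chronic", lookback_days=30, duration_days=None),
    }
    entries = [
        RegistryEntry("surgery_blood_loss", "CPT4", "00560", "surgery"),
        RegistryEntry("condition", "ICD9CM", "282*", "chronic"),
    ]
    return CodeRegistry(entries=entries, policies=policies)


def _event(patient, system, code, day):
    return {
        "event_id": f"E{day}",
        "patient_id": patient,
        "code_system": system,
        "code": code,
        "event_date": date.fromordinal(DAY0 + day).isoformat(),
    }


def test_surgery_window_is_direct_construction():
    events = pd.DataFrame([_event("P1", "CPT4", "00560", 100)])
    windows, report = build_exclusion_windows(events, _registry())
    (iv,) = windows["P1"]
    assert (iv.start, iv.end) == (DAY0 + 100, DAY0 + 190)
    assert iv.category == "surgery_blood_loss"
    assert report["matched"] == 1


def test_chronic_window_is_right_open():
    events = pd.DataFrame([_event("P1", "ICD9CM", "282.1", 50)])
    windows, _ = build_exclusion_windows(events, _registry())
    (iv,) = windows["P1"]
    assert iv.start == DAY0 + 50 - 30 and iv.end == math.inf


def test_same_category_windows_merge():
    events = pd.DataFrame(
        [_event("P1", "CPT4", "00560", 100), _event("P1", "CPT4", "00560", 150)]
    )
    windows, _ = build_exclusion_windows(events, _registry())
    (iv,) = windows["P1"]
    assert (iv.start, iv.end) == (DAY0 + 100, DAY0 + 240)
    assert len(iv.event_ids) == 2


def test_unknown_code_system_skipped_and_counted():
    events = pd.DataFrame([_event("P1", "SNOMED", "123", 10)])
    windows, report = build_exclusion_windows(events, _registry())
    assert windows == {} and report["unknown_system"] == 1


@pytest.mark.parametrize(
    "text,n",
    [
        ("started on methotrexate today", 1),
        ("Methotrexate 10 mg weekly", 1),
        ("methotrexatelike compound", 0),  # word boundary
        ("needs CellCept refill", 1),
        ("plans for mycophenolate mofetil taper", 1),
    ],
)
def test_medication_mention_matching(text, n):
    lex = MedicationLexicon(
        [
            LexiconTerm("methotrexate", "antimetabolite"),
            LexiconTerm("CellCept", "immunosuppressant"),
            LexiconTerm("mycophenolate mofetil", "immunosuppressant"),
        ]
    )
    notes = pd.DataFrame(
        [{"note_id": "N1", "patient_id": "P1", "note_date": "2001-05-05", "text": text}]
    )
    assert len(detect_medication_mentions(notes, lex)) == n


def test_negation_filter_behind_flag():
    lex = MedicationLexicon([LexiconTerm("methotrexate", "antimetabolite")])
    notes = pd.DataFrame(
        [{"note_id": "N1", "patient_id": "P1", "note_date": "2001-05-05",
          "text": "Patient denies methotrexate use."}]
    )
    assert len(detect_medication_mentions(notes, lex)) == 1  # default: sensitive
    assert len(detect_medication_mentions(notes, lex, negation_filter=True)) == 0


def test_empty_lexicon_rejected():
    with pytest.raises(ValueError):
        MedicationLexicon([])


def _labs(days, patient="P1"):
    return pd.DataFrame(
        {
            "lab_id": [f"L{d}" for d in days],
            "patient_id": patient,
            "trait": "HGB",
            "value": 14.0,
            "sample_date": [date.fromordinal(DAY0 + d).isoformat() for d in days],
        }
    )


def test_exclusion_boundaries_closed_interval():
    events = pd.DataFrame([_event("P1", "CPT4", "00560", 100)])
    windows, _ = build_exclusion_windows(events, _registry())
    result = exclude_values(_labs([99, 100, 150, 190, 191]), windows)
    assert result["decision"].tolist() == ["keep", "exclude", "exclude", "exclude", "keep"]
    excl = result[result["decision"] == "exclude"]
    assert (excl["reasons"] == "surgery_blood_loss").all()
    assert (excl["event_ids"] != "").all()


def test_filter_matches_truth_oracle_on_fixtures(registry, lexicon):
    for seed in (0, 1, 2):
        ds = simulate_dataset(
            SimConfig(n_patients=60, m_snps=5, seed=seed), registry=registry,
            lexicon=lexicon,
        )
        result, report = run_filter(ds.labs, ds.events, ds.notes, registry, lexicon)
        truth = ds.truth.values
        assert (
            (result["decision"] == "exclude").to_numpy() == truth["excluded"].to_numpy()
        ).all()
        # reason sets agree exactly
        assert (
            result["reasons"].to_numpy() == truth["reason"].to_numpy()
        ).all()
        assert report["values_kept"] + report["values_excluded"] == len(ds.labs)


def test_enlarging_window_grows_excluded_set():
    events = pd.DataFrame([_event("P1", "CPT4", "00560", 100)])
    labs = _labs(list(range(80, 260, 10)))
    small = _registry()
    big = CodeRegistry(
        entries=small.entries,
        policies={
            "surgery": WindowPolicy("surgery", lookback_days=10, duration_days=150),
            "chronic": small.policies["chronic"],
        },
    )
    w_small, _ = build_exclusion_windows(events, small)
    w_big, _ = build_exclusion_windows(events, big)
    excl_small = set(
        exclude_values(labs, w_small).query("decision == 'exclude'")["lab_id"]
    )
    excl_big = set(exclude_values(labs, w_big).query("decision == 'exclude'")["lab_id"])
    assert excl_small <= excl_big and len(excl_big) > len(excl_small)


def test_audit_log_reconstructs_kept_set(small_dataset, registry, lexicon):
    result, _ = run_filter(
        small_dataset.labs, small_dataset.events, small_dataset.notes, registry, lexicon
    )
    excluded = result[result["decision"] == "exclude"]
    assert (excluded["reasons"] != "").all()
    assert (excluded["event_ids"] != "").all()
    kept_from_audit = set(result["lab_id"]) - set(excluded["lab_id"])
    assert kept_from_audit == set(result.query("decision == 'keep'")["lab_id"])


def test_drop_empty_patients():
    fr = pd.DataFrame(
        {
            "lab_id": ["L1", "L2", "L3", "L4"],
            "patient_id": ["P1", "P1", "P2", "P3"],
            "trait": ["HGB", "HCT", "HGB", "HGB"],
            "sample_date": ["2001-01-01"] * 4,
            "decision": ["exclude", "keep", "exclude", "keep"],
            "reasons": ["surgery_blood_loss", "", "condition", ""],
            "event_ids": ["E1", "", "E2", ""],
        }
    )
    cohort, dropped, per_trait = drop_empty_patients(fr)
    assert cohort == ["P1", "P3"] and dropped == ["P2"]
    hgb = per_trait.set_index("trait").loc["HGB"]
    assert hgb["values_kept"] == 1 and hgb["values_excluded"] == 2


def test_no_exclusions_drops_nobody():
    fr = pd.DataFrame(
        {
            "lab_id": ["L1", "L2"],
            "patient_id": ["P1", "P2"],
            "trait": ["HGB", "HGB"],
            "sample_date": ["2001-01-01"] * 2,
            "decision": ["keep", "keep"],
            "reasons": ["", ""],
            "event_ids": ["", ""],
        }
    )
    cohort, dropped, _ = drop_empty_patients(fr)
    assert dropped == [] and cohort == ["P1", "P2"]
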