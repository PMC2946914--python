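"""Merging and cleaning of multi-source EMR lab-result tables.

Raw extracts from different EMR subsystems carry site-specific test
codes, free-text result fields, and overlapping coverage.  This module
harmonizes them into one table of dated, numeric trait values, and
applies the inpatient rule: values drawn during a hospitalization
(admit date <= sample date <= discharge date, boundaries inclusive) are
excluded unless they are the only values available for that
patient/trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TRAITS, UNIT_WHITELIST

REQUIRED_COLUMNS = ("patient_id", "test_code", "sample_date", "result", "accession")


@dataclass
class LoadReport:
    """Accounting of :func:`load_lab_results`: input = kept + each drop."""

    n_input: int = 0
    n_kept: int = 0
    n_unmapped: int = 0
    n_nonnumeric: int = 0
    n_duplicate: int = 0
    n_bad_unit: int = 0

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "kept": self.n_kept,
            "dropped_unmapped": self.n_unmapped,
            "dropped_nonnumeric": self.n_nonnumeric,
            "dropped_duplicate": self.n_duplicate,
            "dropped_bad_unit": self.n_bad_unit,
        }

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_kept
            + self.n_unmapped
            + self.n_nonnumeric
            + self.n_duplicate
            + self.n_bad_unit
        )


def load_lab_results(
    source_tables: list[pd.DataFrame],
    test_code_map: dict[str, str],
    check_units: bool = False,
) -> tuple[pd.DataFrame, LoadReport]:
    """Merge raw lab extracts into a clean LabResult table.

    Each raw table needs columns ``patient_id, test_code, sample_date,
    result, accession`` (optional ``units``, ``source``).  Records with
    unmapped test codes or non-numeric result text are dropped and
    counted; duplicates on (patient_id, accession, trait) — the same
    physical test surfacing in several sources — collapse to one.

    Returns ``(labs, report)``; the report reconciles exactly.
    """
    frames = []
    for k, tab in enumerate(source_tables):
        missing = [c for c in REQUIRED_COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(
                f"source table {k}: missing mandatory column(s) {', '.join(missing)}"
            )
        t = tab.copy()
        if "source" not in t.columns:
            t["source"] = f"source{k}"
        if "units" not in t.columns:
            t["units"] = ""
        frames.append(t[list(REQUIRED_COLUMNS) + ["units", "source"]])
    raw = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(REQUIRED_COLUMNS) + ["units", "source"]
    )
    report = LoadReport(n_input=len(raw))

    trait = raw["test_code"].astype(str).map(test_code_map)
    unmapped = trait.isna() | ~trait.isin(TRAITS)
    report.n_unmapped = int(unmapped.sum())
    raw = raw[~unmapped].assign(trait=trait[~unmapped])

    value = pd.to_numeric(raw["result"], errors="coerce")
    nonnum = value.isna() | ~np.isfinite(value)
    report.n_nonnumeric = int(nonnum.sum())
    raw = raw[~nonnum].assign(value=value[~nonnum])

    if check_units:
        ok = [
            (u == "") or (u in UNIT_WHITELIST.get(t, set()))
            for u, t in zip(raw["units"].astype(str), raw["trait"])
        ]
        ok = np.asarray(ok, dtype=bool)
        report.n_bad_unit = int((~ok).sum())
        raw = raw[ok]

    # deterministic dedup: order by source then accession, keep first
    raw = raw.sort_values(
        ["patient_id", "accession", "trait", "source"], kind="mergesort"
    )
    dup = raw.duplicated(subset=["patient_id", "accession", "trait"], keep="first")
    report.n_duplicate = int(dup.sum())
    labs = raw[~dup].reset_index(drop=True)

    labs = labs[
        ["patient_id", "trait", "value", "sample_date", "accession", "source"]
    ].copy()
    labs.insert(0, "lab_id", [f"L{i:07d}" for i in range(len(labs))])
    report.n_kept = len(labs)
    assert report.reconciles()
    return labs, report


def flag_inpatient(labs: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Add a boolean ``inpatient`` column: True iff some hospitalization
    episode of the same patient satisfies admit <= sample <= discharge
    (date-only comparison, boundaries inclusive)."""
    out = labs.copy()
    if len(episodes) == 0:
        out["inpatient"] = False
        return out
    sample = pd.to_datetime(out["sample_date"]).dt.normalize()
    flag = np.zeros(len(out), dtype=bool)
    epi = episodes.assign(
        _admit=pd.to_datetime(episodes["admit_date"]).dt.normalize(),
        _disch=pd.to_datetime(episodes["discharge_date"]).dt.normalize(),
    )
    if (epi["_admit"] > epi["_disch"]).any():
        raise ValueError("episode with admit_date > discharge_date")
    for pid, grp in epi.groupby("patient_id", sort=False):
        mask = out["patient_id"].to_numpy() == pid
        if not mask.any():
            continue
        s = sample[mask]
        hit = np.zeros(int(mask.sum()), dtype=bool)
        for a, d in zip(grp["_admit"], grp["_disch"]):
            hit |= ((s >= a) & (s <= d)).to_numpy()
        flag[mask] = hit
    out["inpatient"] = flag
    return out


def apply_inpatient_exclusion(
    flagged_labs: pd.DataFrame, rescue_scope: str = "patient-trait"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove inpatient values, with the rescue rule: if ALL values of a
    (patient, trait) pair — or of a patient, with
    ``rescue_scope='patient'`` — are inpatient, they are retained (they
    are the only tests available).

    Returns ``(kept, excluded)``; the two partition the input.
    """
    if "inpatient" not in flagged_labs.columns:
        raise ValueError("labs must carry the inpatient flag (run flag_inpatient)")
    if rescue_scope not in ("patient-trait", "patient"):
        raise ValueError(f"unknown rescue_scope {rescue_scope!r}")
    keys = (
        ["patient_id", "trait"] if rescue_scope == "patient-trait" else ["patient_id"]
    )
    all_inpatient = flagged_labs.groupby(keys)["inpatient"].transform("all")
    rescued = flagged_labs["inpatient"] & all_inpatient
    drop = flagged_labs["inpatient"] & ~all_inpatient
    kept = flagged_labs[~drop].copy()
    kept["rescued"] = rescued[~drop]
    excluded = flagged_labs[drop].copy()
    return kept, excluded
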