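"""Per-patient phenotype aggregation and cohort summary.

Repeated measurements collapse to one phenotype per patient per trait:
the median (even counts: mean of the two central order statistics).
The cohort summary reports mean ± SD and [Q1, median, Q3]
(linear-interpolation quantiles) per trait, with Welch two-sample tests
for group differences of continuous variables and chi-square tests for
proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TRAITS


def aggregate_median(
    kept_labs: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per patient: per-trait median phenotype and measurement
    count, plus covariates if supplied (joined on patient_id).

    Columns: ``patient_id, <TRAIT>..., n_<TRAIT>..., [age, male, pad]``.
    """
    med = kept_labs.groupby(["patient_id", "trait"])["value"].agg(["median", "size"])
    med = med.unstack("trait")
    out = pd.DataFrame({"patient_id": med.index})
    for t in TRAITS:
        if t in med["median"].columns:
            out[t] = med["median"][t].to_numpy()
            out[f"n_{t}"] = med["size"][t].fillna(0).astype(int).to_numpy()
        else:
            out[t] = np.nan
            out[f"n_{t}"] = 0
    if covariates is not None:
        out = out.merge(
            covariates[["patient_id", "age", "male", "pad"]], on="patient_id", how="left"
        )
    return out.reset_index(drop=True)


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    return tuple(np.quantile(x, [0.25, 0.5, 0.75]))  # linear interpolation


def cohort_summary(
    phenotypes: pd.DataFrame, group_col: str = "pad"
) -> pd.DataFrame:
    """Cohort characteristics overall and by group, with group P values.

    Continuous rows (age + traits): mean, SD, quartiles per group and a
    Welch unequal-variance t-test P; proportion rows (male): count,
    percent and a chi-square P.  If a group is empty the P column is NaN
    and the row is flagged.

    Output columns: variable, kind, overall/case/control summary stats,
    formatted display strings, p_value, flag.
    """
    grp = phenotypes[group_col].to_numpy()
    case = phenotypes[grp == 1]
    ctrl = phenotypes[grp == 0]
    degenerate = len(case) < 2 or len(ctrl) < 2

    rows = []

    def cont_row(name, col):
        vals = {}
        for label, df in (("overall", phenotypes), ("case", case), ("control", ctrl)):
            x = df[col].dropna().to_numpy(dtype=float)
            if len(x):
                q1, q2, q3 = _quartiles(x)
                vals[label] = dict(
                    mean=float(np.mean(x)),
                    sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                    q1=q1,
                    median=q2,
                    q3=q3,
                    n=len(x),
                )
            else:
                vals[label] = dict(mean=np.nan, sd=np.nan, q1=np.nan, median=np.nan, q3=np.nan, n=0)
        if degenerate:
            p = np.nan
        else:
            a = case[col].dropna().to_numpy(dtype=float)
            b = ctrl[col].dropna().to_numpy(dtype=float)
            if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        o, ca, co = vals["overall"], vals["case"], vals["control"]
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "overall": _fmt(o),
                "case": _fmt(ca),
                "control": _fmt(co),
                "overall_mean": o["mean"],
                "overall_sd": o["sd"],
                "overall_q1": o["q1"],
                "overall_median": o["median"],
                "overall_q3": o["q3"],
                "case_mean": ca["mean"],
                "control_mean": co["mean"],
                "p_value": p,
                "flag": "empty-group" if degenerate else "",
            }
        )

    def prop_row(name, col):
        k_case, k_ctrl = int(case[col].sum()), int(ctrl[col].sum())
        n_case, n_ctrl = len(case), len(ctrl)
        if degenerate:
            p = np.nan
        else:
            table = np.array(
                [[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]], dtype=float
            )
            if (table.sum(axis=0) == 0).any():
                p = np.nan
            else:
                p = float(stats.chi2_contingency(table, correction=False).pvalue)
        k_all = k_case + k_ctrl
        n_all = len(phenotypes)
        rows.append(
            {
                "variable": name,
                "kind": "proportion",
                "overall": f"{k_all} ({100 * k_all / max(n_all, 1):.1f})",
                "case": f"{k_case} ({100 * k_case / max(n_case, 1):.1f})",
                "control": f"{k_ctrl} ({100 * k_ctrl / max(n_ctrl, 1):.1f})",
                "overall_mean": k_all / max(n_all, 1),
                "case_mean": k_case / max(n_case, 1),
                "control_mean": k_ctrl / max(n_ctrl, 1),
                "p_value": p,
                "flag": "empty-group" if degenerate else "",
            }
        )

    if "age" in phenotypes.columns:
        cont_row("age", "age")
    if "male" in phenotypes.columns:
        prop_row("male", "male")
    for t in TRAITS:
        if t in phenotypes.columns:
            cont_row(t, t)
    return pd.DataFrame(rows)


def _fmt(v: dict) -> str:
    if v["n"] == 0:
        return "n=0"
    return (
        f"{v['mean']:.1f}±{v['sd']:.1f} "
        f"[{v['q1']:.1f}, {v['median']:.1f}, {v['q3']:.1f}]"
    )
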