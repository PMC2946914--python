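"""Marker and sample quality control.

Implements the standard GWAS QC funnel on a dosage matrix: external
sample exclusions (ancestry / relatedness / label errors supplied as a
list), call rates, minor allele frequency, and the Levene–Haldane exact
test of Hardy–Weinberg equilibrium.  Thresholds follow common platform
practice: keep SNP call rate > 98%, sample call rate > 98%, MAF > 0.05,
HWE exact P > 0.001 — comparisons are strict in the stated direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .plink import GenotypeMatrix


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.98
    sample_call_rate_min: float = 0.98
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    sample_exclusion_list: list = field(default_factory=list)

    def validate(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")


def call_rates(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-marker, per-sample) fraction of non-missing genotypes."""
    if g.n_samples == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    called = g.dosage >= 0
    return called.mean(axis=0), called.mean(axis=1)


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Folded allele frequency min(f, 1-f) per marker; NaN where no
    genotype is called."""
    called = g.dosage >= 0
    n_called = called.sum(axis=0)
    total = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = total / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    maf[n_called == 0] = np.nan
    return maf


@lru_cache(maxsize=None)
def _hwe_het_probs(n_genotypes: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele
    counts (Levene–Haldane), built by the stable ratio recurrence from
    the lowest-parity heterozygote count upward.

    Returns (het_values, probabilities), normalized.
    """
    n_common = 2 * n_genotypes - n_rare
    h0 = n_rare % 2
    hets = np.arange(h0, min(n_rare, n_common) + 1, 2)
    # P(h+2)/P(h) = (n_rare - h)(n_common - h) / ((h + 2)(h + 1))
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        h = hets[k - 1]
        logp[k] = logp[k - 1] + np.log(
            (n_rare - h) * (n_common - h) / ((h + 2.0) * (h + 1.0))
        )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count (probability-mass ordering).  Returns p in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    hets, probs = _hwe_het_probs(n, n_rare)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    # tolerance guards against ties split by floating rounding
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker exact HWE p; NaN where no genotype is called."""
    out = np.full(g.n_markers, np.nan)
    d = g.dosage
    for j in range(g.n_markers):
        col = d[:, j]
        called = col >= 0
        if not called.any():
            continue
        c = col[called]
        out[j] = hwe_exact_test(
            int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
        )
    return out


@dataclass
class QCReport:
    """Per-step drop accounting; kept + dropped reconcile at each step."""

    steps: list = field(default_factory=list)

    def add(self, step: str, axis: str, n_before: int, n_dropped: int, ids: list):
        self.steps.append(
            {
                "step": step,
                "axis": axis,
                "n_before": n_before,
                "n_dropped": n_dropped,
                "n_after": n_before - n_dropped,
                "dropped_ids": list(ids),
            }
        )

    def as_dict(self) -> dict:
        return {"steps": [dict(s) for s in self.steps]}


def apply_qc(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the QC funnel in a fixed, logged order.

    1. drop samples on the external exclusion list,
    2. drop samples with call rate <= sample_call_rate_min,
    3. drop markers with call rate <= snp_call_rate_min,
    4. drop markers with MAF <= maf_min,
    5. drop markers with HWE exact p <= hwe_p_min.

    Samples go before markers so a bad sample cannot take markers down
    with it.  Returns ``(filtered, report)``.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    report = QCReport()

    excl = set(map(str, thresholds.sample_exclusion_list))
    keep_s = np.array([str(s) not in excl for s in g.samples])
    report.add(
        "sample_exclusion_list", "samples", g.n_samples, int((~keep_s).sum()),
        [s for s, k in zip(g.samples, keep_s) if not k],
    )
    g = g.subset(sample_mask=keep_s)

    _, sample_cr = call_rates(g)
    keep_s = sample_cr > thresholds.sample_call_rate_min
    report.add(
        "sample_call_rate", "samples", g.n_samples, int((~keep_s).sum()),
        [s for s, k in zip(g.samples, keep_s) if not k],
    )
    g = g.subset(sample_mask=keep_s)

    marker_cr, _ = call_rates(g)
    keep_m = marker_cr > thresholds.snp_call_rate_min
    report.add(
        "snp_call_rate", "markers", g.n_markers, int((~keep_m).sum()),
        list(g.markers.loc[~keep_m, "marker_id"]),
    )
    g = g.subset(marker_mask=keep_m)

    maf = minor_allele_frequency(g)
    keep_m = maf > thresholds.maf_min
    report.add(
        "maf", "markers", g.n_markers, int((~keep_m).sum()),
        list(g.markers.loc[~keep_m, "marker_id"]),
    )
    g = g.subset(marker_mask=keep_m)

    hwe = hwe_pvalues(g)
    keep_m = hwe > thresholds.hwe_p_min
    report.add(
        "hwe", "markers", g.n_markers, int((~keep_m).sum()),
        list(g.markers.loc[~keep_m, "marker_id"]),
    )
    g = g.subset(marker_mask=keep_m)
    return g, report
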