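"""Value-level exclusion of lab results affected by comorbidity,
medication, or blood loss.

The phenotyping algorithm: billing/procedure codes (ICD-9-CM,
procedural ICD-9, CPT-4) and medication mentions found in clinical
notes each open a time window around the event date; any trait value
whose sample date falls inside a window of its patient is excluded,
with machine-readable reasons forming a complete audit trail.

The bundled registry and medication lexicon are ILLUSTRATIVE, not
authoritative: they contain a small, documented set of representative
codes/drugs per category and are meant to be replaced by a site's own
curated lists (CSV + YAML, see :func:`load_registry`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

CATEGORIES = (
    "condition",
    "transplant",
    "medication_code",
    "surgery_blood_loss",
)
CODE_SYSTEMS = ("ICD9CM", "ICD9PROC", "CPT4")

#: window-policy name used for each category in the default policy file
DEFAULT_CATEGORY_POLICY = {
    "condition": "chronic",
    "transplant": "chronic",
    "medication_code": "medication",
    "medication_nlp": "medication",
    "surgery_blood_loss": "surgery",
}


@dataclass(frozen=True)
class WindowPolicy:
    """Exclusion window around an event date.

    The window is ``[event - lookback_days, event + duration_days]``,
    closed on both finite ends; ``chronic`` policies have no right end
    (the condition permanently disqualifies later values).
    """

    name: str
    lookback_days: int
    duration_days: int | None = None  # None => chronic

    @property
    def chronic(self) -> bool:
        return self.duration_days is None

    def __post_init__(self):
        if self.lookback_days < 0:
            raise ValueError("lookback_days must be >= 0")
        if self.duration_days is not None and self.duration_days <= 0:
            raise ValueError("duration_days must be > 0 or None (chronic)")


@dataclass(frozen=True)
class RegistryEntry:
    """One exclusion trigger: a code (or code-prefix ``282*``) in one
    coding system, tied to a category and a window policy name."""

    category: str
    code_system: str
    code: str
    policy: str
    description: str = ""

    @property
    def is_prefix(self) -> bool:
        return self.code.endswith("*")

    def matches(self, code_system: str, code: str) -> bool:
        if code_system != self.code_system:
            return False
        if self.is_prefix:
            return code.startswith(self.code[:-1])
        return code == self.code

    def concrete_code(self, rng=None) -> str:
        """A concrete code matching this entry (used by the simulator)."""
        if not self.is_prefix:
            return self.code
        stem = self.code[:-1]
        digit = "0" if rng is None else str(int(rng.integers(0, 10)))
        return stem + ("" if stem.endswith(".") else ".") + digit


@dataclass
class CodeRegistry:
    entries: list[RegistryEntry]
    policies: dict[str, WindowPolicy]
    category_policy: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_POLICY)
    )

    def __post_init__(self):
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category {e.category!r}")
            if e.code_system not in CODE_SYSTEMS:
                raise ValueError(f"unknown code system {e.code_system!r}")
            if e.policy not in self.policies:
                raise ValueError(f"entry {e.code}: unknown policy {e.policy!r}")

    def policy_for(self, entry: RegistryEntry) -> WindowPolicy:
        return self.policies[entry.policy]

    def policy_for_category(self, category: str) -> WindowPolicy:
        return self.policies[self.category_policy[category]]

    def match(self, code_system: str, code: str) -> RegistryEntry | None:
        """First matching entry, exact matches preferred over prefixes."""
        hit = None
        for e in self.entries:
            if e.matches(code_system, code):
                if not e.is_prefix:
                    return e
                hit = hit or e
        return hit


@dataclass(frozen=True)
class LexiconTerm:
    name: str
    drug_class: str


@dataclass
class MedicationLexicon:
    """Generic and brand names of marrow-suppressing / immunosuppressive
    drugs; matching is case-insensitive on word boundaries, multi-word
    brand names match as phrases."""

    terms: list[LexiconTerm]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("lexicon must be non-empty")
        names = [t.name.lower() for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate lexicon names")

    def compile(self) -> list[tuple[LexiconTerm, re.Pattern]]:
        out = []
        for t in self.terms:
            words = [re.escape(w) for w in t.name.split()]
            pat = re.compile(r"\b" + r"\s+".join(words) + r"\b", re.IGNORECASE)
            out.append((t, pat))
        return out


# ---------------------------------------------------------------------------
# bundled defaults

def _data_path(name: str):
    return resources.files("emrqtl").joinpath("data", name)


def load_policies(path=None) -> dict[str, WindowPolicy]:
    """Read window policies from YAML ({name: {lookback_days, duration_days
    or 'chronic'}}); bundled defaults when path is None."""
    raw = yaml.safe_load(
        Path(path).read_text() if path else _data_path("policies.yaml").read_text()
    )
    out = {}
    for name, spec in raw.items():
        dur = spec.get("duration_days", "chronic")
        out[name] = WindowPolicy(
            name=name,
            lookback_days=int(spec.get("lookback_days", 0)),
            duration_days=None if dur in (None, "chronic") else int(dur),
        )
    return out


def load_registry(path=None, policies=None) -> CodeRegistry:
    """Read a code registry from CSV (category, code_system, code, policy,
    description); bundled illustrative defaults when path is None."""
    policies = policies or load_policies()
    src = Path(path) if path else _data_path("registry.csv")
    df = pd.read_csv(src, dtype=str).fillna("")
    entries = [
        RegistryEntry(
            category=r["category"],
            code_system=r["code_system"],
            code=r["code"],
            policy=r["policy"],
            description=r.get("description", ""),
        )
        for r in df.to_dict("records")
    ]
    return CodeRegistry(entries=entries, policies=policies)


def load_lexicon(path=None) -> MedicationLexicon:
    """Read a medication lexicon from CSV (name, drug_class)."""
    src = Path(path) if path else _data_path("lexicon.csv")
    df = pd.read_csv(src, dtype=str).fillna("")
    return MedicationLexicon(
        terms=[LexiconTerm(r["name"], r["drug_class"]) for r in df.to_dict("records")]
    )


def default_registry() -> CodeRegistry:
    return load_registry()


def default_lexicon() -> MedicationLexicon:
    return load_lexicon()


# ---------------------------------------------------------------------------
# operations

@dataclass
class Interval:
    """One merged exclusion interval (days are date ordinals)."""

    start: float
    end: float  # math.inf for chronic
    category: str
    event_ids: tuple


def _ordinal(d) -> int:
    return date.fromisoformat(str(d)[:10]).toordinal()


def build_exclusion_windows(
    events: pd.DataFrame, registry: CodeRegistry
) -> tuple[dict, dict]:
    """Map events through the registry into per-patient exclusion
    intervals.

    Each matching event yields ``[event_date - lookback, event_date +
    duration]`` (right end +inf for chronic policies); per patient,
    overlapping or touching intervals of the same category are merged
    and keep every triggering event id.

    Returns ``(windows, report)``: ``windows[patient_id]`` is a list of
    :class:`Interval`; the report counts matched/unmatched/unknown-system
    events.
    """
    report = {"events_in": len(events), "matched": 0, "unmatched": 0, "unknown_system": 0}
    raw: dict[str, list] = {}
    for row in events.itertuples(index=False):
        system = getattr(row, "code_system")
        if system not in CODE_SYSTEMS:
            report["unknown_system"] += 1
            continue
        entry = registry.match(system, getattr(row, "code"))
        if entry is None:
            report["unmatched"] += 1
            continue
        report["matched"] += 1
        pol = registry.policy_for(entry)
        day = _ordinal(getattr(row, "event_date"))
        start = day - pol.lookback_days
        end = math.inf if pol.chronic else day + pol.duration_days
        raw.setdefault(getattr(row, "patient_id"), []).append(
            (entry.category, start, end, getattr(row, "event_id"))
        )
    windows = {
        pid: _merge_intervals(items) for pid, items in raw.items()
    }
    return windows, report


def _merge_intervals(items) -> list[Interval]:
    """Merge overlapping same-category intervals; deterministic order."""
    out = []
    by_cat: dict[str, list] = {}
    for cat, start, end, eid in items:
        by_cat.setdefault(cat, []).append((start, end, eid))
    for cat in sorted(by_cat):
        ivs = sorted(by_cat[cat], key=lambda x: (x[0], x[1] if x[1] != math.inf else 1e18))
        cur_s, cur_e, cur_ids = ivs[0][0], ivs[0][1], [ivs[0][2]]
        for s, e, eid in ivs[1:]:
            if s <= cur_e:  # closed intervals: touching == overlapping
                cur_e = max(cur_e, e)
                cur_ids.append(eid)
            else:
                out.append(Interval(cur_s, cur_e, cat, tuple(sorted(cur_ids))))
                cur_s, cur_e, cur_ids = s, e, [eid]
        out.append(Interval(cur_s, cur_e, cat, tuple(sorted(cur_ids))))
    return out


def detect_medication_mentions(
    notes: pd.DataFrame,
    lexicon: MedicationLexicon,
    negation_filter: bool = False,
) -> pd.DataFrame:
    """Dictionary matching of drug names in note text.

    One event per (note, matched term); whole-word, case-insensitive,
    multi-word phrases allowed.  With ``negation_filter`` a basic
    "no/denies/without/not on <term>" same-sentence filter suppresses
    the match (off by default: exclusion-oriented sensitivity).

    Returns an EventTable with ``code_system='NLP'`` and the matched
    term in ``code``; dated by the note date.
    """
    compiled = lexicon.compile()
    rows = []
    for row in notes.itertuples(index=False):
        text = str(getattr(row, "text"))
        for term, pat in compiled:
            m = pat.search(text)
            if not m:
                continue
            if negation_filter and _is_negated(text, m.start()):
                continue
            rows.append(
                {
                    "event_id": f"NLP-{getattr(row, 'note_id')}-{term.name.replace(' ', '_')}",
                    "patient_id": getattr(row, "patient_id"),
                    "code_system": "NLP",
                    "code": term.name,
                    "event_date": getattr(row, "note_date"),
                    "matched_term": term.name,
                    "drug_class": term.drug_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "patient_id",
            "code_system",
            "code",
            "event_date",
            "matched_term",
            "drug_class",
        ],
    )


_NEGATORS = re.compile(r"\b(no|denies|denied|without|not\s+on|never\s+on)\b", re.IGNORECASE)


def _is_negated(text: str, pos: int) -> bool:
    sent_start = max(text.rfind(".", 0, pos), text.rfind(";", 0, pos)) + 1
    return bool(_NEGATORS.search(text[sent_start:pos]))


def medication_windows(
    mentions: pd.DataFrame, registry: CodeRegistry
) -> dict:
    """Exclusion intervals from NLP medication mentions (the
    ``medication_nlp`` category), merged per patient."""
    pol = registry.policy_for_category("medication_nlp")
    raw: dict[str, list] = {}
    for row in mentions.itertuples(index=False):
        day = _ordinal(getattr(row, "event_date"))
        end = math.inf if pol.chronic else day + pol.duration_days
        raw.setdefault(getattr(row, "patient_id"), []).append(
            ("medication_nlp", day - pol.lookback_days, end, getattr(row, "event_id"))
        )
    return {pid: _merge_intervals(items) for pid, items in raw.items()}


def merge_windows(*window_maps: dict) -> dict:
    """Combine per-patient interval maps (re-merging per category)."""
    raw: dict[str, list] = {}
    for wm in window_maps:
        for pid, ivs in wm.items():
            for iv in ivs:
                for eid in iv.event_ids:
                    raw.setdefault(pid, []).append((iv.category, iv.start, iv.end, eid))
    return {pid: _merge_intervals(items) for pid, items in raw.items()}


def exclude_values(labs: pd.DataFrame, windows: dict) -> pd.DataFrame:
    """Apply exclusion windows to lab values.

    Returns a FilterResult table aligned with ``labs``: ``lab_id,
    patient_id, trait, sample_date, decision (keep|exclude), reasons
    (';'-joined categories), event_ids (';'-joined triggers)``.
    A value is excluded iff its sample date lies in at least one
    interval of its patient; all covering categories are recorded.
    """
    decisions, reasons, eids = [], [], []
    day = labs["sample_date"].map(_ordinal).to_numpy()
    pids = labs["patient_id"].to_numpy()
    for i in range(len(labs)):
        cats, ids = [], []
        for iv in windows.get(pids[i], ()):
            if iv.start <= day[i] <= iv.end:
                if iv.category not in cats:
                    cats.append(iv.category)
                ids.extend(iv.event_ids)
        if cats:
            decisions.append("exclude")
            reasons.append(";".join(sorted(cats)))
            eids.append(";".join(sorted(set(ids))))
        else:
            decisions.append("keep")
            reasons.append("")
            eids.append("")
    return pd.DataFrame(
        {
            "lab_id": labs["lab_id"].to_numpy(),
            "patient_id": pids,
            "trait": labs["trait"].to_numpy(),
            "sample_date": labs["sample_date"].to_numpy(),
            "decision": decisions,
            "reasons": reasons,
            "event_ids": eids,
        }
    )


def drop_empty_patients(
    filter_result: pd.DataFrame,
) -> tuple[list, list, pd.DataFrame]:
    """Patients with no kept value for any trait are dropped from the
    cohort.

    Returns ``(cohort_patients, dropped_patients, per_trait_counts)``;
    the counts table reports kept/excluded per trait plus the number of
    patients retaining at least one value of each trait.
    """
    kept = filter_result[filter_result["decision"] == "keep"]
    all_pids = pd.unique(filter_result["patient_id"])
    kept_pids = set(kept["patient_id"])
    cohort = sorted(kept_pids)
    dropped = sorted(set(all_pids) - kept_pids)
    rows = []
    for trait, grp in filter_result.groupby("trait", sort=True):
        k = grp["decision"].eq("keep")
        rows.append(
            {
                "trait": trait,
                "values_kept": int(k.sum()),
                "values_excluded": int((~k).sum()),
                "patients_with_value": int(grp.loc[k, "patient_id"].nunique()),
            }
        )
    return cohort, dropped, pd.DataFrame(rows)


def run_filter(
    labs: pd.DataFrame,
    events: pd.DataFrame,
    notes: pd.DataFrame,
    registry: CodeRegistry | None = None,
    lexicon: MedicationLexicon | None = None,
    negation_filter: bool = False,
):
    """Convenience wrapper: codes + NLP mentions -> FilterResult.

    Returns ``(filter_result, report)`` with the window-construction
    report augmented by decision counts.
    """
    registry = registry or default_registry()
    lexicon = lexicon or default_lexicon()
    code_windows, report = build_exclusion_windows(events, registry)
    mentions = detect_medication_mentions(notes, lexicon, negation_filter=negation_filter)
    nlp_windows = medication_windows(mentions, registry)
    windows = merge_windows(code_windows, nlp_windows)
    result = exclude_values(labs, windows)
    report = dict(report)
    report["nlp_mentions"] = len(mentions)
    report["values_in"] = len(result)
    report["values_excluded"] = int((result["decision"] == "exclude").sum())
    report["values_kept"] = int((result["decision"] == "keep").sum())
    return result, report
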