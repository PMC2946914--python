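"""Red-blood-cell trait definitions and hematological identities.

The six complete-blood-count red-cell measures form two groups: the
directly measured quantities (hemoglobin concentration, hematocrit,
RBC count) and the derived erythrocyte indices

    MCV  = 10 * HCT / RBC    (fL)
    MCH  = 10 * HGB / RBC    (pg)
    MCHC = 100 * HGB / HCT   (%  == g/dL per packed-cell volume)

These identities are exact at the level of a single blood sample and
are the source of the strong cross-trait correlation seen in any CBC
panel.
"""

from __future__ import annotations

import numpy as np

#: canonical trait order used throughout the package
TRAITS = ("HGB", "HCT", "RBC", "MCV", "MCH", "MCHC")

#: the directly measured primaries; indices are derived from them
PRIMARY_TRAITS = ("HGB", "HCT", "RBC")
DERIVED_TRAITS = ("MCV", "MCH", "MCHC")

#: reporting units per trait
UNITS = {
    "HGB": "g/dL",
    "HCT": "%",
    "RBC": "x10^12/L",
    "MCV": "fL",
    "MCH": "pg",
    "MCHC": "%",
}

#: accepted unit spellings per trait (EMR sources are inconsistent)
UNIT_WHITELIST = {
    "HGB": {"g/dl", "g/dL", "G/DL"},
    "HCT": {"%", "percent"},
    "RBC": {"x10^12/L", "10*12/L", "M/uL", "x10(12)/L"},
    "MCV": {"fl", "fL", "FL"},
    "MCH": {"pg", "PG"},
    "MCHC": {"%", "g/dl", "g/dL"},
}

#: decimals used when values are reported by the (simulated) analyzer
REPORT_DECIMALS = {"HGB": 1, "HCT": 1, "RBC": 2, "MCV": 1, "MCH": 1, "MCHC": 1}


def derive_indices(hgb, hct, rbc):
    """Compute (MCV, MCH, MCHC) from the measured primaries.

    Accepts scalars or arrays; vectorized.
    """
    hgb = np.asarray(hgb, dtype=float)
    hct = np.asarray(hct, dtype=float)
    rbc = np.asarray(rbc, dtype=float)
    mcv = 10.0 * hct / rbc
    mch = 10.0 * hgb / rbc
    mchc = 100.0 * hgb / hct
    return mcv, mch, mchc
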