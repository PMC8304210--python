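"""Risk stratification and diagnostic opinion for suspected APL.

The Sanz/PETHEMA-GIMEMA score stratifies newly diagnosed acute
promyelocytic leukemia by two complete-blood-count values:

* high risk:         WBC > 10 x 10^9/L
* low risk:          WBC <= 10 and platelets > 40 x 10^9/L
* intermediate risk: WBC <= 10 and platelets <= 40 x 10^9/L

A smear is flagged as morphologically suspicious when the classifier finds
promyelocytes in peripheral blood (any positive count by default — their
presence outside the marrow is itself abnormal). The emitted treatment
text mirrors current induction guidance (ATRA + arsenic, plus
chemotherapy induction for high-risk patients) and is advisory only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compact_net.model import CLASS_NAMES

__all__ = ["CBCPanel", "CellCountSummary", "DiagnosticOpinion",
           "stratify_risk", "render_opinion", "DISCLAIMER"]

DISCLAIMER = ("Research prototype output - not for clinical use. "
              "Morphological suspicion requires confirmation by a hematologist "
              "and molecular/flow-cytometric testing.")

TREATMENT_BY_RISK = {
    "low": "ATRA + arsenic",
    "intermediate": "ATRA + arsenic",
    "high": "ATRA + arsenic + chemotherapy induction",
}

_PROMYELOCYTE = CLASS_NAMES.index("promyelocyte")


@dataclass(frozen=True)
class CBCPanel:
    """White-blood-cell and platelet counts, both in 10^9/L."""

    wbc: float
    platelets: float

    def __post_init__(self):
        for name, v in (("wbc", self.wbc), ("platelets", self.platelets)):
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class CellCountSummary:
    """Per-class leukocyte counts aggregated over the examined fields."""

    counts: tuple[int, ...]
    n_fields: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        if len(self.counts) != len(self.class_names):
            raise ValueError("one count per class required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        self.counts = tuple(int(c) for c in self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def promyelocyte_count(self) -> int:
        return self.counts[_PROMYELOCYTE]

    @property
    def promyelocyte_fraction(self) -> float:
        return self.promyelocyte_count / self.total if self.total else 0.0


@dataclass
class DiagnosticOpinion:
    suspected_apl: bool
    risk: str
    potential_treatment: str
    evidence: CellCountSummary
    note: str = ""
    disclaimer: str = DISCLAIMER

    def __post_init__(self):
        if self.suspected_apl != bool(self.potential_treatment):
            raise ValueError("treatment text must be non-empty exactly when "
                             "APL is suspected")

    def as_dict(self) -> dict:
        return {
            "suspected_apl": self.suspected_apl,
            "risk": self.risk,
            "potential_treatment": self.potential_treatment,
            "cell_counts": dict(zip(self.evidence.class_names, self.evidence.counts)),
            "promyelocyte_fraction": self.evidence.promyelocyte_fraction,
            "n_fields": self.evidence.n_fields,
            "note": self.note,
            "disclaimer": self.disclaimer,
        }


def stratify_risk(cbc: CBCPanel) -> str:
    """Sanz risk tier from the CBC panel (thresholds are inclusive:
    WBC of exactly 10 and platelets of exactly 40 are intermediate)."""
    if cbc.wbc > 10.0:
        return "high"
    if cbc.platelets > 40.0:
        return "low"
    return "intermediate"


def render_opinion(summary: CellCountSummary, risk: str,
                   min_promyelocytes: int = 1) -> DiagnosticOpinion:
    """Turn classification counts plus a risk tier into an opinion record."""
    if risk not in TREATMENT_BY_RISK:
        raise ValueError(f"unknown risk tier {risk!r}")
    if min_promyelocytes < 1:
        raise ValueError("min_promyelocytes must be >= 1")
    suspected = summary.promyelocyte_count >= min_promyelocytes
    note = ""
    if summary.total == 0:
        note = "no leukocytes found in the examined fields"
    return DiagnosticOpinion(
        suspected_apl=suspected,
        risk=risk,
        potential_treatment=TREATMENT_BY_RISK[risk] if suspected else "",
        evidence=summary,
        note=note,
    )
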