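"""Questionnaire-based mood-disorder phenotyping.

Assigns each participant to probable bipolar disorder (BD), probable unipolar
mania/hypomania (UM), control, or to a removed stratum (excluded,
depression-only, unclassifiable) from their self-report answers.

Rules
-----
* Participants reporting a severe neurological diagnosis, brain cancer/injury,
  personality disorder, psychosis, schizophrenia, sleep apnoea/insomnia, or a
  shift-work main job are excluded before any analysis.
* Mania core: answered yes to feeling "hyper" or "irritable" for two days or
  more, AND 3 or more manic symptoms (the two instrument dialects count 4 and
  8 candidate symptoms; the absolute threshold of 3 applies to both).
* Depression: 2+ weeks of depressed mood or anhedonia, AND 5 or more
  depressive symptoms, AND a health professional was consulted.
* BD = mania core + depression; UM = mania core without depression;
  control = neither; depression without mania is labelled DEPRESSION_ONLY and
  analysed in none of the three groups (folding it into controls would
  contaminate the comparison group).
* When a participant completed the more detailed online follow-up instrument,
  its answers take precedence over the baseline touchscreen instrument.
* Missing gate or branch answers make the participant UNCLASSIFIABLE rather
  than silently control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .config import EXCLUSION_FLAGS

__all__ = [
    "DiagnosisLabel",
    "MEETS",
    "FAILS",
    "UNCLASSIFIABLE",
    "apply_exclusions",
    "classify_mania",
    "classify_depression",
    "assign_group",
    "phenotype_cohort",
    "record_from_row",
]

MEETS = "meets"
FAILS = "fails"
UNCLASSIFIABLE = "unclassifiable"

ANALYSIS_GROUPS = ("BD", "UM", "CONTROL")
ALL_LABELS = ANALYSIS_GROUPS + ("DEPRESSION_ONLY", "EXCLUDED", "UNCLASSIFIABLE")

MANIA_SYMPTOM_THRESHOLD = 3
DEPRESSION_SYMPTOM_THRESHOLD = 5


@dataclass(frozen=True)
class DiagnosisLabel:
    label: str
    source: Optional[str]  # "online" | "touchscreen" | None
    trace: tuple


def _missing(v) -> bool:
    return v is None or (not isinstance(v, str) and pd.isna(v))


def apply_exclusions(record: Mapping) -> bool:
    """True iff any exclusion flag is set.

    Accepts either an ``exclusion_flags`` iterable of flag names or per-flag
    ``excl_<name>`` truthy entries.
    """
    flags = record.get("exclusion_flags")
    if flags is not None:
        unknown = set(flags) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        return len(flags) > 0
    return any(bool(record.get(f"excl_{name}", 0)) for name in EXCLUSION_FLAGS)


def _gate(yes_a, yes_b) -> str:
    """Evaluate an either-item yes/no gate with missing-data semantics."""
    if yes_a == "yes" or yes_b == "yes":
        return MEETS
    if _missing(yes_a) or _missing(yes_b):
        return UNCLASSIFIABLE
    return FAILS


def classify_mania(record: Mapping) -> str:
    """Mania core criterion: (hyper or irritable >= 2 days) and >= 3 symptoms."""
    gate = _gate(record.get("hyper"), record.get("irritable"))
    if gate != MEETS:
        return gate
    count = record.get("mania_symptoms")
    if _missing(count):
        return UNCLASSIFIABLE
    return MEETS if float(count) >= MANIA_SYMPTOM_THRESHOLD else FAILS


def classify_depression(record: Mapping) -> str:
    """Depression criterion: (depressed or anhedonia >= 2 weeks) and >= 5
    symptoms and a professional was consulted."""
    gate = _gate(record.get("depressed"), record.get("anhedonia"))
    if gate != MEETS:
        return gate
    count = record.get("dep_symptoms")
    consulted = record.get("consulted")
    if _missing(count) or _missing(consulted):
        return UNCLASSIFIABLE
    return MEETS if float(count) >= DEPRESSION_SYMPTOM_THRESHOLD and consulted == "yes" else FAILS


def assign_group(
    touchscreen: Optional[Mapping],
    online: Optional[Mapping] = None,
) -> DiagnosisLabel:
    """Apply the mood-disorder criteria, online instrument taking precedence."""
    if online is not None:
        record, source = online, "online"
    elif touchscreen is not None:
        record, source = touchscreen, "touchscreen"
    else:
        return DiagnosisLabel("UNCLASSIFIABLE", None, ("no questionnaire record",))

    mania = classify_mania(record)
    depression = classify_depression(record)
    trace = (f"instrument={source}", f"mania_core={mania}", f"depression={depression}")
    if mania == UNCLASSIFIABLE or depression == UNCLASSIFIABLE:
        return DiagnosisLabel("UNCLASSIFIABLE", source, trace)
    if mania == MEETS:
        label = "BD" if depression == MEETS else "UM"
    else:
        label = "DEPRESSION_ONLY" if depression == MEETS else "CONTROL"
    return DiagnosisLabel(label, source, trace)


_MOOD_KEYS = ("hyper", "irritable", "mania_symptoms", "mania_duration", "mania_problematic",
              "depressed", "anhedonia", "dep_symptoms", "consulted")


def record_from_row(row: Mapping, prefix: str) -> Optional[dict]:
    """Extract one instrument's record from a prefixed participant row."""
    if prefix == "ol" and not row.get("ol_present", False):
        return None
    return {k: row.get(f"{prefix}_{k}") for k in _MOOD_KEYS}


def phenotype_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Label every participant; adds ``group``, ``group_source``, ``rule_trace``.

    Exclusion criteria are applied first: excluded participants are labelled
    EXCLUDED regardless of their questionnaire answers.
    """
    labels, sources, traces = [], [], []
    for row in df.to_dict("records"):
        if apply_exclusions(row):
            labels.append("EXCLUDED")
            sources.append(None)
            traces.append("exclusion_flag_set")
            continue
        diag = assign_group(record_from_row(row, "ts"), record_from_row(row, "ol"))
        labels.append(diag.label)
        sources.append(diag.source)
        traces.append(";".join(diag.trace))
    out = df.copy()
    out["group"] = labels
    out["group_source"] = sources
    out["rule_trace"] = traces
    return out
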