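"""Patient-level construct validity of the sentence-level detector.

Sentence predictions are aggregated to a per-patient ±1 flag (+1 when
any sentence in any of the patient's notes is classified POSITIVE), and
associated with independent delirium indicators — ICD billing codes,
deliriogenic medications, restraint/sitter orders, in-hospital
mortality, and CAM assessments — via the φ (mean-square contingency)
coefficient, which for ±1 variables equals their Pearson correlation.
Delirium burden is the count of distinct calendar days with at least
one POSITIVE sentence, and mortality is summarized per burden bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Note
from .evaluation import MetricWithCI, bootstrap_ci
from .labels import Label

__all__ = [
    "INDICATOR_COLUMNS", "DegenerateTableWarning",
    "aggregate_patient", "phi_coefficient", "association_report",
    "delirium_days", "mortality_by_days",
]

#: indicator columns compared against the NLP and ICD detectors
INDICATOR_COLUMNS = ("icd", "medication", "restraints_sitter", "mortality", "cam")


class DegenerateTableWarning(UserWarning):
    """A 2x2 margin is zero; φ is reported as 0 by convention."""


def _check_pm1(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.isin(x, (-1, 1)).all():
        raise ValueError(f"{name} must contain only +1/-1 values")
    return x.astype(int)


def aggregate_patient(predictions: pd.DataFrame, notes: Sequence[Note],
                      label_column: str = "predicted_label") -> pd.DataFrame:
    """Per-patient NLP flag: +1 iff >= 1 POSITIVE-classified sentence.

    ``predictions`` needs columns ``note_id`` and ``label_column``;
    every patient in ``notes`` gets a row (patients with no keyword
    sentence at all are -1).  Predictions referencing unknown note_ids
    raise.
    """
    note_patient = {n.note_id: n.patient_id for n in notes}
    unknown = set(predictions["note_id"]) - set(note_patient)
    if unknown:
        raise KeyError(f"predictions reference unknown note_ids: "
                       f"{sorted(unknown)[:5]}")
    labels = predictions[label_column].map(
        lambda v: v.value if isinstance(v, Label) else str(v))
    pos_patients = {
        note_patient[nid]
        for nid, lab in zip(predictions["note_id"], labels)
        if lab == Label.POSITIVE.value
    }
    patient_ids = list(dict.fromkeys(n.patient_id for n in notes))
    return pd.DataFrame({
        "patient_id": patient_ids,
        "nlp": [1 if p in pos_patients else -1 for p in patient_ids],
    })


def phi_coefficient(x: Sequence[int], y: Sequence[int]) -> float:
    """φ = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) of the 2x2 table.

    Equals the Pearson correlation of the two ±1 vectors.  When any
    margin is zero the table is degenerate and 0.0 is returned with a
    :class:`DegenerateTableWarning` (bootstrap resamples hit this
    routinely).
    """
    x, y = _check_pm1(np.asarray(x), "x"), _check_pm1(np.asarray(y), "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == -1)).sum())
    c = int(((x == -1) & (y == 1)).sum())
    d = int(((x == -1) & (y == -1)).sum())
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn("zero margin in 2x2 table; φ reported as 0",
                      DegenerateTableWarning, stacklevel=2)
        return 0.0
    return (a * d - b * c) / np.sqrt(denom)


def association_report(indicators: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """φ of each indicator with the ICD-based and NLP-based detectors.

    ``indicators`` holds per-patient ±1 columns ``nlp``, ``icd`` and any
    of medication / restraints_sitter / mortality / cam (cam may be
    absent or NaN for cohorts without assessments).  Returns one row per
    indicator with φ and a 95% patient-level bootstrap CI for both
    detectors; a constant column is reported absent with the reason.
    """
    if len(indicators) < 2:
        raise ValueError("need at least 2 patients")
    rows = []
    for col in INDICATOR_COLUMNS:
        if col not in indicators.columns:
            continue
        sub = indicators[list(dict.fromkeys(["nlp", "icd", col]))].dropna()
        row: dict = {"indicator": col}
        for detector in ("icd", "nlp"):
            tag = f"phi_{detector}"
            if len(sub) < 2 or sub[col].nunique() < 2:
                row[tag] = np.nan
                row[f"{tag}_low"] = row[f"{tag}_high"] = np.nan
                row[f"{tag}_note"] = "indicator constant across patients" \
                    if len(sub) >= 2 else "too few patients with this indicator"
                continue
            if detector == col:  # e.g. icd vs icd: identically 1
                row[tag], row[f"{tag}_low"], row[f"{tag}_high"] = 1.0, 1.0, 1.0
                row[f"{tag}_note"] = ""
                continue
            x = sub[detector].to_numpy(dtype=int)
            y = sub[col].to_numpy(dtype=int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateTableWarning)
                ci: MetricWithCI = bootstrap_ci(
                    phi_coefficient, (x, y), n_boot=n_boot, seed=seed)
            row[tag] = ci.point
            row[f"{tag}_low"], row[f"{tag}_high"] = ci.ci_low, ci.ci_high
            row[f"{tag}_note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeliriumBurden:
    patient_id: str
    delirium_days: int


def delirium_days(predictions: pd.DataFrame, notes: Sequence[Note],
                  label_column: str = "predicted_label") -> pd.DataFrame:
    """Distinct calendar days with >= 1 POSITIVE sentence, per patient.

    Uses the note-local timestamp date.  Notes without a timestamp are
    excluded with a warning.  Every patient in ``notes`` gets a row.
    """
    note_info: dict[str, tuple[str, object]] = {}
    for n in notes:
        if n.timestamp is None:
            warnings.warn(f"note {n.note_id} has no timestamp; excluded",
                          stacklevel=2)
            continue
        note_info[n.note_id] = (n.patient_id, n.timestamp.date())
    unknown = set(predictions["note_id"]) - {n.note_id for n in notes}
    if unknown:
        raise KeyError(f"predictions reference unknown note_ids: "
                       f"{sorted(unknown)[:5]}")
    labels = predictions[label_column].map(
        lambda v: v.value if isinstance(v, Label) else str(v))
    days: dict[str, set] = {}
    for nid, lab in zip(predictions["note_id"], labels):
        if lab == Label.POSITIVE.value and nid in note_info:
            pid, date = note_info[nid]
            days.setdefault(pid, set()).add(date)
    patient_ids = list(dict.fromkeys(n.patient_id for n in notes))
    return pd.DataFrame({
        "patient_id": patient_ids,
        "delirium_days": [len(days.get(p, ())) for p in patient_ids],
    })


def mortality_by_days(burden: pd.DataFrame, mortality: pd.DataFrame,
                      k_max: int = 5) -> pd.DataFrame:
    """Mortality rate per delirium-day bin 0, 1, ..., k_max+ (top open).

    ``burden`` from :func:`delirium_days`; ``mortality`` has columns
    ``patient_id`` and ±1 ``mortality``.  Returns bin, n_patients, and
    the fraction with mortality == +1.
    """
    merged = burden.merge(mortality, on="patient_id", how="inner")
    _check_pm1(merged["mortality"].to_numpy(), "mortality")
    binned = merged["delirium_days"].clip(upper=k_max)
    rows = []
    for b in range(k_max + 1):
        grp = merged[binned == b]
        rows.append({
            "delirium_days_bin": f"{b}+" if b == k_max else str(b),
            "n_patients": len(grp),
            "mortality_rate": float((grp["mortality"] == 1).mean())
            if len(grp) else np.nan,
        })
    return pd.DataFrame(rows)
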