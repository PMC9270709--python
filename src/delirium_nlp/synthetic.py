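"""Synthetic clinical-note cohorts with known ground truth.

Real delirium notes are protected health information, so every pipeline
stage is exercised on generated multi-note patient records instead.  A
patient is latently delirious with configurable prevalence; delirious
patients carry a contiguous block of delirium days on which their notes
are dense in POSITIVE keyword sentences ("Pt remains confused
overnight."), while all patients produce occasional NEGATIVE ("No
evidence of delirium today.") and NEITHER ("Family confused about the
medication schedule.") keyword sentences plus keyword-free filler.
Binary clinical indicators (ICD code, deliriogenic medications,
restraint/sitter orders, CAM) are drawn Bernoulli from the latent flag
at stated sensitivity/specificity — ICD sensitivity is low by default,
mirroring its poor recall for delirium — and mortality follows a
logistic model increasing in true delirium days.

The global sentence-class mixture (default 0.88 / 0.08 / 0.04) is
honored exactly in expectation: the per-delirium-note positive rate is
solved against the realized share of keyword slots that fall on
delirium days.  Sentences are grammar-based slot-filled templates, not
real clinical language.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import Note
from .labels import Label
from .patterns import AlwaysPattern

__all__ = [
    "GeneratorConfig", "SyntheticCohort", "TemplateBank",
    "generate", "expected_phi", "default_always_patterns", "oracle_from_truth",
]

# ---------------------------------------------------------------------------
# template grammar

_ADJ = ("confused", "agitated", "delirious", "disoriented", "inattentive")
_NOUN = ("confusion", "agitation", "delirium", "disorientation",
         "encephalopathy", "psychosis", "inattention", "lethargy")

_POSITIVE_TEMPLATES = (
    "Pt remains {adj} overnight.",
    "Patient was {adj} and required frequent redirection.",
    "Acute {noun} noted on exam.",
    "Waxing and waning mental status with episodes of {noun}.",
    "Continues with altered mental status and worsening {noun}.",
    "New onset {noun} with visual hallucinations this evening.",
    "Pt {adj}, pulling at lines, restraints applied for safety.",
)
_NEGATIVE_TEMPLATES = (
    "No evidence of {noun} today.",
    "Pt denies {noun} and hallucinations.",
    "No {noun} noted on exam.",
    "Patient is not {adj} at this time.",
    "Remains alert and oriented, without {noun}.",
    "Screening negative for {noun}.",
)
_NEITHER_TEMPLATES = (
    "Family confused about the medication schedule.",
    "Discussed risks of {noun} with the family.",
    "Daughter was confused about visiting hours.",
    "Delirium precautions protocol reviewed with nursing staff.",
    "Provided education on {noun} to the caregiver.",
)
#: ambiguous hedges used only by the "noisy" regime (class drawn at random)
_HEDGE_TEMPLATES = (
    "Possibly {adj}, will continue to monitor.",
    "Rule out {noun}.",
)
_FILLER_TEMPLATES = (
    "Vital signs stable.",
    "Tolerating diet well.",
    "Plan to continue current medications.",
    "Afebrile overnight.",
    "Ambulating with assistance.",
    "Family at bedside.",
    "Labs reviewed this morning.",
)


@dataclass(frozen=True)
class TemplateBank:
    positive: tuple[str, ...] = _POSITIVE_TEMPLATES
    negative: tuple[str, ...] = _NEGATIVE_TEMPLATES
    neither: tuple[str, ...] = _NEITHER_TEMPLATES
    hedge: tuple[str, ...] = _HEDGE_TEMPLATES
    filler: tuple[str, ...] = _FILLER_TEMPLATES

    def render(self, which: str, rng: np.random.Generator) -> str:
        pool: tuple[str, ...] = getattr(self, which)
        template = pool[rng.integers(len(pool))]
        return template.format(adj=_ADJ[rng.integers(len(_ADJ))],
                               noun=_NOUN[rng.integers(len(_NOUN))])


def default_always_patterns() -> list[AlwaysPattern]:
    """Illustrative always patterns matched to the default template bank.

    Deliberately not exhaustive: two templates stay uncovered so the
    active-learning loop and the coverage analysis have work to do.
    """
    adj = "|".join(_ADJ)
    nouns = "|".join(_NOUN)
    spec = [
        (rf"remains ({adj})", Label.POSITIVE),
        (r"acute \w+ noted", Label.POSITIVE),
        (r"waxing and waning mental status with", Label.POSITIVE),
        (r"restraints applied", Label.POSITIVE),
        (r"new onset", Label.POSITIVE),
        (r"required frequent redirection", Label.POSITIVE),
        (r"no evidence of", Label.NEGATIVE),
        (r"\bdenies\b", Label.NEGATIVE),
        (r"\bno \w+ noted", Label.NEGATIVE),
        (rf"is not ({adj})", Label.NEGATIVE),
        (rf"without ({nouns})", Label.NEGATIVE),
        (r"negative for", Label.NEGATIVE),
        (r"confused about", Label.NEITHER),
        (r"discussed risks of", Label.NEITHER),
        (r"precautions protocol", Label.NEITHER),
    ]
    return [AlwaysPattern(pattern=p, label=l, author="synthetic-bank")
            for p, l in spec]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``class_mixture`` is the target global distribution of keyword
    sentences over (POSITIVE, NEGATIVE, NEITHER); the default matches
    the heavily imbalanced mixture seen in labeled clinical corpora.
    ``keyword_sentence_rate`` applies inside delirium-day notes;
    elsewhere the rate is scaled down by ``background_keyword_ratio``
    (delirium keywords cluster in delirious patients' notes, which is
    what makes the high positive share attainable).  Indicator
    sensitivities/specificities are vs the latent patient flag; ICD
    sensitivity is low by default.  ``regime`` is "separable" or
    "noisy" (adds ambiguous hedge sentences on delirium days).
    """

    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (3, 8)
    sentences_per_note: tuple[int, int] = (4, 10)
    keyword_sentence_rate: float = 0.8
    background_keyword_ratio: float = 0.015
    class_mixture: tuple[float, float, float] = (0.88, 0.08, 0.04)
    latent_delirium_prevalence: float = 0.35
    delirium_days_range: tuple[int, int] = (1, 4)
    indicator_sensitivity: dict = field(default_factory=lambda: {
        "icd": 0.2, "medication": 0.65, "restraints_sitter": 0.55, "cam": 0.8})
    indicator_specificity: dict = field(default_factory=lambda: {
        "icd": 0.98, "medication": 0.85, "restraints_sitter": 0.9, "cam": 0.9})
    mortality_base_logodds: float = -2.5
    mortality_logodds_per_day: float = 0.35
    regime: str = "separable"
    hedge_rate: float = 0.15
    template_bank: TemplateBank = field(default_factory=TemplateBank)
    seed: int = 0

    def __post_init__(self):
        probs = [self.keyword_sentence_rate, self.latent_delirium_prevalence,
                 self.hedge_rate, *self.class_mixture,
                 *self.indicator_sensitivity.values(),
                 *self.indicator_specificity.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if self.regime not in ("separable", "noisy"):
            raise ValueError("regime must be 'separable' or 'noisy'")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class SyntheticCohort:
    """Generated corpus plus its ground truth."""

    notes: list[Note]
    sentence_truth: pd.DataFrame   # note_id, sentence_index, label
    patient_truth: pd.DataFrame    # patient_id, delirious, delirium_days
    indicators: pd.DataFrame       # patient_id, nlp-comparable ±1 columns

    def truth_label_map(self) -> dict[tuple[str, int], Label]:
        return {
            (r.note_id, int(r.sentence_index)): Label[r.label]
            for r in self.sentence_truth.itertuples()
        }


def oracle_from_truth(cohort: SyntheticCohort) -> Callable:
    """Labeling callback for simulated active-learning runs."""
    mapping = cohort.truth_label_map()

    def oracle(sentence) -> Label:
        return mapping[sentence.key]

    return oracle


# ---------------------------------------------------------------------------
# generation

def generate(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a cohort; byte-identical for a fixed config/seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    mix = np.asarray(cfg.class_mixture, dtype=float)
    bg_rate = cfg.keyword_sentence_rate * cfg.background_keyword_ratio

    # ---- pass 1: patients, notes, and keyword-slot layout
    n_lo, n_hi = cfg.notes_per_patient
    s_lo, s_hi = cfg.sentences_per_note
    d_lo, d_hi = cfg.delirium_days_range
    patients = []
    slots = []  # (patient_idx, note_idx, slot_idx, on_delirium_day)
    layout = []  # per patient: list of (note_day, n_sent, del_day_flag)
    for i in range(cfg.n_patients):
        delirious = bool(rng.random() < cfg.latent_delirium_prevalence)
        n_notes = int(rng.integers(n_lo, n_hi + 1))
        del_days: set[int] = set()
        if delirious:
            d = int(min(n_notes, rng.integers(d_lo, d_hi + 1)))
            start = int(rng.integers(0, n_notes - d + 1))
            del_days = set(range(start, start + d))
        start_date = date(2024, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        notes_meta = []
        for j in range(n_notes):
            n_sent = int(rng.integers(s_lo, s_hi + 1))
            on_del = j in del_days
            rate = cfg.keyword_sentence_rate if on_del else bg_rate
            is_kw = rng.random(n_sent) < rate
            for k in range(n_sent):
                if is_kw[k]:
                    slots.append((i, j, k, on_del))
            notes_meta.append((start_date + timedelta(days=j), n_sent, on_del,
                               {k for k in range(n_sent) if is_kw[k]}))
        patients.append((f"P{i:05d}", delirious))
        layout.append(notes_meta)

    # ---- solve the per-delirium-slot positive rate against the layout
    n_del_slots = sum(1 for s in slots if s[3])
    n_other_slots = len(slots) - n_del_slots
    if mix[0] > 0 and len(slots) > 0:
        if n_del_slots == 0:
            raise ValueError(
                "class_mixture requests POSITIVE sentences but no keyword "
                "slot falls on a delirium day (prevalence too low?)")
        p_pos = mix[0] * len(slots) / n_del_slots
        if p_pos > 1.0 + 1e-9:
            raise ValueError(
                f"class_mixture positive share {mix[0]} unreachable: only "
                f"{n_del_slots}/{len(slots)} keyword slots are on delirium "
                "days; raise prevalence or lower background_keyword_ratio")
        p_pos = min(p_pos, 1.0)
    else:
        p_pos = 0.0
    neg_ratio = mix[1] / (mix[1] + mix[2]) if mix[1] + mix[2] > 0 else 0.5

    # ---- pass 2: render text and assign truth labels
    bank = cfg.template_bank
    notes: list[Note] = []
    truth_rows = []
    pos_days: dict[str, set] = {}
    for i, (pid, delirious) in enumerate(patients):
        for j, (day, n_sent, on_del, kw_slots) in enumerate(layout[i]):
            note_id = f"{pid}-N{j:03d}"
            texts = []
            for k in range(n_sent):
                if k not in kw_slots:
                    texts.append(bank.render("filler", rng))
                    continue
                if on_del and cfg.regime == "noisy" \
                        and rng.random() < cfg.hedge_rate:
                    label = Label.POSITIVE if rng.random() < 0.5 \
                        else Label.NEGATIVE
                    texts.append(bank.render("hedge", rng))
                elif on_del:
                    u = rng.random()
                    if u < p_pos:
                        label = Label.POSITIVE
                        texts.append(bank.render("positive", rng))
                    elif u < p_pos + (1 - p_pos) * neg_ratio:
                        label = Label.NEGATIVE
                        texts.append(bank.render("negative", rng))
                    else:
                        label = Label.NEITHER
                        texts.append(bank.render("neither", rng))
                else:
                    if rng.random() < neg_ratio:
                        label = Label.NEGATIVE
                        texts.append(bank.render("negative", rng))
                    else:
                        label = Label.NEITHER
                        texts.append(bank.render("neither", rng))
                truth_rows.append({"note_id": note_id, "sentence_index": k,
                                   "label": label.value})
                if label is Label.POSITIVE:
                    pos_days.setdefault(pid, set()).add(day)
            notes.append(Note(
                patient_id=pid, note_id=note_id,
                timestamp=datetime.combine(day, time(8, 0)),
                text=" ".join(texts)))

    # ---- patient-level truth and indicators
    patient_rows = []
    ind_rows = []
    for pid, delirious in patients:
        n_days = len(pos_days.get(pid, ()))
        patient_rows.append({"patient_id": pid,
                             "delirious": 1 if delirious else -1,
                             "delirium_days": n_days})
        row = {"patient_id": pid}
        for name in ("icd", "medication", "restraints_sitter", "cam"):
            sens = cfg.indicator_sensitivity[name]
            spec = cfg.indicator_specificity[name]
            p_flag = sens if delirious else 1.0 - spec
            row[name] = 1 if rng.random() < p_flag else -1
        logodds = cfg.mortality_base_logodds \
            + cfg.mortality_logodds_per_day * n_days
        p_mort = 1.0 / (1.0 + np.exp(-logodds))
        row["mortality"] = 1 if rng.random() < p_mort else -1
        ind_rows.append(row)

    return SyntheticCohort(
        notes=notes,
        sentence_truth=pd.DataFrame(
            truth_rows, columns=["note_id", "sentence_index", "label"]),
        patient_truth=pd.DataFrame(patient_rows),
        indicators=pd.DataFrame(ind_rows),
    )


# ---------------------------------------------------------------------------
# analytic oracle for the association analysis

def expected_phi(config: GeneratorConfig) -> dict[str, float | None]:
    """Closed-form φ of (perfect detector, noisy indicator) per indicator.

    With prevalence π and an indicator of sensitivity s and specificity
    t, the 2x2 cell probabilities are (πs, π(1-s), (1-π)(1-t), (1-π)t)
    and φ follows from the margin formula.  Degenerate prevalence (0 or
    1) makes every φ undefined: the values are None and a warning names
    the reason.
    """
    pi = config.latent_delirium_prevalence
    out: dict[str, float | None] = {}
    if pi in (0.0, 1.0):
        warnings.warn("degenerate prevalence: detector column is constant, "
                      "phi undefined", stacklevel=2)
        return {name: None for name in config.indicator_sensitivity}
    for name, sens in config.indicator_sensitivity.items():
        spec = config.indicator_specificity[name]
        a = pi * sens
        b = pi * (1 - sens)
        c = (1 - pi) * (1 - spec)
        d = (1 - pi) * spec
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        out[name] = None if denom == 0 else float((a * d - b * c) / np.sqrt(denom))
    return out
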