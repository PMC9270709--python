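"""Shared fixtures: synthetic cohorts and labeled sentence sets."""

from __future__ import annotations

import pytest

from delirium_nlp import corpus, synthetic
from delirium_nlp.corpus import Lexicon, Sentence
from delirium_nlp.labels import Provenance
from delirium_nlp.patterns import LabeledSentence


def make_sentence(text: str, note_id: str = "n0", idx: int = 0) -> Sentence:
    """Ad-hoc sentence with keyword matches attached (for unit tests)."""
    return Sentence(note_id=note_id, sentence_index=idx, text=text,
                    start=0, end=len(text), matches=tuple(Lexicon().find(text)))


@pytest.fixture(scope="session")
def small_cohort() -> synthetic.SyntheticCohort:
    return synthetic.generate(synthetic.GeneratorConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def small_sentences(small_cohort):
    return corpus.extract_keyword_sentences(small_cohort.notes)


@pytest.fixture(scope="session")
def small_labeled(small_cohort, small_sentences) -> list[LabeledSentence]:
    truth = small_cohort.truth_label_map()
    return [LabeledSentence(s, truth[s.key], Provenance.HUMAN)
            for s in small_sentences]
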