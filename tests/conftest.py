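import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phenotext.extraction import TriggerEntry
from phenotext.synth import SynthConfig, generate_corpus
from phenotext.terminology import Lexicon, TermEntry, filter_lexicon

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


def make_lexicon(terms: dict[str, str]) -> Lexicon:
    """surface_term -> concept_id, all 'Finding', pre-filtered."""
    entries = [
        TermEntry(t, c, t.capitalize(), "Finding", "FRE") for t, c in terms.items()
    ]
    return filter_lexicon(Lexicon(entries=entries), min_len=2)


@pytest.fixture
def simple_lexicon() -> Lexicon:
    return make_lexicon(
        {
            "diabète": "C010",
            "fièvre": "C020",
            "toux": "C030",
            "asthme": "C040",
            "scoliose": "C050",
            "retard de croissance": "C060",
            "croissance": "C061",
        }
    )


@pytest.fixture
def simple_triggers() -> list[TriggerEntry]:
    return [
        TriggerEntry("pas de", "negation"),
        TriggerEntry("absence", "negation"),
        TriggerEntry("sans", "negation"),
        TriggerEntry("mère", "family"),
        TriggerEntry("père", "family"),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic warehouse shared across tests (20 cohort / 60 background)."""
    return generate_corpus(SynthConfig(seed=11, n_cohort_patients=20, n_background_patients=60))


def mentions_frame(mentions) -> pd.DataFrame:
    df = pd.DataFrame(
        [(m.patient_id, m.doc_id, m.concept_id, m.negated, m.experiencer) for m in mentions],
        columns=["patient_id", "doc_id", "concept_id", "negated", "experiencer"],
    )
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
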