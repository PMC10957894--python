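import numpy as np
import pandas as pd
import pytest

import natsemsoc as ns
from natsemsoc import synthdata as sd


@pytest.fixture(scope="session")
def small_lexicon():
    lex, truth = sd.gen_lexicon(300, missing_rate=0.1, seed=42)
    return lex, truth


@pytest.fixture(scope="session")
def complete_lexicon():
    lex, truth = sd.gen_lexicon(2000, missing_rate=0.0, seed=7)
    return lex, truth


@pytest.fixture(scope="session")
def event_table():
    ev, truth = sd.gen_events(200, seed=3)
    return ev, truth


@pytest.fixture
def toy_events():
    return pd.DataFrame(
        {
            "movie_id": "m",
            "index": [0, 1, 2],
            "onset": [0.0, 10.0, 25.0],
            "duration": [10.0, 15.0, 8.0],
            "semantic": [4.0, 7.0, 2.0],
            "social": [6.0, 3.0, 5.0],
        }
    )


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete synthetic study shared across smoke tests."""
    cfg = ns.PipelineConfig(n_sim_cluster=150, n_sim_cluster_subject=60, seed=21)
    return ns.simulate_study(
        n_subjects=6,
        n_movies=2,
        n_events=50,
        n_words_lexicon=250,
        shape=(10, 10, 10),
        effects={"content_words": 0.5, "semantic_events": 0.5},
        seed=21,
        config=cfg,
    )
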