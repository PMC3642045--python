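import warnings

import pytest

import songsyntax as ss


@pytest.fixture(scope="session")
def recovery_truth():
    """A verified random depth-3 ground truth (see simulate module)."""
    return ss.random_recovery_model(seed=1)


@pytest.fixture(scope="session")
def recovery_corpus(recovery_truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ss.simulate_corpus(
            recovery_truth.model,
            ss.SimulationConfig(n_songs=3000, seed=7),
        )


@pytest.fixture(scope="session")
def two_ctx():
    """Depth-2 ground truth and a medium corpus drawn from it."""
    model = ss.two_context_model(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corpus = ss.simulate_corpus(
            model, ss.SimulationConfig(n_songs=500, seed=5)
        )
    return model, corpus


@pytest.fixture()
def tiny_corpus():
    """Two songs, four phrase types, built by hand."""
    def song(song_id, tuples):
        return ss.Song(
            song_id=song_id,
            phrases=[
                ss.PhraseAnnotation(on, off, lab, song_id)
                for on, off, lab in tuples
            ],
        )

    return ss.Corpus(
        songs=[
            song("s0", [(0.0, 1.0, "A"), (1.1, 2.0, "B"), (2.1, 3.5, "C")]),
            song("s1", [(0.0, 0.8, "B"), (0.9, 2.0, "A"), (2.1, 2.9, "D")]),
        ],
        subject_id="tiny",
    )
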