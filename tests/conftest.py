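import numpy as np
import pytest

from songshare import (
    NeighborhoodSpec,
    Recording,
    generate_neighborhood,
    make_syllable_bank,
    synthesize_song_audio,
)

SR = 48_000


@pytest.fixture(scope="session")
def small_neighborhood():
    """Two groups with analytic pool sizes: within-group syllable RS = 40/60."""
    spec = NeighborhoodSpec(
        n_groups=2,
        individuals_per_group=4,
        shared_pool_size=40,
        private_pool_size=10,
        dialect_sequence_length=7,
        songs_per_individual=3,
        song_length=60,
        seed=42,
    )
    transcripts, territories = generate_neighborhood(spec)
    return spec, transcripts, territories


@pytest.fixture(scope="session")
def song_wave():
    """A short synthetic song waveform and its control Recording."""
    labels = [f"s{i % 12}" for i in range(15)]
    bank = make_syllable_bank(sorted(set(labels)), seed=7)
    wave = synthesize_song_audio(labels, bank, SR)
    return wave, Recording(wave, SR, role="control", distance=1.56, height=2.0)
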