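import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songshare import (
    ChannelSpec,
    NeighborhoodSpec,
    ResponseSpec,
    dialect_sequence,
    generate_neighborhood,
    generate_response_table,
    make_syllable_bank,
    pairwise_rs_matrix,
    propagate,
    repertoires_from_transcripts,
    spherical_distance,
    synthesize_song_audio,
    territory_distance_matrix,
)
from songshare.degradation import Recording, envelope
from songshare.songsynth import MEASURE_COLS

SR = 48_000


class TestNeighborhood:
    def test_dialect_planted_in_every_song(self, small_neighborhood):
        spec, tr, _ = small_neighborhood
        for gi in range(spec.n_groups):
            needle = ",".join(dialect_sequence(spec, gi))
            group = tr[tr["group_id"] == f"g{gi}"]
            for _, song in group.groupby("song_id"):
                hay = ",".join(song.sort_values("position")["syllable"])
                assert needle in hay

    def test_within_group_rs_is_analytic(self, small_neighborhood):
        spec, tr, _ = small_neighborhood
        reps = repertoires_from_transcripts(tr, "syllable")
        m = pairwise_rs_matrix(reps.values())
        g, p = spec.shared_pool_size, spec.private_pool_size
        within = [f"g0i{i}" for i in range(spec.individuals_per_group)]
        for a, b in itertools.combinations(within, 2):
            assert m.loc[a, b] == pytest.approx(g / (g + 2 * p), abs=0)

    def test_between_group_rs_zero_with_disjoint_pools(self, small_neighborhood):
        spec, tr, _ = small_neighborhood
        reps = repertoires_from_transcripts(tr, "syllable")
        assert (
            len(reps["g0i0"].items & reps["g1i0"].items) == 0
        )

    def test_deterministic_under_seed(self, small_neighborhood):
        spec, tr, terr = small_neighborhood
        tr2, terr2 = generate_neighborhood(spec)
        assert tr.equals(tr2) and terr.equals(terr2)

    def test_dialect_longer_than_song_rejected(self):
        spec = NeighborhoodSpec(song_length=5, dialect_sequence_length=7)
        with pytest.raises(ValueError, match="song_length"):
            generate_neighborhood(spec)

    def test_within_group_distances_much_smaller_than_between(
        self, small_neighborhood
    ):
        _, _, terr = small_neighborhood
        d = territory_distance_matrix(terr)
        g0 = terr[terr["group_id"] == "g0"]["individual_id"]
        g1 = terr[terr["group_id"] == "g1"]["individual_id"]
        within = max(d.loc[a, b] for a, b in itertools.combinations(g0, 2))
        between = min(d.loc[a, b] for a in g0 for b in g1)
        assert within * 10 < between


class TestSphericalDistance:
    def test_closed_forms(self):
        assert spherical_distance((48.7, 2.2), (48.7, 2.2)) == 0.0
        # One degree of latitude on the conventional sphere.
        assert spherical_distance((0.0, 10.0), (1.0, 10.0)) == pytest.approx(
            111_194.9, abs=0.5
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
        st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
    )
    def test_symmetric_and_nonnegative(self, a, b):
        assert spherical_distance(a, b) == spherical_distance(b, a) >= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            spherical_distance((91.0, 0.0), (0.0, 0.0))


class TestSongAudio:
    def test_empty_transcript_gives_empty_waveform(self):
        assert len(synthesize_song_audio([], {})) == 0

    def test_duration_arithmetic(self):
        bank = make_syllable_bank(["a"], seed=0, duration=0.1)
        w = synthesize_song_audio(["a"] * 10, bank, SR, gap=0.02)
        assert abs(len(w) - round(1.18 * SR)) <= 1
        assert np.max(np.abs(w)) <= 1.0

    def test_energy_confined_to_song_band(self, song_wave):
        wave, _ = song_wave
        freqs = np.fft.rfftfreq(len(wave), 1 / SR)
        power = np.abs(np.fft.rfft(wave)) ** 2
        out = power[(freqs < 1_600) | (freqs > 7_000)].sum()
        assert out / power.sum() < 0.01

    def test_unknown_label_names_the_label(self):
        bank = make_syllable_bank(["a"], seed=0)
        with pytest.raises(KeyError, match="zzz"):
            synthesize_song_audio(["a", "zzz"], bank)


class TestChannel:
    def test_identity_channel(self, song_wave):
        wave, _ = song_wave
        ch = ChannelSpec(distance=1.56, reference_distance=1.56, noise_floor=0.0)
        assert np.allclose(propagate(wave, ch, SR), wave, atol=1e-10)

    def test_spherical_spreading_halves_rms(self, song_wave):
        wave, _ = song_wave
        ch = ChannelSpec(distance=3.12, reference_distance=1.56,
                         excess_attenuation=0.0, noise_floor=0.0)
        y = propagate(wave, ch, SR)
        ratio = np.sqrt(np.mean(y**2) / np.mean(wave**2))
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_output_energy_never_exceeds_input(self, song_wave):
        wave, _ = song_wave
        for d in (1.56, 12.5, 100.0):
            ch = ChannelSpec(distance=d, noise_floor=0.0)
            y = propagate(wave, ch, SR)
            assert np.mean(y**2) <= np.mean(wave**2) * (1 + 1e-12)

    def test_envelope_correlation_decreases_with_distance(self, song_wave):
        """Mean envelope r with the control strictly drops across
        12.5 -> 50 -> 200 m at a fixed positive noise floor (over seeds)."""
        from songshare.permstats import pearson_r

        wave, control = song_wave
        env_c = envelope(control)
        means = []
        for d in (12.5, 50.0, 200.0):
            rs = []
            for seed in range(20):
                ch = ChannelSpec(distance=d, noise_floor=5e-4, seed=seed)
                y = propagate(wave, ch, SR)
                rs.append(pearson_r(env_c, envelope(Recording(y, SR))))
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]

    def test_distance_below_reference_rejected(self):
        with pytest.raises(ValueError, match="reference_distance"):
            ChannelSpec(distance=1.0, reference_distance=1.56).validate()

    def test_deterministic_under_seed(self, song_wave):
        wave, _ = song_wave
        ch = ChannelSpec(distance=50.0, noise_floor=1e-3, seed=5)
        assert np.array_equal(propagate(wave, ch, SR), propagate(wave, ch, SR))


class TestResponseTable:
    def test_zero_noise_equal_effects_gives_constant_measures(self):
        spec = ResponseSpec(n_subjects=5, noise_sd=0.0, subject_sd=0.0,
                            latent_sd=0.0, seed=0)
        t = generate_response_table(spec)
        for col in MEASURE_COLS:
            assert t[col].nunique() == 1
            assert t[col].between(0, 180).all()

    def test_same_seed_identical(self):
        spec = ResponseSpec(seed=9)
        assert generate_response_table(spec).equals(generate_response_table(spec))

    def test_stranger_effect_raises_positive_measures(self):
        spec = ResponseSpec(
            n_subjects=400,
            treatment_effects={"aN": 0.0, "dN": 0.0, "S": 1.0},
            seed=3,
        )
        t = generate_response_table(spec)
        s = t[t["treatment"] == "S"]
        a = t[t["treatment"] == "aN"]
        for col in MEASURE_COLS[:3]:
            se = np.sqrt(s[col].var() / len(s) + a[col].var() / len(a))
            assert s[col].mean() - a[col].mean() > 3 * se  # loads positively
        # latency loads negatively: strangers provoke faster responses
        se = np.sqrt(s["latency"].var() / len(s) + a["latency"].var() / len(a))
        assert a["latency"].mean() - s["latency"].mean() > 3 * se

    def test_order_randomized_and_complete(self):
        t = generate_response_table(ResponseSpec(n_subjects=30, seed=2))
        for _, sub in t.groupby("subject_id"):
            assert sorted(sub["order"]) == [1, 2, 3]
        assert t.groupby("treatment")["order"].mean().std() < 0.5

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            generate_response_table(ResponseSpec(n_subjects=1))

    def test_latency_loading_must_oppose_durations(self):
        with pytest.raises(ValueError, match="latency"):
            ResponseSpec(loadings=(0.9, 0.8, 0.7, 0.6)).validate()
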