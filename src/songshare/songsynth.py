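"""Synthetic study generator: neighbourhoods, territories, song audio and playback responses.

Emulates the structure of a field study on territorial songbirds whose
neighbourhoods carry a vocal group signature (a "microdialect"): groups of
individuals that share a syllable pool and a planted multi-syllable sequence,
a territory map on the sphere, frequency-modulated song audio, a parametric
open-field propagation channel, and playback-response tables driven by a
latent aggression factor.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

#: Treatment codes: adjacent neighbour, distant neighbour, stranger.
TREATMENTS = ("aN", "dN", "S")

#: The four playback-response measures, in canonical column order.
MEASURE_COLS = ("move_dur_10m", "time_10m", "total_move_dur", "latency")


# ---------------------------------------------------------------------------
# Neighbourhood specification and transcript generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborhoodSpec:
    """Parameters of a synthetic neighbourhood of song groups.

    Each group of ``individuals_per_group`` males shares a pool of
    ``shared_pool_size`` syllable types plus, per individual, a disjoint
    private pool of ``private_pool_size`` types.  A contiguous dialect
    sequence of ``dialect_sequence_length`` syllables (drawn from the
    group's shared pool) is planted verbatim in every song of every group
    member.  With disjoint private pools the within-group syllable-repertoire
    similarity is analytically g / (g + 2 p).
    """

    n_groups: int = 2
    individuals_per_group: int = 7
    shared_pool_size: int = 40
    private_pool_size: int = 10
    dialect_sequence_length: int = 7
    songs_per_individual: int = 3
    song_length: int = 60
    seed: int = 0
    #: Fraction of the shared pool drawn from a pool common to all groups.
    group_overlap_fraction: float = 0.0
    #: "deterministic": every individual expresses its full pool, making the
    #: within-group similarity analytic (g/(g+2p)); "random": filler syllables
    #: are purely i.i.d., so expressed repertoires (and similarities) vary.
    pool_sampling: str = "deterministic"
    #: Metres between group centres (groups are kilometres apart in the field).
    group_spacing_m: float = 5_800.0
    #: Approximate metres between adjacent territories within a group.
    territory_spacing_m: float = 130.0

    def validate(self) -> None:
        if self.n_groups < 1 or self.individuals_per_group < 1:
            raise ValueError("need at least one group with one individual")
        if self.dialect_sequence_length < 3:
            raise ValueError("dialect_sequence_length must be >= 3")
        if self.shared_pool_size < self.dialect_sequence_length:
            raise ValueError(
                "shared_pool_size must be >= dialect_sequence_length "
                f"({self.shared_pool_size} < {self.dialect_sequence_length})"
            )
        if self.dialect_sequence_length > self.song_length:
            raise ValueError(
                "dialect sequence cannot fit in a song: "
                f"dialect_sequence_length={self.dialect_sequence_length} > "
                f"song_length={self.song_length}"
            )
        if not 0.0 <= self.group_overlap_fraction <= 1.0:
            raise ValueError("group_overlap_fraction must be in [0, 1]")
        if self.pool_sampling not in ("deterministic", "random"):
            raise ValueError(
                f"unknown pool_sampling mode {self.pool_sampling!r}")
        if self.songs_per_individual < 1 or self.song_length < 1:
            raise ValueError("need at least one song of at least one syllable")


def _group_pools(spec: NeighborhoodSpec) -> list[list[str]]:
    """Shared syllable pool per group; disjoint except for the overlap fraction."""
    n_common = int(round(spec.group_overlap_fraction * spec.shared_pool_size))
    common = [f"C{j:03d}" for j in range(n_common)]
    pools = []
    for gi in range(spec.n_groups):
        own = [f"G{gi}S{j:03d}" for j in range(spec.shared_pool_size - n_common)]
        pools.append(common + own)
    return pools


def generate_neighborhood(
    spec: NeighborhoodSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate syllable-labelled transcripts and a territory map.

    Returns
    -------
    transcripts : DataFrame
        Tidy long format with columns ``individual_id, group_id, song_id,
        position, syllable``; positions are contiguous from 0 within a song.
    territories : DataFrame
        One row per individual: ``individual_id, group_id, lat, lon``.

    Every song of every individual contains the group's planted dialect
    sequence verbatim at least once; the remaining positions are i.i.d.
    uniform draws from that individual's shared-plus-private pool.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pools = _group_pools(spec)

    rows: list[tuple[str, str, str, int, str]] = []
    terr_rows: list[tuple[str, str, float, float]] = []

    # Territory geometry: group centres along a parallel, individuals on a
    # jittered within-group grid.  Degrees per metre on the sphere.
    lat0 = 48.70
    m_per_deg_lat = 2 * np.pi * EARTH_RADIUS_M / 360.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(lat0))

    for gi in range(spec.n_groups):
        group_id = f"g{gi}"
        pool = pools[gi]
        dialect = dialect_sequence(spec, gi)

        center_lon = lat0 * 0.0 + 2.20 + gi * spec.group_spacing_m / m_per_deg_lon
        side = int(np.ceil(np.sqrt(spec.individuals_per_group)))

        for ii in range(spec.individuals_per_group):
            ind_id = f"g{gi}i{ii}"
            private = [f"{ind_id}P{j:02d}" for j in range(spec.private_pool_size)]
            own_pool = pool + private

            gx, gy = ii % side, ii // side
            jitter = rng.uniform(-0.15, 0.15, size=2) * spec.territory_spacing_m
            lat = lat0 + (gy * spec.territory_spacing_m + jitter[0]) / m_per_deg_lat
            lon = center_lon + (gx * spec.territory_spacing_m + jitter[1]) / m_per_deg_lon
            terr_rows.append((ind_id, group_id, lat, lon))

            # Filler syllables for the non-dialect positions of all songs.
            # The first |pool| fillers are a permutation of the full pool so
            # every individual expresses its entire repertoire (making the
            # within-group similarity analytic); the rest are i.i.d. uniform.
            fill_len = spec.song_length - spec.dialect_sequence_length
            n_fill = spec.songs_per_individual * fill_len
            if spec.pool_sampling == "deterministic" and n_fill >= len(own_pool):
                extra = rng.integers(0, len(own_pool),
                                     size=n_fill - len(own_pool))
                fillers = np.concatenate(
                    [rng.permutation(len(own_pool)), extra])
                rng.shuffle(fillers)
            else:
                fillers = rng.integers(0, len(own_pool), size=n_fill)

            for si in range(spec.songs_per_individual):
                song_id = f"{ind_id}s{si}"
                chunk = fillers[si * fill_len : (si + 1) * fill_len]
                labels = [own_pool[k] for k in chunk]
                at = int(rng.integers(0, fill_len + 1))
                labels[at:at] = dialect
                rows.extend(
                    (ind_id, group_id, song_id, pos, lab)
                    for pos, lab in enumerate(labels)
                )

    transcripts = pd.DataFrame(
        rows, columns=["individual_id", "group_id", "song_id", "position", "syllable"]
    )
    territories = pd.DataFrame(
        terr_rows, columns=["individual_id", "group_id", "lat", "lon"]
    )
    return transcripts, territories


def dialect_sequence(spec: NeighborhoodSpec, group_index: int) -> list[str]:
    """The dialect sequence planted in every song of the given group.

    A seeded ordering of the group's shared pool (sub-seeded per group, so
    dialects stay group-specific even under pool overlap); exposes the planted
    ground truth independently of the transcripts.
    """
    spec.validate()
    pool = _group_pools(spec)[group_index]
    rng = np.random.default_rng([spec.seed, group_index])
    order = rng.permutation(len(pool))
    return [pool[k] for k in order[: spec.dialect_sequence_length]]


# ---------------------------------------------------------------------------
# Spherical geometry
# ---------------------------------------------------------------------------

def spherical_distance(
    a: tuple[float, float],
    b: tuple[float, float],
    radius: float = EARTH_RADIUS_M,
) -> float:
    """Great-circle (haversine) distance in metres between (lat, lon) points
    given in decimal degrees, on a sphere of the conventional mean Earth
    radius by default."""
    for lat, lon in (a, b):
        if not (np.isfinite(lat) and np.isfinite(lon)):
            raise ValueError("coordinates must be finite")
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2.0 * radius * np.arcsin(np.sqrt(s)))


def territory_distance_matrix(territories: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (m) between territory centres."""
    ids = territories["individual_id"].tolist()
    pts = territories[["lat", "lon"]].to_numpy()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = spherical_distance(tuple(pts[i]), tuple(pts[j]))
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Song audio synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Syllable:
    """A short frequency-modulated tone: linear sweep f_start -> f_end over
    ``duration`` seconds with a raised-cosine amplitude envelope."""

    f_start: float
    f_end: float
    duration: float = 0.1


def make_syllable_bank(
    labels,
    seed: int = 0,
    f_low: float = 2_000.0,
    f_high: float = 6_500.0,
    duration: float = 0.1,
) -> dict[str, Syllable]:
    """Random FM syllables confined well inside the 1.6-7 kHz song band."""
    rng = np.random.default_rng(seed)
    bank = {}
    for lab in labels:
        f0, f1 = rng.uniform(f_low, f_high, size=2)
        bank[lab] = Syllable(float(f0), float(f1), duration)
    return bank


def synthesize_song_audio(
    labels,
    syllable_bank: dict[str, Syllable],
    sample_rate: int = 48_000,
    gap: float = 0.02,
    amplitude: float = 0.9,
) -> np.ndarray:
    """Concatenate syllable waveforms with brief silent gaps.

    Duration is the sum of syllable durations plus ``gap`` seconds between
    consecutive syllables; peak amplitude never exceeds 1.
    """
    labels = list(labels)
    pieces: list[np.ndarray] = []
    gap_samples = int(round(gap * sample_rate))
    for k, lab in enumerate(labels):
        try:
            syl = syllable_bank[lab]
        except KeyError:
            raise KeyError(f"no bank entry for syllable label {lab!r}") from None
        n = int(round(syl.duration * sample_rate))
        t = np.arange(n) / sample_rate
        # Linear chirp: phase = 2*pi*(f0 t + (f1-f0) t^2 / (2 T)).
        phase = 2 * np.pi * (
            syl.f_start * t + (syl.f_end - syl.f_start) * t**2 / (2 * syl.duration)
        )
        env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
        pieces.append(amplitude * env * np.sin(phase))
        if k < len(labels) - 1:
            pieces.append(np.zeros(gap_samples))
    if not pieces:
        return np.zeros(0)
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# Propagation channel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """Parametric open-field transmission channel.

    Broadband gain follows spherical spreading (reference_distance/distance);
    each frequency is further attenuated by ``excess_attenuation`` dB per
    100 m of excess path per kHz; white Gaussian noise of RMS ``noise_floor``
    is added after attenuation.  Height is carried as metadata only.
    """

    distance: float
    reference_distance: float = 1.56
    height: float = 2.0
    excess_attenuation: float = 1.0  # dB / 100 m / kHz
    noise_floor: float = 5e-4  # linear RMS amplitude
    seed: int = 0

    def validate(self) -> None:
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be > 0")
        if self.distance < self.reference_distance:
            raise ValueError(
                f"distance ({self.distance} m) must be >= reference_distance "
                f"({self.reference_distance} m)"
            )
        if self.excess_attenuation < 0 or self.noise_floor < 0:
            raise ValueError("excess_attenuation and noise_floor must be >= 0")


def propagate(
    waveform: np.ndarray, channel: ChannelSpec, sample_rate: int = 48_000
) -> np.ndarray:
    """Apply the channel's frequency-dependent attenuation and additive noise."""
    channel.validate()
    x = np.asarray(waveform, dtype=float)
    spread = channel.reference_distance / channel.distance
    excess_m = channel.distance - channel.reference_distance

    spec = np.fft.rfft(x)
    f_khz = np.fft.rfftfreq(len(x), d=1.0 / sample_rate) / 1_000.0
    atten_db = channel.excess_attenuation * (excess_m / 100.0) * f_khz
    gains = spread * 10.0 ** (-atten_db / 20.0)
    y = np.fft.irfft(spec * gains, n=len(x))

    if channel.noise_floor > 0:
        rng = np.random.default_rng(channel.seed)
        y = y + rng.normal(0.0, channel.noise_floor, size=len(x))
    return y


# ---------------------------------------------------------------------------
# Playback responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseSpec:
    """Latent-factor generator for the 4 playback-response measures.

    One latent aggression score per subject x treatment with mean
    ``treatment_effects[treatment]`` plus a subject-level intercept and unit
    residual; measure_j = baseline_j + scale_j * loading_j * latent + noise.
    The latency loading must oppose the three duration loadings in sign
    (an aggressive bird moves more and starts moving sooner).
    """

    n_subjects: int = 17
    treatment_effects: dict = field(
        default_factory=lambda: {"aN": 0.0, "dN": 0.0, "S": 0.0}
    )
    loadings: tuple = (0.9, 0.8, 0.75, -0.6)
    noise_sd: float = 0.3
    subject_sd: float = 0.5
    #: Residual spread of the latent score within subject x treatment.
    latent_sd: float = 1.0
    #: Latent-score change per metre of singer distance applied to aN/dN rows.
    distance_slope: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if set(self.treatment_effects) != set(TREATMENTS):
            raise ValueError(f"treatment_effects must cover exactly {TREATMENTS}")
        if len(self.loadings) != 4:
            raise ValueError("exactly 4 loadings (one per response measure)")
        durs, lat = self.loadings[:3], self.loadings[3]
        if not (all(np.sign(v) == np.sign(durs[0]) != 0 for v in durs)
                and np.sign(lat) == -np.sign(durs[0])):
            raise ValueError(
                "latency loading must oppose the three duration loadings in sign"
            )
        if self.noise_sd < 0 or self.subject_sd < 0 or self.latent_sd < 0:
            raise ValueError("noise_sd, subject_sd and latent_sd must be >= 0")


#: Baselines/scales map the unit-variance latent scale onto plausible
#: seconds within the 180-s scoring window.
_BASELINES = {"move_dur_10m": 40.0, "time_10m": 60.0, "total_move_dur": 80.0,
              "latency": 60.0}
_SCALES = {"move_dur_10m": 15.0, "time_10m": 20.0, "total_move_dur": 20.0,
           "latency": 25.0}


def generate_response_table(spec: ResponseSpec) -> pd.DataFrame:
    """Per subject x treatment playback responses with randomized order.

    Columns: subject_id, group_id, treatment, order, the four measures
    (seconds, clipped to the 180-s scoring window) and distance_to_singer
    (metres; NaN for stranger rows).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for si in range(spec.n_subjects):
        subject = f"subj{si:02d}"
        group = f"g{si % 2}"
        subj_eff = rng.normal(0.0, spec.subject_sd)
        order = rng.permutation(len(TREATMENTS)) + 1
        # Singer distances mirror the field design: adjacent ~130 m,
        # distant ~230-570 m, stranger in another neighbourhood (no distance).
        dist = {
            "aN": rng.normal(130.0, 30.0),
            "dN": rng.uniform(230.0, 570.0),
            "S": np.nan,
        }
        for k, trt in enumerate(TREATMENTS):
            d = dist[trt]
            latent = (spec.treatment_effects[trt] + subj_eff
                      + rng.normal(0.0, spec.latent_sd))
            if np.isfinite(d):
                latent += spec.distance_slope * d
            row = {
                "subject_id": subject,
                "group_id": group,
                "treatment": trt,
                "order": int(order[k]),
                "distance_to_singer": float(d) if np.isfinite(d) else np.nan,
            }
            for col, load in zip(MEASURE_COLS, spec.loadings):
                val = (_BASELINES[col] + _SCALES[col] * load * latent
                       + _SCALES[col] * rng.normal(0.0, spec.noise_sd))
                row[col] = float(np.clip(val, 0.0, 180.0))
            rows.append(row)
    cols = ["subject_id", "group_id", "treatment", "order", *MEASURE_COLS,
            "distance_to_singer"]
    return pd.DataFrame(rows)[cols]
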