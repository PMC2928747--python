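"""File formats, configuration and the end-to-end pipeline.

Formats: transcripts as TSV (syllable labels may contain commas in user
data), numeric tables as CSV, audio as mono PCM WAV with a manifest CSV,
results as CSV/JSON, config as YAML or JSON.  UTF-8, LF line endings, header
mandatory; positions are 0-based and windows half-open throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import degradation as deg
from . import permstats, repertoire, response, songsynth
from .songsynth import ChannelSpec, NeighborhoodSpec, ResponseSpec

__version__ = "0.1.0"

log = logging.getLogger("songshare")

TRANSCRIPT_COLS = ["individual_id", "group_id", "song_id", "position", "syllable"]
MANIFEST_COLS = ["file", "role", "distance_m", "height_m", "exemplar"]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_transcripts(transcripts: pd.DataFrame, path) -> None:
    transcripts[TRANSCRIPT_COLS].to_csv(path, sep="\t", index=False,
                                        lineterminator="\n")


def read_transcripts(path) -> pd.DataFrame:
    """Read and validate a transcript TSV.

    Positions must be contiguous from 0 within each song and unique per
    (song, position); violations are reported with the file row number
    (1-based, header = row 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"syllable": str})
    missing = [c for c in TRANSCRIPT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return df[TRANSCRIPT_COLS]
    df = df[TRANSCRIPT_COLS]
    dup = df.duplicated(subset=["song_id", "position"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (song_id, position) at row {row}")
    for song, sub in df.groupby("song_id", sort=False):
        pos = np.sort(sub["position"].to_numpy())
        if not np.array_equal(pos, np.arange(len(pos))):
            row = int(sub.index[0]) + 2
            raise ValueError(
                f"{path}: song {song!r} has non-contiguous positions "
                f"(starting at row {row})"
            )
    return df


def write_responses(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["subject_id", "treatment", *songsynth.MEASURE_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_wav(path, waveform: np.ndarray, sample_rate: int = 48_000) -> None:
    """Mono float32 PCM WAV."""
    wavfile.write(path, sample_rate, np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    else:
        data = data.astype(float)
    return data, int(sr)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def load_recordings(manifest_path) -> tuple[list, list]:
    """Load (controls, propagated) Recording lists from a manifest CSV;
    relative file paths resolve against the manifest's directory."""
    mdir = Path(manifest_path).parent
    manifest = read_manifest(manifest_path)
    controls, propagated = [], []
    for _, row in manifest.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = mdir / p
        wave, sr = read_wav(p)
        rec = deg.Recording(wave, sr, role=row["role"],
                            distance=float(row["distance_m"]),
                            height=float(row["height_m"]),
                            exemplar=int(row["exemplar"]))
        (controls if row["role"] == "control" else propagated).append(rec)
    return controls, propagated


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every stage parameter of the end-to-end run; defaults mirror the
    per-module defaults."""

    seed: int = 0
    out_dir: str = "songshare_out"
    # neighbourhood generator
    neighborhood: dict = field(default_factory=dict)
    # repertoire windows
    n_min: int = repertoire.SEQ_N_MIN
    n_max: int = repertoire.SEQ_N_MAX
    # permutation tests
    n_perm_paired: int = 10_000
    n_perm_corr: int = 1_000
    # propagation stage
    distances: tuple = (12.5, 25.0, 50.0, 100.0, 200.0)
    heights: tuple = (0.1, 2.0)
    n_exemplars: int = 5
    reference_distance: float = 1.56
    excess_attenuation: float = 1.0
    noise_floor: float = 5e-4
    audio_song_length: int = 15
    sample_rate: int = 48_000
    # degradation analysis
    band_low: float = deg.BAND_LOW_HZ
    band_high: float = deg.BAND_HIGH_HZ
    nfft_spectrum: int = 1_024
    nfft_spectrogram: int = 256
    max_lag: float = 0.5
    # playback responses
    response: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.distances, list):
            cfg.distances = tuple(cfg.distances)
        if isinstance(cfg.heights, list):
            cfg.heights = tuple(cfg.heights)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distances"] = list(self.distances)
        d["heights"] = list(self.heights)
        return d


@dataclass(frozen=True)
class RunRecord:
    config: dict
    version: str
    seed: int
    checksums: dict
    started: float
    finished: float


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _partner_map(territories: pd.DataFrame, dist: pd.DataFrame,
                 rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """aN = nearest same-group territory; dN = a same-group territory a few
    territories away (middle of the sorted distance ranking); S = a random
    individual from another group."""
    groups = territories.set_index("individual_id")["group_id"]
    partner = {}
    for focal in territories["individual_id"]:
        same = [i for i in territories["individual_id"]
                if i != focal and groups[i] == groups[focal]]
        other = [i for i in territories["individual_id"]
                 if groups[i] != groups[focal]]
        if not same or not other:
            continue
        ranked = sorted(same, key=lambda i: dist.loc[focal, i])
        partner[focal] = {
            "aN": ranked[0],
            "dN": ranked[min(len(ranked) // 2 + 1, len(ranked) - 1)],
            "S": other[int(rng.integers(len(other)))],
        }
    return partner


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute simulate -> repertoire -> permutation tests -> degradation ->
    response on synthetic inputs, writing every result under config.out_dir."""
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def _stage(name):
        log.info("stage %s (seed=%d)", name, config.seed)

    # -- simulate ----------------------------------------------------------
    try:
        _stage("simulate")
        # The pipeline is an observational emulation, so repertoire sharing
        # varies between pairs (random pool sampling) unless configured
        # otherwise; the analytic deterministic mode is for unit checks.
        spec = NeighborhoodSpec(**{"seed": config.seed,
                                   "pool_sampling": "random",
                                   **config.neighborhood})
        transcripts, territories = songsynth.generate_neighborhood(spec)
        write_transcripts(transcripts, out / "transcripts.tsv")
        territories.to_csv(out / "territories.csv", index=False,
                           lineterminator="\n")
        outputs += [out / "transcripts.tsv", out / "territories.csv"]
    except Exception as e:  # noqa: BLE001 - report the failing stage
        raise StageError("simulate", e) from e

    # -- repertoire --------------------------------------------------------
    try:
        _stage("repertoire")
        rng = np.random.default_rng([config.seed, 1])
        dist = songsynth.territory_distance_matrix(territories)
        partners = _partner_map(territories, dist, rng)
        cat_tables = []
        reps_by_kind = {}
        for kind in ("syllable", "sequence"):
            reps = repertoire.repertoires_from_transcripts(
                transcripts, kind, config.n_min, config.n_max)
            reps_by_kind[kind] = reps
            mat = repertoire.pairwise_rs_matrix(reps.values())
            mat.to_csv(out / f"rs_{kind}.csv", lineterminator="\n")
            outputs.append(out / f"rs_{kind}.csv")
            cat_tables.append(repertoire.category_rs_table(
                sorted(partners), partners, reps))
        cat = pd.concat(cat_tables, ignore_index=True)
        cat.to_csv(out / "category_rs.csv", index=False, lineterminator="\n")
        outputs.append(out / "category_rs.csv")
    except Exception as e:
        raise StageError("repertoire", e) from e

    # -- permutation tests -------------------------------------------------
    try:
        _stage("permstats")
        results = {}
        for kind in ("syllable", "sequence"):
            sub = cat[cat["kind"] == kind].pivot(index="focal_id",
                                                 columns="category",
                                                 values="RS")
            for a, b in (("aN", "S"), ("dN", "S"), ("aN", "dN")):
                res = permstats.paired_permutation_test(
                    sub[[a, b]].to_numpy(), n_perm=config.n_perm_paired,
                    seed=config.seed)
                results[f"{kind}_{a}_vs_{b}"] = res.as_dict()
            # Mantel-type: neighbour RS against territory distance.
            xs, ys = [], []
            for focal, row in sub.iterrows():
                for catg in ("aN", "dN"):
                    xs.append(dist.loc[focal, partners[focal][catg]])
                    ys.append(row[catg])
            res = permstats.permuted_correlation_test(
                np.array(xs), np.array(ys), n_perm=config.n_perm_corr,
                seed=config.seed)
            results[f"{kind}_rs_vs_distance"] = res.as_dict()
        (out / "permutation_tests.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n")
        outputs.append(out / "permutation_tests.json")
    except Exception as e:
        raise StageError("permstats", e) from e

    # -- degradation -------------------------------------------------------
    try:
        _stage("degradation")
        # One synthetic song sequence, broadcast n_exemplars times through
        # channels that differ only in their noise realization.
        first = transcripts[transcripts["individual_id"]
                            == transcripts["individual_id"].iloc[0]]
        first_song = first[first["song_id"] == first["song_id"].iloc[0]]
        labels = first_song.sort_values("position")["syllable"].tolist()
        labels = labels[: config.audio_song_length]
        bank = songsynth.make_syllable_bank(sorted(set(labels)),
                                            seed=config.seed)
        wave = songsynth.synthesize_song_audio(labels, bank,
                                               config.sample_rate)
        wav_dir = out / "audio"
        wav_dir.mkdir(exist_ok=True)
        manifest_rows = []
        controls, propagated = [], []
        for ex in range(config.n_exemplars):
            name = f"control_ex{ex}.wav"
            write_wav(wav_dir / name, wave, config.sample_rate)
            manifest_rows.append([f"audio/{name}", "control",
                                  config.reference_distance, 2.0, ex])
            controls.append(deg.Recording(wave, config.sample_rate, "control",
                                          config.reference_distance, 2.0, ex))
            for hi, h in enumerate(config.heights):
                for di, d in enumerate(config.distances):
                    ch = ChannelSpec(
                        distance=d,
                        reference_distance=config.reference_distance,
                        height=h,
                        excess_attenuation=config.excess_attenuation,
                        noise_floor=config.noise_floor,
                        seed=int(np.random.default_rng(
                            [config.seed, 2, ex, hi, di]).integers(2**31)),
                    )
                    y = songsynth.propagate(wave, ch, config.sample_rate)
                    name = f"prop_ex{ex}_h{hi}_d{di}.wav"
                    write_wav(wav_dir / name, y, config.sample_rate)
                    manifest_rows.append([f"audio/{name}", "propagated",
                                          d, h, ex])
                    propagated.append(deg.Recording(y, config.sample_rate,
                                                    "propagated", d, h, ex))
        pd.DataFrame(manifest_rows, columns=MANIFEST_COLS).to_csv(
            out / "manifest.csv", index=False, lineterminator="\n")
        outputs.append(out / "manifest.csv")

        table = deg.degradation_table(
            controls, propagated,
            nfft_spectrum=config.nfft_spectrum,
            nfft_spectrogram=config.nfft_spectrogram,
            max_lag=config.max_lag,
            band=(config.band_low, config.band_high),
        )
        table.to_csv(out / "degradation_long.csv", index=False,
                     lineterminator="\n")
        deg.degradation_wide(table).to_csv(out / "degradation_table.csv",
                                           lineterminator="\n")
        outputs += [out / "degradation_long.csv",
                    out / "degradation_table.csv"]
    except Exception as e:
        raise StageError("degradation", e) from e

    # -- response ----------------------------------------------------------
    try:
        _stage("response")
        rspec = ResponseSpec(**{"seed": config.seed, **config.response})
        rtable = songsynth.generate_response_table(rspec)
        write_responses(rtable, out / "responses.csv")
        model, scored = response.pca_scores(rtable)
        response.loadings_table(model).to_csv(out / "pca_report.csv",
                                              lineterminator="\n")
        tests = response.compare_treatments(scored, seed=config.seed)
        dist_eff = response.distance_effect(scored)
        payload = {
            "omnibus": tests["omnibus"],
            "pairwise": {k: v.as_dict() for k, v in tests["pairwise"].items()},
            "distance_effect": dataclasses.asdict(dist_eff),
            "retained_components": list(model.retained),
        }
        (out / "response_tests.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        outputs += [out / "responses.csv", out / "pca_report.csv",
                    out / "response_tests.json"]
    except Exception as e:
        raise StageError("response", e) from e

    finished = time.time()
    record = RunRecord(
        config=config.as_dict(),
        version=__version__,
        seed=config.seed,
        checksums={str(p.relative_to(out)): _sha256(p) for p in outputs},
        started=started,
        finished=finished,
    )
    (out / "run_record.json").write_text(
        json.dumps(dataclasses.asdict(record), indent=2, sort_keys=True) + "\n")
    return record
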