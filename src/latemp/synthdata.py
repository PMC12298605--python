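"""Synthetic bilateral-temperature experiment generator.

Emulates the statistical structure of a two-experiment emotion-induction
study: 10 participants each complete four emotion blocks (fear, sadness,
joy, love; two 120-s labeled segments per emotion) while tympanic membrane
temperature (TMT) and dorsal wrist skin temperature are recorded bilaterally
at 20 Hz.  The quantity of interest downstream is the right-minus-left
temperature difference; the generator plants a valence-dependent shift on
the latent 1-Hz tympanic difference (negative-valence segments are shifted
downward inside a configurable time window) on top of participant-level
baselines, slow drift, AR(1) noise, 20-Hz sensor white noise, and optional
movement-spike artifacts.

The generator encodes only the assumptions of the analysis, not real
thermophysiology: no ambient coupling, no hemodynamics, no circadian trend.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, DatasetFormatError, ValidationError

RATING_ITEMS = (
    "anger",
    "disgust",
    "fear",
    "sadness",
    "amusement",
    "inspiration",
    "joy",
    "tenderness",
)

#: rating item a successfully induced target emotion should dominate
TARGET_ITEM = {"fear": "fear", "sadness": "sadness", "joy": "joy", "love": "tenderness"}

RECORDING_COLUMNS = ["participant", "experiment", "site", "side", "time_s", "value_c"]
TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "block",
    "sub_block",
    "emotion",
    "valence",
    "start_s",
    "end_s",
]


@dataclass(frozen=True)
class StudyDesign:
    """Counts and labels defining one simulated study.

    Defaults reproduce the reference design: 10 participants, four discrete
    emotions mapped two-and-two onto positive/negative valence, two labeled
    120-s segments per emotion, raw sampling at 20 Hz, two experiments.
    """

    n_participants: int = 10
    emotions: tuple[str, ...] = ("fear", "sadness", "joy", "love")
    valence_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "fear": "negative",
            "sadness": "negative",
            "joy": "positive",
            "love": "positive",
        }
    )
    n_subblocks_per_emotion: int = 2
    segment_length: float = 120.0
    raw_rate: int = 20
    experiments: tuple[str, ...] = ("exp1", "exp2")
    gap_length: float = 60.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("need at least 2 participants")
        if not self.emotions:
            raise ConfigurationError("need at least one emotion")
        if set(self.emotions) != set(self.valence_map):
            raise ConfigurationError("valence_map must cover exactly the emotions")
        if set(self.valence_map.values()) != {"positive", "negative"}:
            raise ConfigurationError("both valences must be present")
        n_raw = self.segment_length * self.raw_rate
        if abs(n_raw - round(n_raw)) > 1e-9:
            raise ConfigurationError(
                "segment_length x raw_rate must be an integer sample count"
            )
        if self.n_subblocks_per_emotion < 1 or self.raw_rate < 1:
            raise ConfigurationError("counts must be positive")
        if self.segment_length < 1 or self.gap_length < 0:
            raise ConfigurationError("invalid segment/gap length")

    @property
    def n_segments(self) -> int:
        return len(self.emotions) * self.n_subblocks_per_emotion

    @property
    def participants(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]

    def total_duration(self) -> float:
        """Recording span per participant-experiment: lead-in gap, then
        segment+gap repeated."""
        return self.gap_length + self.n_segments * (self.segment_length + self.gap_length)


@dataclass(frozen=True)
class EffectSpec:
    """Magnitudes of the planted signal and of every nuisance term.

    All temperatures in deg C, times in seconds.  ``effect_magnitude`` is the
    shift applied to the latent right-left tympanic difference of
    negative-valence segments inside ``effect_window`` (the sign convention:
    a negative magnitude lowers right-left for negative emotions, so
    positive-minus-negative equals ``-effect_magnitude`` there).  Wrist
    channels receive ``wrist_effect_magnitude`` instead (default 0, so the
    tympanic-vs-wrist contrast is reproducible by construction).
    """

    effect_window: tuple[float, float] = (70.0, 85.0)
    effect_magnitude: float = -0.3
    #: "smooth-bump" (cosine-tapered) by default: physiological temperature
    #: shifts build up gradually; a boxcar's 1-s step edge is indistinguishable
    #: from a movement artifact and would be zeroed by the 5-sd rule
    effect_shape: str = "smooth-bump"
    drift_sd: float = 0.001  # random-walk innovation sd per second, on the diff
    noise_sd: float = 0.05  # stationary sd of the 1-Hz AR(1) noise on the diff
    ar_coefficient: float = 0.8
    artifact_rate: float = 0.0  # movement spikes per second, at the raw rate
    artifact_magnitude: float = 2.0
    baseline_tympanic: float = 36.8
    baseline_wrist: float = 33.0
    baseline_between_participant_sd: float = 0.3
    diff_baseline_sd: float = 0.1  # participant-level right-left offset sd
    sensor_noise_sd: float = 0.02  # white noise per raw 20-Hz sample, per channel
    wrist_effect_magnitude: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.effect_window
        if not 0 <= lo < hi:
            raise ConfigurationError("effect_window must satisfy 0 <= start < end")
        if self.effect_shape not in ("boxcar", "smooth-bump"):
            raise ConfigurationError(f"unknown effect_shape {self.effect_shape!r}")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ConfigurationError("|ar_coefficient| must be < 1")
        for name in ("drift_sd", "noise_sd", "sensor_noise_sd",
                     "baseline_between_participant_sd", "diff_baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class TemperatureRecording:
    """One sensor channel: timestamped deg-C series for a participant/site/side."""

    participant: str
    experiment: str
    site: str  # "tympanic" | "wrist"
    side: str  # "left" | "right"
    rate: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError(
                    f"times must be strictly increasing "
                    f"({self.participant}/{self.site}/{self.side})"
                )
            if not np.allclose(dt, 1.0 / self.rate, atol=1e-6):
                raise ValidationError("times must be uniformly spaced at 1/rate")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.participant, self.experiment, self.site, self.side)


def _effect_profile(effects: EffectSpec, segment_length: float) -> np.ndarray:
    """Unit effect time course over one segment at 1 Hz (scaled by magnitude later)."""
    t = np.arange(int(round(segment_length)), dtype=float)
    lo, hi = effects.effect_window
    hi = min(hi, segment_length)
    inside = (t >= lo) & (t < hi)
    prof = inside.astype(float)
    if effects.effect_shape == "smooth-bump" and inside.any():
        # cosine taper over the window: 0 at edges, 1 at the centre
        span = hi - lo
        prof[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - lo) / span))
    return prof


def _ar1(rng: np.random.Generator, n: int, stationary_sd: float, a: float) -> np.ndarray:
    if stationary_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = stationary_sd * math.sqrt(1 - a * a)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, stationary_sd)  # start in the stationary distribution
    return lfilter([1.0], [1.0, -a], e)


def _segment_schedule(design: StudyDesign, rng: np.random.Generator) -> list[dict]:
    """Randomly ordered emotion blocks; consecutive sub-blocks within a block."""
    order = [design.emotions[i] for i in rng.permutation(len(design.emotions))]
    rows = []
    t = design.gap_length
    for block, emotion in enumerate(order):
        for sub in range(design.n_subblocks_per_emotion):
            rows.append(
                {
                    "block": block,
                    "sub_block": sub,
                    "emotion": emotion,
                    "valence": design.valence_map[emotion],
                    "start_s": t,
                    "end_s": t + design.segment_length,
                }
            )
            t += design.segment_length + design.gap_length
    return rows


def generate_experiment(
    design: StudyDesign,
    effects: EffectSpec | Mapping[str, EffectSpec],
    seed: int,
) -> tuple[list[TemperatureRecording], pd.DataFrame, pd.DataFrame]:
    """Simulate all recordings, the trial table, and the rating table.

    ``effects`` may be a single :class:`EffectSpec` (shared by every
    experiment) or a mapping ``experiment -> EffectSpec`` so that e.g. the
    effect window can differ between experiments.

    Returns ``(recordings, trials, ratings)``: four recordings (tympanic and
    wrist, left and right) per participant per experiment; one trial row per
    labeled segment; one rating row per participant x experiment x emotion
    sub-block.  Identical arguments give bit-identical output.
    """
    if isinstance(effects, EffectSpec):
        effect_map = {e: effects for e in design.experiments}
    else:
        effect_map = dict(effects)
        missing = set(design.experiments) - set(effect_map)
        if missing:
            raise ConfigurationError(f"no EffectSpec for experiments {sorted(missing)}")

    root = np.random.SeedSequence(seed)
    part_seeds = root.spawn(design.n_participants)

    recordings: list[TemperatureRecording] = []
    trial_rows: list[dict] = []
    rating_rows: list[dict] = []

    total = design.total_duration()
    n1 = int(round(total))  # latent 1-Hz length
    upsample = design.raw_rate
    n_raw = n1 * upsample
    t_raw = np.arange(n_raw) / design.raw_rate

    for p_idx, participant in enumerate(design.participants):
        p_root = part_seeds[p_idx]
        p_rng = np.random.default_rng(p_root)
        # participant-level constants shared across experiments
        any_effects = next(iter(effect_map.values()))
        body_offset = p_rng.normal(0.0, any_effects.baseline_between_participant_sd)
        diff_offset = {
            "tympanic": p_rng.normal(0.0, any_effects.diff_baseline_sd),
            "wrist": p_rng.normal(0.0, any_effects.diff_baseline_sd),
        }
        schedule = _segment_schedule(design, p_rng)  # same block order in both experiments

        exp_seeds = p_root.spawn(len(design.experiments))
        for e_idx, experiment in enumerate(design.experiments):
            eff = effect_map[experiment]
            rng = np.random.default_rng(exp_seeds[e_idx])
            profile = _effect_profile(eff, design.segment_length)

            for row in schedule:
                trial_rows.append(
                    {"participant": participant, "experiment": experiment, **row}
                )

            for site in ("tympanic", "wrist"):
                base = (
                    eff.baseline_tympanic if site == "tympanic" else eff.baseline_wrist
                ) + body_offset
                magnitude = (
                    eff.effect_magnitude if site == "tympanic" else eff.wrist_effect_magnitude
                )
                # latent 1-Hz right-left difference
                diff = np.full(n1, diff_offset[site])
                diff += np.cumsum(rng.normal(0.0, eff.drift_sd, size=n1))
                diff += _ar1(rng, n1, eff.noise_sd, eff.ar_coefficient)
                for row in schedule:
                    if row["valence"] == "negative" and magnitude != 0:
                        s = int(round(row["start_s"]))
                        diff[s : s + len(profile)] += magnitude * profile
                # left channel: baseline + its own slow body drift
                left1 = base + np.cumsum(rng.normal(0.0, eff.drift_sd, size=n1))
                right1 = left1 + diff
                for side, lat in (("left", left1), ("right", right1)):
                    raw = np.repeat(lat, upsample)
                    if eff.sensor_noise_sd > 0:
                        raw = raw + rng.normal(0.0, eff.sensor_noise_sd, size=n_raw)
                    rec = TemperatureRecording(
                        participant, experiment, site, side, design.raw_rate, t_raw, raw
                    )
                    # drawn unconditionally so the noise stream is identical
                    # with and without artifacts (parameter-recovery tests)
                    artifact_seed = int(rng.integers(0, 2**31 - 1))
                    if eff.artifact_rate > 0:
                        rec = inject_artifacts(
                            rec, eff.artifact_rate, eff.artifact_magnitude, artifact_seed
                        )
                    recordings.append(rec)

            # ratings: one row per emotion sub-block, target-consistent
            for emotion in design.emotions:
                target = TARGET_ITEM[emotion]
                valence = design.valence_map[emotion]
                for sub in range(design.n_subblocks_per_emotion):
                    row = {
                        "participant": participant,
                        "experiment": experiment,
                        "emotion": emotion,
                        "sub_block": sub,
                    }
                    for item in RATING_ITEMS:
                        if item == target:
                            mu = 7.5
                        elif _item_valence(item) == valence:
                            mu = 4.5
                        else:
                            mu = 2.0
                        row[item] = int(np.clip(round(rng.normal(mu, 1.0)), 1, 9))
                    rating_rows.append(row)

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    ratings = pd.DataFrame(
        rating_rows,
        columns=["participant", "experiment", "emotion", "sub_block", *RATING_ITEMS],
    )
    return recordings, trials, ratings


def _item_valence(item: str) -> str:
    return "negative" if item in ("anger", "disgust", "fear", "sadness") else "positive"


def inject_artifacts(
    recording: TemperatureRecording, rate: float, magnitude: float, seed: int
) -> TemperatureRecording:
    """Insert movement-spike artifacts: step changes of +-``magnitude`` at
    Poisson-distributed onsets, each persisting 1-3 s before reverting.

    ``rate`` is in spikes per second over the recording's span.  Returns a new
    recording; the input is untouched.  ``rate=0`` returns the input unchanged.
    """
    if rate < 0:
        raise ConfigurationError("artifact rate must be >= 0")
    if rate == 0 or recording.times.size == 0:
        return recording
    rng = np.random.default_rng(seed)
    duration = recording.times.size / recording.rate
    n_spikes = rng.poisson(rate * duration)
    values = recording.values.copy()
    for _ in range(n_spikes):
        onset = rng.uniform(0.0, duration)
        persist = rng.uniform(1.0, 3.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lo = int(onset * recording.rate)
        hi = min(int((onset + persist) * recording.rate), values.size)
        values[lo:hi] += sign * magnitude
    return dataclasses.replace(recording, values=values)


# ---------------------------------------------------------------------------
# dataset IO: recordings.csv / trials.csv / ratings.csv / config.json
# ---------------------------------------------------------------------------

def write_dataset(
    recordings: list[TemperatureRecording],
    trials: pd.DataFrame,
    ratings: pd.DataFrame,
    directory: str | Path,
    design: StudyDesign | None = None,
    effects: EffectSpec | Mapping[str, EffectSpec] | None = None,
) -> None:
    """Write the dataset as plain CSV (long-format recordings) plus config.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant": rec.participant,
                    "experiment": rec.experiment,
                    "site": rec.site,
                    "side": rec.side,
                    "time_s": rec.times,
                    "value_c": rec.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(directory / "recordings.csv", index=False)
    trials.to_csv(directory / "trials.csv", index=False)
    ratings.to_csv(directory / "ratings.csv", index=False)
    config: dict = {}
    if design is not None:
        config["design"] = design_to_dict(design)
    if effects is not None:
        if isinstance(effects, EffectSpec):
            config["effects"] = effects_to_dict(effects)
        else:
            config["effects"] = {k: effects_to_dict(v) for k, v in effects.items()}
    (directory / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))


def read_dataset(
    directory: str | Path,
) -> tuple[list[TemperatureRecording], pd.DataFrame, pd.DataFrame]:
    """Read a dataset written by :func:`write_dataset`; validates structure."""
    directory = Path(directory)
    rec_path = directory / "recordings.csv"
    try:
        df = pd.read_csv(rec_path)
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise DatasetFormatError(f"{rec_path}: cannot parse ({exc})") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{rec_path}: missing column(s) {missing}")
    recordings = []
    for key, grp in df.groupby(["participant", "experiment", "site", "side"], sort=True):
        times = grp["time_s"].to_numpy(float)
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ValidationError(f"{rec_path}: non-monotonic times for channel {key}")
        rate = 1.0 / float(np.median(np.diff(times))) if times.size >= 2 else 1.0
        recordings.append(
            TemperatureRecording(
                str(key[0]), str(key[1]), str(key[2]), str(key[3]),
                float(round(rate, 6)), times, grp["value_c"].to_numpy(float),
            )
        )
    trials_path = directory / "trials.csv"
    trials = pd.read_csv(trials_path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DatasetFormatError(f"{trials_path}: missing column(s) {missing}")
    ratings = pd.read_csv(directory / "ratings.csv")
    return recordings, trials, ratings


def design_to_dict(design: StudyDesign) -> dict:
    d = dataclasses.asdict(design)
    d["emotions"] = list(design.emotions)
    d["experiments"] = list(design.experiments)
    d["valence_map"] = dict(design.valence_map)
    return d


def design_from_dict(d: Mapping) -> StudyDesign:
    d = dict(d)
    d["emotions"] = tuple(d.get("emotions", ("fear", "sadness", "joy", "love")))
    if "experiments" in d:
        d["experiments"] = tuple(d["experiments"])
    return StudyDesign(**d)


def effects_to_dict(effects: EffectSpec) -> dict:
    d = dataclasses.asdict(effects)
    d["effect_window"] = list(effects.effect_window)
    return d


def effects_from_dict(d: Mapping) -> EffectSpec:
    d = dict(d)
    if "effect_window" in d:
        d["effect_window"] = tuple(d["effect_window"])
    return EffectSpec(**d)
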