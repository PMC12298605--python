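"""Noise reduction and derivation of labeled right-left difference samples.

The pipeline per channel: average the raw 20-Hz signal into non-overlapping
one-second bins (1 Hz); difference the 1-Hz series; zero any first difference
further than five standard deviations from the mean of the differences
(movement artifacts appear as step changes, i.e. single outlying
differences); reintegrate from the first sample.  Right-minus-left series
are then cut into labeled trial samples using the trial table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthdata import TemperatureRecording

SAMPLE_COLUMNS = [
    "participant",
    "experiment",
    "site",
    "emotion",
    "valence",
    "trial_id",
    "t",
    "diff_c",
]


@dataclass
class CleanSeries:
    """A 1-Hz channel after resampling (and, later, artifact removal)."""

    participant: str
    experiment: str
    site: str
    side: str
    values: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TrialSample:
    """One labeled right-minus-left 1-Hz series for a single trial segment."""

    participant: str
    experiment: str
    site: str
    emotion: str
    valence: str
    trial_id: int
    diff_values: np.ndarray

    def __post_init__(self) -> None:
        self.diff_values = np.asarray(self.diff_values, dtype=float)


def resample_to_1hz(recording: TemperatureRecording) -> CleanSeries:
    """Mean over each non-overlapping 1-s interval; trailing partial second dropped."""
    if recording.values.size == 0:
        raise ValidationError("cannot resample an empty recording")
    rate = int(round(recording.rate))
    if rate != 20:
        raise ValidationError(f"expected a 20 Hz recording, got {recording.rate} Hz")
    n = recording.values.size // rate
    if n == 0:
        raise ValidationError("recording shorter than one second")
    values = recording.values[: n * rate].reshape(n, rate).mean(axis=1)
    return CleanSeries(
        recording.participant, recording.experiment, recording.site, recording.side, values
    )


def remove_artifacts(series: CleanSeries) -> CleanSeries:
    """Zero outlying one-second differences (|d - mean| > 5 sd) and reintegrate.

    Statistics are computed over this channel's full recording in a single
    pass (no re-estimation after zeroing).  sd is the sample standard
    deviation; a constant or two-point series is returned unchanged.  The
    reconstruction is anchored at the first 1-Hz sample, so it is the exact
    identity whenever no difference is flagged.
    """
    x = series.values
    if x.size < 2:
        raise ValidationError("artifact removal needs at least 2 samples")
    d = np.diff(x)
    if d.size < 2:
        return dataclasses.replace(series, values=x.copy())
    mu = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return dataclasses.replace(series, values=x.copy())
    d = np.where(np.abs(d - mu) > 5 * sd, 0.0, d)
    values = np.concatenate(([x[0]], x[0] + np.cumsum(d)))
    return dataclasses.replace(series, values=values)


def lateral_difference(right: CleanSeries, left: CleanSeries) -> np.ndarray:
    """Elementwise right-minus-left temperature, deg C."""
    for attr in ("participant", "experiment", "site"):
        if getattr(right, attr) != getattr(left, attr):
            raise ValidationError(f"channels differ in {attr}")
    if right.values.size != left.values.size:
        raise ValidationError(
            f"length mismatch: right {right.values.size} vs left {left.values.size}"
        )
    return right.values - left.values


def extract_trial_samples(
    channels: list[CleanSeries], trials: pd.DataFrame
) -> list[TrialSample]:
    """Cut labeled right-left difference segments out of the clean channels.

    Produces one sample per trial row per site.  Trial start/end are in
    seconds from the start of the recording; at 1 Hz they index samples
    directly.
    """
    by_key: dict[tuple, CleanSeries] = {
        (s.participant, s.experiment, s.site, s.side): s for s in channels
    }
    samples: list[TrialSample] = []
    for trial_id, row in trials.iterrows():
        for site in ("tympanic", "wrist"):
            key_r = (row["participant"], row["experiment"], site, "right")
            key_l = (row["participant"], row["experiment"], site, "left")
            if key_r not in by_key or key_l not in by_key:
                continue  # site not recorded for this participant-experiment
            diff = lateral_difference(by_key[key_r], by_key[key_l])
            start, end = int(round(row["start_s"])), int(round(row["end_s"]))
            if end > diff.size:
                raise ValidationError(
                    f"trial {trial_id} ({row['participant']}/{row['experiment']}/"
                    f"{row['emotion']}) ends at {end}s beyond recording "
                    f"({diff.size}s)"
                )
            samples.append(
                TrialSample(
                    str(row["participant"]),
                    str(row["experiment"]),
                    site,
                    str(row["emotion"]),
                    str(row["valence"]),
                    int(trial_id),
                    diff[start:end],
                )
            )
    return samples


def baseline_correct(sample: TrialSample) -> TrialSample:
    """Subtract the first time point from the whole sample (idempotent)."""
    v = sample.diff_values
    return dataclasses.replace(sample, diff_values=v - v[0])


def preprocess_dataset(
    recordings: list[TemperatureRecording], trials: pd.DataFrame
) -> list[TrialSample]:
    """Full preprocessing: resample, remove artifacts, difference, segment."""
    channels = [remove_artifacts(resample_to_1hz(r)) for r in recordings]
    return extract_trial_samples(channels, trials)


def samples_to_frame(samples: list[TrialSample]) -> pd.DataFrame:
    """Long-format table (one row per sample per second), for samples.csv."""
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant,
                    "experiment": s.experiment,
                    "site": s.site,
                    "emotion": s.emotion,
                    "valence": s.valence,
                    "trial_id": s.trial_id,
                    "t": np.arange(s.diff_values.size),
                    "diff_c": s.diff_values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_samples(df: pd.DataFrame) -> list[TrialSample]:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"samples table missing column(s) {missing}")
    samples = []
    keys = ["participant", "experiment", "site", "trial_id"]
    for (participant, experiment, site, trial_id), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("t")
        samples.append(
            TrialSample(
                str(participant),
                str(experiment),
                str(site),
                str(grp["emotion"].iloc[0]),
                str(grp["valence"].iloc[0]),
                int(trial_id),
                grp["diff_c"].to_numpy(float),
            )
        )
    return samples
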