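"""Windowed feature extraction and within-participant normalization.

Each 1-Hz right-left difference sample is sliced into 20-s windows with a
10-s stride; each window contributes its mean, minimum, maximum, and Shannon
entropy (histogram over 10 equal-width bins spanning the window's own range,
log base 2), concatenated window-major into one feature vector — 44 values
for a 120-s sample.  Features are then min-max scaled to [0, 1] per feature
dimension within each participant (and experiment and site), which removes
cross-participant baseline differences without ever touching another
participant's data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .preprocess import TrialSample

WINDOW_S = 20
STRIDE_S = 10
N_BINS = 10
FEATURE_NAMES = ("mean", "min", "max", "entropy")


@dataclass
class FeatureVector:
    """One sample's concatenated window features plus its labels."""

    participant: str
    experiment: str
    site: str
    emotion: str
    valence: str
    trial_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def window_slice(
    values: np.ndarray, window: int = WINDOW_S, stride: int = STRIDE_S
) -> list[np.ndarray]:
    """Ordered sliding windows starting at 0, stride, 2*stride, ...; trailing
    samples not covered by a full window are dropped."""
    values = np.asarray(values, dtype=float)
    if window < 1 or stride < 1:
        raise ConfigurationError("window and stride must be positive")
    if values.size < window:
        raise ValidationError(
            f"series of length {values.size} is shorter than one {window}-s window"
        )
    n_windows = (values.size - window) // stride + 1
    return [values[i * stride : i * stride + window] for i in range(n_windows)]


def shannon_entropy(values: np.ndarray, n_bins: int = N_BINS) -> float:
    """Histogram-based Shannon entropy in bits.

    Bins are equal-width over [min, max] of the window itself; p log p with
    p = 0 contributes 0.  A constant window has zero entropy by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("entropy of an empty window is undefined")
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def build_feature_vector(
    sample: TrialSample,
    window: int = WINDOW_S,
    stride: int = STRIDE_S,
    n_bins: int = N_BINS,
) -> FeatureVector:
    """Window-major [mean, min, max, entropy] concatenation for one sample."""
    windows = window_slice(sample.diff_values, window, stride)
    feats = np.empty(4 * len(windows))
    for w, win in enumerate(windows):
        feats[4 * w : 4 * w + 4] = (
            win.mean(),
            win.min(),
            win.max(),
            shannon_entropy(win, n_bins),
        )
    return FeatureVector(
        sample.participant,
        sample.experiment,
        sample.site,
        sample.emotion,
        sample.valence,
        sample.trial_id,
        feats,
    )


def normalize_within_participant(vectors: list[FeatureVector]) -> list[FeatureVector]:
    """Min-max scale each feature dimension to [0, 1] within each participant
    (separately per experiment and site).

    A dimension constant within a scope maps to 0 for all of that scope's
    samples.  A scope with a single sample is an error — its normalization
    would be undefined (and any choice would leak the label).
    """
    groups: dict[tuple, list[int]] = {}
    for i, v in enumerate(vectors):
        groups.setdefault((v.participant, v.experiment, v.site), []).append(i)
    out: list[FeatureVector] = [None] * len(vectors)  # type: ignore[list-item]
    for key, idxs in groups.items():
        if len(idxs) < 2:
            raise ValidationError(
                f"participant scope {key} has a single sample; min-max "
                "normalization is undefined"
            )
        mat = np.stack([vectors[i].values for i in idxs])
        lo = mat.min(axis=0)
        span = mat.max(axis=0) - lo
        scaled = np.where(span > 0, (mat - lo) / np.where(span > 0, span, 1.0), 0.0)
        for row, i in enumerate(idxs):
            out[i] = dataclasses.replace(vectors[i], values=scaled[row])
    return out


def vectors_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Wide table with columns f001.. for features.csv."""
    if not vectors:
        return pd.DataFrame()
    width = vectors[0].values.size
    rows = []
    for v in vectors:
        if v.values.size != width:
            raise ValidationError("feature vectors differ in length")
        row = {
            "participant": v.participant,
            "experiment": v.experiment,
            "site": v.site,
            "emotion": v.emotion,
            "valence": v.valence,
            "trial_id": v.trial_id,
        }
        row.update({f"f{k + 1:03d}": v.values[k] for k in range(width)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_vectors(df: pd.DataFrame) -> list[FeatureVector]:
    fcols = sorted(c for c in df.columns if c.startswith("f") and c[1:].isdigit())
    if not fcols:
        raise ValidationError("features table has no f### columns")
    return [
        FeatureVector(
            str(r["participant"]),
            str(r["experiment"]),
            str(r["site"]),
            str(r["emotion"]),
            str(r["valence"]),
            int(r["trial_id"]),
            np.array([r[c] for c in fcols], dtype=float),
        )
        for _, r in df.iterrows()
    ]
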