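"""Cluster-based permutation testing of right-left temperature time courses.

Within-subject design: for each participant and condition, trial samples are
baseline-corrected (first time point subtracted) and averaged into one mean
time course per condition, giving a tensor x[i, j, k] over participants i,
conditions j, and time points k.  A pointwise statistic is computed at every
time point — a paired t for the two-condition valence contrast, a
repeated-measures one-way F for the four discrete emotions — and time points
exceeding the alpha = 0.05 critical value are grouped into clusters of
consecutive seconds.  Each cluster's mass is the sum of its pointwise
statistics.  The null distribution is built by permuting condition labels
independently within each participant (a space of (c!)^n relabelings),
recording the largest absolute cluster mass of each permutation; this
max-statistic construction controls the family-wise error rate over time.

Cluster p-values are reported two ways: the plain proportion of null masses
at least as large as the observed mass (which can reach 0), and the
(b + 1) / (m + 1) correction which cannot.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import ConfigurationError, ValidationError
from .preprocess import TrialSample, baseline_correct

ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 1000
EXHAUSTIVE_CAP = 100_000  # refuse exhaustive enumeration beyond this many patterns


@dataclass
class ConditionMeans:
    """Per-participant mean time course per condition: data[i, j, k]."""

    data: np.ndarray  # (n_participants, n_conditions, n_timepoints)
    participants: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("condition means must be a 3-d tensor")
        n, c, _ = self.data.shape
        if n != len(self.participants) or c != len(self.conditions):
            raise ValidationError("tensor shape inconsistent with labels")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def c(self) -> int:
        return self.data.shape[1]


@dataclass
class PointwiseStats:
    kind: str  # "paired_t" | "rm_anova_F"
    values: np.ndarray
    df: tuple[int, ...]
    threshold: float


@dataclass
class Cluster:
    start_s: int
    end_s: int  # inclusive
    mass: float
    sign: str  # "+", "-", or "n/a" for F
    p_value: float | None = None
    p_value_corrected: float | None = None

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s,
            "end_s": self.end_s,
            "mass": self.mass,
            "sign": self.sign,
            "p_value": self.p_value,
            "p_value_corrected": self.p_value_corrected,
        }


@dataclass
class NullDistribution:
    max_stats: np.ndarray  # max |cluster mass| per permutation, 0 when none
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.max_stats = np.asarray(self.max_stats, dtype=float)
        if self.max_stats.size != self.n_permutations:
            raise ValidationError("null distribution size mismatch")


@dataclass
class ClusterTestResult:
    grouping: str
    stats: PointwiseStats
    clusters: list[Cluster]
    null: NullDistribution
    condition_means: ConditionMeans = field(repr=False)

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < ALPHA]

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "statistic": self.stats.kind,
            "df": list(self.stats.df),
            "threshold": self.stats.threshold,
            "pointwise": self.stats.values.tolist(),
            "clusters": [c.to_dict() for c in self.clusters],
            "null_max_stats": self.null.max_stats.tolist(),
            "n_permutations": self.null.n_permutations,
            "exhaustive": self.null.exhaustive,
            "conditions": self.condition_means.conditions,
            "condition_mean_curves": self.condition_means.data.mean(axis=0).tolist(),
        }


def condition_means(samples: list[TrialSample], grouping: str) -> ConditionMeans:
    """Average baseline-corrected samples into the (participant, condition,
    time) tensor.  ``grouping`` is ``"valence"`` or ``"emotion"``.

    For the valence grouping, conditions are ordered ``[negative, positive]``
    so that the paired-t difference is positive-minus-negative.
    """
    if grouping not in ("valence", "emotion"):
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    if not samples:
        raise ValidationError("no samples")
    label = lambda s: s.valence if grouping == "valence" else s.emotion  # noqa: E731
    participants = sorted({s.participant for s in samples})
    if grouping == "valence":
        conditions = ["negative", "positive"]
    else:
        seen = {s.emotion for s in samples}
        canonical = ["fear", "sadness", "joy", "love"]
        conditions = [e for e in canonical if e in seen] + sorted(seen - set(canonical))
    if len(participants) < 2:
        raise ValidationError("within-subject test needs at least 2 participants")
    T = samples[0].diff_values.size
    cells: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in samples:
        if s.diff_values.size != T:
            raise ValidationError("samples differ in length")
        cells.setdefault((s.participant, label(s)), []).append(s.diff_values)
    data = np.empty((len(participants), len(conditions), T))
    for i, p in enumerate(participants):
        for j, cond in enumerate(conditions):
            if (p, cond) not in cells:
                raise ValidationError(f"participant {p} has no {cond!r} samples")
            data[i, j] = np.mean(cells[(p, cond)], axis=0)
    return ConditionMeans(data, participants, conditions)


def paired_t_series(m: ConditionMeans) -> PointwiseStats:
    """Pointwise paired t between the two conditions (second minus first).

    Degenerate time points where the paired differences have zero variance
    get t = 0 with a warning.
    """
    if m.c != 2:
        raise ValidationError("paired t requires exactly 2 conditions")
    values = _paired_t_values(m.data[:, 1, :] - m.data[:, 0, :])
    df = m.n - 1
    threshold = float(sstats.t.ppf(1 - ALPHA / 2, df))
    return PointwiseStats("paired_t", values, (df,), threshold)


def _paired_t_values(d: np.ndarray) -> np.ndarray:
    """t per column of an (n, T) matrix of paired differences; 0 where sd = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} time point(s) have zero-variance paired "
            "differences; statistic set to 0",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t[degenerate] = 0.0
    return t


def rm_anova_F_series(m: ConditionMeans) -> PointwiseStats:
    """Pointwise one-way repeated-measures ANOVA F across conditions.

    At each time point the total sum of squares over the n x c cell matrix is
    partitioned into condition, subject, and residual components;
    F = MS_condition / MS_residual with df (c - 1, (n - 1)(c - 1)).
    A zero residual yields +inf with a warning.
    """
    if m.n < 2 or m.c < 2:
        raise ValidationError("repeated-measures ANOVA needs n >= 2 and c >= 2")
    values = _rm_anova_F_values(m.data)
    df = (m.c - 1, (m.n - 1) * (m.c - 1))
    threshold = float(sstats.f.ppf(1 - ALPHA, *df))
    return PointwiseStats("rm_anova_F", values, df, threshold)


def _rm_anova_F_values(x: np.ndarray) -> np.ndarray:
    """F per time point of an (n, c, T) tensor."""
    n, c, _ = x.shape
    grand = x.mean(axis=(0, 1))  # (T,)
    cond_means = x.mean(axis=0)  # (c, T)
    subj_means = x.mean(axis=1)  # (n, T)
    ss_cond = n * ((cond_means - grand) ** 2).sum(axis=0)
    ss_subj = c * ((subj_means - grand) ** 2).sum(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_cond - ss_subj
    ss_err = np.maximum(ss_err, 0.0)  # guard tiny negative round-off
    ms_cond = ss_cond / (c - 1)
    ms_err = ss_err / ((n - 1) * (c - 1))
    degenerate = ms_err <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_cond / ms_err
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} time point(s) have zero residual variance",
            stacklevel=3,
        )
        # ms_cond that is zero up to round-off (identical conditions) gives
        # F = 0; a genuine condition effect with no residual gives +inf
        tiny = 1e-12 * np.maximum(ss_total, np.finfo(float).tiny)
        F[degenerate & (ss_cond > tiny)] = np.inf
        F[degenerate & (ss_cond <= tiny)] = 0.0
    return F


def form_clusters(stats: PointwiseStats) -> list[Cluster]:
    """Group consecutive supra-threshold time points into clusters.

    For t statistics, positive and negative excursions form separate clusters
    (a sign change breaks adjacency); for F only the upper tail exists.
    Cluster mass is the sum of the pointwise statistic over the run.
    """
    clusters: list[Cluster] = []
    v = stats.values
    thr = stats.threshold
    if stats.kind == "paired_t":
        labels = np.where(v > thr, 1, np.where(v < -thr, -1, 0))
    else:
        labels = np.where(v > thr, 1, 0)
    for start, end, lab in _runs(labels):
        mass = float(v[start : end + 1].sum())
        sign = "n/a" if stats.kind != "paired_t" else ("+" if lab > 0 else "-")
        clusters.append(Cluster(start, end, mass, sign))
    return clusters


def _runs(labels: np.ndarray):
    """Maximal runs of equal nonzero label: yields (start, end_inclusive, label)."""
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    edges = np.concatenate(([0], boundaries, [labels.size]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        if labels[lo] != 0:
            yield int(lo), int(hi - 1), int(labels[lo])


def _max_cluster_mass(values: np.ndarray, threshold: float, signed: bool) -> float:
    """Largest absolute cluster mass of one statistic series (0 if no cluster)."""
    if signed:
        labels = np.where(values > threshold, 1, np.where(values < -threshold, -1, 0))
    else:
        labels = np.where(values > threshold, 1, 0)
    best = 0.0
    for start, end, _ in _runs(labels):
        best = max(best, abs(float(values[start : end + 1].sum())))
    return best


def _all_label_patterns(c: int, n: int):
    """Every within-participant relabeling: one permutation of 0..c-1 per participant."""
    perms = list(itertools.permutations(range(c)))
    return itertools.product(perms, repeat=n)


def permutation_null(
    m: ConditionMeans,
    kind: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> NullDistribution:
    """Max-statistic null over within-participant condition relabelings.

    Random mode draws ``n_permutations`` i.i.d. uniform patterns from the
    (c!)^n space, with replacement and with the identity allowed.  Exhaustive
    mode enumerates the whole space (refused above ``EXHAUSTIVE_CAP``
    patterns) and ignores ``n_permutations``.
    """
    if n_permutations < 1 and not exhaustive:
        raise ConfigurationError("n_permutations must be >= 1")
    stat_fn = {"paired_t": paired_t_series, "rm_anova_F": rm_anova_F_series}.get(kind)
    if stat_fn is None:
        raise ConfigurationError(f"unknown statistic kind {kind!r}")
    observed = stat_fn(m)
    thr = observed.threshold
    signed = kind == "paired_t"
    n, c, _ = m.data.shape
    perms = list(itertools.permutations(range(c)))

    if exhaustive:
        space = math.factorial(c) ** n
        if space > EXHAUSTIVE_CAP:
            raise ConfigurationError(
                f"(c!)^n = {space} exceeds the exhaustive cap {EXHAUSTIVE_CAP}"
            )
        patterns = _all_label_patterns(c, n)
        n_draws = space
        choice = None
    else:
        rng = np.random.default_rng(seed)
        # one permutation index per (draw, participant)
        choice = rng.integers(0, len(perms), size=(n_permutations, n))
        n_draws = n_permutations

    max_stats = np.empty(n_draws)

    if signed and c == 2:
        # Fast path: for two conditions a within-participant relabeling is a
        # sign flip of that participant's paired difference; the pointwise
        # sum of squared differences is flip-invariant, so the whole t matrix
        # vectorizes over draws.
        d = m.data[:, 1, :] - m.data[:, 0, :]  # (n, T)
        if choice is None:
            signs = np.array(
                [[1 if p == (0, 1) else -1 for p in pat] for pat in patterns]
            )
        else:
            signs = np.where(choice == perms.index((0, 1)), 1, -1)
        means = signs @ d / n  # (B, T)
        ss = (d * d).sum(axis=0)  # (T,), invariant
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (ss - n * means**2) / (n - 1)
            var = np.maximum(var, 0.0)
            t = means / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        for b in range(n_draws):
            max_stats[b] = _max_cluster_mass(t[b], thr, signed=True)
    else:
        idx = np.arange(n)[:, None]
        if choice is None:
            pattern_iter = patterns
        else:
            pattern_iter = ([perms[j] for j in row] for row in choice)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b, pattern in enumerate(pattern_iter):
                perm_idx = np.array(pattern)  # (n, c)
                permuted = m.data[idx, perm_idx, :]
                values = (
                    _paired_t_values(permuted[:, 1, :] - permuted[:, 0, :])
                    if signed
                    else _rm_anova_F_values(permuted)
                )
                max_stats[b] = _max_cluster_mass(values, thr, signed)

    return NullDistribution(max_stats, n_draws, seed, exhaustive)


def cluster_p_values(observed: list[Cluster], null: NullDistribution) -> list[Cluster]:
    """Attach permutation p-values: the proportion of null max-statistics at
    least as large as |mass|, plus the (b + 1) / (m + 1) corrected version."""
    m_draws = null.n_permutations
    out = []
    for cl in observed:
        b = int(np.count_nonzero(null.max_stats >= abs(cl.mass)))
        out.append(
            Cluster(
                cl.start_s,
                cl.end_s,
                cl.mass,
                cl.sign,
                p_value=b / m_draws,
                p_value_corrected=(b + 1) / (m_draws + 1),
            )
        )
    return out


def cluster_test(
    samples: list[TrialSample],
    grouping: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Full cluster-based permutation test on a set of trial samples.

    Baseline-corrects every sample, averages per participant and condition,
    computes the pointwise statistic (paired t for ``grouping="valence"``,
    repeated-measures F for ``grouping="emotion"``), forms clusters at the
    alpha = 0.05 critical value, and calibrates cluster masses against the
    within-participant permutation null.
    """
    corrected = [baseline_correct(s) for s in samples]
    m = condition_means(corrected, grouping)
    kind = "paired_t" if grouping == "valence" else "rm_anova_F"
    observed = paired_t_series(m) if kind == "paired_t" else rm_anova_F_series(m)
    clusters = form_clusters(observed)
    null = permutation_null(m, kind, n_permutations, seed, exhaustive)
    clusters = cluster_p_values(clusters, null)
    return ClusterTestResult(grouping, observed, clusters, null, m)
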