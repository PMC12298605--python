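"""Leave-one-participant-out (LOPO) emotion classification and chance testing.

Two tasks — valence (positive vs negative, chance 0.5) and discrete emotion
(fear/sadness/joy/love, chance 0.25) — evaluated per recording site with
three classifiers: Gaussian naive Bayes, an RBF-kernel SVM with C = 0.5, and
a three-hidden-layer (300, 300, 300) multilayer perceptron.  Each fold
trains on all participants but one and tests on the held-out participant's
samples; the per-participant accuracies (one per fold) are compared to
chance with a two-tailed one-sample t-test, df = n - 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError, ValidationError
from .features import FeatureVector

CLASSIFIERS = ("gnb", "svm_rbf", "mlp")
TASKS = {"valence": 2, "discrete": 4}


@dataclass
class CVResult:
    """LOPO cross-validation summary for one task/site/classifier."""

    task: str
    site: str
    classifier: str
    per_participant_accuracy: dict[str, float]
    mean: float
    sd: float
    chance: float
    t_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "site": self.site,
            "classifier": self.classifier,
            "per_participant_accuracy": self.per_participant_accuracy,
            "mean": self.mean,
            "sd": self.sd,
            "chance": self.chance,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def _labels(vectors: list[FeatureVector], task: str) -> list[str]:
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}")
    return [v.valence if task == "valence" else v.emotion for v in vectors]


def lopo_folds(
    vectors: list[FeatureVector],
) -> list[tuple[str, list[FeatureVector], list[FeatureVector]]]:
    """One fold per participant: (held-out participant, train set, test set)."""
    seen = set()
    for v in vectors:
        key = (v.participant, v.experiment, v.site, v.trial_id)
        if key in seen:
            raise ValidationError(f"duplicate sample id {key}")
        seen.add(key)
    participants = sorted({v.participant for v in vectors})
    if len(participants) < 2:
        raise ValidationError("LOPO needs at least 2 participants")
    folds = []
    for p in participants:
        train = [v for v in vectors if v.participant != p]
        test = [v for v in vectors if v.participant == p]
        folds.append((p, train, test))
    return folds


def make_classifier(kind: str, seed: int):
    """The three reference classifiers with pinned hyperparameters."""
    if kind == "gnb":
        return GaussianNB(var_smoothing=1e-9)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", C=0.5, gamma="scale")
    if kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(300, 300, 300),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            alpha=1e-4,
            max_iter=200,
            random_state=seed,
        )
    raise ConfigurationError(f"unknown classifier {kind!r}")


def train_eval(
    kind: str,
    train: list[FeatureVector],
    test: list[FeatureVector],
    task: str,
    seed: int = 0,
) -> float:
    """Fit one classifier on the train split, return test accuracy."""
    y_train = _labels(train, task)
    y_test = _labels(test, task)
    required = set(y_train) | set(y_test)
    missing = required - set(y_train)
    if missing:
        raise ValidationError(f"training set is missing class(es) {sorted(missing)}")
    X_train = np.stack([v.values for v in train])
    X_test = np.stack([v.values for v in test])
    clf = make_classifier(kind, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter at the iteration cap
        clf.fit(X_train, y_train)
    return float(np.mean(clf.predict(X_test) == np.array(y_test)))


def chance_t_test(accuracies: np.ndarray, chance: float) -> tuple[float, float]:
    """Two-tailed one-sample t of per-participant accuracies against chance."""
    n = accuracies.size
    sd = accuracies.std(ddof=1)
    if sd == 0:
        if accuracies.mean() == chance:
            return 0.0, 1.0
        return math.copysign(math.inf, accuracies.mean() - chance), 0.0
    t = (accuracies.mean() - chance) / (sd / math.sqrt(n))
    p = 2 * sstats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def run_task(
    vectors: list[FeatureVector],
    task: str,
    site: str | None = None,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    seed: int = 0,
) -> list[CVResult]:
    """LOPO evaluation of each classifier on one task (optionally one site)."""
    if site is not None:
        vectors = [v for v in vectors if v.site == site]
    if not vectors:
        raise ValidationError("no feature vectors for the requested site")
    sites = {v.site for v in vectors}
    if len(sites) > 1:
        raise ValidationError(f"mixed sites {sorted(sites)}; pass site= to select one")
    site_name = vectors[0].site
    chance = 1.0 / TASKS[task]
    folds = lopo_folds(vectors)
    results = []
    for kind in classifiers:
        accs = {}
        for participant, train, test in folds:
            accs[participant] = train_eval(kind, train, test, task, seed)
        arr = np.array(list(accs.values()))
        t, p = chance_t_test(arr, chance)
        results.append(
            CVResult(
                task,
                site_name,
                kind,
                accs,
                float(arr.mean()),
                float(arr.std(ddof=1)),
                chance,
                t,
                p,
            )
        )
    return results
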