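"""Ensemble gradient-boosted classifier with posterior draws and metrics.

The classifier follows the statsmodels convention: :class:`EnsembleClassifier`
is a model built from data whose :meth:`~EnsembleClassifier.fit` returns an
:class:`EnsembleResults` object carrying the fitted members, diagnostics and
a ``summary()`` table. The boosting engine itself (stagewise additive update
F_m = F_{m-1} + eta * f_m under binary log loss) is delegated to LightGBM;
this module owns everything around it: the independently seeded ensemble,
the posterior-draw composition, per-sample log-loss diagnostics, evaluation
metrics with split percentile bands, and accuracy-maximizing threshold
calibration for external continuous scorers.

Posterior draws approximate the distribution over plausible models: by
default each of the 10 members contributes snapshot predictions at 10 evenly
spaced boosting stages, giving the 100 probability columns per molecule the
acquisition layer consumes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from lipal.chemio import CountFingerprint

LOGLOSS_CLIP = 1e-15
_SERIAL_FORMAT = "lipal-ensemble-v1"

# the LightGBM sklearn wrapper records synthetic column names at fit time;
# predicting from plain arrays then emits a spurious feature-name warning
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble and boosting-engine settings.

    ``n_members`` independently seeded members approximate model uncertainty;
    ``n_draws`` posterior probability columns are composed from staged
    snapshots of the members. ``learning_rate`` is the shrinkage eta of the
    stagewise boosting update; ``n_iterations`` and ``tree_depth`` bound the
    additive expansion. ``member_seeds`` defaults to ``base_seed + 0..n-1``.
    """

    n_members: int = 10
    n_draws: int = 100
    learning_rate: float = 0.1
    n_iterations: int = 100
    tree_depth: int = 6
    member_seeds: tuple[int, ...] | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.n_draws < self.n_members:
            raise ValueError("n_draws must be >= n_members")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        seeds = self.resolved_seeds()
        if len(set(seeds)) != len(seeds):
            raise ValueError("member_seeds must be distinct")

    def resolved_seeds(self) -> tuple[int, ...]:
        if self.member_seeds is not None:
            seeds = tuple(int(s) for s in self.member_seeds)
            if len(seeds) != self.n_members:
                raise ValueError("member_seeds length must equal n_members")
            return seeds
        return tuple(self.base_seed + i for i in range(self.n_members))


@dataclass(frozen=True)
class PosteriorSamples:
    """Class-1 probabilities, candidates x posterior draws."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2:
            raise ValueError("probs must be a 2-D matrix (candidates x draws)")
        if probs.size and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_candidates(self) -> int:
        return self.probs.shape[0]

    @property
    def n_draws(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class MetricsReport:
    """Binary-classifier metrics; AUROC/AUPRC absent for single-class labels.

    ``band`` optionally maps each metric name to its (20th, 80th) percentile
    interval over independent train/test splits; ``per_split`` then holds
    the raw per-split values.
    """

    accuracy: float
    f1: float
    auroc: float | None = None
    auprc: float | None = None
    band: dict[str, tuple[float, float]] | None = None
    per_split: pd.DataFrame | None = field(default=None, compare=False, repr=False)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64)
    if len(features) and isinstance(features[0], CountFingerprint):
        return np.vstack([fp.counts for fp in features]).astype(np.float64)
    return np.asarray(features, dtype=np.float64)


def _lgbm_params(config: EnsembleConfig) -> dict:
    # min_child_samples/max_bin are sized for the tens-to-hundreds-sample
    # regime of labeling campaigns; subsample/colsample give the seeded
    # members genuinely different boosting paths.
    return dict(
        objective="binary",
        n_estimators=config.n_iterations,
        learning_rate=config.learning_rate,
        max_depth=config.tree_depth,
        num_leaves=31,
        min_child_samples=2,
        max_bin=15,
        subsample=0.8,
        subsample_freq=1,
        colsample_bytree=0.8,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_col_wise=True,
    )


class EnsembleClassifier:
    """Synthesizability classifier: an ensemble of seeded boosted-tree models.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Binary synthesizability labels.
    exog : array-like, CountFingerprint sequence, or (n, p) matrix
        Molecular features.
    config : EnsembleConfig, optional

    Examples
    --------
    >>> results = EnsembleClassifier(y, X).fit()
    >>> results.predict_proba(X_new)
    """

    def __init__(self, endog, exog, config: EnsembleConfig | None = None):
        self.endog = np.asarray(endog, dtype=np.int64)
        self.exog = _as_matrix(exog)
        self.config = config or EnsembleConfig()
        if self.exog.ndim != 2:
            raise ValueError("exog must be a 2-D feature matrix")
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError(
                f"label count {self.endog.shape[0]} != sample count {self.exog.shape[0]}"
            )
        if self.endog.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        classes = np.unique(self.endog)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be binary {0, 1}")
        if classes.size < 2:
            raise ValueError("both classes must be present in the training labels")

    @classmethod
    def from_fingerprints(
        cls,
        fingerprints: Sequence[CountFingerprint],
        labels,
        config: EnsembleConfig | None = None,
    ) -> "EnsembleClassifier":
        return cls(labels, fingerprints, config=config)

    def fit(self) -> "EnsembleResults":
        X, y = self.exog, self.endog
        # Constant columns cannot host a split; dropping them is
        # model-invariant and much faster on sparse fingerprint pools.
        mask = (X.max(axis=0) - X.min(axis=0)) > 0
        if not mask.any():
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[0] = True
        Xr = X[:, mask]
        params = _lgbm_params(self.config)
        members = []
        for seed in self.config.resolved_seeds():
            m = LGBMClassifier(random_state=int(seed) % (2**31 - 1), **params)
            m.fit(Xr, y)
            members.append(m)
        return EnsembleResults(model=self, members=members, feature_mask=mask)


class EnsembleResults:
    """Fitted ensemble: members, posterior draws, diagnostics, summary."""

    def __init__(self, model: EnsembleClassifier, members: list, feature_mask: np.ndarray):
        self.model = model
        self.config = model.config
        self.members = members
        self.feature_mask = np.asarray(feature_mask, dtype=bool)
        self.n_features_in = self.feature_mask.shape[0]

    # -- prediction -----------------------------------------------------

    def _reduce(self, features) -> np.ndarray:
        X = _as_matrix(features)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise ValueError(f"expected {self.n_features_in} feature columns")
        return X[:, self.feature_mask]

    def member_proba(self, features) -> np.ndarray:
        """Per-member class-1 probabilities, shape (n, n_members)."""
        Xr = self._reduce(features)
        return np.column_stack([m.predict_proba(Xr)[:, 1] for m in self.members])

    def predict_proba(self, features) -> np.ndarray:
        """Ensemble-mean class-1 probability per sample."""
        return self.member_proba(features).mean(axis=1)

    def predict(self, features, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(features) >= threshold).astype(np.int64)

    def posterior_draws(self, features, n_draws: int | None = None) -> PosteriorSamples:
        """Posterior probability draws via staged member snapshots.

        Draws are split as evenly as possible over members; a member owing
        d draws predicts at d evenly spaced boosting stages ending at the
        full expansion. Deterministic given the fitted handle.
        """
        n_draws = self.config.n_draws if n_draws is None else int(n_draws)
        n_members = len(self.members)
        if n_draws < n_members:
            raise ValueError("n_draws must be >= n_members")
        Xr = self._reduce(features)
        per_member = [n_draws // n_members] * n_members
        for i in range(n_draws - sum(per_member)):
            per_member[i] += 1
        total_iter = self.config.n_iterations
        cols = []
        for m, d in zip(self.members, per_member):
            stages = np.unique(
                np.maximum(1, np.round(total_iter * np.arange(1, d + 1) / d)).astype(int)
            )
            for stage in stages:
                cols.append(m.predict_proba(Xr, num_iteration=int(stage))[:, 1])
            # rounding collisions: repeat the final snapshot to keep d columns
            for _ in range(d - len(stages)):
                cols.append(cols[-1])
        return PosteriorSamples(probs=np.column_stack(cols))

    # -- diagnostics ----------------------------------------------------

    def train_logloss(self) -> np.ndarray:
        return per_sample_logloss(self.predict_proba(self.model.exog), self.model.endog)

    def summary(self) -> str:
        y = self.model.endog
        probs = self.predict_proba(self.model.exog)
        acc = float(np.mean((probs >= 0.5) == y))
        ll = float(np.mean(per_sample_logloss(probs, y)))
        cfg = self.config
        lines = [
            "Ensemble synthesizability classifier",
            "=" * 52,
            f"{'No. samples:':<28}{y.shape[0]}",
            f"{'Positive / negative:':<28}{int(y.sum())} / {int((1 - y).sum())}",
            f"{'Members:':<28}{cfg.n_members}",
            f"{'Member seeds:':<28}{list(cfg.resolved_seeds())}",
            f"{'Boosting iterations:':<28}{cfg.n_iterations}",
            f"{'Learning rate (eta):':<28}{cfg.learning_rate}",
            f"{'Tree depth:':<28}{cfg.tree_depth}",
            f"{'Active feature columns:':<28}{int(self.feature_mask.sum())} of {self.n_features_in}",
            f"{'Posterior draws:':<28}{cfg.n_draws}",
            "-" * 52,
            f"{'Training accuracy:':<28}{acc:.4f}",
            f"{'Training mean log loss:':<28}{ll:.4f}",
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": _SERIAL_FORMAT,
            "config": dataclasses.asdict(self.config),
            "feature_mask": self.feature_mask,
            "members": self.members,
            "endog": self.model.endog,
            "exog": self.model.exog,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleResults":
        payload = joblib.load(path)
        if payload.get("format") != _SERIAL_FORMAT:
            raise ValueError(f"unrecognized model file format: {payload.get('format')!r}")
        cfg_dict = payload["config"]
        if cfg_dict.get("member_seeds") is not None:
            cfg_dict["member_seeds"] = tuple(cfg_dict["member_seeds"])
        config = EnsembleConfig(**cfg_dict)
        model = EnsembleClassifier(payload["endog"], payload["exog"], config=config)
        return cls(model=model, members=payload["members"], feature_mask=payload["feature_mask"])


def fit_ensemble(features, labels, config: EnsembleConfig | None = None) -> EnsembleResults:
    """Fit the seeded ensemble; functional entry point over the model class."""
    return EnsembleClassifier(labels, features, config=config).fit()


def posterior_draws(results: EnsembleResults, features, n_draws: int | None = None) -> PosteriorSamples:
    return results.posterior_draws(features, n_draws=n_draws)


def per_sample_logloss(mean_probs, labels) -> np.ndarray:
    """Elementwise binary log loss -[y ln p + (1-y) ln(1-p)], clipped."""
    p = np.clip(np.asarray(mean_probs, dtype=np.float64), LOGLOSS_CLIP, 1 - LOGLOSS_CLIP)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("mean_probs and labels must have equal length")
    return -(y * np.log(p) + (1 - y) * np.log(1 - p))


def rank_logloss(mean_probs, labels) -> np.ndarray:
    """Indices sorted by descending per-sample log loss (outlier inspection)."""
    losses = per_sample_logloss(mean_probs, labels)
    return np.argsort(-losses, kind="stable")


def evaluate_metrics(probs, labels, threshold: float = 0.5) -> MetricsReport:
    """Accuracy/F1 at a probability threshold plus ranking metrics.

    AUROC is the concordance probability with ties counted 1/2; AUPRC is
    the area under the precision-recall step curve. Both are reported
    absent when the labels contain a single class.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    pred = (p >= threshold).astype(np.int64)
    accuracy = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, zero_division=0))
    if np.unique(y).size < 2:
        return MetricsReport(accuracy=accuracy, f1=f1, auroc=None, auprc=None)
    return MetricsReport(
        accuracy=accuracy,
        f1=f1,
        auroc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
    )


_METRIC_NAMES = ("accuracy", "auprc", "auroc", "f1")


def split_metrics(
    features,
    labels,
    config: EnsembleConfig | None = None,
    n_splits: int = 10,
    test_size: float = 0.3,
    split_seeds: Sequence[int] | None = None,
) -> MetricsReport:
    """Median metrics with (20th, 80th) percentile bands over train/test splits.

    Each split is a stratified random train/test partition; the ensemble is
    refitted per split. The returned report holds per-metric medians, the
    percentile band, and the raw per-split table in ``per_split``.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_splits:
        raise ValueError(
            f"need at least n_splits={n_splits} samples per class, got {counts.tolist()}"
        )
    if split_seeds is None:
        split_seeds = list(range(n_splits))
    if len(split_seeds) != n_splits:
        raise ValueError("split_seeds length must equal n_splits")
    config = config or EnsembleConfig()

    rows = []
    for seed in split_seeds:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_size, random_state=int(seed))
        (train_idx, test_idx), = splitter.split(X, y)
        results = EnsembleClassifier(y[train_idx], X[train_idx], config=config).fit()
        rep = evaluate_metrics(results.predict_proba(X[test_idx]), y[test_idx])
        rows.append({m: getattr(rep, m) for m in _METRIC_NAMES})
    table = pd.DataFrame(rows)

    band = {
        m: (float(np.percentile(table[m], 20)), float(np.percentile(table[m], 80)))
        for m in _METRIC_NAMES
    }
    medians = {m: float(np.median(table[m])) for m in _METRIC_NAMES}
    return MetricsReport(
        accuracy=medians["accuracy"],
        f1=medians["f1"],
        auroc=medians["auroc"],
        auprc=medians["auprc"],
        band=band,
        per_split=table,
    )


def threshold_from_train(scores, labels) -> float:
    """Accuracy-maximizing decision threshold for a continuous scorer.

    Candidates are the midpoints between adjacent distinct sorted scores
    plus sentinels below the minimum and above the maximum; predict-positive
    is ``score >= threshold``. Returns the smallest maximizing candidate.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if s.size == 0:
        raise ValueError("need at least one sample")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best_t, best_acc = None, -1.0
    for t in candidates:  # ascending; strict > keeps the smallest maximizer
        acc = float(np.mean((s >= t) == y))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t
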