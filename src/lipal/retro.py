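"""Retrospective label-efficiency experiments on a fully labeled dataset.

Active learning is simulated by withholding labels: each replica starts
from a small random initial set, iterates batch selection / label reveal /
refit, and records the labeled-set size at which test accuracy first
reaches a target. Two arms are compared — joint-entropy acquisition ("al")
and uniform random sampling ("random") — by default with paired initial
sets per replica so the only difference between arms is the selection rule.
Convergence-size distributions are binned with tail widening (final two
bins each hold at least five replicas) and compared with a Pearson
chi-squared contingency test without continuity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from lipal.acquisition import build_entropy_matrix, select_batch
from lipal.model import EnsembleConfig, EnsembleClassifier

STRATEGY_AL = "al"
STRATEGY_RANDOM = "random"


@dataclass(frozen=True)
class RetroConfig:
    """Replica-experiment protocol settings.

    Defaults mirror a small labeling campaign: 25-molecule initial sets
    drawn from a 215-sample training partition (190-molecule pool), batches
    of 10, a fixed 42-sample stratified test set, a 0.83 accuracy target,
    and 200 replicas.
    """

    n_replicas: int = 200
    init_size: int = 25
    pool_size: int = 190
    batch_size: int = 10
    test_size: int = 42
    target_accuracy: float = 0.83
    strategies: tuple[str, ...] = (STRATEGY_AL, STRATEGY_RANDOM)
    master_seed: int = 0
    paired: bool = True
    selection_method: str = "greedy"
    ensemble_config: EnsembleConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        if self.target_accuracy < 0:
            raise ValueError("target_accuracy must be non-negative")
        if self.init_size < 1 or self.batch_size < 1:
            raise ValueError("init_size and batch_size must be >= 1")
        for s in self.strategies:
            if s not in (STRATEGY_AL, STRATEGY_RANDOM):
                raise ValueError(f"unknown strategy {s!r}")


@dataclass(frozen=True)
class ReplicaResult:
    replica: int
    convergence_size: int
    censored: bool


@dataclass
class ConvergenceDistribution:
    """Per-strategy convergence sizes over replicas, with the protocol echo."""

    results: dict[str, list[ReplicaResult]]
    config: RetroConfig
    initial_sets: dict[str, list[list[int]]] = field(default_factory=dict)

    def sizes(self, strategy: str, include_censored: bool = False) -> np.ndarray:
        rs = self.results[strategy]
        return np.array(
            [r.convergence_size for r in rs if include_censored or not r.censored],
            dtype=np.int64,
        )

    def n_censored(self, strategy: str) -> int:
        return sum(r.censored for r in self.results[strategy])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def run_experiment(X, y, config: RetroConfig) -> ConvergenceDistribution:
    """Run the replica protocol for every strategy.

    Per replica: draw the initial labeled set from the training partition
    (replica-specific seed, shared across arms when ``paired``), fit the
    ensemble, check test accuracy, then repeat select-batch / reveal-labels
    / refit until the target accuracy is reached or the pool is exhausted
    (censored). Accuracy uses the ensemble-mean probability at the fixed
    0.5 threshold on the frozen stratified test set.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n = y.shape[0]
    train_needed = config.init_size + config.pool_size
    if config.test_size + train_needed > n:
        raise ValueError(
            f"init_size + pool_size + test_size = {train_needed + config.test_size} "
            f"exceeds the dataset size {n}"
        )
    ens_cfg = config.ensemble_config or EnsembleConfig()

    root = np.random.SeedSequence(config.master_seed)
    test_ss, replica_root = root.spawn(2)
    train_idx, test_idx = train_test_split(
        np.arange(n),
        test_size=config.test_size,
        random_state=_seed_int(test_ss),
        stratify=y,
    )
    X_test, y_test = X[test_idx], y[test_idx]

    replica_seeds = replica_root.spawn(config.n_replicas)
    results: dict[str, list[ReplicaResult]] = {s: [] for s in config.strategies}
    initial_sets: dict[str, list[list[int]]] = {s: [] for s in config.strategies}

    for rep in range(config.n_replicas):
        # pre-spawn so paired arms observe identical seed material
        children = replica_seeds[rep].spawn(2 + 2 * len(config.strategies))
        for si, strategy in enumerate(config.strategies):
            if config.paired:
                init_ss, run_ss = children[0], children[1]
            else:
                init_ss, run_ss = children[2 + 2 * si], children[3 + 2 * si]
            rng = np.random.default_rng(init_ss)
            perm = rng.permutation(train_idx)
            labeled = list(perm[: config.init_size])
            pool = list(perm[config.init_size : config.init_size + config.pool_size])
            initial_sets[strategy].append(sorted(int(i) for i in labeled))

            run_rng = np.random.default_rng(run_ss)
            base_seed = _seed_int(run_ss)
            size, censored = _run_single(
                X, y, X_test, y_test, labeled, pool, strategy, config, ens_cfg,
                base_seed, run_rng,
            )
            results[strategy].append(
                ReplicaResult(replica=rep, convergence_size=size, censored=censored)
            )
    return ConvergenceDistribution(results=results, config=config, initial_sets=initial_sets)


def _run_single(
    X, y, X_test, y_test, labeled, pool, strategy, config, ens_cfg, base_seed, rng
) -> tuple[int, bool]:
    cfg = EnsembleConfig(
        n_members=ens_cfg.n_members,
        n_draws=ens_cfg.n_draws,
        learning_rate=ens_cfg.learning_rate,
        n_iterations=ens_cfg.n_iterations,
        tree_depth=ens_cfg.tree_depth,
        base_seed=base_seed,
    )

    def _refit():
        y_l = y[labeled]
        if np.unique(y_l).size < 2:
            return None, None  # single-class seed set cannot be fitted; keep labeling
        fitted = EnsembleClassifier(y_l, X[labeled], config=cfg).fit()
        acc = float(np.mean((fitted.predict_proba(X_test) >= 0.5) == y_test))
        return acc, fitted

    acc, fitted = _refit()
    if acc is not None and acc >= config.target_accuracy:
        return len(labeled), False

    while pool:
        k = min(config.batch_size, len(pool))
        if strategy == STRATEGY_RANDOM or fitted is None:
            pick = rng.choice(len(pool), size=k, replace=False)
        else:
            samples = fitted.posterior_draws(X[pool])
            matrix = build_entropy_matrix(samples)
            batch = select_batch(matrix, batch_size=k, method=config.selection_method)
            pick = np.asarray(batch.indices)
        picked = [pool[i] for i in sorted(pick, reverse=True)]
        for i in sorted(pick, reverse=True):
            del pool[i]
        labeled.extend(picked)
        acc, fitted = _refit()
        if acc is not None and acc >= config.target_accuracy:
            return len(labeled), False
    return len(labeled), True


# ---------------------------------------------------------------------------
# histograms and comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Histogram:
    counts: np.ndarray
    edges: np.ndarray  # len(counts) + 1; last bin right-inclusive

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.float64))


def bin_convergence(
    sizes: Sequence[int],
    bin_width: int,
    min_tail_count: int = 5,
    start: int | None = None,
) -> Histogram:
    """Fixed-width bins with right-to-left tail widening.

    Bins of ``bin_width`` run from ``start`` (default: the smallest size)
    upward; the last two bins are then repeatedly merged rightmost-first
    until each of the final two holds at least ``min_tail_count``
    observations, keeping statistical tests on the tail well-posed.
    """
    sizes = np.asarray(list(sizes), dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("sizes must be non-empty")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if sizes.size < 2 * min_tail_count:
        raise ValueError(
            f"cannot place {min_tail_count} observations in each of the final "
            f"two bins with only {sizes.size} observations"
        )
    lo = int(sizes.min()) if start is None else int(start)
    if sizes.min() < lo:
        raise ValueError("start must not exceed the smallest size")
    n_bins = max(2, int(np.ceil((sizes.max() - lo + 1) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1, dtype=np.float64)
    counts, _ = np.histogram(sizes, bins=edges)

    counts = list(counts)
    edges = list(edges)
    while len(counts) >= 3 and (counts[-1] < min_tail_count or counts[-2] < min_tail_count):
        counts[-2] += counts[-1]
        del counts[-1], edges[-2]  # widen the final bin leftward
    if len(counts) < 2 or counts[-1] < min_tail_count or counts[-2] < min_tail_count:
        raise ValueError("tail rule unsatisfiable for these sizes")
    return Histogram(counts=np.array(counts), edges=np.array(edges))


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    dof: int
    p_value: float


def compare_distributions(hist_a: Histogram, hist_b: Histogram) -> Chi2Result:
    """Pearson chi-squared on the 2xK contingency table of bin counts.

    No continuity correction, any K; requires identical bin edges and
    strictly positive expected counts.
    """
    if hist_a.edges.shape != hist_b.edges.shape or not np.allclose(hist_a.edges, hist_b.edges):
        raise ValueError("histograms must share identical bin edges")
    table = np.vstack([hist_a.counts, hist_b.counts])
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a bin is empty in both histograms; re-bin before testing")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(stat), dof=int(dof), p_value=float(p))


def summarize_convergence(dist: ConvergenceDistribution) -> dict[str, dict]:
    """Per-strategy mean/median convergence size over non-censored replicas."""
    out: dict[str, dict] = {}
    for strategy in dist.results:
        sizes = dist.sizes(strategy)
        n_cens = dist.n_censored(strategy)
        if sizes.size == 0:
            out[strategy] = {"mean": None, "median": None, "n_censored": n_cens, "n": 0}
        else:
            out[strategy] = {
                "mean": float(np.mean(sizes)),
                "median": float(np.median(sizes)),
                "n_censored": n_cens,
                "n": int(sizes.size),
            }
    return out


def experiment_report(
    dist: ConvergenceDistribution, min_tail_count: int = 5
) -> dict:
    """Summary plus (when both arms ran) the binned chi-squared comparison."""
    report: dict = {"summary": summarize_convergence(dist)}
    if {STRATEGY_AL, STRATEGY_RANDOM} <= set(dist.results):
        al = dist.sizes(STRATEGY_AL, include_censored=True)
        rnd = dist.sizes(STRATEGY_RANDOM, include_censored=True)
        lo = int(min(al.min(), rnd.min()))
        hi = int(max(al.max(), rnd.max()))
        width = dist.config.batch_size
        # shared edges: bin both samples over the common range, then apply
        # the tail rule to the pooled counts so edges stay identical
        edges = lo + width * np.arange(int(np.ceil((hi - lo + 1) / width)) + 1)
        ca, _ = np.histogram(al, bins=edges)
        cb, _ = np.histogram(rnd, bins=edges)
        counts_a, counts_b, e = (
            [int(c) for c in ca],
            [int(c) for c in cb],
            [float(x) for x in edges],
        )
        while len(counts_a) >= 3 and (
            min(counts_a[-1], counts_b[-1]) < min_tail_count
            or min(counts_a[-2], counts_b[-2]) < min_tail_count
        ):
            counts_a[-2] += counts_a[-1]
            counts_b[-2] += counts_b[-1]
            del counts_a[-1], counts_b[-1], e[-2]
        ha = Histogram(counts=np.array(counts_a), edges=np.array(e))
        hb = Histogram(counts=np.array(counts_b), edges=np.array(e))
        try:
            chi2 = compare_distributions(ha, hb)
            report["chi2"] = asdict(chi2)
        except ValueError:
            report["chi2"] = None
        report["bin_edges"] = e
        report["counts"] = {STRATEGY_AL: counts_a, STRATEGY_RANDOM: counts_b}
    return report


def write_results_csv(dist: ConvergenceDistribution, path: str | Path) -> None:
    rows = [
        {
            "strategy": strategy,
            "replica": r.replica,
            "convergence_size": r.convergence_size,
            "censored": int(r.censored),
        }
        for strategy, rs in dist.results.items()
        for r in rs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report_json(dist: ConvergenceDistribution, path: str | Path) -> dict:
    report = experiment_report(dist)
    Path(path).write_text(json.dumps(report, indent=2))
    return report


def plot_convergence(dist: ConvergenceDistribution, path: str | Path) -> None:
    """Side-by-side convergence-size histograms per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    width = dist.config.batch_size
    for strategy, shift in zip(dist.results, (0.0, 0.35)):
        sizes = dist.sizes(strategy, include_censored=True)
        bins = np.arange(sizes.min(), sizes.max() + 2 * width, width)
        counts, edges = np.histogram(sizes, bins=bins)
        ax.bar(
            edges[:-1] + shift * width,
            counts,
            width=0.35 * width,
            label=strategy,
            align="edge",
        )
    ax.set_xlabel("labeled-set size at first target attainment")
    ax.set_ylabel("replicas")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
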