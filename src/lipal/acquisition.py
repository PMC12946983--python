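"""Joint-entropy batch acquisition from ensemble posterior draws.

A batch of candidates is scored by the information its labels would carry
jointly. True batch joint entropy over N binary predictions needs 2^N joint
probabilities — far more than a hundred posterior draws can estimate — so
higher-order dependence is smoothed away: assuming the dual total
correlations vanish for N >= 3, the joint entropy reduces to

    H(X_1, ..., X_N)  ~=  1/(N-1) * sum_{i<j} H(X_i, X_j),

and the batch with maximal approximate joint entropy is the one maximizing
the pair-sum acquisition a(B) = sum_{i<j in B} H(X_i, X_j). Pairwise joint
entropies are estimated from the posterior draws as mixtures of per-draw
product Bernoullis: the two predictions are conditionally independent given
a draw, and the mixture over draws carries the model-uncertainty coupling.

Entropies are in bits; the base only rescales the acquisition and never
changes the argmax.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from lipal.model import PosteriorSamples

_P_FLOOR = 1e-12  # joint probabilities below this are treated as exact zeros


@dataclass(frozen=True)
class EntropyMatrix:
    """Symmetric pairwise joint-entropy table, marginal entropies on the diagonal.

    Off-diagonal ``H[i, j]`` is the pairwise joint entropy H(X_i, X_j) in
    bits; diagonal ``H[i, i]`` is the marginal entropy H(X_i). All entries
    lie in [0, 2] and max(H_ii, H_jj) <= H_ij <= H_ii + H_jj.
    """

    H: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=np.float64)
        object.__setattr__(self, "H", H)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("entropy matrix must be square")

    @property
    def n(self) -> int:
        return self.H.shape[0]


@dataclass(frozen=True)
class Batch:
    """A set of candidate indices with its acquisition value (if computed)."""

    indices: tuple[int, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(set(idx)) != len(idx):
            raise ValueError("batch indices must be distinct")
        object.__setattr__(self, "indices", idx)

    @property
    def size(self) -> int:
        return len(self.indices)


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    """-sum p log2 p over the last axis, with 0 log 0 = 0."""
    p = np.where(p < _P_FLOOR, 0.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def marginal_entropy(draws: np.ndarray) -> float:
    """Entropy in bits of the mean-Bernoulli mixture marginal of one candidate."""
    pbar = float(np.mean(draws))
    return float(_entropy_bits(np.array([pbar, 1.0 - pbar])))


def pairwise_entropy(draws_i, draws_j) -> tuple[np.ndarray, float]:
    """Joint 2x2 table and joint entropy (bits) for two candidates.

    The joint law is the mixture over draws of product Bernoullis:
    p(a, b) = (1/T) sum_t p_i^t(a) p_j^t(b). The table rows index X_i
    (0 then 1), columns index X_j, and it sums to 1.
    """
    pi = np.asarray(draws_i, dtype=np.float64)
    pj = np.asarray(draws_j, dtype=np.float64)
    if pi.shape != pj.shape or pi.ndim != 1:
        raise ValueError("draw vectors must be 1-D with equal length")
    if pi.size < 1:
        raise ValueError("need at least one draw")
    p11 = float(np.mean(pi * pj))
    p10 = float(np.mean(pi * (1 - pj)))
    p01 = float(np.mean((1 - pi) * pj))
    p00 = float(np.mean((1 - pi) * (1 - pj)))
    table = np.array([[p00, p01], [p10, p11]])
    return table, float(_entropy_bits(table.ravel()))


def build_entropy_matrix(
    samples: PosteriorSamples, candidates: Sequence[int] | None = None
) -> EntropyMatrix:
    """All pairwise joint entropies over the chosen candidates, vectorized.

    The diagonal carries the marginal entropy of each candidate's mean
    Bernoulli mixture; off-diagonal entries come from the same mixture
    joint as :func:`pairwise_entropy`.
    """
    P = samples.probs
    if candidates is not None:
        idx = np.asarray(list(candidates), dtype=np.int64)
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate candidate indices")
        P = P[idx]
    n, T = P.shape
    pbar = P.mean(axis=1)
    p11 = (P @ P.T) / T
    p10 = pbar[:, None] - p11
    p01 = pbar[None, :] - p11
    p00 = 1.0 - pbar[:, None] - pbar[None, :] + p11
    stacked = np.clip(np.stack([p00, p01, p10, p11], axis=-1), 0.0, 1.0)
    H = _entropy_bits(stacked)
    H = (H + H.T) / 2.0  # symmetrize away float asymmetry
    np.fill_diagonal(H, _entropy_bits(np.stack([pbar, 1.0 - pbar], axis=-1)))
    return EntropyMatrix(H=H)


def _check_batch(matrix: EntropyMatrix, batch: Batch) -> np.ndarray:
    idx = np.asarray(batch.indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= matrix.n):
        raise ValueError("batch indices outside the candidate universe")
    return idx


def _pair_sum(H: np.ndarray, idx: np.ndarray) -> float:
    sub = H[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / 2.0)


def approx_joint_entropy(matrix: EntropyMatrix, batch: Batch) -> float:
    """Batch joint entropy in bits under the vanishing-dual-total-correlation
    approximation: (1/(N-1)) * sum_{i<j} H(X_i, X_j). Exact at N=2 and for
    mutually independent candidates; an overestimate under higher-order
    redundancy."""
    idx = _check_batch(matrix, batch)
    if idx.size < 2:
        raise ValueError("approximate joint entropy needs a batch of size >= 2")
    return _pair_sum(matrix.H, idx) / (idx.size - 1)


def acquisition(matrix: EntropyMatrix, batch: Batch) -> float:
    """Pair-sum acquisition sum_{i<j} H(X_i, X_j); empty sum (N=1) is 0."""
    idx = _check_batch(matrix, batch)
    if idx.size < 1:
        raise ValueError("batch must contain at least one candidate")
    return _pair_sum(matrix.H, idx)


EXHAUSTIVE_BUDGET = 100_000


def select_batch(
    matrix: EntropyMatrix,
    batch_size: int,
    method: str = "greedy",
    seed: int | None = None,
) -> Batch:
    """Select a batch maximizing (or sampling under) the acquisition.

    ``exhaustive`` enumerates all C(n, batch_size) batches (refused above
    100,000 combinations); ``greedy`` seeds with the maximal pairwise entry,
    grows by best acquisition gain, then makes one single-swap improvement
    pass; ``random`` draws uniformly without replacement under ``seed``.
    Ties always break toward the lowest index.
    """
    n = matrix.n
    if not 1 <= batch_size <= n:
        raise ValueError(f"batch_size must be in [1, {n}], got {batch_size}")
    H = matrix.H
    if batch_size == n:
        idx = tuple(range(n))
        return Batch(indices=idx, score=_pair_sum(H, np.arange(n)))

    if method == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=batch_size, replace=False))
        return Batch(indices=tuple(int(i) for i in idx), score=_pair_sum(H, idx))

    if method == "exhaustive":
        n_comb = math.comb(n, batch_size)
        if n_comb > EXHAUSTIVE_BUDGET:
            raise ValueError(
                f"exhaustive search over {n_comb} combinations exceeds the "
                f"{EXHAUSTIVE_BUDGET} budget; use method='greedy'"
            )
        best_idx, best_val = None, -np.inf
        for combo in itertools.combinations(range(n), batch_size):
            val = _pair_sum(H, np.asarray(combo))
            if val > best_val:  # lexicographic enumeration => lowest-index ties win
                best_idx, best_val = combo, val
        return Batch(indices=best_idx, score=best_val)

    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    if batch_size == 1:
        # every singleton has acquisition 0; the tie rule picks index 0
        return Batch(indices=(0,), score=0.0)

    # seed with the maximal off-diagonal pair, lowest (i, j) on ties
    off = H.copy()
    np.fill_diagonal(off, -np.inf)
    flat = int(np.argmax(off))  # row-major argmax takes the lowest (i, j)
    i, j = divmod(flat, n)
    chosen = [min(i, j), max(i, j)]
    in_batch = np.zeros(n, dtype=bool)
    in_batch[chosen] = True

    while len(chosen) < batch_size:
        gains = H[:, chosen].sum(axis=1)
        gains[in_batch] = -np.inf
        c = int(np.argmax(gains))
        chosen.append(c)
        in_batch[c] = True

    # one pass of single-swap improvement, members in ascending index order
    value = _pair_sum(H, np.asarray(chosen))
    for member in sorted(chosen):
        if member not in chosen:  # replaced earlier in the pass
            continue
        others = [c for c in chosen if c != member]
        base = sum(H[member, o] for o in others)
        cand_gain = H[:, others].sum(axis=1)
        cand_gain[in_batch] = -np.inf
        best = int(np.argmax(cand_gain))
        if cand_gain[best] > base + 1e-12:
            in_batch[member] = False
            in_batch[best] = True
            chosen[chosen.index(member)] = best
            value += float(cand_gain[best] - base)

    idx = tuple(sorted(chosen))
    return Batch(indices=idx, score=_pair_sum(H, np.asarray(idx)))


def write_entropy_csv(matrix: EntropyMatrix, path: str | Path) -> None:
    """Export the entropy matrix as CSV for audit."""
    np.savetxt(path, matrix.H, delimiter=",", fmt="%.10g")


def write_batch_csv(
    batch: Batch, ids: Sequence[str], path: str | Path, round_no: int = 1
) -> None:
    """Write a selected batch as CSV (round, id, acquisition_value)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["round", "id", "acquisition_value"])
        for i in batch.indices:
            writer.writerow([round_no, ids[i], f"{batch.score:.6f}" if batch.score is not None else ""])
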