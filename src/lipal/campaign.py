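"""Campaign driver: label policy, annotation resolution, agreement, rounds.

A labeling campaign alternates model fitting on the labeled set with
joint-entropy batch selection from the unlabeled pool, sending the batch to
annotators and folding resolved labels back into the state. The label
policy is the step-count rule: a molecule is synthesizable iff the
estimated number of reaction steps is strictly fewer than k (k = 15 by
default — a per-laboratory feasibility threshold). Annotators may skip
molecules; redundant annotations are resolved by unanimity or majority,
with two-way ties escalated for manual resolution rather than auto-broken.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from lipal.acquisition import Batch, build_entropy_matrix, select_batch
from lipal.model import EnsembleConfig, EnsembleClassifier

LABEL_SYNTH = 1
LABEL_NONSYNTH = 0
_LABEL_STR = {LABEL_SYNTH: "synthesizable", LABEL_NONSYNTH: "nonsynthesizable"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}


@dataclass(frozen=True)
class LabelingPolicy:
    """Step-count labeling rule: synthesizable iff steps < k (strict)."""

    k: int = 15

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def apply_label_policy(steps: int, policy: LabelingPolicy | None = None) -> int:
    """Label from an estimated step count; 0 steps counts as synthesizable."""
    policy = policy or LabelingPolicy()
    if steps < 0:
        raise ValueError("step count cannot be negative")
    return LABEL_SYNTH if steps < policy.k else LABEL_NONSYNTH


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotator's assessment of one molecule.

    ``label`` and ``estimated_steps`` may each be absent; a record with
    neither is a skip. When both are given and conflict under the policy,
    the explicit label reflects annotator intent and wins (flagged at
    resolution time).
    """

    molecule_id: str
    annotator_id: str
    estimated_steps: int | None = None
    label: int | None = None
    comment: str = ""

    @property
    def skipped(self) -> bool:
        return self.label is None and self.estimated_steps is None

    def effective_label(self, policy: LabelingPolicy | None = None) -> int | None:
        if self.label is not None:
            return self.label
        if self.estimated_steps is not None:
            return apply_label_policy(self.estimated_steps, policy)
        return None

    def policy_conflict(self, policy: LabelingPolicy | None = None) -> bool:
        if self.label is None or self.estimated_steps is None:
            return False
        return self.label != apply_label_policy(self.estimated_steps, policy)


@dataclass
class ResolutionResult:
    final_labels: dict[str, int]
    conflicts: list[str]  # two-way ties needing manual resolution
    flagged: list[str]  # molecules with any internal disagreement or policy conflict


def resolve_annotations(
    records: Sequence[AnnotationRecord], policy: LabelingPolicy | None = None
) -> ResolutionResult:
    """Resolve redundant annotations per molecule.

    Skips are ignored. Unanimous labels stand; among three or more
    annotators a majority wins (molecule flagged as inconsistent); an even
    two-way tie yields no final label and lands on the conflict list.
    """
    by_mol: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for rec in records:
        if not rec.skipped:
            by_mol[rec.molecule_id].append(rec)

    final: dict[str, int] = {}
    conflicts: list[str] = []
    flagged: list[str] = []
    for mol_id, recs in by_mol.items():
        labels = [rec.effective_label(policy) for rec in recs]
        if any(rec.policy_conflict(policy) for rec in recs):
            flagged.append(mol_id)
        tally = Counter(labels)
        if len(tally) == 1:
            final[mol_id] = labels[0]
            continue
        if mol_id not in flagged:
            flagged.append(mol_id)
        (top, top_n), (_, second_n) = tally.most_common(2)
        if top_n == second_n:
            conflicts.append(mol_id)
        else:
            final[mol_id] = top
    return ResolutionResult(final_labels=final, conflicts=conflicts, flagged=flagged)


@dataclass(frozen=True)
class AgreementReport:
    n_redundant: int
    n_disagreeing: int
    percent_agreement: float | None


def agreement_rate(
    records: Sequence[AnnotationRecord], policy: LabelingPolicy | None = None
) -> AgreementReport:
    """Agreement among molecules with two or more non-skipped annotations."""
    by_mol: dict[str, list[int]] = defaultdict(list)
    for rec in records:
        if not rec.skipped:
            by_mol[rec.molecule_id].append(rec.effective_label(policy))
    redundant = {m: labs for m, labs in by_mol.items() if len(labs) >= 2}
    n_red = len(redundant)
    n_dis = sum(1 for labs in redundant.values() if len(set(labs)) > 1)
    percent = 100.0 * (n_red - n_dis) / n_red if n_red else None
    return AgreementReport(n_redundant=n_red, n_disagreeing=n_dis, percent_agreement=percent)


# ---------------------------------------------------------------------------
# campaign state and rounds
# ---------------------------------------------------------------------------


@dataclass
class RoundRecord:
    round: int
    selected: list[str]
    n_labeled: int
    n_positive: int
    n_negative: int
    pool_tag: str


@dataclass
class CampaignState:
    """Labeled set, unlabeled pool (with pool tags) and batch history.

    The unit of persistence between rounds; ``labeled`` and ``pool`` are
    always disjoint. Molecules selected but skipped by every annotator are
    parked in ``skipped`` so they are not immediately re-selected.
    """

    labeled: dict[str, int] = field(default_factory=dict)
    pool: dict[str, str] = field(default_factory=dict)
    history: list[RoundRecord] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.labeled) & set(self.pool)
        if overlap:
            raise ValueError(f"labeled and pool overlap: {sorted(overlap)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labeled": self.labeled,
            "pool": self.pool,
            "history": [asdict(r) for r in self.history],
            "skipped": self.skipped,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CampaignState":
        payload = json.loads(Path(path).read_text())
        return cls(
            labeled={k: int(v) for k, v in payload["labeled"].items()},
            pool=dict(payload["pool"]),
            history=[RoundRecord(**r) for r in payload["history"]],
            skipped=list(payload.get("skipped", [])),
        )


@dataclass(frozen=True)
class SelectionConfig:
    batch_size: int = 30
    method: str = "greedy"
    seed: int = 0


def run_round(
    state: CampaignState,
    features: Mapping[str, np.ndarray],
    ensemble_config: EnsembleConfig | None = None,
    selection: SelectionConfig | None = None,
    labeler: Callable[[str], int | None] | None = None,
) -> tuple[CampaignState, Batch, list[str]]:
    """Run one active-learning round in place.

    Fits the ensemble on the labeled set, draws the posterior on the pool,
    builds the pairwise entropy matrix and selects a batch. If ``labeler``
    is given it is called per selected molecule (returning 0/1 or None for
    a skip); resolved labels move molecules from pool to labeled and a
    history row is appended. Returns the state, the selected
    :class:`~lipal.acquisition.Batch` (indices into the sorted pool ids),
    and the selected molecule ids.
    """
    ensemble_config = ensemble_config or EnsembleConfig()
    selection = selection or SelectionConfig()
    if not state.pool:
        raise ValueError("the unlabeled pool is empty")
    labeled_ids = sorted(state.labeled)
    y = np.array([state.labeled[i] for i in labeled_ids], dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError(
            "the labeled set holds a single class; enrich the seed set with "
            "both synthesizable and nonsynthesizable molecules before running AL"
        )
    pool_ids = sorted(state.pool)
    X_l = np.vstack([features[i] for i in labeled_ids])
    X_p = np.vstack([features[i] for i in pool_ids])

    results = EnsembleClassifier(y, X_l, config=ensemble_config).fit()
    samples = results.posterior_draws(X_p)
    matrix = build_entropy_matrix(samples)
    batch = select_batch(
        matrix, batch_size=min(selection.batch_size, len(pool_ids)),
        method=selection.method, seed=selection.seed,
    )
    selected_ids = [pool_ids[i] for i in batch.indices]

    if labeler is not None:
        new_labels = {mol: labeler(mol) for mol in selected_ids}
        tags = Counter(state.pool[mol] for mol in selected_ids)
        pool_tag = tags.most_common(1)[0][0]
        n_pos = sum(1 for v in new_labels.values() if v == LABEL_SYNTH)
        n_neg = sum(1 for v in new_labels.values() if v == LABEL_NONSYNTH)
        for mol, lab in new_labels.items():
            del state.pool[mol]
            if lab is None:
                state.skipped.append(mol)
            else:
                state.labeled[mol] = int(lab)
        state.history.append(
            RoundRecord(
                round=len(state.history) + 1,
                selected=selected_ids,
                n_labeled=n_pos + n_neg,
                n_positive=n_pos,
                n_negative=n_neg,
                pool_tag=pool_tag,
            )
        )
    return state, batch, selected_ids


def campaign_summary(state: CampaignState) -> dict[str, pd.DataFrame]:
    """Stage and per-batch summary tables of a campaign.

    ``stages`` mirrors the dataset-characteristics layout (initial part,
    active-learning part, total); ``batches`` mirrors the per-round
    campaign-progress layout (labeled / unlabeled / positive / negative /
    pool). Row sums are internally consistent by construction.
    """
    al_ids = {mol for rec in state.history for mol in rec.selected if mol in state.labeled}
    initial_ids = [m for m in state.labeled if m not in al_ids]

    def _row(stage: str, ids) -> dict:
        labels = [state.labeled[m] for m in ids]
        pos = sum(labels)
        return {
            "stage": stage,
            "samples": len(labels),
            "positive": pos,
            "negative": len(labels) - pos,
        }

    stages = pd.DataFrame(
        [
            _row("total data set", list(state.labeled)),
            _row("initial part", initial_ids),
            _row("active learning part", sorted(al_ids)),
        ]
    )
    if not state.labeled:
        stages = stages.iloc[0:0]

    batch_rows = []
    for rec in state.history:
        batch_rows.append(
            {
                "batch": rec.round,
                "labeled": rec.n_labeled,
                "unlabeled": len(rec.selected) - rec.n_labeled,
                "positive": rec.n_positive,
                "negative": rec.n_negative,
                "pool": rec.pool_tag,
            }
        )
    batches = pd.DataFrame(
        batch_rows, columns=["batch", "labeled", "unlabeled", "positive", "negative", "pool"]
    )
    return {"stages": stages, "batches": batches}


# ---------------------------------------------------------------------------
# annotation CSV IO (schema: molecule_id, annotator_id, estimated_steps, label, comment)
# ---------------------------------------------------------------------------


def read_annotations_csv(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, dtype={"molecule_id": str, "annotator_id": str})
    required = {"molecule_id", "annotator_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        steps = row.get("estimated_steps")
        steps = int(steps) if pd.notna(steps) else None
        label_raw = row.get("label")
        label = None
        if pd.notna(label_raw) and str(label_raw).strip():
            key = str(label_raw).strip().lower()
            if key not in _STR_LABEL:
                raise ValueError(f"unknown label {label_raw!r} for {row['molecule_id']}")
            label = _STR_LABEL[key]
        comment = row.get("comment")
        records.append(
            AnnotationRecord(
                molecule_id=row["molecule_id"],
                annotator_id=row["annotator_id"],
                estimated_steps=steps,
                label=label,
                comment=str(comment) if pd.notna(comment) else "",
            )
        )
    return records


def write_annotations_csv(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "annotator_id": r.annotator_id,
            "estimated_steps": r.estimated_steps,
            "label": _LABEL_STR[r.label] if r.label is not None else "",
            "comment": r.comment,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
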