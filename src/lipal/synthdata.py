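"""Synthetic lipid campaigns: structures, step-count oracle, annotations.

Stands in for a withheld expert-labeled dataset so every downstream module
runs end-to-end offline. Lipid-like molecules are assembled from a built-in
head/linker/tail fragment library (ionizable amine heads, diester/amide
linkers, C16-C22 aliphatic tails); a deterministic oracle assigns each
molecule a "true" reaction-step count that is additive in its fragments
plus penalties for synthesis-complicating moieties (aromatic rings, double
bonds, sulfur). Binary labels follow the step-count policy (synthesizable
iff steps < k, k = 15). The additive oracle is a deliberate simplification:
it gives exact ground truth that is a function of structure (so count
fingerprints carry signal by construction) with no claim of chemical
realism.

Default conditions emulate the reference campaign shape: ~60% positive
class balance overall, and redundant annotations with a configurable
single-annotator disagreement rate (default 1 in 30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from lipal.campaign import AnnotationRecord, LabelingPolicy, apply_label_policy
from lipal.chemio import MoleculeRecord, canonicalize
from lipal.pool import FragmentLibrary, enumerate_combinatorial

DEFAULT_HEADS = (
    "[*:1]CCN(C)C",
    "[*:1]CCCN(CC)CC",
    "[*:1]CCN1CCCC1",
    "[*:1]CCN(C)CCO",
    "[*:1]CCCN1CCN(C)CC1",
    "[*:1]CCN(CCO)CCO",
    "[*:1]CCCCN(C)C",
    "[*:1]CCN(C)CCCN(C)C",
)
DEFAULT_LINKERS = (
    "[*:1]OC(=O)CCCCCCCC(=O)O[*:2]",
    "[*:1]OC(=O)CCCCCCCCCCC(=O)O[*:2]",
    "[*:1]NC(=O)CCCCCCCC(=O)O[*:2]",
    "[*:1]OC(=O)CCSCCCCC(=O)O[*:2]",
    "[*:1]OCC(CO[*:2])OC(=O)CCCCCCC",
    "[*:1]OC(=O)c1ccc(cc1)C(=O)OCCCC(=O)O[*:2]",
)
DEFAULT_TAILS = (
    "[*:2]CCCCCCCCCCCCCCCC",
    "[*:2]CCCCCCCCCCCCCCCCCC",
    "[*:2]CCCCCCCCCCCCCCCCCCCC",
    "[*:2]CCCCCCCC/C=C\\CCCCCCCC",
    "[*:2]CCCCCC/C=C\\C/C=C\\CCCCCC",
    "[*:2]CCCCCCCC(CCCCCCCC)CCCCCC",
    "[*:2]CCCCCCCCCCCC(C)CCCCCCC",
    "[*:2]CCCCCCCCCCCCCCCCCCCCCC",
)

# (SMARTS, extra steps, count at most once)
DEFAULT_MOIETY_PENALTIES = (
    ("a1aaaaa1", 2, True),  # aromatic ring: protection/deprotection overhead
    ("C=C", 1, False),  # each alkene: stereoselective installation
    ("[#16]", 2, True),  # sulfur chemistry
)


def default_library() -> FragmentLibrary:
    return FragmentLibrary(heads=DEFAULT_HEADS, linkers=DEFAULT_LINKERS, tails=DEFAULT_TAILS)


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-campaign conditions.

    ``target_positive_fraction`` is met within +/- ``balance_tolerance`` by
    tuning a single integer offset on the oracle's base step count. Fragment
    coupling costs are bimodal: each fragment is independently routine
    (cost drawn from ``routine_cost_range``, inclusive) or synthetically
    demanding (cost drawn from its category's demanding range) with
    probability ``demanding_fraction``, all under ``seed``. The bimodal mix
    keeps most step counts away from the labeling boundary, the way routine
    couplings and exotic chemistry separate in practice.
    """

    n_molecules: int = 257
    k: int = 15
    target_positive_fraction: float = 0.60
    balance_tolerance: float = 0.05
    routine_cost_range: tuple[int, int] = (1, 2)
    head_cost_range: tuple[int, int] = (5, 6)
    linker_cost_range: tuple[int, int] = (6, 7)
    tail_cost_range: tuple[int, int] = (5, 6)
    demanding_fraction: float = 0.5
    base_steps: int = 2
    moiety_penalties: tuple[tuple[str, int, bool], ...] = DEFAULT_MOIETY_PENALTIES
    disagreement_rate: float = 1.0 / 30.0
    seed: int = 0
    library: FragmentLibrary | None = None

    def __post_init__(self) -> None:
        if not 0 < self.target_positive_fraction < 1:
            raise ValueError("target_positive_fraction must lie in (0, 1)")
        if not 0 <= self.disagreement_rate <= 1:
            raise ValueError("disagreement_rate must lie in [0, 1]")
        for lo, hi in (
            self.routine_cost_range,
            self.head_cost_range,
            self.linker_cost_range,
            self.tail_cost_range,
        ):
            if lo < 0 or hi < lo:
                raise ValueError("cost ranges must be non-negative and ordered")
        if not 0 <= self.demanding_fraction <= 1:
            raise ValueError("demanding_fraction must lie in [0, 1]")


class SyntheticOracle:
    """Deterministic molecule -> true step count map.

    steps = base + coupling cost of each fragment + moiety penalties,
    evaluated on the canonical SMILES, so the count is invariant to the
    SMILES spelling and identical across calls and seeds.
    """

    def __init__(
        self,
        fragment_costs: Mapping[str, Sequence[int]],
        triples: Mapping[str, tuple[int, int, int]],
        base_steps: int,
        moiety_penalties: Sequence[tuple[str, int, bool]] = DEFAULT_MOIETY_PENALTIES,
    ):
        self.fragment_costs = {k: list(v) for k, v in fragment_costs.items()}
        self._triples = dict(triples)
        self.base_steps = int(base_steps)
        self._penalties = [
            (Chem.MolFromSmarts(smarts), int(steps), bool(once), smarts)
            for smarts, steps, once in moiety_penalties
        ]
        for patt, _, _, smarts in self._penalties:
            if patt is None:
                raise ValueError(f"moiety penalty pattern {smarts!r} is not valid SMARTS")

    def moiety_penalty(self, smiles_canonical: str) -> int:
        mol = Chem.MolFromSmiles(smiles_canonical)
        total = 0
        for patt, steps, once, _ in self._penalties:
            n = len(mol.GetSubstructMatches(patt))
            if n:
                total += steps if once else steps * n
        return total

    def step_count(self, molecule: str | MoleculeRecord) -> int:
        if isinstance(molecule, MoleculeRecord):
            canonical = molecule.smiles_canonical
        else:
            rec = canonicalize(molecule)
            if not rec.valid:
                raise ValueError(f"cannot canonicalize {molecule!r}")
            canonical = rec.smiles_canonical
        if canonical not in self._triples:
            raise KeyError(f"molecule {canonical!r} is outside the oracle's library")
        hi, li, ti = self._triples[canonical]
        raw = (
            self.base_steps
            + self.fragment_costs["heads"][hi]
            + self.fragment_costs["linkers"][li]
            + self.fragment_costs["tails"][ti]
            + self.moiety_penalty(canonical)
        )
        return max(1, raw)


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]
    steps: np.ndarray
    labels: np.ndarray
    oracle: SyntheticOracle
    config: SynthConfig

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels))


def generate_dataset(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate a fully labeled synthetic campaign dataset.

    Molecules are head-linker-tail assemblies (exhaustive when the product
    space is small, else a seeded uniform sample); the oracle's base step
    count is auto-tuned by an integer offset so the realized positive
    fraction under the k-policy lands within the balance tolerance of the
    target. Byte-identical outputs for identical configs.
    """
    config = config or SynthConfig()
    library = config.library or default_library()
    rng = np.random.default_rng(config.seed)
    records, triples = enumerate_combinatorial(
        library, max_molecules=config.n_molecules, seed=config.seed,
        id_prefix="syn", return_indices=True,
    )

    def _bimodal_costs(demanding_range: tuple[int, int], n: int) -> list[int]:
        demanding = rng.random(n) < config.demanding_fraction
        routine = rng.integers(
            config.routine_cost_range[0], config.routine_cost_range[1] + 1, n
        )
        exotic = rng.integers(demanding_range[0], demanding_range[1] + 1, n)
        return np.where(demanding, exotic, routine).tolist()

    costs = {
        "heads": _bimodal_costs(config.head_cost_range, len(library.heads)),
        "linkers": _bimodal_costs(config.linker_cost_range, len(library.linkers)),
        "tails": _bimodal_costs(config.tail_cost_range, len(library.tails)),
    }
    triple_map = {rec.smiles_canonical: t for rec, t in zip(records, triples)}
    proto = SyntheticOracle(costs, triple_map, config.base_steps, config.moiety_penalties)
    raw = np.array(
        [
            config.base_steps
            + costs["heads"][hi]
            + costs["linkers"][li]
            + costs["tails"][ti]
            + proto.moiety_penalty(rec.smiles_canonical)
            for rec, (hi, li, ti) in zip(records, triples)
        ],
        dtype=np.int64,
    )

    # tune a single integer offset of the base step count toward the target
    # class balance under the k-policy
    offsets = np.arange(-(raw.max() + 1), raw.max() + 2)
    fractions = np.array(
        [np.mean(np.maximum(raw + d, 1) < config.k) for d in offsets]
    )
    best = int(np.argmin(np.abs(fractions - config.target_positive_fraction)))
    if abs(fractions[best] - config.target_positive_fraction) > config.balance_tolerance:
        raise ValueError(
            "cannot reach the target positive fraction "
            f"{config.target_positive_fraction:.2f} within +/-{config.balance_tolerance}; "
            "widen the fragment cost ranges to diversify step counts"
        )
    offset = int(offsets[best])

    oracle = SyntheticOracle(
        costs, triple_map, config.base_steps + offset, config.moiety_penalties
    )
    steps = np.array([oracle.step_count(rec) for rec in records], dtype=np.int64)
    policy = LabelingPolicy(k=config.k)
    labels = np.array([apply_label_policy(int(s), policy) for s in steps], dtype=np.int64)
    return SyntheticDataset(
        records=records, steps=steps, labels=labels, oracle=oracle, config=config
    )


def simulate_annotations(
    labels: Mapping[str, int],
    n_redundant: int,
    annotators_per_molecule: Sequence[int] | None = None,
    disagreement_rate: float = 1.0 / 30.0,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Simulate a labeling campaign's annotation table.

    ``n_redundant`` molecules receive multiple independent annotations
    (defaulting to the observed campaign pattern of roughly 23 double- to 7
    triple-annotated per 30); each redundant molecule has one annotator
    flipped with probability ``disagreement_rate``. All other molecules get
    a single truthful annotation.
    """
    ids = list(labels)
    if n_redundant > len(ids):
        raise ValueError("n_redundant exceeds the number of molecules")
    if annotators_per_molecule is None:
        n_triple = int(round(n_redundant * 7 / 30))
        annotators_per_molecule = [2] * (n_redundant - n_triple) + [3] * n_triple
    if len(annotators_per_molecule) != n_redundant:
        raise ValueError("annotators_per_molecule length must equal n_redundant")
    if any(a < 2 for a in annotators_per_molecule):
        raise ValueError("redundant molecules need at least 2 annotators")

    rng = np.random.default_rng(seed)
    redundant = set(rng.choice(len(ids), size=n_redundant, replace=False).tolist())
    records: list[AnnotationRecord] = []
    red_iter = iter(annotators_per_molecule)
    for i, mol_id in enumerate(ids):
        truth = int(labels[mol_id])
        if i in redundant:
            n_ann = next(red_iter)
            assigned = [truth] * n_ann
            if rng.random() < disagreement_rate:
                assigned[int(rng.integers(n_ann))] = 1 - truth
            for a, lab in enumerate(assigned):
                records.append(
                    AnnotationRecord(
                        molecule_id=mol_id, annotator_id=f"ann{a:02d}", label=lab
                    )
                )
        else:
            records.append(
                AnnotationRecord(molecule_id=mol_id, annotator_id="ann00", label=truth)
            )
    return records


def make_learnable(labels, signal_strength: float, seed: int = 0) -> np.ndarray:
    """Inject label noise: flip each label with probability (1 - s)/2.

    At ``signal_strength`` 1 labels are unchanged (fully structure-
    determined); at 0 each label is an independent coin flip, severing the
    structure-label link.
    """
    if not 0 <= signal_strength <= 1:
        raise ValueError("signal_strength must lie in [0, 1]")
    y = np.asarray(labels, dtype=np.int64).copy()
    rng = np.random.default_rng(seed)
    flip = rng.random(y.shape[0]) < (1.0 - signal_strength) / 2.0
    y[flip] = 1 - y[flip]
    return y


def write_dataset_csv(dataset: SyntheticDataset, path: str | Path) -> None:
    """Emit the labeled dataset as CSV (id, smiles, steps, label)."""
    pd.DataFrame(
        {
            "id": dataset.ids,
            "smiles": [r.smiles_canonical for r in dataset.records],
            "steps": dataset.steps,
            "label": dataset.labels,
        }
    ).to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV lacks columns: {sorted(missing)}")
    return df
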