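"""Build, filter and diversity-cluster unlabeled candidate pools.

Pools are assembled by a head–linker–tail combinatorial grammar: each
fragment carries RDKit attachment markers (``[*:1]`` joins head to linker,
``[*:2]`` joins linker to tail) and assemblies are zipped into single
molecules with single-bond junctions. Filtering applies, in a fixed order,
validity, uniqueness (canonical SMILES), a molecular-weight window
(500–1500 Da inclusive by default), a maximum ring size (8 atoms), and an
optional banned-moiety SMARTS list. Diversity reduction is K-means on count
fingerprints with nearest-to-centroid representatives.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from sklearn.cluster import KMeans

from lipal.chemio import CountFingerprint, MoleculeRecord, canonicalize, max_ring_size

_HEAD_MARKS = {1}
_LINKER_MARKS = {1, 2}
_TAIL_MARKS = {2}


@dataclass(frozen=True)
class FragmentLibrary:
    """Head/linker/tail fragment SMILES, one attachment marker per junction."""

    heads: tuple[str, ...]
    linkers: tuple[str, ...]
    tails: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "heads", tuple(self.heads))
        object.__setattr__(self, "linkers", tuple(self.linkers))
        object.__setattr__(self, "tails", tuple(self.tails))
        for role, frags, marks in (
            ("head", self.heads, _HEAD_MARKS),
            ("linker", self.linkers, _LINKER_MARKS),
            ("tail", self.tails, _TAIL_MARKS),
        ):
            if not frags:
                raise ValueError(f"fragment library has no {role} fragments")
            for smi in frags:
                _check_fragment(role, smi, marks)

    @property
    def n_products(self) -> int:
        return len(self.heads) * len(self.linkers) * len(self.tails)


def _check_fragment(role: str, smiles: str, expected_marks: set[int]) -> None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"{role} fragment {smiles!r} does not parse")
    marks = sorted(
        a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum()
    )
    if marks != sorted(expected_marks):
        raise ValueError(
            f"{role} fragment {smiles!r} has attachment markers {marks}, "
            f"expected {sorted(expected_marks)}"
        )


def assemble_fragments(head: str, linker: str, tail: str) -> str | None:
    """Zip a head, linker and tail into one molecule; canonical SMILES or None."""
    mols = [Chem.MolFromSmiles(s) for s in (head, linker, tail)]
    if any(m is None for m in mols):
        return None
    combo = Chem.CombineMols(Chem.CombineMols(mols[0], mols[1]), mols[2])
    try:
        zipped = Chem.molzip(combo)
        Chem.SanitizeMol(zipped)
    except Exception:
        return None
    return Chem.MolToSmiles(zipped)


def enumerate_combinatorial(
    library: FragmentLibrary,
    max_molecules: int,
    seed: int = 0,
    id_prefix: str = "mol",
    return_indices: bool = False,
):
    """Enumerate head–linker–tail assemblies, deduplicated by canonical SMILES.

    If the full product space holds at most ``max_molecules`` assemblies the
    enumeration is exhaustive (lexicographic fragment order); otherwise
    fragment triples are visited in a seed-determined uniform random order
    until ``max_molecules`` unique molecules are collected.

    Returns a list of :class:`MoleculeRecord`; with ``return_indices=True``
    additionally the parallel list of (head, linker, tail) index triples.
    """
    if max_molecules < 1:
        raise ValueError("max_molecules must be >= 1")
    total = library.n_products
    n_l, n_t = len(library.linkers), len(library.tails)
    if total <= max_molecules:
        order = np.arange(total)
        limit = total
    else:
        order = np.random.default_rng(seed).permutation(total)
        limit = max_molecules

    records: list[MoleculeRecord] = []
    triples: list[tuple[int, int, int]] = []
    seen: set[str] = set()
    for flat in order:
        if len(records) >= limit:
            break
        hi, rest = divmod(int(flat), n_l * n_t)
        li, ti = divmod(rest, n_t)
        smi = assemble_fragments(library.heads[hi], library.linkers[li], library.tails[ti])
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        rec = canonicalize(smi, mol_id=f"{id_prefix}{len(records):06d}")
        records.append(rec)
        triples.append((hi, li, ti))
    if return_indices:
        return records, triples
    return records


@dataclass(frozen=True)
class PoolFilterConfig:
    """Pool filtering rules; weight bounds inclusive on both ends."""

    mw_min: float = 500.0
    mw_max: float = 1500.0
    max_ring_atoms: int = 8
    banned_moieties: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "banned_moieties", tuple(self.banned_moieties))
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be strictly below mw_max")
        if self.max_ring_atoms < 3:
            raise ValueError("max_ring_atoms must be >= 3")


# Removal counts are attributed to the first failing rule in this order.
FILTER_RULES = ("validity", "uniqueness", "mw", "ring", "moiety")


def filter_pool(
    pool: Sequence[MoleculeRecord], config: PoolFilterConfig
) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Apply the filtering rules; return kept records and per-rule removal counts."""
    patterns = []
    for smarts in config.banned_moieties:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"banned moiety {smarts!r} is not valid SMARTS")
        patterns.append(patt)

    counts: Counter[str] = Counter({rule: 0 for rule in FILTER_RULES})
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    for rec in pool:
        if not rec.valid:
            counts["validity"] += 1
            continue
        if rec.smiles_canonical in seen:
            counts["uniqueness"] += 1
            continue
        seen.add(rec.smiles_canonical)
        if not config.mw_min <= rec.mol_weight <= config.mw_max:
            counts["mw"] += 1
            continue
        if max_ring_size(rec) > config.max_ring_atoms:
            counts["ring"] += 1
            continue
        if patterns:
            mol = Chem.MolFromSmiles(rec.smiles_canonical)
            if any(mol.HasSubstructMatch(p) for p in patterns):
                counts["moiety"] += 1
                continue
        kept.append(rec)
    return kept, dict(counts)


@dataclass(frozen=True)
class ClusteredPool:
    """K-means assignments and nearest-to-centroid representatives."""

    assignments: Mapping[str, int]
    representatives: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        object.__setattr__(self, "representatives", tuple(self.representatives))


def cluster_representatives(
    fingerprints: Sequence[CountFingerprint] | np.ndarray,
    k: int,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    n_restarts: int = 4,
) -> ClusteredPool:
    """K-means (Euclidean) on count vectors with per-cluster representatives.

    The representative of each non-empty cluster is the member closest to
    the cluster centroid (ties broken toward the lowest index).
    """
    if isinstance(fingerprints, np.ndarray):
        X = np.asarray(fingerprints, dtype=np.float64)
    else:
        X = np.vstack([fp.counts for fp in fingerprints]).astype(np.float64)
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must match number of fingerprints")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)

    assignments = {ids[i]: int(labels[i]) for i in range(n)}
    representatives: list[str] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        dists = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        representatives.append(ids[members[int(np.argmin(dists))]])
    return ClusteredPool(assignments=assignments, representatives=tuple(representatives))


def read_moiety_file(path: str | Path) -> tuple[str, ...]:
    """Read banned-moiety SMARTS patterns, one per line; '#' comments allowed."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(line)
    return tuple(patterns)


def write_cluster_csv(clustered: ClusteredPool, path: str | Path) -> None:
    """Write cluster output as CSV (id, cluster, is_representative)."""
    reps = set(clustered.representatives)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "cluster", "is_representative"])
        for mol_id, cluster in clustered.assignments.items():
            writer.writerow([mol_id, cluster, int(mol_id in reps)])
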