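"""SMILES ingestion, canonicalization, descriptors and count fingerprints.

All chemistry enters the pipeline through this module. Molecules are parsed
and canonicalized with RDKit; the canonical SMILES string is the internal
identity key for uniqueness checks, so it must never be compared across
toolkit versions. Featurization uses the extended-connectivity (Morgan)
fingerprint in its count-based, chirality-aware variant — radius 3 folded
into 2048 slots by default — which counts circular atom environments rather
than recording mere presence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

# Invalid SMILES are an expected input (valid=False), not log noise.
RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 3
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: identifiers, raw and canonical SMILES, weight, validity.

    ``valid`` is true iff RDKit could parse and sanitize ``smiles_raw``;
    exactly then ``smiles_canonical`` and ``mol_weight`` (average atomic
    masses, Daltons) are present.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str | None = None
    mol_weight: float | None = None
    valid: bool = False

    def __post_init__(self) -> None:
        if self.valid != (self.smiles_canonical is not None):
            raise ValueError("valid must hold exactly when smiles_canonical is present")
        if self.valid != (self.mol_weight is not None):
            raise ValueError("mol_weight must be present exactly for valid records")


@dataclass(frozen=True)
class CountFingerprint:
    """Hashed circular-substructure count vector.

    Counts accumulate under modulo-``n_bits`` folding, so hash collisions
    add. Entries are non-negative integers; two SMILES spellings of the
    same molecule yield identical vectors.
    """

    counts: np.ndarray
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS
    chirality: bool = True

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.shape[0] != self.n_bits:
            raise ValueError(f"counts must be a vector of length n_bits={self.n_bits}")
        if (counts < 0).any():
            raise ValueError("fingerprint counts must be non-negative")


def canonicalize(smiles: str, mol_id: str | None = None) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Never raises on malformed input: unparseable strings yield a record
    with ``valid=False``. Canonicalization is idempotent — canonicalizing
    the canonical form returns the same string.
    """
    mol = Chem.MolFromSmiles(smiles)
    ident = mol_id if mol_id is not None else smiles
    if mol is None:
        return MoleculeRecord(id=ident, smiles_raw=smiles)
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        id=ident,
        smiles_raw=smiles,
        smiles_canonical=canonical,
        mol_weight=float(Descriptors.MolWt(mol)),
        valid=True,
    )


def _mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    if not record.valid or record.smiles_canonical is None:
        raise ValueError(f"molecule {record.id!r} is not a valid, canonicalized record")
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:  # canonical SMILES must round-trip
        raise ValueError(f"canonical SMILES of {record.id!r} failed to re-parse")
    return mol


def max_ring_size(record: MoleculeRecord) -> int:
    """Size in atoms of the largest ring (SSSR ring set); 0 if acyclic."""
    mol = _mol_from_record(record)
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int, chirality: bool):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=chirality
    )


def ecfp_counts(
    record: MoleculeRecord,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    chirality: bool = True,
) -> CountFingerprint:
    """Count-based circular fingerprint of a valid molecule."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_record(record)
    gen = _morgan_generator(radius, n_bits, chirality)
    counts = gen.GetCountFingerprintAsNumPy(mol).astype(np.int64)
    return CountFingerprint(counts=counts, radius=radius, n_bits=n_bits, chirality=chirality)


def fingerprint_matrix(
    records: Sequence[MoleculeRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    chirality: bool = True,
) -> np.ndarray:
    """Stack fingerprints of valid records into an (n, n_bits) float matrix."""
    return np.vstack(
        [ecfp_counts(r, radius, n_bits, chirality).counts for r in records]
    ).astype(np.float64)


def read_smi(path: str | Path) -> list[MoleculeRecord]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    records: list[MoleculeRecord] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"smi{i:06d}"
        records.append(canonicalize(smiles, mol_id=mol_id))
    return records


def read_smiles_csv(
    path: str | Path, smiles_col: str = "smiles", id_col: str | None = "id"
) -> list[MoleculeRecord]:
    """Read molecules from a CSV with a configurable SMILES column."""
    records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_col not in reader.fieldnames:
            raise ValueError(f"CSV {path} has no column {smiles_col!r}")
        for i, row in enumerate(reader):
            mol_id = row[id_col] if id_col and id_col in row else f"csv{i:06d}"
            records.append(canonicalize(row[smiles_col], mol_id=mol_id))
    return records


def write_pool_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write valid records as a canonical pool CSV (id, smiles, mol_weight)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "mol_weight"])
        for r in records:
            if r.valid:
                writer.writerow([r.id, r.smiles_canonical, f"{r.mol_weight:.3f}"])
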