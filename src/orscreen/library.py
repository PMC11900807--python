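"""Molecule library handling: loading, descriptors, odorant-likeness filtering.

Insect odorant receptors detect small volatile molecules, so screening
libraries are first reduced to an "odorant-like" subset using four
physicochemical descriptors: molecular weight, heavy-atom count,
heteroatom count and Crippen logP. The default bounds (MW <= 400 g/mol,
<= 25 heavy atoms, <= 10 heteroatoms, logP in [-1, 7]) separate odorous
from odorless compounds reasonably well in curated odorant databases.

All molecules are handled as 2D structures; conformer generation for
docking is an external step whose scores this package only consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise; we log skips ourselves

#: Filter reason codes emitted by :func:`physchem_filter`.
REASON_MW = "mw"
REASON_HEAVY = "heavy_atoms"
REASON_HETERO = "heteroatoms"
REASON_LOGP = "logp"


@dataclass
class MoleculeRecord:
    """A 2D molecule with its screening-relevant descriptors.

    Attributes
    ----------
    id : str
        Unique identifier within a library.
    smiles : str
        Canonical SMILES (canonicalized on descriptor computation).
    mw : float or None
        Molecular weight, g/mol.
    heavy_atoms : int or None
        Number of non-hydrogen atoms.
    heteroatoms : int or None
        Number of atoms that are neither carbon nor hydrogen.
    logp : float or None
        Crippen atomic-contribution octanol/water logP.
    fingerprint : ndarray or None
        Binary Morgan fingerprint (uint8 vector).
    """

    id: str
    smiles: str
    mw: float | None = None
    heavy_atoms: int | None = None
    heteroatoms: int | None = None
    logp: float | None = None
    fingerprint: np.ndarray | None = field(default=None, repr=False)

    @property
    def has_descriptors(self) -> bool:
        return None not in (self.mw, self.heavy_atoms, self.heteroatoms, self.logp)


@dataclass(frozen=True)
class FilterLimits:
    """Inclusive bounds of the odorant-likeness filter."""

    mw_max: float = 400.0
    heavy_atoms_max: int = 25
    heteroatoms_max: int = 10
    logp_min: float = -1.0
    logp_max: float = 7.0

    def __post_init__(self) -> None:
        if self.logp_min >= self.logp_max:
            raise ValueError("logp_min must be < logp_max")
        if min(self.mw_max, self.heavy_atoms_max, self.heteroatoms_max) < 0:
            raise ValueError("max limits must be non-negative")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _largest_fragment(mol: Chem.Mol, mol_id: str | None = None) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        logger.warning(
            "molecule %s has %d fragments; keeping the largest",
            mol_id or Chem.MolToSmiles(mol), len(frags),
        )
        return max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def load_library(path: str | Path, format: str = "smiles_table") -> list[MoleculeRecord]:
    """Load a molecule library from a delimited SMILES table or an SDF.

    Unparseable molecules are skipped with a warning; duplicate ids raise.
    Records are returned without descriptors — call
    :func:`compute_descriptors` (or :func:`prepare_library`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[MoleculeRecord] = []
    skipped = 0
    if format == "smiles_table":
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        missing = {"id", "smiles"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for _, row in df.iterrows():
            mol_id, smi = str(row["id"]), str(row["smiles"])
            if Chem.MolFromSmiles(smi) is None:
                logger.warning("skipping %s: unparseable SMILES %r", mol_id, smi)
                skipped += 1
                continue
            records.append(MoleculeRecord(id=mol_id, smiles=smi))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping SDF entry %d: unparseable", i)
                skipped += 1
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            if not mol_id:
                raise ValueError(f"SDF entry {i} has no name/title usable as id")
            records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown format {format!r}; expected smiles_table or sdf")

    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate molecule id: {rec.id!r}")
        seen.add(rec.id)
    if skipped:
        logger.warning("%d unparseable entries skipped from %s", skipped, path)
    return records


def compute_descriptors(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy of *record* with MW, atom counts and logP populated.

    Multi-fragment SMILES (salts) are reduced to the largest fragment
    before computation; the SMILES stored back is the canonical form of
    that fragment.
    """
    mol = _largest_fragment(_mol_from_smiles(record.smiles), record.id)
    heavy = mol.GetNumHeavyAtoms()
    hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return replace(
        record,
        smiles=Chem.MolToSmiles(mol),
        mw=float(Descriptors.MolWt(mol)),
        heavy_atoms=int(heavy),
        heteroatoms=int(hetero),
        logp=float(Crippen.MolLogP(mol)),
    )


def physchem_filter(
    records: Sequence[MoleculeRecord], limits: FilterLimits = FilterLimits()
) -> tuple[list[MoleculeRecord], list[tuple[MoleculeRecord, list[str]]]]:
    """Partition *records* into (passing, rejected-with-reasons).

    All bounds are inclusive. Every violated bound contributes a reason
    code so rejection reports are complete.
    """
    passing: list[MoleculeRecord] = []
    rejected: list[tuple[MoleculeRecord, list[str]]] = []
    for rec in records:
        if not rec.has_descriptors:
            raise ValueError(f"record {rec.id!r} lacks descriptors; run compute_descriptors first")
        reasons = []
        if rec.mw > limits.mw_max:
            reasons.append(REASON_MW)
        if rec.heavy_atoms > limits.heavy_atoms_max:
            reasons.append(REASON_HEAVY)
        if rec.heteroatoms > limits.heteroatoms_max:
            reasons.append(REASON_HETERO)
        if not (limits.logp_min <= rec.logp <= limits.logp_max):
            reasons.append(REASON_LOGP)
        if reasons:
            rejected.append((rec, reasons))
        else:
            passing.append(rec)
    return passing, rejected


def fingerprint(record: MoleculeRecord, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan (circular) fingerprint as a uint8 0/1 vector, stored on the record.

    Deterministic for a given molecule: SMILES is canonicalized by RDKit,
    so "CCO" and "OCC" give identical vectors.
    """
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    mol = _mol_from_smiles(record.smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = np.array(gen.GetFingerprint(mol), dtype=np.uint8)
    record.fingerprint = fp
    return fp


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity between two binary fingerprints.

    Two all-zero vectors are defined to be identical (similarity 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def prepare_library(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """compute_descriptors over a whole library (convenience)."""
    return [compute_descriptors(r) for r in records]


def library_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Tabular view (id, smiles, mw, heavy_atoms, heteroatoms, logp)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "mw": [r.mw for r in records],
            "heavy_atoms": [r.heavy_atoms for r in records],
            "heteroatoms": [r.heteroatoms for r in records],
            "logp": [r.logp for r in records],
        }
    )


def frame_to_library(df: pd.DataFrame) -> list[MoleculeRecord]:
    """Inverse of :func:`library_to_frame`; descriptor columns optional."""
    have_desc = {"mw", "heavy_atoms", "heteroatoms", "logp"} <= set(df.columns)
    records = []
    for _, row in df.iterrows():
        rec = MoleculeRecord(id=str(row["id"]), smiles=str(row["smiles"]))
        if have_desc:
            rec.mw = float(row["mw"])
            rec.heavy_atoms = int(row["heavy_atoms"])
            rec.heteroatoms = int(row["heteroatoms"])
            rec.logp = float(row["logp"])
        records.append(rec)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids: {dup}")
    return records
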