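"""Docking-score ingestion and ligand-efficiency rescoring.

Empirical docking scoring functions of the Vina family (Vinardo here)
tend to reward sheer molecular size: heavier molecules make more
contacts and receive more negative scores, while the entropic penalty is
under-estimated. Dividing the raw score by a function of the heavy-atom
count (HA) corrects this bias, in the spirit of ligand efficiency:

    LE   = score / HA
    LEln = score / (1 + ln HA)
    LESA = score / HA^(2/3)

Scores are more negative = stronger predicted binding throughout, and
downstream logic always consumes best-first *ranks*, never sign-flipped
scores.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .library import MoleculeRecord

logger = logging.getLogger(__name__)

RAW_METHOD = "vinardo_raw"
RESCORE_METHODS = ("LE", "LEln", "LESA")
METHODS = (RAW_METHOD,) + RESCORE_METHODS


@dataclass
class ScoreTable:
    """Per-receptor molecule → docking score map with method provenance."""

    receptor_id: str
    method: str
    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown scoring method {self.method!r}")
        for mol_id, score in self.entries.items():
            if not mol_id:
                raise ValueError("empty molecule id in score table")
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for {mol_id!r}")


@dataclass
class RankedList:
    """Best-first ordering of a ScoreTable (rank 1 = most negative score)."""

    receptor_id: str
    method: str
    order: list[str]
    rank: dict[str, int]
    scores: dict[str, float]

    def __len__(self) -> int:
        return len(self.order)


def _parse_smina_log(path: Path) -> dict[str, float]:
    """Best (first-row) affinity per molecule block of a smina-style log.

    Molecule blocks are introduced by ``Ligand: <id>`` marker lines; a
    file without markers is read as a single molecule named by the file
    stem. The first row after each ``mode | affinity`` header is the
    best pose.
    """
    entries: dict[str, float] = {}
    current = path.stem
    in_table = False
    got_affinity = False
    row_re = re.compile(r"^\s*\d+\s+(-?\d+(?:\.\d+)?)\s")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        lig = re.match(r"^\s*Ligand:\s*(\S+)", line)
        if lig:
            current = lig.group(1)
            in_table = False
            got_affinity = False
            continue
        if re.match(r"^\s*mode\s*\|\s*affinity", line):
            in_table = True
            continue
        if in_table and not got_affinity:
            m = row_re.match(line)
            if m:
                score = float(m.group(1))
                if current in entries:
                    if score < entries[current]:
                        logger.warning("%s: duplicate block for %s, keeping best", path, current)
                        entries[current] = score
                else:
                    entries[current] = score
                got_affinity = True
            elif re.match(r"^\s*\d+\s", line):
                raise ValueError(f"{path}:{lineno}: non-numeric affinity in {line!r}")
    if not entries:
        raise ValueError(f"{path}: no parseable affinity found")
    return entries


def parse_scores(
    paths: Sequence[str | Path], dialect: str = "table"
) -> list[ScoreTable]:
    """Read raw docking scores into per-receptor ScoreTables.

    ``table`` files are CSV/TSV with columns receptor, molecule, score;
    duplicate (receptor, molecule) rows keep the most negative score
    with a warning. ``smina_log`` files each hold one receptor's log,
    receptor id = file stem.
    """
    per_receptor: dict[str, dict[str, float]] = {}
    if dialect == "table":
        for path in paths:
            path = Path(path)
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
            df = pd.read_csv(path, sep=sep)
            missing = {"receptor", "molecule", "score"} - set(df.columns)
            if missing:
                raise ValueError(f"{path}: missing columns {sorted(missing)}")
            for i, row in df.iterrows():
                try:
                    score = float(row["score"])
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: row {i}: non-numeric score {row['score']!r}") from exc
                if not math.isfinite(score):
                    raise ValueError(f"{path}: row {i}: non-finite score")
                rec, mol = str(row["receptor"]), str(row["molecule"])
                table = per_receptor.setdefault(rec, {})
                if mol in table:
                    logger.warning("%s: duplicate score for (%s, %s); keeping best", path, rec, mol)
                    score = min(score, table[mol])
                table[mol] = score
    elif dialect == "smina_log":
        for path in paths:
            path = Path(path)
            per_receptor.setdefault(path.stem, {}).update(_parse_smina_log(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return [
        ScoreTable(receptor_id=rec, method=RAW_METHOD, entries=entries)
        for rec, entries in sorted(per_receptor.items())
    ]


def rescore(
    table: ScoreTable, library: Sequence[MoleculeRecord] | Mapping[str, int], method: str
) -> ScoreTable:
    """Apply a heavy-atom-weighted rescoring function to a raw table.

    *library* may be a list of MoleculeRecords or a molecule→HA mapping.
    """
    if table.method != RAW_METHOD:
        raise ValueError(f"rescore expects a {RAW_METHOD} table, got {table.method!r}")
    if method not in RESCORE_METHODS:
        raise ValueError(f"unknown rescoring method {method!r}")
    if isinstance(library, Mapping):
        ha_map = dict(library)
    else:
        ha_map = {r.id: r.heavy_atoms for r in library}

    out: dict[str, float] = {}
    for mol_id, score in table.entries.items():
        ha = ha_map.get(mol_id)
        if ha is None:
            raise KeyError(f"molecule {mol_id!r} missing from library")
        if ha < 1:
            raise ValueError(f"molecule {mol_id!r} has heavy-atom count {ha} < 1")
        if method == "LE":
            out[mol_id] = score / ha
        elif method == "LEln":
            out[mol_id] = score / (1.0 + math.log(ha))
        else:  # LESA
            out[mol_id] = score / ha ** (2.0 / 3.0)
    return ScoreTable(receptor_id=table.receptor_id, method=method, entries=out)


def rank(table: ScoreTable) -> RankedList:
    """Best-first ranking; ties broken lexicographically by molecule id."""
    if not table.entries:
        raise ValueError("cannot rank an empty score table")
    order = sorted(table.entries, key=lambda m: (table.entries[m], m))
    return RankedList(
        receptor_id=table.receptor_id,
        method=table.method,
        order=order,
        rank={m: i + 1 for i, m in enumerate(order)},
        scores=dict(table.entries),
    )


def rescored_frame(
    raw_tables: Sequence[ScoreTable], library: Sequence[MoleculeRecord] | Mapping[str, int]
) -> pd.DataFrame:
    """All-methods table: receptor, molecule, raw, LE, LEln, LESA + ranks."""
    rows = []
    for raw in raw_tables:
        per_method = {RAW_METHOD: raw}
        for m in RESCORE_METHODS:
            per_method[m] = rescore(raw, library, m)
        ranks = {m: rank(t).rank for m, t in per_method.items()}
        for mol in sorted(raw.entries):
            row = {"receptor": raw.receptor_id, "molecule": mol, "raw": raw.entries[mol]}
            for m in RESCORE_METHODS:
                row[m] = per_method[m].entries[mol]
            for m in METHODS:
                row[f"rank_{m}"] = ranks[m][mol]
            rows.append(row)
    return pd.DataFrame(rows)


def tables_from_frame(df: pd.DataFrame, method: str) -> list[ScoreTable]:
    """Extract per-receptor ScoreTables for one method from a rescored frame."""
    col = "raw" if method == RAW_METHOD else method
    if col not in df.columns:
        raise ValueError(f"column {col!r} not in frame")
    out = []
    for rec, sub in df.groupby("receptor"):
        entries = dict(zip(sub["molecule"].astype(str), sub[col].astype(float)))
        out.append(ScoreTable(receptor_id=str(rec), method=method, entries=entries))
    return sorted(out, key=lambda t: t.receptor_id)
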