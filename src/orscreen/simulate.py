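"""Synthetic libraries, docking-score panels and pocket tables.

Every stage of the screening workflow can be exercised without external
data. The score model captures the statistical structure the workflow
assumes about real docking output:

* raw scores improve (grow more negative) with molecular size
  (``ha_bias`` per heavy atom) regardless of activity — the size bias
  that ligand-efficiency rescoring is meant to remove;
* true binders gain an additional per-heavy-atom improvement
  (``binder_effect``) and are planted among the smaller molecules of
  the library (``binder_ha_quantile``), mirroring the volatile-sized
  ligands of odorant receptors — which is exactly why raw size-biased
  scores rank them poorly;
* planted decoys receive the binder-effect improvement on *every*
  receptor while being labeled inactive everywhere — systematic
  over-scoring, not biology;
* Gaussian noise (``background_sd``) on every (receptor, molecule)
  score.

Molecules are assembled from a small volatile-like fragment grammar
(alkyl/alkenyl chains terminated by ester, phenol, aldehyde, acid or
aromatic groups), giving valid, parseable, unique SMILES with an exact
target heavy-atom count. All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ACTIVE, INACTIVE, NON_PHEROMONAL, ActivityMatrix
from .library import MoleculeRecord, compute_descriptors
from .pocket import STANDARD_DESCRIPTORS
from .rescoring import RAW_METHOD, ScoreTable

# (SMILES suffix appended to an alkyl chain, heavy atoms it adds)
_TAILS: tuple[tuple[str, int], ...] = (
    ("O", 1),              # alcohol
    ("C=O", 2),            # aldehyde
    ("OC", 2),             # methyl ether
    ("C(=O)O", 3),         # carboxylic acid
    ("C(C)=O", 3),         # methyl ketone
    ("OC=O", 3),           # formate ester
    ("C(=O)OC", 4),        # methyl ester
    ("OC(C)=O", 4),        # acetate ester
    ("c1ccco1", 5),        # furan
    ("C(=O)OCC", 5),       # ethyl ester
    ("c1ccccc1", 6),       # phenyl
    ("C1CCCCC1", 6),       # cyclohexyl
    ("c1ccc(O)cc1", 7),    # phenol
    ("c1ccc(C)cc1", 7),    # tolyl
    ("c1ccc(OC)cc1", 8),   # methoxyphenol ether
)
# chain-growing tokens: linear, ether link, branches, unsaturation
_CHAIN_TOKENS: tuple[tuple[str, int], ...] = (
    ("C", 1), ("C", 1), ("C", 1),
    ("C(C)", 2), ("C=C", 2), ("C(=C)", 2), ("OC", 2),
)


def _random_smiles(rng: np.random.Generator, target_ha: int) -> str:
    """One random volatile-like SMILES with exactly *target_ha* heavy atoms."""
    if target_ha < 2:
        raise ValueError("target heavy-atom count must be >= 2")
    eligible = [(s, o) for s, o in _TAILS if o <= target_ha - 1]
    tail, overhead = eligible[rng.integers(len(eligible))]
    budget = target_ha - overhead
    chain: list[str] = []
    while budget > 0:
        tokens = [(s, h) for s, h in _CHAIN_TOKENS if h <= budget]
        tok, h = tokens[rng.integers(len(tokens))]
        chain.append(tok)
        budget -= h
    return "".join(chain) + tail


def generate_library(
    n: int,
    seed: int = 0,
    ha_targets: Sequence[int] | None = None,
    ha_range: tuple[int, int] = (5, 18),
) -> list[MoleculeRecord]:
    """Generate *n* unique, valid molecules with descriptors populated.

    ``ha_targets`` pins the heavy-atom count of each molecule (len n);
    otherwise counts are drawn uniformly from ``ha_range``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if ha_targets is not None and len(ha_targets) != n:
        raise ValueError("ha_targets must have length n")

    width = len(str(n))
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    i = 0
    while len(records) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError(f"could not assemble {n} unique molecules")
        target = (
            int(ha_targets[len(records)])
            if ha_targets is not None
            else int(rng.integers(ha_range[0], ha_range[1] + 1))
        )
        smi = _random_smiles(rng, target)
        rec = compute_descriptors(MoleculeRecord(id=f"mol{len(records):0{width}d}", smiles=smi))
        if rec.smiles in seen:
            continue
        assert rec.heavy_atoms == target  # grammar accounting is exact
        seen.add(rec.smiles)
        records.append(rec)
        i += 1
    return records


@dataclass(frozen=True)
class ScreenSimulationConfig:
    """Conditions of a simulated docking screen.

    Defaults emulate a desk-scale version of a moth odorant-receptor
    panel: 15 non-pheromonal receptors, a few hundred volatile-sized
    molecules, raw scores in the -2..-6 kcal/mol-like range dominated
    by molecular size, with ~10% true binders per receptor and a few
    percent of systematically over-scored decoys.
    """

    n_receptors: int = 15
    n_molecules: int = 500
    frac_binders: float = 0.10
    frac_decoys: float = 0.03
    ha_range: tuple[int, int] = (6, 22)
    background_mean: float = -0.5
    background_sd: float = 1.0
    ha_bias: float = 0.25
    binder_effect: float = 0.15
    binder_ha_quantile: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.frac_binders < 1 and 0 < self.frac_decoys < 1):
            raise ValueError("fractions must be in (0, 1)")
        if not 0 < self.binder_ha_quantile <= 1:
            raise ValueError("binder_ha_quantile must be in (0, 1]")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if not (1 <= self.ha_range[0] <= self.ha_range[1] <= 25):
            raise ValueError("ha_range must lie within [1, 25]")
        if self.n_receptors < 1 or self.n_molecules < 2:
            raise ValueError("need >= 1 receptor and >= 2 molecules")


def simulate_screen(
    config: ScreenSimulationConfig,
) -> tuple[list[MoleculeRecord], dict[str, ScoreTable], ActivityMatrix]:
    """Simulate a docking screen under *config*.

    Returns the molecule library, one raw ScoreTable per receptor, and
    the ground-truth activity matrix. Identical config (including seed)
    gives bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    ha_targets = rng.integers(
        config.ha_range[0], config.ha_range[1] + 1, size=config.n_molecules
    )
    library = generate_library(
        config.n_molecules,
        seed=int(rng.integers(2**31)),
        ha_targets=[int(h) for h in ha_targets],
    )
    mol_ids = [r.id for r in library]
    ha = {r.id: r.heavy_atoms for r in library}
    receptors = [f"R{i:02d}" for i in range(1, config.n_receptors + 1)]

    n_decoys = int(round(config.frac_decoys * config.n_molecules))
    decoy_ids = set(rng.choice(mol_ids, size=n_decoys, replace=False)) if n_decoys else set()
    # binders are volatile-sized: drawn from the smaller end of the library
    ha_cutoff = float(np.quantile(list(ha.values()), config.binder_ha_quantile))
    candidates = [m for m in mol_ids if m not in decoy_ids and ha[m] <= ha_cutoff]
    n_binders = max(1, int(round(config.frac_binders * config.n_molecules)))
    n_binders = min(n_binders, len(candidates))

    binders: dict[str, set[str]] = {
        rec: set(rng.choice(candidates, size=n_binders, replace=False)) for rec in receptors
    }

    tables: dict[str, ScoreTable] = {}
    labels: dict[tuple[str, str], str] = {}
    for rec in receptors:
        noise = rng.normal(0.0, config.background_sd, size=config.n_molecules)
        entries: dict[str, float] = {}
        for mol, eps in zip(mol_ids, noise):
            score = config.background_mean - config.ha_bias * ha[mol] + eps
            boosted = mol in binders[rec] or mol in decoy_ids
            if boosted:
                score -= config.binder_effect * ha[mol]
            entries[mol] = float(score)
            labels[(rec, mol)] = ACTIVE if mol in binders[rec] else INACTIVE
        tables[rec] = ScoreTable(receptor_id=rec, method=RAW_METHOD, entries=entries)

    truth = ActivityMatrix(
        receptor_class={rec: NON_PHEROMONAL for rec in receptors}, labels=labels
    )
    return library, tables, truth


#: Uniform sampling ranges of the synthetic pocket descriptors, chosen to
#: bracket cavity volumes around the few-hundred-A^3 scale of insect OR
#: binding pockets.
POCKET_RANGES = {
    "volume": (200.0, 700.0),        # A^3
    "sasa": (250.0, 800.0),          # A^2
    "hydrophobicity": (5.0, 45.0),   # cavity-tool score, unitless
    "polarity": (2.0, 20.0),         # cavity-tool score, unitless
}


def simulate_pockets(
    n_receptors: int,
    beta: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    integerize: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pocket descriptors plus counts from a known linear model.

    *beta* is (intercept, volume, sasa, hydrophobicity, polarity).
    Counts are ``X @ beta + N(0, noise_sd)``, truncated at zero;
    ``integerize`` additionally rounds them to whole molecules (turn
    off for exact noise-free parameter-recovery checks).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(beta) != 1 + len(STANDARD_DESCRIPTORS):
        raise ValueError(f"beta must have length {1 + len(STANDARD_DESCRIPTORS)} (incl. intercept)")
    rng = np.random.default_rng(seed)
    receptors = [f"R{i:02d}" for i in range(1, n_receptors + 1)]
    data = {
        name: rng.uniform(*POCKET_RANGES[name], size=n_receptors)
        for name in STANDARD_DESCRIPTORS
    }
    df = pd.DataFrame(data, index=pd.Index(receptors, name="receptor"))
    X = df.to_numpy()
    y = float(beta[0]) + X @ np.asarray(beta[1:], dtype=float)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_receptors)
    y = np.clip(y, 0.0, None)
    if integerize:
        y = np.round(y)
    counts = {rec: float(v) for rec, v in zip(receptors, y)}
    return df, counts
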