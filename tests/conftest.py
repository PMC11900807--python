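import numpy as np
import pytest

from orscreen.calibration import ACTIVE, INACTIVE
from orscreen.library import MoleculeRecord, compute_descriptors, prepare_library
from orscreen.rescoring import RAW_METHOD, ScoreTable, rank
from orscreen.simulate import ScreenSimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_library():
    """Ten hand-checkable volatiles with descriptors populated."""
    smiles = {
        "ethanol": "CCO",
        "benzene": "c1ccccc1",
        "eugenol": "COc1cc(CC=C)ccc1O",
        "acetophenone": "CC(=O)c1ccccc1",
        "benzyl_formate": "O=COCc1ccccc1",
        "hexanal": "CCCCCC=O",
        "acetic_acid": "CC(=O)O",
        "limonene": "CC1=CCC(CC1)C(=C)C",
        "ethyl_acetate": "CCOC(C)=O",
        "phenol": "Oc1ccccc1",
    }
    return prepare_library(MoleculeRecord(k, v) for k, v in smiles.items())


@pytest.fixture(scope="session")
def sim_screen():
    """One simulated docking screen at the default study conditions."""
    return simulate_screen(ScreenSimulationConfig(seed=11))


def make_ranked(scores: dict[str, float], receptor: str = "R1", method: str = RAW_METHOD):
    return rank(ScoreTable(receptor_id=receptor, method=method, entries=scores))


def labels_by_rank(ranked, active_ranks: set[int]) -> dict[str, str]:
    """Label molecules active at the given 1-based ranks."""
    return {
        m: (ACTIVE if ranked.rank[m] in active_ranks else INACTIVE) for m in ranked.order
    }


def brute_force_auc(scores: dict[str, float], labels: dict[str, str]) -> float:
    """Pairwise Mann-Whitney oracle: enumerate every (active, inactive)
    pair; better (more negative) active score scores 1, ties 0.5."""
    actives = [scores[m] for m, lab in labels.items() if lab == ACTIVE]
    inactives = [scores[m] for m, lab in labels.items() if lab == INACTIVE]
    total = 0.0
    for a in actives:
        for b in inactives:
            if a < b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(actives) * len(inactives))


def random_instance(rng: np.random.Generator, n_max: int = 50):
    """Random scored/labeled instance with >=1 active and >=1 inactive;
    duplicate scores are likely, exercising tie handling."""
    n = int(rng.integers(3, n_max + 1))
    scores = {f"m{i}": float(rng.integers(-12, 0)) for i in range(n)}
    n_act = int(rng.integers(1, n))
    ids = list(scores)
    rng.shuffle(ids)
    labels = {m: (ACTIVE if m in set(ids[:n_act]) else INACTIVE) for m in scores}
    return scores, labels
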