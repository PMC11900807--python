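"""Chemical-space mapping of triaged molecule sets and candidate selection.

Morgan fingerprints are embedded to 2D with UMAP (n_neighbors=10,
min_dist=0.0 by default) and the embedded coordinates are clustered
with HDBSCAN (minimum cluster size 30 by default). Cluster coherence is
checked by comparing mean intra-cluster Tanimoto similarity against
the Tanimoto similarity between cluster medoids.

Candidate molecules for experimental testing are then drawn one per
cluster (best docking score, supplier-available), except clusters that
already contain a known ligand, which contribute up to five.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .library import tanimoto
from .rescoring import ScoreTable

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass
class ClusterAssignment:
    """2D embedding plus density-cluster labels for a molecule set."""

    embedding: dict[str, tuple[float, float]]
    labels: dict[str, int]  # cluster id >= 0, or NOISE
    n_neighbors: int
    min_dist: float
    min_cluster_size: int
    seed: int

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for mol, lab in self.labels.items():
            if lab != NOISE:
                out.setdefault(lab, []).append(mol)
        return {k: sorted(v) for k, v in sorted(out.items())}


def embed_and_cluster(
    fingerprints: Mapping[str, np.ndarray],
    n_neighbors: int = 10,
    min_dist: float = 0.0,
    min_cluster_size: int = 30,
    seed: int = 42,
    metric: str = "euclidean",
) -> ClusterAssignment:
    """UMAP to 2D, then HDBSCAN on the embedded coordinates.

    Molecules are processed in sorted-id order so the result is
    invariant to input ordering; the seed fixes the stochastic parts of
    the embedding. Fewer molecules than ``min_cluster_size`` yields
    all-noise labels. Cluster ids are relabeled to contiguous integers
    ordered by decreasing cluster size.
    """
    import umap  # deferred: heavy numba compilation on first import

    mols = sorted(fingerprints)
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules to embed")
    X = np.asarray([fingerprints[m] for m in mols], dtype=np.float32)
    if X.ndim != 2:
        raise ValueError("fingerprints have mismatched lengths")
    logger.info("embedding %d molecules (seed=%d)", len(mols), seed)

    nn = min(n_neighbors, len(mols) - 1)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=nn,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)

    if len(mols) < min_cluster_size:
        raw = np.full(len(mols), NOISE)
    else:
        raw = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(coords)

    # contiguous ids, largest cluster first, deterministic tie-break
    sizes: dict[int, int] = {}
    for lab in raw:
        if lab != NOISE:
            sizes[lab] = sizes.get(lab, 0) + 1
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order)}
    labels = {m: (NOISE if lab == NOISE else remap[lab]) for m, lab in zip(mols, raw)}

    return ClusterAssignment(
        embedding={m: (float(x), float(y)) for m, (x, y) in zip(mols, coords)},
        labels=labels,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        min_cluster_size=min_cluster_size,
        seed=seed,
    )


def _medoid(members: Sequence[str], fingerprints: Mapping[str, np.ndarray]) -> str:
    """Member maximizing mean Tanimoto similarity to its cluster."""
    best, best_sim = None, -1.0
    for m in members:
        sim = float(np.mean([tanimoto(fingerprints[m], fingerprints[o]) for o in members]))
        if sim > best_sim:
            best, best_sim = m, sim
    return best


@dataclass
class ConsistencyReport:
    """Intra- vs inter-cluster Tanimoto check."""

    intra_mean: dict[int, float | None]  # None for singleton clusters
    medoids: dict[int, str]
    inter_medoid: pd.DataFrame  # cluster x cluster Tanimoto between medoids
    passed: bool


def cluster_consistency(
    assignment: ClusterAssignment, fingerprints: Mapping[str, np.ndarray]
) -> ConsistencyReport:
    """Check that clusters are chemically coherent.

    Passes iff every cluster's mean intra-cluster Tanimoto exceeds
    every inter-cluster medoid Tanimoto involving it. Singleton
    clusters have undefined intra similarity (reported as None and not
    counted against the pass flag).
    """
    clusters = assignment.clusters
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for a consistency check")

    intra: dict[int, float | None] = {}
    medoids: dict[int, str] = {}
    for cid, members in clusters.items():
        medoids[cid] = _medoid(members, fingerprints)
        if len(members) < 2:
            intra[cid] = None
            continue
        sims = [
            tanimoto(fingerprints[a], fingerprints[b])
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        intra[cid] = float(np.mean(sims))

    cids = sorted(clusters)
    inter = pd.DataFrame(index=cids, columns=cids, dtype=float)
    for i in cids:
        for j in cids:
            inter.loc[i, j] = (
                1.0 if i == j else tanimoto(fingerprints[medoids[i]], fingerprints[medoids[j]])
            )

    passed = True
    for cid in cids:
        if intra[cid] is None:
            continue
        others = [inter.loc[cid, j] for j in cids if j != cid]
        if others and intra[cid] <= max(others):
            passed = False
    return ConsistencyReport(intra_mean=intra, medoids=medoids, inter_medoid=inter, passed=passed)


@dataclass
class CandidateSlate:
    """Cluster representatives proposed for experimental testing."""

    candidates: pd.DataFrame  # cluster, rank_in_cluster, molecule, score, flagged
    cluster_order: list[int]  # densest first


def select_candidates(
    triage_set: set[str],
    assignment: ClusterAssignment,
    scores: ScoreTable,
    known_ligands: set[str] = frozenset(),
    available: set[str] | None = None,
    top_k_known: int = 5,
) -> CandidateSlate:
    """Pick purchasable cluster representatives, best score first.

    Clusters holding a known ligand are flagged and contribute up to
    ``top_k_known`` available molecules; other clusters contribute one.
    Unavailable molecules are skipped in favor of the next-best of the
    same cluster. Noise molecules never enter the slate. Clusters are
    emitted densest-first.
    """
    if not triage_set:
        raise ValueError("empty triage set")
    clusters = {
        cid: [m for m in members if m in triage_set]
        for cid, members in assignment.clusters.items()
    }
    clusters = {cid: ms for cid, ms in clusters.items() if ms}
    if not clusters:
        raise ValueError("no clusters cover the triage set")
    missing = triage_set - set(assignment.labels)
    if missing:
        raise ValueError(f"triage set not fully clustered: {sorted(missing)[:5]}")

    order = sorted(clusters, key=lambda cid: (-len(clusters[cid]), cid))
    rows = []
    for cid in order:
        members = clusters[cid]
        flagged = any(m in known_ligands for m in members)
        pool = members if available is None else [m for m in members if m in available]
        pool = sorted(pool, key=lambda m: (scores.entries[m], m))  # best (most negative) first
        quota = top_k_known if flagged else 1
        for i, mol in enumerate(pool[:quota]):
            rows.append(
                {
                    "cluster": cid,
                    "rank_in_cluster": i + 1,
                    "molecule": mol,
                    "score": scores.entries[mol],
                    "flagged": flagged,
                }
            )
    return CandidateSlate(candidates=pd.DataFrame(rows), cluster_order=order)
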