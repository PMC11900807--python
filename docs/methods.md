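# Methods

`orscreen` implements a structure-based virtual-screening (SBVS) workflow
for insect odorant receptors (ORs): from a molecule library and
per-receptor docking-score tables it produces size-corrected rescored
rankings, calibrates them against an experimental activity panel,
triages the library into potential binders / suspected decoys /
potential non-binders, clusters candidate sets in chemical space to
pick diverse molecules for experimental testing, and fits a linear
model relating binding-pocket descriptors to receptor tuning breadth.
Docking itself (and receptor modeling, cavity detection, conformer
generation) is out of scope: scores and pocket descriptors enter as
data.

## Odorant-likeness filter

Volatile odorants occupy a narrow physicochemical window. Libraries are
reduced with four descriptors computed by RDKit from 2D structures:
molecular weight ≤ 400 g/mol, ≤ 25 heavy atoms, ≤ 10 heteroatoms
(atoms that are neither C nor H), and Crippen logP in [−1, 7]. All
bounds are inclusive ("not exceeding", "no more than" read as closed
intervals). The logP method is pinned to the Crippen atomic-contribution
estimate for reproducibility; different logP implementations move a few
percent of borderline molecules across the bound, which is why the
method is part of the configuration rather than an implementation
detail. Multi-fragment SMILES (salts) are reduced to their largest
fragment before descriptor computation. Invalid SMILES are skipped with
a warning at library load but raise in per-record operations.

## Ligand-efficiency rescoring

Empirical docking scores of the Vina family under-penalize molecular
size: each additional heavy atom adds contacts, so large molecules
accumulate more negative (better) scores regardless of activity, while
the entropic cost is mostly ignored. With raw Vinardo scores this makes
ranking nearly useless for receptors whose true ligands are small
volatiles. The correction divides the raw score s by a function of the
heavy-atom count HA:

    LE   = s / HA
    LEln = s / (1 + ln HA)
    LESA = s / HA^(2/3)

LE removes a strictly proportional size trend exactly; LEln and LESA
are softer corrections (LESA's 2/3 exponent corresponds to a
surface-area-like scaling). All three are strictly increasing in HA for
fixed s < 0 and preserve ranks within groups of equal-HA molecules.
More negative is better everywhere; downstream logic consumes ranks,
never sign-flipped scores. Ties are broken lexicographically by
molecule id so threshold cuts are reproducible.

## Calibration against an activity panel

Given per-receptor rankings and binary activity labels (or p-values
thresholded at p < 0.001, strict), the calibration computes:

- **ROC AUC** as the Mann-Whitney statistic — the fraction of
  (active, inactive) pairs in which the active molecule scores better,
  tied scores counting 0.5. Computed from midranks; an O(n²) pairwise
  oracle backs it in the tests.
- **Enrichment factor** EF(f) = (active rate in the best fraction f) /
  (overall active rate), with top-set size k = max(1, round-half-up
  (f·N)). The maximum EF is taken over the cutoff grid.
- **Optimal top fraction**: the grid fraction maximizing TPR/FPR, with
  a continuity correction FPR′ = 0.5/(#inactives) when no inactive is
  selected (avoids infinite ratios while preserving the ordering);
  ties go to the smallest fraction. The default grid is 1%…100% in 1%
  steps.
- **Non-binder fraction**: per receptor, the normalized rank at which
  the true-positive rate first reaches 1 (the rank of the worst-ranked
  active); the median over receptors defines the bottom fraction below
  which molecules are called potential non-binders.

Receptors carry a class tag. Pheromone receptors behave very
differently from non-pheromonal ones under raw scores (raw docking
already separates pheromone-receptor actives well), so threshold
derivation is restricted to the non-pheromonal class by default, and
medians (midpoint convention for even counts) are reported per class.
The scoring method used for threshold derivation defaults to the one
with the highest median AUC in that class; enrichment factors provide
the cross-check that the same method wins under both criteria.

## Triage

With the calibrated parameters (defaults: top fraction 0.06, decoy
frequency 0.7, bottom fraction 0.45):

1. per receptor, the top set is the best k = max(1, round(0.06·N))
   molecules;
2. a molecule's promiscuity frequency is the share of receptors whose
   top set contains it; molecules at frequency ≥ 0.7 (inclusive) are
   **suspected decoys** — systematic over-scoring is a more
   parsimonious explanation than genuine activity on 70% of a diverse
   receptor panel. Decoy status is global; the receptor subset over
   which frequency is computed is an explicit parameter;
3. **potential binders** per receptor are the top set minus decoys;
4. **potential non-binders** are the worst ⌊0.45·N⌋ ranks; everything
   else is unclassified.

With a single receptor the frequency is degenerate ({0,1}), so the
whole top set is flagged as decoys at any threshold ≤ 1 — documented
rather than special-cased.

Workflow predictions are scored against experimental outcomes as a 2×2
contingency (predicted binder × experimentally active); precision is
reported as a percentage, accuracy as a fraction, and undefined ratios
as absent rather than 0. On the bundled SlitOR25 validation panel
(19 predicted binders of which 2 active, plus 3 decoys and 5
non-binders, all inactive) this yields precision 10.5% and accuracy
0.370; on the SlitOR31 panel (17 binders, 1 active) precision 5.9%.

## Chemical space and candidate selection

Morgan radius-2 fingerprints (2048 bits) are embedded to 2D with UMAP
(n_neighbors = 10, min_dist = 0.0, Euclidean metric on raw bits,
configurable to Jaccard) and clustered with HDBSCAN (minimum cluster
size 30) on the embedded coordinates. Molecules are processed in
sorted-id order before embedding: UMAP is not strictly
order-equivariant even when seeded, and canonicalizing the order makes
the assignment invariant to input ordering by construction. The seed
(default 42) is recorded in the assignment; fewer points than the
minimum cluster size yield all-noise labels; cluster ids are relabeled
contiguously, largest first.

Cluster coherence is checked by comparing each cluster's mean
intra-cluster Tanimoto similarity to the Tanimoto similarity between
cluster medoids. The medoid (member maximizing mean similarity to its
cluster) stands in for the "centroid": a Tanimoto between averaged bit
vectors is ill-defined. The check passes when every cluster's intra
mean exceeds every inter-medoid similarity involving it; singleton
clusters have undefined intra similarity and are excluded. The Tanimoto
convention for two all-zero vectors is 1.0.

Candidates for purchase are drawn per cluster, densest clusters first:
one best-scoring available molecule per cluster, except clusters
containing a known ligand, which are flagged and contribute up to five.
Unavailable molecules are skipped in favor of the next-best in the same
cluster; noise molecules never enter the slate. Availability is an
input list (supplier catalogs are queried offline).

## Pocket-descriptor tuning model

A receptor's tuning breadth (number of active molecules among the
tested odorants, p < 0.001) is regressed by OLS on binding-pocket
descriptors: cavity volume (Å³), solvent-accessible surface area (Å²),
and the hydrophobicity/polarity scores of the cavity-analysis tool,
treated as opaque named columns. Reported metrics are in-sample —
Pearson r between fitted and observed counts, and RMSE in
molecule-count units — matching how such small-n (17 receptors) models
are usually summarized; a leave-one-out variant is available but not
the default. Counts are modeled as unbounded continuous responses (no
count GLM). Rank-deficient designs (duplicate, constant or collinear
columns) and constant responses raise with the offending columns
named. Adding variables never lowers in-sample r (nested OLS), which
the tests assert; the observed directions on synthetic data with the
published signs are: larger volume/SASA and lower hydrophobicity ⇒
fewer actives.

## Synthetic data generator

The generator exists so every stage can be exercised and calibrated
with known ground truth. Molecules are assembled from a volatile-like
fragment grammar — alkyl/alkenyl/ether chains terminated by alcohol,
aldehyde, acid, ketone, ester, furan or (methoxy)phenyl groups — giving
valid, unique SMILES with an exact target heavy-atom count. Docking
scores follow

    s(r, m) = background_mean − ha_bias·HA(m) + ε,   ε ~ N(0, background_sd²)

with an additional −binder_effect·HA(m) for (receptor, molecule) pairs
planted as binders. Planted decoys receive the binder-effect term on
*every* receptor but are labeled inactive everywhere, modeling decoys
as a scoring artifact rather than biology. Gaussian noise was chosen
for the analytic tractability of expected AUC. All generators are pure
functions of (config, seed).

Default study conditions: 15 non-pheromonal receptors × 500 molecules
of 6–22 heavy atoms, 10% binders per receptor, 3% decoys,
background_mean −0.5, ha_bias 0.25/atom (raw scores ≈ −2…−6),
background_sd 1.0, binder_effect 0.15/atom. Binders are planted among
the smaller molecules of the library (below the 0.4 heavy-atom
quantile): OR ligands are small volatiles (the validated ligand panels
average roughly 8–12 heavy atoms), and this size-activity structure is
exactly what makes raw size-biased scores fail and ligand-efficiency
rescoring succeed. Under these conditions raw scoring performs at
chance (median AUC ≈ 0.49), LE reaches ≈ 0.87 and is selected both by
median AUC and by median maximum enrichment factor, reproducing the
qualitative calibration structure of the real panel. The small score
intercept matters: a large intercept re-introduces a small-molecule
artifact into LE (tiny molecules ranked top regardless of activity — a
known failure mode of ligand-efficiency rescoring) and blurs the
method comparison.

The pocket generator draws descriptors uniformly from documented
ranges (volume 200–700 Å³, SASA 250–800 Å², hydrophobicity 5–45,
polarity 2–20), builds counts from a user-supplied linear coefficient
vector plus Gaussian noise, truncates at zero and rounds to whole
molecules. Truncation and rounding slightly bias coefficient recovery
at small n; the `integerize` flag disables rounding for exact
noise-free recovery checks, and recovery tests plant an intercept that
keeps the linear predictor away from the truncation boundary so that
OLS assumptions actually hold for the data generated.

What the generator does **not** emulate: real docking-score error is
neither Gaussian nor independent across receptors (shared poses,
shared scoring-function biases), chemical similarity between molecules
induces correlated scores, and activity is not a clean binary. Passing
tests on synthetic screens therefore demonstrate that the pipeline's
logic is correct and well-calibrated under its own assumptions — not
that any particular hit rate will be achieved on a real receptor.

## Problem sizes and numerical choices

Tests and the acceptance script run the synthetic screens at
15 × 500 (20 seeds for the scoring-function comparison) and the
end-to-end workflow at 5–6 receptors × 150–200 molecules with a reduced
minimum cluster size (4), which keeps full-pipeline runs comfortably
interactive while leaving every statistical conclusion unchanged at
larger sizes. Determinism is enforced end to end: a fixed top-level
seed, canonical sort orders before every stochastic step, fixed float
formatting in CSV output, and content hashes of every stage output in
the run manifest, which echoes the full configuration and input hashes
so a run can be reproduced from the manifest alone.

## Known limitations

- The workflow consumes best-pose scores per molecule; aggregation
  over stereoisomers/tautomers of a parent compound is keep-best by
  parent id.
- The promiscuity filter needs a reasonably large and diverse receptor
  panel; with few receptors the frequency estimate is coarse.
- In-sample regression metrics at n = 17 are optimistic; the
  leave-one-out option exists for a stricter view.
- The published per-receptor pocket-descriptor table is supplementary
  data not bundled here; the regression is validated by parameter
  recovery on synthetic tables, and the reference-table check runs
  only when a user supplies `data/slitor_pocket_descriptors.csv`.
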