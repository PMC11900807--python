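# orscreen

Structure-based virtual screening (SBVS) toolkit for insect odorant
receptors (ORs).

Insect ORs are odorant-gated ion channels whose ligands — small
volatile molecules — are mostly unknown outside a handful of model
receptors. Docking a large natural-product library into a predicted
receptor structure can propose new ligands without any prior knowledge
of the receptor's chemistry, but raw docking scores are badly
size-biased and cannot separate binders from non-binders on their own.
`orscreen` implements the downstream half of such a campaign, for
computational chemical ecologists and anyone triaging docking output
against small experimental panels:

- **Library preparation** — SMILES/SDF loading, RDKit descriptors, and
  the odorant-likeness filter (MW ≤ 400 g/mol, ≤ 25 heavy atoms,
  ≤ 10 heteroatoms, Crippen logP ∈ [−1, 7]).
- **Ligand-efficiency rescoring** of Vinardo-style docking scores s by
  heavy-atom count HA: LE = s/HA, LEln = s/(1 + ln HA),
  LESA = s/HA^(2/3).
- **Calibration** against a receptor × odorant activity panel: ROC AUC
  (Mann-Whitney, ties at 0.5), enrichment factors
  EF(f) = (actives in top f)/(f · overall active rate), and the
  top-fraction cutoff maximizing TPR/FPR.
- **Triage** into *potential binders* (top 6%, decoys removed),
  *suspected decoys* (molecules in the top 6% of ≥ 70% of receptors —
  scoring artifacts, not polypharmacology), and *potential
  non-binders* (bottom 45%), plus precision/accuracy scoring of
  predictions against experimental outcomes.
- **Chemical-space clustering** of Morgan fingerprints (UMAP 2D +
  HDBSCAN), Tanimoto consistency checks, and selection of purchasable
  cluster representatives.
- **Pocket tuning model** — OLS predicting a receptor's number of
  active molecules from binding-pocket descriptors (volume, SASA,
  hydrophobicity, polarity).
- **Synthetic data** — seeded generators for libraries, score panels
  with planted binders/decoys, and pocket tables, so the whole
  pipeline is testable with known ground truth.

Docking itself, receptor modeling and cavity detection are external;
their outputs are consumed as plain CSV/text.

## Worked example

Score a simulated screen end to end:

```bash
orscreen simulate screen --seed 7 --out sim/
orscreen run --config run.yaml
```

with `run.yaml`:

```yaml
library_path: sim/library.csv
scores_path: sim/scores.csv
activity_path: sim/activity.csv
out_dir: sim/run
min_cluster_size: 4
seed: 42
```

which prints the screening funnel:

```json
{
  "loaded": 500,
  "filtered": 495,
  "scored": 495,
  "potential_binders_union": 187,
  "suspected_decoys": 0,
  "candidates_total": 35
}
```

500 generated molecules enter; 495 survive the odorant-likeness filter;
after LE rescoring (chosen automatically by median AUC against the
activity panel), each receptor's top 6% (30 molecules) is screened for
promiscuity — at this simulation's default decoy strength no molecule
reaches the 0.7-frequency flag — leaving 187 distinct potential binders
across the 15 receptors, clustered into per-receptor candidate slates
of best-scoring representatives (35 candidates in total).
`sim/run/manifest.json`
records the full configuration, input hashes and per-output content
hashes; rerunning with the same seed reproduces the hashes bit for bit.

Scoring the published SlitOR25 in vivo validation panel (19 predicted
binders tested, 2 active; 3 suspected decoys and 5 potential
non-binders, all inactive):

```python
>>> from orscreen.panels import SLITOR25_PANEL
>>> from orscreen.triage import evaluate_predictions
>>> ev = evaluate_predictions(*SLITOR25_PANEL)
>>> round(ev.precision_pct, 1), round(ev.accuracy, 3)
(10.5, 0.37)
```

i.e. 10.5% of the predicted binders were experimentally active, and
none of the molecules discarded as decoys or non-binders were active.

## Layout

```
src/orscreen/
  library.py     molecule records, descriptors, filter, fingerprints
  rescoring.py   score parsing, LE/LEln/LESA, ranking
  calibration.py ROC/EF calibration, threshold optimization
  triage.py      binder/decoy/non-binder partition, prediction scoring
  chemspace.py   UMAP+HDBSCAN clustering, consistency, candidate slates
  pocket.py      tuning-breadth regression
  simulate.py    synthetic libraries, screens, pocket tables
  panels.py      bundled SlitOR25/SlitOR31 validation outcomes
  workflow.py    filter→rescore→calibrate→triage→cluster→select runner
  cli.py         the `orscreen` command line
docs/methods.md  model assumptions, parameter choices, limitations
```
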