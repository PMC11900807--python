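"""End-to-end screening workflow: filter -> rescore -> (calibrate) ->
triage -> cluster -> select, with a reproducible run manifest.

All interchange between stages is via files; the manifest echoes the
full configuration, the molecule count surviving each stage (the
screening funnel) and content hashes of every output, so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, chemspace, library, rescoring
from .triage import triage as run_triage, triage_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full workflow run. Defaults are the published
    screening-protocol values."""

    library_path: str = ""
    scores_path: str = ""
    activity_path: str = ""       # optional calibration panel
    classes_path: str = ""        # optional receptor-class tags (YAML)
    out_dir: str = "orscreen_run"

    # odorant-likeness filter
    mw_max: float = 400.0
    heavy_atoms_max: int = 25
    heteroatoms_max: int = 10
    logp_min: float = -1.0
    logp_max: float = 7.0

    # rescoring and triage
    method: str = "LE"
    top_fraction: float = 0.06
    promiscuity_threshold: float = 0.7
    bottom_fraction: float = 0.45

    # chemical space
    n_neighbors: int = 10
    min_dist: float = 0.0
    min_cluster_size: int = 30
    fingerprint_bits: int = 2048

    seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def limits(self) -> library.FilterLimits:
        return library.FilterLimits(
            mw_max=self.mw_max,
            heavy_atoms_max=self.heavy_atoms_max,
            heteroatoms_max=self.heteroatoms_max,
            logp_min=self.logp_min,
            logp_max=self.logp_max,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float format so reruns are byte-identical
    df.to_csv(path, index=False, float_format="%.10g")


def run_workflow(config: RunConfig) -> dict:
    """Execute the workflow; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}
    outputs: list[Path] = []
    stage = "load"
    try:
        records = library.prepare_library(
            library.load_library(config.library_path, format="smiles_table")
        )
        funnel["loaded"] = len(records)

        stage = "filter"
        passed, rejected = library.physchem_filter(records, config.limits())
        funnel["filtered"] = len(passed)
        passed_path = out / "passed.csv"
        _write_csv(library.library_to_frame(passed), passed_path)
        rej = pd.DataFrame(
            {"id": [r.id for r, _ in rejected], "reasons": ["|".join(rs) for _, rs in rejected]}
        )
        rejects_path = out / "rejects.csv"
        _write_csv(rej, rejects_path)
        outputs += [passed_path, rejects_path]

        stage = "rescore"
        if not config.scores_path:
            raise ValueError("config missing the scores path")
        raw_tables = rescoring.parse_scores([config.scores_path], dialect="table")
        kept_ids = {r.id for r in passed}
        raw_tables = [
            rescoring.ScoreTable(
                receptor_id=t.receptor_id,
                method=t.method,
                entries={m: s for m, s in t.entries.items() if m in kept_ids},
            )
            for t in raw_tables
        ]
        frame = rescoring.rescored_frame(raw_tables, passed)
        rescored_path = out / "rescored.csv"
        _write_csv(frame, rescored_path)
        outputs.append(rescored_path)
        funnel["scored"] = frame["molecule"].nunique()

        stage = "calibrate"
        chosen_method = config.method
        if config.activity_path:
            activity = calibration.ActivityMatrix.from_frame(
                pd.read_csv(config.activity_path),
                receptor_class=(
                    yaml.safe_load(Path(config.classes_path).read_text())
                    if config.classes_path
                    else None
                ),
            )
            tables: dict[str, dict[str, rescoring.ScoreTable]] = {}
            for m in rescoring.METHODS:
                for t in rescoring.tables_from_frame(frame, m):
                    tables.setdefault(t.receptor_id, {})[m] = t
            report = calibration.calibrate(tables, activity)
            (out / "calibration.json").write_text(report.to_json())
            outputs.append(out / "calibration.json")
            chosen_method = report.chosen_method

        stage = "triage"
        method_tables = rescoring.tables_from_frame(frame, chosen_method)
        ranked = {t.receptor_id: rescoring.rank(t) for t in method_tables}
        result = run_triage(
            ranked,
            top_fraction=config.top_fraction,
            promiscuity_threshold=config.promiscuity_threshold,
            bottom_fraction=config.bottom_fraction,
        )
        tri_frame = triage_frame(result, ranked)
        triage_path = out / "triage.csv"
        _write_csv(tri_frame, triage_path)
        outputs.append(triage_path)
        funnel["potential_binders_union"] = len(
            set().union(*result.potential_binders.values())
        )
        funnel["suspected_decoys"] = len(result.suspected_decoys)

        stage = "cluster"
        by_id = {r.id: r for r in passed}
        slates = {}
        for rec in sorted(result.potential_binders):
            binder_set = result.potential_binders[rec]
            if len(binder_set) < 2:
                logger.warning("receptor %s: <2 potential binders, skipping clustering", rec)
                continue
            fps = {
                m: library.fingerprint(by_id[m], n_bits=config.fingerprint_bits)
                for m in sorted(binder_set)
            }
            assignment = chemspace.embed_and_cluster(
                fps,
                n_neighbors=config.n_neighbors,
                min_dist=config.min_dist,
                min_cluster_size=config.min_cluster_size,
                seed=config.seed,
            )
            emb = pd.DataFrame(
                {
                    "molecule": sorted(fps),
                    "x": [assignment.embedding[m][0] for m in sorted(fps)],
                    "y": [assignment.embedding[m][1] for m in sorted(fps)],
                    "cluster": [assignment.labels[m] for m in sorted(fps)],
                }
            )
            cluster_path = out / f"clusters_{rec}.csv"
            _write_csv(emb, cluster_path)
            outputs.append(cluster_path)

            stage = "select"
            scores = next(t for t in method_tables if t.receptor_id == rec)
            clustered = {m for m, lab in assignment.labels.items() if lab != chemspace.NOISE}
            if clustered:
                slate = chemspace.select_candidates(clustered, assignment, scores)
                slate_path = out / f"slate_{rec}.csv"
                _write_csv(slate.candidates, slate_path)
                outputs.append(slate_path)
                slates[rec] = len(slate.candidates)
        funnel["candidates_total"] = sum(slates.values())
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "funnel": funnel,
        "input_hashes": {
            p: _sha256(Path(p))
            for p in (config.library_path, config.scores_path, config.activity_path)
            if p
        },
        "output_hashes": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
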