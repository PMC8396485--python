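"""End-to-end orchestration: trajectory → occurrence statistics → frequent
models → merged per-ligand models → final merged model → validation screen.

Every stage delegates to the corresponding analysis module; this module
only sequences them, writes the artifacts (CSV/JSON) and logs wall times.
All outputs are reproducible bit-identically for a given config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientModelsError
from .interaction_analysis import (
    GeometricRules,
    build_model_ensemble,
    last_fraction_window,
    occurrence_table,
    select_frequent_models,
)
from .io_structures import Trajectory, downsample, write_pharmacophore
from .pharmacophore_build import (
    FlagsSpec,
    PharmacophoreModel,
    build_final_model,
    merge_models,
)
from .screening import (
    ScreenSettings,
    enrichment_metrics,
    ranked_records,
    roc_points,
    screen_library,
)
from .trajectory_metrics import (
    align_to_first_frame,
    pairwise_ligand_rmsd,
    ring_distance_series,
    rmsf_per_residue,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the standard workflow.

    ``frames`` — evenly distributed frames analyzed per trajectory;
    ``window_frac`` — trailing fraction used for model building (the last
    20% of a production run by default); ``top_k_models`` — number of most
    frequent per-frame models merged per ligand.
    """

    frames: int = 500
    window_frac: float = 0.2
    top_k_models: int = 4
    merge_tol: float = 1.5
    align_min_pairs: int = 3
    align_tol: float = 1.5
    pairwise_samples: int = 5000
    ef_fractions: tuple = (0.01, 0.05, 0.1)
    seed: int = 0
    rules: GeometricRules = field(default_factory=GeometricRules)
    flags: FlagsSpec = field(default_factory=FlagsSpec)
    screen: ScreenSettings = field(default_factory=ScreenSettings)

    def __post_init__(self):
        if not 0 < self.window_frac <= 1:
            raise ValueError("window_frac must be in (0, 1]")
        if self.top_k_models < 1:
            raise ValueError("top_k_models must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        nested = {}
        if "rules" in data:
            nested["rules"] = GeometricRules(**data.pop("rules"))
        if "flags" in data:
            nested["flags"] = FlagsSpec(**data.pop("flags"))
        if "screen" in data:
            nested["screen"] = ScreenSettings(**data.pop("screen"))
        if "ef_fractions" in data:
            data["ef_fractions"] = tuple(data["ef_fractions"])
        return cls(**data, **nested)


def _stage(logbook: list, name: str, t0: float, artifact=None):
    logbook.append({"stage": name, "wall_s": round(time.perf_counter() - t0, 4),
                    "artifact": str(artifact) if artifact else None})


def run_complex_analysis(traj: Trajectory, config: Optional[PipelineConfig] = None,
                         outdir="analysis") -> dict:
    """Full single-complex analysis; returns a dict of artifact paths."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    logbook: list = []

    t0 = time.perf_counter()
    if traj.n_frames > config.frames:
        traj = downsample(traj, config.frames)
    traj = align_to_first_frame(traj)
    _stage(logbook, "preprocess", t0)

    window = last_fraction_window(traj.n_frames, config.window_frac)

    t0 = time.perf_counter()
    occ = occurrence_table(traj, config.rules, window)
    paths["occurrence"] = outdir / "occurrence.csv"
    occ.to_csv(paths["occurrence"])
    _stage(logbook, "occurrence_table", t0, paths["occurrence"])

    t0 = time.perf_counter()
    ensemble = build_model_ensemble(traj, config.rules, window)
    hist = ensemble.histogram
    hist_df = pd.DataFrame(
        [{"signature": json.dumps(sig), "n_features": len(sig), "count": count}
         for sig, count in sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))])
    paths["histogram"] = outdir / "model_histogram.csv"
    hist_df.to_csv(paths["histogram"], index=False)
    _stage(logbook, "model_histogram", t0, paths["histogram"])

    t0 = time.perf_counter()
    frequent = select_frequent_models(ensemble, min(config.top_k_models, max(len(hist), 1)))
    merged = merge_models(frequent, tol=config.merge_tol)
    paths["merged_model"] = outdir / "merged_model.json"
    write_pharmacophore(merged, paths["merged_model"])
    _stage(logbook, "merge_models", t0, paths["merged_model"])

    t0 = time.perf_counter()
    rmsf = rmsf_per_residue(traj)
    paths["rmsf"] = outdir / "rmsf.csv"
    rmsf.to_csv(paths["rmsf"], index=False)
    _stage(logbook, "rmsf", t0, paths["rmsf"])

    t0 = time.perf_counter()
    matrix = pairwise_ligand_rmsd(traj, min(config.pairwise_samples, traj.n_frames))
    paths["pairwise_rmsd"] = outdir / "pairwise_rmsd.csv"
    np.savetxt(paths["pairwise_rmsd"], matrix, delimiter=",", fmt="%.6f")
    _stage(logbook, "pairwise_rmsd", t0, paths["pairwise_rmsd"])

    t0 = time.perf_counter()
    pairs = _aromatic_pairs(traj)
    if pairs:
        series = ring_distance_series(traj, pairs)
        paths["ring_distances"] = outdir / "ring_distances.csv"
        series.table.to_csv(paths["ring_distances"], index=False)
        _stage(logbook, "ring_distances", t0, paths["ring_distances"])

    paths["log"] = outdir / "analysis_log.json"
    Path(paths["log"]).write_text(json.dumps(logbook, indent=1))
    return paths


def _aromatic_pairs(traj: Trajectory):
    """Within-chain (aromatic, aromatic) residue pairs, e.g. the S5/S6
    phenyl rings whose centroid distance reports on side-chain rotation."""
    from .feature_perception import RING_ATOMS

    by_chain: dict[str, list] = {}
    seen = set()
    for i in traj.protein_indices:
        a = traj.atom_table[i]
        key = (a.chain, a.resid)
        if key in seen:
            continue
        seen.add(key)
        if a.resname in RING_ATOMS:
            by_chain.setdefault(a.chain, []).append((a.chain, a.resid))
    pairs = []
    for chain, residues in sorted(by_chain.items()):
        residues.sort()
        for r1, r2 in zip(residues, residues[1:]):
            pairs.append((r1, r2))
    return pairs


def run_final_model_build(merged_models: Sequence[PharmacophoreModel],
                          config: Optional[PipelineConfig] = None,
                          outdir="final_model",
                          exclusion_traj: Optional[Trajectory] = None) -> dict:
    """Build the final merged model from per-ligand merged models.

    Writes the final model JSON and an exclusion report naming un-alignable
    models with the failure reason. ``exclusion_traj`` optionally supplies
    a trajectory from which exclusion volumes are generated.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = build_final_model(list(merged_models), config.flags,
                               min_pairs=config.align_min_pairs,
                               align_tol=config.align_tol,
                               merge_tol=config.merge_tol)
    model = result.model
    if exclusion_traj is not None:
        from .pharmacophore_build import generate_exclusion_volumes

        window = last_fraction_window(exclusion_traj.n_frames, config.window_frac)
        model.exclusion_volumes = generate_exclusion_volumes(
            exclusion_traj, window, model=model)
    paths = {"final_model": outdir / "final_model.json",
             "exclusion_report": outdir / "exclusion_report.json"}
    write_pharmacophore(model, paths["final_model"])
    report = {
        "n_input_models": len(merged_models),
        "n_aligned": len(merged_models) - len(result.excluded),
        "excluded": [{"model": name, "reason": reason}
                     for name, reason in result.excluded],
    }
    Path(paths["exclusion_report"]).write_text(json.dumps(report, indent=1))
    return {**paths, "model": model, "result": result}


def run_validation(model: PharmacophoreModel, library, labels: dict,
                   config: Optional[PipelineConfig] = None,
                   outdir="validation") -> dict:
    """Screen a labelled library and write results, ROC points and metrics."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = screen_library(library, model, config.screen, labels=labels)
    metrics = enrichment_metrics(records, labels, fractions=config.ef_fractions)
    paths = {}
    df = pd.DataFrame(
        [{"id": r.molecule_id, "matched": r.matched,
          "score": "" if r.fit_score is None else round(r.fit_score, 4),
          "conformer": "" if r.conformer is None else r.conformer,
          "label": labels.get(r.molecule_id, r.label)}
         for r in ranked_records(records)])
    paths["results"] = outdir / "screen_results.csv"
    df.to_csv(paths["results"], index=False)
    pts = roc_points(records, labels)
    paths["roc"] = outdir / "roc.csv"
    np.savetxt(paths["roc"], pts, delimiter=",", header="fpr,tpr", comments="")
    payload = {
        "auc": metrics.auc,
        "ef": {str(f): v for f, v in metrics.ef.items()},
        "actives_retrieved": metrics.tp,
        "decoys_retrieved": metrics.fp,
        "n_actives": metrics.n_actives,
        "n_decoys": metrics.n_decoys,
        "n_library": metrics.n,
    }
    paths["metrics_json"] = outdir / "metrics.json"
    Path(paths["metrics_json"]).write_text(json.dumps(payload, indent=1))
    return {**paths, "metrics": metrics, "records": records}
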