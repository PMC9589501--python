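"""End-to-end pipeline: simulate -> waveforms -> structuring -> selection -> recognition.

Every stage draws its seed from the master seed through a stated counter
scheme (see :func:`stressfeat.io.stage_seed`), and all seeds are recorded in
the run manifest, so any stage can be replayed in isolation and a rerun with
the same configuration reproduces every artifact byte for byte (the manifest
itself differs only in wall-clock stage timings).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bpso import SwarmConfig, consensus_features, run_bpso
from .errors import ValidationError
from .grf import condition_trial, extract_event_value, pca_decompose, reconstruct_rank1, waveform_matrix
from .io import (
    FLOAT_FORMAT,
    RunConfig,
    RunManifest,
    sha256_of,
    stage_seed,
    write_feature_csv,
    write_grf_csv,
    write_stress_csv,
    write_waveform_csv,
)
from .recognition import ClassifierSpec, per_bone_report, total_accuracy
from .stress import (
    NodeSubsetSpec,
    build_feature_matrix,
    pareto_bins,
    percentile_bands,
    thin_ranks,
)
from .synth import gen_grf_trials, gen_stress_field

__all__ = ["run_pipeline"]

log = logging.getLogger("stressfeat")

# stage indices for the seed-derivation counter scheme (shared with the CLI)
STAGE_STRESS = 1
STAGE_GRF = 2
STAGE_SELECT = 3
STAGE_RECOG = 4


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline described by ``config``; return the manifest.

    Stages, in order: synthetic input generation (stress fields per
    comparison, GRF trials per landing height), GRF conditioning + PCA +
    principal-waveform event extraction, stress structuring per node-subset
    case, multi-seed BPSO selection per comparison x case with top-3
    consensus, cross-validated per-bone recognition, and the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    seeds: dict[str, int] = {}

    def _register(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = sha256_of(path)

    # ---- stage 1: synthetic inputs -------------------------------------
    t0 = time.perf_counter()
    fields_by_comparison = {}
    for i, comp in enumerate(config.comparisons):
        seed = stage_seed(config.seed, STAGE_STRESS * 100 + i)
        seeds[f"stress/{comp.name}"] = seed
        spec = config.stress_spec(comp, seed)
        fields_a, fields_b = gen_stress_field(spec)
        fields_by_comparison[comp.name] = (fields_a, fields_b)
        path = out / f"stress_{comp.name}.csv"
        write_stress_csv(fields_a + fields_b, path)
        _register(path)
        log.info("simulate: comparison %s -> %s", comp.name, path.name)
    timings["simulate_stress"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trials_by_height = {}
    for i, h in enumerate(config.heights_m):
        seed = stage_seed(config.seed, STAGE_GRF * 100 + i)
        seeds[f"grf/{h}"] = seed
        trials = gen_grf_trials(config.grf_spec(h, seed))
        trials_by_height[h] = trials
        path = out / f"grf_raw_{h}m.csv"
        write_grf_csv(trials, path)
        _register(path)
    timings["simulate_grf"] = time.perf_counter() - t0

    # ---- stage 2: waveform conditioning, PCA, principal GRF ------------
    t0 = time.perf_counter()
    event_values = {}
    for h, trials in trials_by_height.items():
        phase_samples = int(round(config.grf_phase_duration * config.grf_sampling_rate))
        conditioned = [
            condition_trial(
                t,
                fs=config.grf_sampling_rate,
                phase_samples=phase_samples,
            )
            for t in trials
        ]
        waveforms = {t.trial_id: c for t, c in zip(trials, conditioned)}
        path = out / f"waveforms_{h}m.csv"
        write_waveform_csv(waveforms, path)
        _register(path)
        axis_events = {}
        principal = {}
        for axis in conditioned[0]:
            W = waveform_matrix(conditioned, axis)
            pw = reconstruct_rank1(pca_decompose(W))
            principal[axis] = pw.principal_grf
            axis_events[axis] = extract_event_value(pw.principal_grf, config.event_phase)
        path = out / f"principal_grf_{h}m.csv"
        write_waveform_csv({0: principal}, path)
        _register(path)
        event_values[f"{h}m"] = axis_events
    path = out / "grf_event_values.json"
    _json_dump(event_values, path)
    _register(path)
    timings["waveforms"] = time.perf_counter() - t0
    log.info("waveforms: principal GRF + event values for %d heights", len(trials_by_height))

    # ---- stage 3: stress structuring per subset case -------------------
    t0 = time.perf_counter()
    matrices = {}
    pareto_rows = []
    for comp in config.comparisons:
        fields_a, fields_b = fields_by_comparison[comp.name]
        for bone, ns in fields_a[0].bones.items():
            dist = pareto_bins(ns.stresses)
            bands = percentile_bands(ns.stresses)
            row = {
                "comparison": comp.name,
                "condition": fields_a[0].condition,
                "bone": bone,
                "n_nodes": len(ns),
                "n_bins": dist.n_bins,
                "max_count_bin": int(dist.counts.argmax()),
            }
            for name, (lo, hi) in bands.items():
                row[f"{name}_low"], row[f"{name}_high"] = lo, hi
            pareto_rows.append(row)
        for si, case in enumerate(config.cases):
            subset = NodeSubsetSpec.from_case(case)
            mat_seed = stage_seed(config.seed, 500 + 10 * len(matrices))
            fm = build_feature_matrix(
                fields_a, fields_b, subset, summary="sampled", seed=mat_seed
            )
            matrices[(comp.name, case)] = fm
    path = out / "stress_structure.csv"
    pd.DataFrame(pareto_rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    _register(path)
    timings["structuring"] = time.perf_counter() - t0
    log.info("structuring: %d feature matrices", len(matrices))

    # ---- stage 4: BPSO selection per comparison x case -----------------
    t0 = time.perf_counter()
    selection_out = {}
    for ci, comp in enumerate(config.comparisons):
        per_case = {}
        for si, case in enumerate(config.cases):
            fm = thin_ranks(matrices[(comp.name, case)], config.select_max_instances)
            base = stage_seed(config.seed, STAGE_SELECT * 1000 + ci * 100 + si)
            seeds[f"select/{comp.name}/{case}"] = base
            masks = []
            traces_ok = True
            for s in range(config.n_bpso_seeds):
                cfg = SwarmConfig(
                    dimensions=fm.n_features,
                    n_particles=config.n_particles,
                    iterations=config.bpso_iterations,
                    alpha=config.alpha,
                    velocity_clamp=config.velocity_clamp,
                    holdout_fraction=config.holdout_fraction,
                    knn_k=config.knn_k,
                    seed=base + s,
                )
                run = run_bpso(fm, cfg)
                masks.append(run.mask)
                traces_ok &= bool(np.all(np.diff(run.trace) <= 0))
            if not traces_ok:
                raise ValidationError("global-best fitness trace increased")
            magnitudes = np.abs(fm.X.to_numpy(float)).mean(axis=0)
            result = consensus_features(masks, list(fm.bone_labels), magnitudes)
            per_case[case] = {
                "consensus_top3": list(result.consensus),
                "counts": result.counts_by_label(),
                "masks": [[int(v) for v in m] for m in result.masks],
                "n_instances": fm.n_instances,
            }
            log.info(
                "select: %s case %s -> %s", comp.name, case, result.consensus
            )
        selection_out[comp.name] = per_case
        path = out / f"selection_{comp.name}.json"
        _json_dump(per_case, path)
        _register(path)
        export_case = "200" if "200" in config.cases else config.cases[-1]
        feat_path = out / f"features_{comp.name}_{export_case}.csv"
        write_feature_csv(
            thin_ranks(matrices[(comp.name, export_case)], config.select_max_instances),
            feat_path,
        )
        _register(feat_path)
    timings["selection"] = time.perf_counter() - t0

    # ---- stage 5: recognition report -----------------------------------
    t0 = time.perf_counter()
    fold_seed = stage_seed(config.seed, STAGE_RECOG)
    seeds["recognition"] = fold_seed
    datasets = {
        key: thin_ranks(fm, config.recognition_max_instances)
        for key, fm in matrices.items()
    }
    specs = (
        ClassifierSpec("knn", {"n_neighbors": config.knn_k}, seed=fold_seed),
        ClassifierSpec("svm", {}, seed=fold_seed),
        ClassifierSpec("ann", {}, seed=fold_seed),
    )
    report = per_bone_report(
        datasets,
        specs,
        folds=config.cv_folds,
        fold_seed=fold_seed,
        highlight_margin=config.highlight_margin,
    )
    path = out / "recognition.csv"
    report.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    _register(path)
    totals = {
        "per_case": {
            f"{comp}|{case}": v
            for (comp, case), v in total_accuracy(report, "case").items()
        },
        "per_comparison": dict(total_accuracy(report, "comparison")),
        "highlights": report.highlights().to_dict(orient="records"),
    }
    path = out / "recognition_totals.json"
    _json_dump(totals, path)
    _register(path)
    timings["recognition"] = time.perf_counter() - t0
    log.info("recognition: %d accuracy cells", len(report.table))

    # ---- stage 6: summary + manifest -----------------------------------
    summary = ["# stressfeat run summary", ""]
    for comp in config.comparisons:
        summary.append(f"## {comp.name}")
        summary.append(f"- planted effects: {dict(comp.effect_map) or 'none'}")
        for case in config.cases:
            sel = selection_out[comp.name][case]
            acc = totals["per_case"][f"{comp.name}|{case}"]
            summary.append(
                f"- case {case}: consensus {sel['consensus_top3']}, "
                f"total accuracy {acc:.3f}"
            )
        summary.append("")
    path = out / "summary.md"
    path.write_text("\n".join(summary), encoding="utf-8")
    _register(path)

    manifest = RunManifest(
        config=config.to_dict(),
        seeds=seeds,
        artifacts=artifacts,
        timings_s={k: round(v, 3) for k, v in timings.items()},
        version=__version__,
    )
    manifest.write(out / "manifest.json")
    return manifest
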