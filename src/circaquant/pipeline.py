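"""Workflow orchestration: simulate, image-based phagocytosis analysis,
and table-based proteoglycan analysis, with a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig
from .image import quantify_image
from .pg import class_totals, fit_standard_curve, normalize_table, species_rhythms, zscore_matrix
from .rhythm import EchoRhythmFitter, carrier_zenith, time_convert
from .stats import preprocess_intensities, timepoint_summary
from .synth import (
    ExperimentDesign,
    GroundTruthRhythm,
    phase_for_zenith,
    simulate_pg_experiment,
    simulate_phagocytosis_experiment,
    simulate_standard_curve,
)

log = logging.getLogger("circaquant")

__all__ = ["run_pipeline", "write_report"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(out: Path, cfg: PipelineConfig, inputs: list[Path],
              counts: dict[str, int]) -> None:
    manifest = {
        "package": "circaquant",
        "version": __version__,
        "seed": cfg.seed,
        "workflow": cfg.workflow,
        "config": {k: getattr(cfg, k) for k in vars(cfg)},
        "input_digests": {str(p): _sha256(p) for p in sorted(inputs)},
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _simulate(cfg: PipelineConfig, out: Path) -> dict:
    design = ExperimentDesign(start=cfg.start, interval=cfg.interval,
                              span=cfg.span, replicates=cfg.replicates,
                              cells_per_image=cfg.cells_per_image, seed=cfg.seed)
    # Uptake zenith at PS32, matching the observed phagocytosis rhythm.
    truth = GroundTruthRhythm(amplitude=900.0, ac_coeff=0.0, period=24.0,
                              phase=phase_for_zenith(32.0, design.start, 24.0),
                              equilibrium=2000.0)
    samples = simulate_phagocytosis_experiment(design, truth)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    index_rows, truth_tables = [], []
    for s in samples:
        name = f"t{s.time_ps:05.1f}_r{s.replicate}.tif"
        tifffile.imwrite(img_dir / name, np.round(s.image).astype(np.uint16))
        index_rows.append({"filename": name, "time_ps": s.time_ps,
                           "replicate": s.replicate})
        truth_tables.append(s.truth)
    pd.DataFrame(index_rows).to_csv(img_dir / "index.csv", index=False)
    pd.concat(truth_tables, ignore_index=True).to_csv(
        img_dir / "ground_truth.csv", index=False)

    pg_design = ExperimentDesign(start=cfg.start, interval=cfg.interval,
                                 span=cfg.span, replicates=4,
                                 seed=cfg.seed + 1)
    species = {
        ("HS", code): GroundTruthRhythm(
            amplitude=amp, ac_coeff=0.0, period=24.0,
            phase=phase_for_zenith(20.0, pg_design.start, 24.0),
            equilibrium=eq, noise_sd=0.05 * eq)
        for code, amp, eq in
        [("0S", 2.0e-4, 6.0e-4), ("NS", 8.0e-5, 2.4e-4), ("TriS", 4.0e-5, 1.2e-4)]
    }
    pg = simulate_pg_experiment(species, pg_design, seed=cfg.seed + 1)
    pg.to_csv(out / "pg_raw.csv", index=False)
    sc = simulate_standard_curve(2.0e-3, 150.0,
                                 np.linspace(0, 1.0e6 / 5, 8), 30.0, cfg.seed + 2)
    sc.to_csv(out / "standard_curve.csv", index=False)
    sidecar = {"design": vars(design), "phagocytosis_truth": vars(truth),
               "pg_species": {f"{c}:{s}": vars(t) for (c, s), t in species.items()}}
    (out / "simulation_metadata.json").write_text(json.dumps(sidecar, indent=2))
    counts = {"images": len(samples), "pg_rows": len(pg),
              "standard_curve_points": len(sc)}
    log.info("simulate: wrote %d images, %d pg rows", len(samples), len(pg))
    return {"counts": counts, "inputs": [], "summary": counts}


def _phagocytosis(cfg: PipelineConfig, out: Path) -> dict:
    img_dir = Path(cfg.input_dir)
    index = pd.read_csv(img_dir / "index.csv")
    seg = cfg.segmentation()
    per_cell = []
    for row in index.itertuples():
        img = tifffile.imread(img_dir / row.filename).astype(float)
        table = quantify_image(img, seg)
        table["time_ps"] = row.time_ps
        table["replicate"] = row.replicate
        per_cell.append(table)
        log.info("quantify %s: %d objects, background %.1f",
                 row.filename, len(table), table["background"].iloc[0]
                 if len(table) else float("nan"))
    cells = pd.concat(per_cell, ignore_index=True)
    cells.to_csv(out / "per_cell.csv", index=False)
    if cells.empty:
        raise RuntimeError("phagocytosis: no objects detected in any image")

    pre = preprocess_intensities(cells.rename(columns={"corrected_mean": "value"}),
                                 cfg.background_signal,
                                 iqr_multiplier=cfg.iqr_multiplier)
    pre.kept.to_csv(out / "per_cell_filtered.csv", index=False)
    rep_means, tp_means = timepoint_summary(pre.kept)
    rep_means.to_csv(out / "replicate_means.csv", index=False)

    est = EchoRhythmFitter(cfg.criteria(), detrend=cfg.detrend, smooth=cfg.smooth,
                           collapse_replicates=cfg.collapse_replicates)
    est.fit_series(rep_means)
    f = est.fit_
    fit_row = {
        "id": "phagocytosis", "amplitude": f.amplitude, "ac_coeff": f.ac_coeff,
        "period": f.period, "phase": f.phase, "equilibrium": f.equilibrium,
        "sse": f.sse, "p": f.p, "p_bh": f.p_bh, "p_by": f.p_by,
        "circadian": f.circadian, "reasons": ";".join(f.reasons),
        "zenith_ps": f.zenith_ps,
        "zenith_ct": None if f.zenith_ps is None
                     else time_convert(f.zenith_ps, "PS", "CT",
                                       index_to_ps=cfg.index_to_ps,
                                       ps_to_ct=cfg.ps_to_ct),
        "nadir_ps": f.nadir_ps,
        "zenith_phase_ps": carrier_zenith(f) if f.amplitude > 0 else None,
    }
    fits = pd.DataFrame([fit_row])
    fits.to_csv(out / "rhythm_fits.csv", index=False)
    counts = {"objects": len(cells), "kept": len(pre.kept),
              "below_threshold": pre.n_below_threshold,
              "iqr_removed": pre.n_iqr_removed}
    return {"counts": counts,
            "inputs": [img_dir / f for f in index["filename"]] + [img_dir / "index.csv"],
            "summary": {"fits": fits, "removal": counts}}


def _proteoglycan(cfg: PipelineConfig, out: Path) -> dict:
    table = pd.read_csv(cfg.pg_table)
    sc_points = pd.read_csv(cfg.standard_curve)
    dilution = float(table["dilution"].iloc[0]) if "dilution" in table else 1.0
    curve = fit_standard_curve(sc_points, dilution=dilution)
    normalized = normalize_table(table, curve)
    normalized.to_csv(out / "pg_normalized.csv", index=False)
    cell_rows = normalized[normalized["unit"] == "ng/cell"]
    totals = class_totals(cell_rows)
    totals.to_csv(out / "pg_class_totals.csv", index=False)
    z = zscore_matrix(cell_rows)
    z.to_csv(out / "pg_zscores.csv")
    fits = species_rhythms(cell_rows, cfg.criteria(),
                           detrend=cfg.detrend, smooth=cfg.smooth)
    fits.to_csv(out / "pg_rhythms.csv", index=False)
    counts = {"rows": len(table), "species_fitted": len(fits),
              "circadian": int(fits["circadian"].sum())}
    return {"counts": counts,
            "inputs": [Path(cfg.pg_table), Path(cfg.standard_curve)],
            "summary": {"fits": fits, "curve": curve}}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured workflow; outputs land under ``cfg.output_dir``.

    On a stage failure, partial outputs are kept and a FAILED marker names
    the failing stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = {"simulate": _simulate, "phagocytosis": _phagocytosis,
             "proteoglycan": _proteoglycan}[cfg.workflow]
    try:
        result = stage(cfg, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {cfg.workflow} failed: {exc}\n")
        raise
    _manifest(out, cfg, result["inputs"], result["counts"])
    result["output_dir"] = out
    return result


def write_report(result: dict, cfg: PipelineConfig, path: str | Path) -> int:
    """Human-readable run summary; returns a process exit status (0 = ok)."""
    lines = [f"circaquant {__version__} — workflow: {cfg.workflow}",
             f"seed: {cfg.seed}", ""]
    status = 0
    counts = result.get("counts", {})
    for k, v in counts.items():
        lines.append(f"{k}: {v}")
    summary = result.get("summary", {})
    fits = summary.get("fits") if isinstance(summary, dict) else None
    if fits is not None and len(fits):
        lines.append("")
        lines.append("rhythm verdicts (PS and CT hours):")
        for row in fits.itertuples():
            zen_ps = getattr(row, "zenith_ps", None)
            zen_ct = getattr(row, "zenith_ct", None)
            lines.append(
                f"  {row.id}: circadian={row.circadian} period={row.period:.2f} h "
                f"ac={row.ac_coeff:+.3f}/h p={row.p:.3g} BH={row.p_bh:.3g} "
                f"BY={row.p_by:.3g} zenith PS{zen_ps:.1f}/CT{zen_ct:.1f} "
                f"reasons=[{row.reasons}]"
                if zen_ps is not None and zen_ct is not None else
                f"  {row.id}: circadian={row.circadian} reasons=[{row.reasons}]")
    if counts.get("objects") == 0 or counts.get("kept") == 0:
        lines.append("")
        lines.append("WARNING: empty result (no detected cells)")
        status = 1
    Path(path).write_text("\n".join(lines) + "\n")
    return status
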