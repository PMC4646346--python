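"""End-to-end protocol run: simulate -> quantify -> analyze -> report.

Mirrors the three-phase study flow (baseline PreMch, methacholine
challenge PostMch, deep-inspiration recovery PostDI): every virtual
subject contributes an image and a recording per condition, the
measurement pipelines produce the study table, and the linkage analyses
run on it.  Every artifact is written under the output directory with a
manifest recording the configuration hash and seed, sufficient to re-run
the protocol byte-identically.
"""

from __future__ import annotations


import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .cohort import CohortSpec, simulate_cohort
from .config import RunConfig
from .errors import InsufficientDataError
from .io import write_image, write_recording, write_study_table
from .mechanics import default_waveform
from .stats import ahr_analysis, condition_summary, linkage_analysis

logger = logging.getLogger(__name__)

__all__ = ["run_protocol", "cohort_spec_from_config", "analyze_table"]


def cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    c = config.cohort
    return CohortSpec(
        n_healthy=c.n_healthy, n_asthmatic=c.n_asthmatic, coupling=c.coupling,
        pc20_range=(c.pc20_min, c.pc20_max), noise_sigma=c.noise_sigma,
        seed=config.seed, image_shape=tuple(c.image_shape),
        recording_fs_hz=config.mechanics.fs_hz,
        recording_duration_s=config.mechanics.duration_s,
    )


def analyze_table(table: pd.DataFrame, config: RunConfig, outdir: Path) -> dict:
    """Run the condition summary, CV-mechanics linkage and AHR analyses,
    writing CSV results and a plain-text report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary, comparisons = condition_summary(table, alpha=config.analysis.alpha)
    linkage = linkage_analysis(table)
    linkage_df = pd.DataFrame(
        [{"subset": c.subset, "x": c.pair[0], "y": c.pair[1],
          "r": c.r, "p": c.p, "n": c.n} for c in linkage]
    )
    try:
        ahr = ahr_analysis(table, log_pc20=config.analysis.log_pc20)
        ahr_df = pd.DataFrame(
            [{"x": c.pair[0], "y": c.pair[1], "r": c.r, "p": c.p, "n": c.n}
             for c in ahr]
        )
    except InsufficientDataError as exc:
        logger.warning("AHR analysis skipped: %s", exc)
        ahr_df = pd.DataFrame(columns=["x", "y", "r", "p", "n"])
    summary.to_csv(outdir / "condition_summary.csv", index=False)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)
    linkage_df.to_csv(outdir / "linkage_correlations.csv", index=False)
    ahr_df.to_csv(outdir / "ahr_correlations.csv", index=False)
    with open(outdir / "report.txt", "w") as fh:
        fh.write("Condition summary (mean +/- SD)\n")
        fh.write(summary.to_string(index=False))
        fh.write("\n\nPairwise contrasts\n")
        fh.write(comparisons.to_string(index=False))
        fh.write("\n\nCV vs mechanics correlations\n")
        fh.write(linkage_df.to_string(index=False))
        fh.write("\n\nBaseline predictors of AHR (PC20)\n")
        fh.write(ahr_df.to_string(index=False))
        fh.write("\n")
    return {"summary": summary, "comparisons": comparisons,
            "linkage": linkage_df, "ahr": ahr_df}


def run_protocol(config: RunConfig, outdir) -> dict:
    """Execute the full virtual study and write all artifacts."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def sink(sid, cond, image, recording, truth):
        img_path = outdir / "images" / f"{sid}_{cond}.nii.gz"
        rec_path = outdir / "recordings" / f"{sid}_{cond}.csv"
        write_image(image, img_path)
        write_recording(recording, rec_path)
        files.append(str(img_path.relative_to(outdir)))
        files.append(str(rec_path.relative_to(outdir)))

    m = config.mechanics
    stage = time.perf_counter()
    waveform = default_waveform(
        fundamental_hz=m.fundamental_hz, f_min=m.f_min, f_max=m.f_max,
        count=m.count, growth_factor=m.growth_factor,
        tidal_volume_l=m.tidal_volume_l, duration_s=m.duration_s, fs_hz=m.fs_hz,
        amplitude_profile=m.amplitude_profile,
        optimizer_restarts=m.optimizer_restarts, seed=config.seed,
    )
    logger.info("waveform design: %.2f s", time.perf_counter() - stage)

    stage = time.perf_counter()
    result = simulate_cohort(
        cohort_spec_from_config(config), sink=sink,
        imaging_config=config.imaging, waveform=waveform,
    )
    logger.info("cohort simulation + measurement: %.2f s",
                time.perf_counter() - stage)
    write_study_table(result.table, outdir / "study_table.csv")
    files.append("study_table.csv")

    stage = time.perf_counter()
    analyses = analyze_table(result.table, config, outdir / "analysis")
    logger.info("analysis: %.2f s", time.perf_counter() - stage)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": int(result.table["subject_id"].nunique()),
        "conditions": sorted(result.table["condition"].unique().tolist()),
        "waveform_multiples": list(waveform.multiples),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"table": result.table, "waveform": waveform,
            "manifest": manifest, **analyses}
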