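"""End-to-end study pipeline: simulate → decimate → estimate → analyze → report.

:func:`run_pipeline` executes a full synthetic framerate study from a
:class:`~ciliabeat.config.StudyConfig` and writes a self-contained artifact
directory: the record table, regression and slope-test tables, group
summaries, the Nyquist-margin table, optional kymograph images and
scatter plots, and a manifest capturing config, package version and seed.
Identical config + seed produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import StudyConfig
from .study import (
    group_summary,
    nyquist_margin,
    records_to_frame,
    regression_frame,
    regression_table,
    run_study,
    summary_frame,
)
from .video import save_kymograph

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _write_plots(records_df, reg_df, outdir: Path) -> list[Path]:
    """Scatter of estimate vs reference per framerate with the fitted line
    and the identity line, one panel per method (0–50 Hz band)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    sub = reg_df[(reg_df.band_low_hz == 0) & (reg_df.band_high_hz == 50)]
    for fps in sorted(sub.fps.unique()):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
        for ax, method in zip(axes, ("peak_spacing", "fft")):
            pts = records_df[(records_df.fps == fps)
                             & (records_df.method == method)
                             & (~records_df.failed)
                             & records_df.reference_cbf_hz.notna()]
            ax.scatter(pts.reference_cbf_hz, pts.cbf_hz, s=8, alpha=0.6)
            row = sub[(sub.fps == fps) & (sub.method == method)]
            lims = (0, 55)
            ax.plot(lims, lims, "k--", lw=0.8, label="identity")
            if len(row):
                r = row.iloc[0]
                ax.plot(lims, [r.intercept + r.slope * v for v in lims], "r-",
                        lw=1.0,
                        label=f"fit: slope={r.slope:.2f}, R²={r.r_squared:.2f}")
            ax.set_title(f"{method} @ {fps:g} fps")
            ax.set_xlabel("reference CBF (Hz)")
            ax.legend(fontsize=7)
        axes[0].set_ylabel("estimated CBF (Hz)")
        fig.tight_layout()
        p = outdir / f"scatter_{int(fps)}fps.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def run_pipeline(config: StudyConfig) -> Path:
    """Run the configured study and write all artifacts.

    Returns the output directory.  On failure, partially written outputs
    are flagged by an ``INCOMPLETE`` marker file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    try:
        specs = config.population_specs()
        records, kymos = run_study(
            specs,
            fps_grid=config.fps_grid,
            reference_fps=config.reference_fps,
            methods=config.methods,
            seed=config.seed,
            simulation_fps=config.simulation_fps,
            duration=config.duration,
            n_positions=config.n_positions,
            estimator_config=config.estimator,
            return_kymographs=True,
        )
        records_df = records_to_frame(records)
        records_df.to_csv(outdir / "records.csv", index=False)

        reg = regression_table(records, fps_values=[f for f in config.fps_grid
                                                    if f != config.reference_fps],
                               methods=config.methods)
        reg_df = regression_frame(reg)
        reg_df.to_csv(outdir / "regressions.csv", index=False)

        summ_df = summary_frame(group_summary(records))
        summ_df.to_csv(outdir / "group_summary.csv", index=False)

        nyq = nyquist_margin(records)
        nyq.to_csv(outdir / "nyquist_margin.csv", index=False)

        if config.write_kymographs:
            kdir = outdir / "kymographs"
            kdir.mkdir(exist_ok=True)
            for cid, kymo in kymos.items():
                save_kymograph(kymo, kdir / f"{cid}.tif")
        if config.write_plots:
            pdir = outdir / "plots"
            pdir.mkdir(exist_ok=True)
            _write_plots(records_df, reg_df, pdir)

        manifest = {
            "package": "ciliabeat",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_records": len(records),
            "artifacts": sorted(p.name for p in outdir.iterdir()
                                if p.name != "INCOMPLETE"),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        logger.exception("pipeline failed; outputs in %s are incomplete", outdir)
        raise
    marker.unlink()
    return outdir
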