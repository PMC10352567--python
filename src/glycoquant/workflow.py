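"""End-to-end pipeline: peak lists in, quantitation / traits / statistics out.

Stages: read -> S/N filter -> recalibrate -> match light/heavy pairs ->
average replicates -> CV panel filter -> IQR outlier fencing -> derived
traits -> group statistics.  ``run_on_dataset`` operates on an in-memory
simulated dataset; ``run_pipeline`` is the file-based variant used by the
command-line interface and writes every table, the figures, a run log and
a machine-readable summary.
"""
from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import ARTIFACT_DEFAULTS, PipelineConfig
from .derived_traits import TraitTable, compute_traits, export_traits
from .glycan_model import TheoreticalLibrary, build_library
from .group_stats import compare_all, heatmap_matrix, plot_heatmap, plot_traits
from .peak_processing import process_dataset_dir, process_peaklists
from .quant_qc import QuantTable, assemble_quant_table, cv_filter
from .synthetic_data import Dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def _reproducibility_table(
    aggregates_or_pairs: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame | None:
    """Per-spot ratios of the pooled reference sample, spots x glycans."""
    pool_ids = set(manifest.loc[manifest["group"] == "POOL", "sample_id"])
    if not pool_ids:
        return None
    sub = aggregates_or_pairs[aggregates_or_pairs["sample_id"].isin(pool_ids)]
    if sub.empty:
        return None
    return sub.pivot_table(
        index="replicate", columns="glycan", values="ratio"
    )


def _bundle_from_tables(
    spot_pairs: pd.DataFrame,
    calibration: pd.DataFrame,
    manifest: pd.DataFrame,
    library: TheoreticalLibrary,
    config: PipelineConfig,
) -> dict:
    repro = _reproducibility_table(spot_pairs, manifest)
    qc = cv_filter(repro, threshold=config.cv_threshold) if repro is not None else None

    aggregates = (
        spot_pairs.groupby(["sample_id", "glycan"], sort=False)
        .agg(
            ratio=("ratio", "mean"),
            n_replicates=("ratio", "count"),
        )
        .reset_index()
    )
    quant = assemble_quant_table(
        aggregates, manifest, qc=qc, iqr_k=config.iqr_k, strata=config.strata
    )
    traits = compute_traits(quant)
    glycan_stats = compare_all(quant.masked_values(), quant.meta)
    trait_stats = compare_all(traits.values, traits.meta)
    hm, n_nonpos = heatmap_matrix(quant.masked_values(), quant.meta)
    return {
        "library": library,
        "calibration": calibration,
        "spot_pairs": spot_pairs,
        "qc": qc,
        "quant": quant,
        "traits": traits,
        "glycan_stats": glycan_stats,
        "trait_stats": trait_stats,
        "heatmap": hm,
        "n_nonpositive": n_nonpos,
    }


def _spot_pairs_long(
    peaklists: Mapping[tuple[str, int], pd.DataFrame],
    library: TheoreticalLibrary,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every spot, keeping per-spot (replicate-level) ratios."""
    from .peak_processing import process_spot

    rows = []
    calib_rows = []
    for (sid, rep), peaks in peaklists.items():
        pairs, fit = process_spot(
            peaks, library, config.calibrants,
            snr_threshold=config.snr_threshold,
            snr_exclude_da=config.snr_exclude_da,
            calib_tol=config.calib_search_da,
            match_tol_ppm=config.match_tol_ppm,
        )
        pairs = pairs.assign(sample_id=sid, replicate=rep)
        rows.append(pairs)
        calib_rows.append(
            {
                "sample_id": sid,
                "replicate": rep,
                "n_calibrants": fit.n_matched,
                "offset": fit.offset,
                "slope": fit.slope,
                "identity": fit.identity,
            }
        )
    ok = pd.concat(rows, ignore_index=True)
    return ok[ok["status"] == "ok"], pd.DataFrame(calib_rows)


def run_on_dataset(dataset: Dataset, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis on an in-memory simulated dataset."""
    config = config or PipelineConfig(panel=dataset.panel)
    library = _build_library_stage(config)
    spot_pairs, calibration = _process_stage_mem(dataset.peaklists, library, config)
    return _assemble_stage(spot_pairs, calibration, dataset.manifest, library, config)


_build_library_stage = _stage("library")(
    lambda config: build_library(config.panel, tol_ppm=config.library_tol_ppm,
                                 window=config.mz_window)
)
_process_stage_mem = _stage("peak_processing")(_spot_pairs_long)
_assemble_stage = _stage("quantitation")(_bundle_from_tables)


def write_bundle(
    bundle: dict, out_dir: str | Path, config: PipelineConfig,
    make_figures: bool = True,
) -> Path:
    """Write every table of a result bundle, plus run log and summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle["library"].write_tsv(out / "library.tsv")
    bundle["calibration"].to_csv(
        out / "calibration_report.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bundle["spot_pairs"].to_csv(
        out / "spot_pairs.tsv", sep="\t", index=False, float_format="%.9g"
    )
    bundle["quant"].write(out)
    export_traits(bundle["traits"], out / "traits.tsv")
    bundle["glycan_stats"].to_csv(
        out / "stats_glycans.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bundle["trait_stats"].to_csv(
        out / "stats_traits.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bundle["heatmap"].to_csv(
        out / "heatmap_matrix.tsv", sep="\t", float_format="%.6g"
    )
    if make_figures:
        plot_heatmap(bundle["heatmap"], bundle["quant"].meta, out / "heatmap.png")
        plot_traits(
            bundle["traits"].values, bundle["traits"].meta, out / "traits.png"
        )

    config.to_yaml(out / "config.yaml")
    qc = bundle["qc"]
    quant = bundle["quant"]
    summary = {
        "version": __version__,
        "n_library": len(bundle["library"]),
        "n_collisions": len(bundle["library"].collisions),
        "n_samples": int(quant.values.shape[0]),
        "n_glycans_retained": int(quant.values.shape[1]),
        "n_glycans_dropped": (
            int((~qc["retained"]).sum()) if qc is not None else 0
        ),
        "n_outlier_cells": int(quant.mask.to_numpy().sum()),
        "n_nonpositive_heatmap_cells": bundle["n_nonpositive"],
        "n_significant_glycans_pooled": int(
            (
                (bundle["glycan_stats"]["week"] == "pooled")
                & (bundle["glycan_stats"]["p"] < 0.05)
            ).sum()
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"glycoquant {__version__} on python {platform.python_version()}\n")
        fh.write(f"seed: {config.seed}\n")
        for k, v in config.to_dict().items():
            tag = " [artifact default]" if k in ARTIFACT_DEFAULTS else ""
            fh.write(f"{k}: {v}{tag}\n")
        for k, v in summary.items():
            fh.write(f"summary.{k}: {v}\n")
    return out


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    make_figures: bool = True,
) -> dict:
    """File-based end-to-end run on a dataset directory.

    ``input_dir`` must hold ``manifest.tsv`` and the spot files it names
    (the layout :func:`glycoquant.synthetic_data.write_dataset` produces,
    or equivalent real exports).  If the directory carries a ``panel.txt``
    it overrides the configured panel.  All outputs are written to
    ``out_dir``; any stage failure raises :class:`PipelineError` naming
    the stage.
    """
    input_dir = Path(input_dir)
    config = config or PipelineConfig()
    panel_file = input_dir / "panel.txt"
    if panel_file.exists():
        from .glycan_model import load_panel
        config = PipelineConfig(**{**config.to_dict(), "panel": load_panel(panel_file)})
        config = PipelineConfig.from_dict(config.to_dict())

    library = _build_library_stage(config)

    @_stage("read_peaklists")
    def _read():
        manifest_path = input_dir / "manifest.tsv"
        if not manifest_path.exists():
            raise FileNotFoundError(f"manifest not found: {manifest_path}")
        manifest = pd.read_csv(manifest_path, sep="\t")
        from .peak_processing import read_peaklist
        peaklists = {
            (row["sample_id"], int(row["replicate"])): read_peaklist(
                input_dir / row["file"], window=config.mz_window
            )
            for _, row in manifest.iterrows()
        }
        return manifest, peaklists

    manifest, peaklists = _read()
    spot_pairs, calibration = _process_stage_mem(peaklists, library, config)
    bundle = _assemble_stage(spot_pairs, calibration, manifest, library, config)
    write_bundle(bundle, out_dir, config, make_figures=make_figures)
    return bundle
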