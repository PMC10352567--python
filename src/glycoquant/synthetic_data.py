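"""Synthetic study generator: ground-truth glycan abundances and rendered
MALDI peak lists with the statistical structure the analysis assumes.

The generator emulates a two-diet (ad libitum vs 30% calorie restriction)
mouse cohort of both sexes sampled at seven ages, measured as light/heavy
intensity ratios against a per-glycan deuteride-labeled internal standard,
with triplicate target-plate spots per serum sample.  Programmed effects:

* a generalized downward shift of most glycans under CR,
* an upward shift of O-acetylated glycans carrying only alpha2,6-linked
  sialic acid,
* a female > male offset on fucosylated glycans,
* multiplicative (log-normal) biological and technical noise,
* occasional abundance outliers, decoy noise peaks, and affine
  mass-calibration drift.

Effect magnitudes are synthetic choices that reproduce the directions the
analysis is meant to detect; they are not measured values.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .glycan_model import MZ_WINDOW, TheoreticalLibrary, build_library, DEFAULT_PANEL

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "EffectModel",
    "SpectrumModel",
    "Dataset",
    "realize_effects",
    "simulate_abundances",
    "render_peaklist",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: diet groups x sexes x ages, with technical replicates.

    Defaults mirror a 30-mice-per-group-and-sex design sampled at weeks
    15, 19, 23, 27, 31, 35 and 60, three spots per serum sample.
    """

    groups: tuple[str, ...] = ("AL", "CR")
    sexes: tuple[str, ...] = ("M", "F")
    weeks: tuple[int, ...] = (15, 19, 23, 27, 31, 35, 60)
    mice_per_group_sex: int = 30
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_group_sex < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        if not self.groups or not self.sexes or not self.weeks:
            raise ValueError("groups, sexes and weeks must be non-empty")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return (
            len(self.groups) * len(self.sexes) * self.mice_per_group_sex
            * len(self.weeks)
        )


@dataclass(frozen=True)
class EffectModel:
    """Per-glycan effect structure of the simulated cohort.

    ``cr_down_range``/``cr_up_range`` are the uniform ranges from which the
    CR multiplier of each glycan is drawn: most glycans decrease (0.5-0.9);
    glycans that are O-acetylated and carry no alpha2,3-linked sialic acid
    increase (1.2-1.6).  ``cr_multipliers`` (and ``baselines``) can pin
    exact per-glycan values instead.  The sex multiplier applies to
    fucosylated glycans in females.  CVs are multiplicative log-normal.
    """

    baselines: Mapping[str, float] | None = None
    baseline_median: float = 1.0
    baseline_sigma: float = 0.4
    cr_multipliers: Mapping[str, float] | None = None
    cr_down_range: tuple[float, float] = (0.5, 0.9)
    cr_up_range: tuple[float, float] = (1.2, 1.6)
    sex_fucose_multiplier: float = 1.3
    biological_cv: float = 0.20
    technical_cv: float = 0.10
    outlier_prob: float = 0.02
    outlier_multiplier: float = 5.0
    time_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.biological_cv <= 1 and 0 <= self.technical_cv <= 1):
            raise ValueError("CVs must lie in [0, 1]")
        if self.sex_fucose_multiplier <= 0 or self.outlier_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier probability must lie in [0, 1]")


@dataclass(frozen=True)
class SpectrumModel:
    """Rendering of true ratios into a centroided peak list.

    The heavy (internal standard) channel is the unit-scale reference; the
    light peak carries intensity ``ratio x heavy``.  ``bleed`` is the
    fraction of the light A+3 isotopologue overlapping the heavy
    monoisotopic peak (0 by default, as no correction is applied
    downstream either).
    """

    mz_jitter_sd: float = 0.003
    drift_offset: float = 0.0
    drift_slope_ppm: float = 0.0
    n_noise_peaks: int = 50
    noise_intensity_scale: float = 1.0
    intensity_scale: float = 100.0
    bleed: float = 0.0

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if self.n_noise_peaks < 0 or self.intensity_scale <= 0:
            raise ValueError("invalid spectrum parameters")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def realize_effects(
    library: TheoreticalLibrary,
    effects: EffectModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (or copy) per-glycan baseline ratios and CR multipliers.

    Returns a frame indexed by glycan name with columns ``baseline``,
    ``cr_multiplier``, ``fucosylated`` and ``acetylated_a26`` (the
    CR-increased class: Ac >= 1 with zero alpha2,3-linked sialic acids).
    """
    rows = []
    for entry in library:
        s = entry.structure
        acet_a26 = s.acetylated and s.a23 == 0
        if effects.baselines is not None:
            base = float(effects.baselines[entry.name])
        else:
            base = float(
                np.exp(rng.normal(np.log(effects.baseline_median),
                                  effects.baseline_sigma))
            )
        if effects.cr_multipliers is not None:
            mult = float(effects.cr_multipliers[entry.name])
        else:
            lo, hi = effects.cr_up_range if acet_a26 else effects.cr_down_range
            mult = float(rng.uniform(lo, hi))
        rows.append(
            {
                "glycan": entry.name,
                "baseline": base,
                "cr_multiplier": mult,
                "fucosylated": s.fucosylated,
                "acetylated_a26": acet_a26,
            }
        )
    return pd.DataFrame(rows).set_index("glycan")


def simulate_abundances(
    design: StudyDesign,
    effects: EffectModel,
    library: TheoreticalLibrary,
    rng: np.random.Generator | None = None,
    glycan_effects: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ground-truth light/heavy ratios per (mouse, week, glycan).

    true ratio = baseline x CR multiplier (CR group only)
               x sex multiplier (fucosylated glycans in females)
               x exp(time_slope x (week - first week))
               x unit-mean log-normal biological noise,
    with outliers injected at ``outlier_prob`` (x ``outlier_multiplier``).

    Returns ``(truth, glycan_effects)``: a tidy frame with columns
    mouse_id, group, sex, week, sample_id, glycan, true_ratio, is_outlier,
    and the per-glycan effect table used.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if glycan_effects is None:
        glycan_effects = realize_effects(library, effects, rng)
    glycans = list(glycan_effects.index)

    sample_rows = []
    for group in design.groups:
        for sex in design.sexes:
            for i in range(1, design.mice_per_group_sex + 1):
                mouse = f"{group}-{sex}-{i:02d}"
                for week in design.weeks:
                    sample_rows.append((mouse, group, sex, week))
    samples = pd.DataFrame(
        sample_rows, columns=["mouse_id", "group", "sex", "week"]
    )
    samples["sample_id"] = (
        samples["mouse_id"] + "_w" + samples["week"].astype(str).str.zfill(2)
    )

    n_s, n_g = len(samples), len(glycans)
    base = glycan_effects["baseline"].to_numpy()[None, :]
    mult = glycan_effects["cr_multiplier"].to_numpy()[None, :]
    fuc = glycan_effects["fucosylated"].to_numpy()[None, :]
    is_cr = (samples["group"] == "CR").to_numpy()[:, None]
    is_f = (samples["sex"] == "F").to_numpy()[:, None]
    dt = (samples["week"] - design.weeks[0]).to_numpy(float)[:, None]

    ratio = base * np.where(is_cr, mult, 1.0)
    ratio = ratio * np.where(is_f & fuc, effects.sex_fucose_multiplier, 1.0)
    ratio = ratio * np.exp(effects.time_slope * dt)
    ratio = ratio * _lognormal_factor(rng, effects.biological_cv, (n_s, n_g))
    is_outlier = rng.random((n_s, n_g)) < effects.outlier_prob
    ratio = np.where(is_outlier, ratio * effects.outlier_multiplier, ratio)

    truth = samples.loc[samples.index.repeat(n_g)].reset_index(drop=True)
    truth["glycan"] = np.tile(glycans, n_s)
    truth["true_ratio"] = ratio.ravel()
    truth["is_outlier"] = is_outlier.ravel()
    return truth, glycan_effects


def render_peaklist(
    ratios: Mapping[str, float] | pd.Series,
    library: TheoreticalLibrary,
    spectrum: SpectrumModel,
    rng: np.random.Generator,
    technical_cv: float = 0.0,
) -> pd.DataFrame:
    """Render one spot: a centroided (m/z, intensity) list.

    Every library glycan gets a heavy peak at unit scale and a light peak
    at ``true ratio x heavy``; per-spot technical noise multiplies the
    light channel (so the measured ratio carries it) and, independently,
    the heavy amplitude (which cancels in the ratio).  Decoy noise peaks
    avoid library m/z.  Raises if the programmed affine drift could push a
    peak more than half the minimum library spacing, which would make the
    simulated data unmatchable.
    """
    all_mz = library.all_mz()
    min_gap = float(np.diff(all_mz).min()) if len(all_mz) > 1 else np.inf
    max_disp = abs(spectrum.drift_offset) + abs(
        spectrum.drift_slope_ppm
    ) * 1e-6 * library.window[1]
    if max_disp > min_gap / 2:
        raise ValueError(
            f"drift displacement {max_disp:.3f} Da exceeds half the minimum "
            f"library spacing {min_gap:.3f} Da; peaks would be unmatchable"
        )

    ratios = pd.Series(ratios)
    mz_list, int_list = [], []
    for entry in library:
        r = float(ratios[entry.name])
        heavy = spectrum.intensity_scale * _lognormal_factor(rng, technical_cv, None)
        light = r * heavy * _lognormal_factor(rng, technical_cv, None)
        heavy_obs = heavy + spectrum.bleed * light
        mz_list += [entry.light_mz, entry.heavy_mz]
        int_list += [light, heavy_obs]

    mz = np.asarray(mz_list, dtype=float)
    intensity = np.asarray(int_list, dtype=float)

    # decoy noise peaks, kept clear of library m/z
    if spectrum.n_noise_peaks:
        lo, hi = library.window
        decoys = []
        while len(decoys) < spectrum.n_noise_peaks:
            cand = rng.uniform(lo, hi, size=spectrum.n_noise_peaks)
            dist = np.abs(cand[:, None] - all_mz[None, :]).min(axis=1)
            decoys.extend(cand[dist > 0.2].tolist())
        decoys = np.array(decoys[: spectrum.n_noise_peaks])
        decoy_int = rng.exponential(spectrum.noise_intensity_scale,
                                    size=len(decoys))
        mz = np.concatenate([mz, decoys])
        intensity = np.concatenate([intensity, decoy_int])

    # affine calibration drift + per-peak jitter
    mz = mz * (1 + spectrum.drift_slope_ppm * 1e-6) + spectrum.drift_offset
    if spectrum.mz_jitter_sd > 0:
        mz = mz + rng.normal(0, spectrum.mz_jitter_sd, size=mz.shape)

    order = np.argsort(mz)
    return pd.DataFrame({"mz": mz[order], "intensity": intensity[order]})


@dataclass
class Dataset:
    """One simulated study: truth, manifest, and per-spot peak lists."""

    design: StudyDesign
    effects: EffectModel
    spectrum: SpectrumModel
    truth: pd.DataFrame
    glycan_effects: pd.DataFrame
    manifest: pd.DataFrame
    peaklists: dict[tuple[str, int], pd.DataFrame]
    panel: tuple[str, ...]

    def params(self) -> dict:
        out: dict[str, object] = {}
        for prefix, obj in (
            ("design", self.design),
            ("effects", self.effects),
            ("spectrum", self.spectrum),
        ):
            for k, v in asdict(obj).items():
                if isinstance(v, Mapping):
                    v = dict(v)
                out[f"{prefix}.{k}"] = v
        out["panel"] = ",".join(self.panel)
        return out


def generate_dataset(
    design: StudyDesign | None = None,
    effects: EffectModel | None = None,
    spectrum: SpectrumModel | None = None,
    library: TheoreticalLibrary | None = None,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    include_pooled: bool = True,
    pooled_replicates: int = 6,
) -> Dataset:
    """Simulate abundances and render every spot of the study.

    In addition to the cohort samples, a pooled reference sample (true
    ratios = the per-glycan baselines) is rendered ``pooled_replicates``
    times with technical noise only; its spots constitute the
    reproducibility set used by the CV-based panel filter.  The pooled rows
    are marked with group ``POOL`` in the manifest.
    """
    design = design or StudyDesign()
    effects = effects or EffectModel()
    spectrum = spectrum or SpectrumModel()
    if library is None:
        library = build_library(panel)
    else:
        panel = tuple(library.names)

    rng = np.random.default_rng(design.seed)
    truth, glycan_effects = simulate_abundances(design, effects, library, rng)

    manifest_rows = []
    peaklists: dict[tuple[str, int], pd.DataFrame] = {}

    by_sample = truth.set_index(["sample_id", "glycan"])["true_ratio"]
    sample_meta = truth[
        ["sample_id", "mouse_id", "group", "sex", "week"]
    ].drop_duplicates("sample_id")
    for _, meta in sample_meta.iterrows():
        sid = meta["sample_id"]
        ratios = by_sample.loc[sid]
        for rep in range(1, design.replicates + 1):
            peaklists[(sid, rep)] = render_peaklist(
                ratios, library, spectrum, rng,
                technical_cv=effects.technical_cv,
            )
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "mouse_id": meta["mouse_id"],
                    "group": meta["group"],
                    "sex": meta["sex"],
                    "week": meta["week"],
                    "replicate": rep,
                    "file": f"spots/{sid}_r{rep}.tsv",
                }
            )

    if include_pooled:
        pooled = glycan_effects["baseline"]
        for rep in range(1, pooled_replicates + 1):
            peaklists[("POOL", rep)] = render_peaklist(
                pooled, library, spectrum, rng,
                technical_cv=effects.technical_cv,
            )
            manifest_rows.append(
                {
                    "sample_id": "POOL",
                    "mouse_id": "POOL",
                    "group": "POOL",
                    "sex": "NA",
                    "week": 0,
                    "replicate": rep,
                    "file": f"spots/POOL_r{rep}.tsv",
                }
            )

    manifest = pd.DataFrame(manifest_rows)
    return Dataset(
        design=design,
        effects=effects,
        spectrum=spectrum,
        truth=truth,
        glycan_effects=glycan_effects,
        manifest=manifest,
        peaklists=peaklists,
        panel=tuple(library.names),
    )


def write_dataset(
    dataset: Dataset, out_dir: str | Path, overwrite: bool = False
) -> Path:
    """Write the dataset as plain-text files.

    Layout: ``spots/<sample>_r<rep>.tsv`` (two-column mz/intensity),
    ``manifest.tsv``, ``ground_truth.tsv``, ``panel.txt`` and a flat
    ``params.txt`` sufficient to regenerate the dataset byte-identically.
    Refuses a non-empty directory unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    (out / "spots").mkdir(parents=True, exist_ok=True)

    for (sid, rep), peaks in dataset.peaklists.items():
        peaks.to_csv(
            out / "spots" / f"{sid}_r{rep}.tsv",
            sep="\t", index=False, float_format="%.6f",
        )
    dataset.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    dataset.truth.to_csv(
        out / "ground_truth.tsv", sep="\t", index=False, float_format="%.9g"
    )
    dataset.glycan_effects.to_csv(
        out / "glycan_effects.tsv", sep="\t", float_format="%.9g"
    )
    (out / "panel.txt").write_text("\n".join(dataset.panel) + "\n")
    with open(out / "params.txt", "w") as fh:
        for k, v in dataset.params().items():
            fh.write(f"{k}={v}\n")
    logger.info(
        "wrote %d spot files for %d manifest rows to %s",
        len(dataset.peaklists), len(dataset.manifest), out,
    )
    return out


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all text files of a written dataset (regeneration check)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
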