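"""Peak-list ingestion, mass recalibration, library matching, and
light/heavy pair extraction.

A spot's processing chain is: read the centroided peak list, estimate
signal-to-noise and drop sub-threshold peaks, recalibrate the mass axis
against the known calibrant glycans (affine fit of mass error vs m/z),
match each library glycan's light and heavy m/z to the nearest observed
peak within a ppm tolerance, and form the light/heavy intensity ratio that
is the quantitative readout.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    MZ_WINDOW,
    TheoreticalLibrary,
    parse_composition,
    sodiated_mz,
)

logger = logging.getLogger(__name__)

OK = "ok"
LIGHT_MISSING = "light_missing"
HEAVY_MISSING = "heavy_missing"
AMBIGUOUS = "ambiguous"


class PeakListError(ValueError):
    """A peak-list file could not be parsed."""


def read_peaklist(
    path: str | Path, window: tuple[float, float] = MZ_WINDOW
) -> pd.DataFrame:
    """Read a two-column (m/z, intensity) text file.

    Columns may be separated by tabs, commas or whitespace; a single
    non-numeric header line is tolerated.  Peaks outside ``window`` are
    dropped (count logged).  Malformed rows raise ``PeakListError`` naming
    the line number; an empty file is an error.
    """
    path = Path(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = re.split(r"[,\t ]+", s)
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1 and not mzs:
                    continue  # optional header
                raise PeakListError(
                    f"{path}: malformed row at line {lineno}: {s!r}"
                ) from None
            if inten < 0:
                raise PeakListError(
                    f"{path}: negative intensity at line {lineno}"
                )
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise PeakListError(f"{path}: no peaks found")
    df = pd.DataFrame({"mz": mzs, "intensity": intens})
    lo, hi = window
    n_before = len(df)
    df = df[(df["mz"] >= lo) & (df["mz"] <= hi)]
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d peaks outside [%g, %g]", path, dropped, lo, hi)
    return df.sort_values("mz", ignore_index=True)


def estimate_snr(
    peaks: pd.DataFrame,
    library: TheoreticalLibrary,
    exclude_da: float = 0.5,
    window_da: float = 300.0,
) -> pd.DataFrame:
    """Attach a signal-to-noise estimate to each peak.

    The local noise level is the median intensity of peaks that do not lie
    within ``exclude_da`` of any library m/z (light or heavy), taken over a
    ``window_da``-wide window centred on the peak; if a window holds no
    such peaks the global median of non-library peaks is used, and if every
    peak is library-matched S/N is infinite.  The exclusion tolerance is in
    Da (not ppm) so that an uncorrected calibration drift cannot misfile
    analyte peaks into the noise set.
    """
    mz = peaks["mz"].to_numpy()
    inten = peaks["intensity"].to_numpy()
    lib_mz = library.all_mz()
    if len(lib_mz):
        idx = np.clip(np.searchsorted(lib_mz, mz), 1, len(lib_mz) - 1)
        dist = np.minimum(np.abs(mz - lib_mz[idx - 1]), np.abs(mz - lib_mz[idx]))
        is_noise = dist > exclude_da
    else:
        is_noise = np.ones_like(mz, dtype=bool)

    out = peaks.copy()
    if not is_noise.any():
        out["snr"] = np.inf
        return out
    noise_mz = mz[is_noise]
    noise_int = inten[is_noise]
    global_noise = float(np.median(noise_int))
    half = window_da / 2
    lo_idx = np.searchsorted(noise_mz, mz - half)
    hi_idx = np.searchsorted(noise_mz, mz + half)
    noise = np.empty_like(mz)
    for i, (lo, hi) in enumerate(zip(lo_idx, hi_idx)):
        local = noise_int[lo:hi]
        noise[i] = np.median(local) if len(local) else global_noise
    with np.errstate(divide="ignore"):
        out["snr"] = np.where(noise > 0, inten / noise, np.inf)
    return out


def snr_filter(peaks: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Retain peaks with S/N strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("S/N threshold must be >= 0")
    if "snr" not in peaks.columns:
        raise ValueError("peaks carry no 'snr' column; run estimate_snr first")
    out = peaks[peaks["snr"] > threshold].reset_index(drop=True)
    if out.empty:
        logger.warning("S/N filter at %g removed every peak", threshold)
    return out


@dataclass(frozen=True)
class CalibrationFit:
    """Affine mass-recalibration report for one spot.

    ``corrected m/z = m/z - (offset + slope * m/z)``; with fewer than two
    matched calibrants the identity transform is applied and ``identity``
    is set.
    """

    n_matched: int
    offset: float
    slope: float
    residuals_pre: tuple[float, ...]
    residuals_post: tuple[float, ...]
    identity: bool = False


def recalibrate(
    peaks: pd.DataFrame,
    calibrants: Sequence[str | float],
    tol: float = 0.3,
) -> tuple[pd.DataFrame, CalibrationFit]:
    """Recalibrate the mass axis against known calibrant glycans.

    Each calibrant (a composition string or a theoretical m/z) is matched
    to the nearest observed peak within ``tol`` Da; the mass errors of the
    matched calibrants are fit as an affine function of m/z by least
    squares and subtracted from every peak.  Fewer than two matches leaves
    the peaks untouched and returns an identity fit with a warning.
    """
    targets = np.array(
        [c if isinstance(c, (int, float)) else sodiated_mz(parse_composition(c))
         for c in calibrants],
        dtype=float,
    )
    mz = peaks["mz"].to_numpy()
    matched_obs, matched_true = [], []
    for t in targets:
        i = np.searchsorted(mz, t)
        best, err = None, tol
        for j in (i - 1, i):
            if 0 <= j < len(mz) and abs(mz[j] - t) <= err:
                best, err = j, abs(mz[j] - t)
        if best is not None:
            matched_obs.append(mz[best])
            matched_true.append(t)
    matched_obs = np.array(matched_obs)
    matched_true = np.array(matched_true)
    res_pre = tuple(matched_obs - matched_true)

    if len(matched_obs) < 2:
        logger.warning(
            "only %d calibrants matched (need >= 2); identity calibration",
            len(matched_obs),
        )
        return peaks.copy(), CalibrationFit(
            n_matched=len(matched_obs), offset=0.0, slope=0.0,
            residuals_pre=res_pre, residuals_post=res_pre, identity=True,
        )

    slope, offset = np.polyfit(matched_obs, matched_obs - matched_true, 1)
    corrected = peaks.copy()
    corrected["mz"] = corrected["mz"] - (offset + slope * corrected["mz"])
    corrected = corrected.sort_values("mz", ignore_index=True)
    post = matched_obs - (offset + slope * matched_obs) - matched_true
    return corrected, CalibrationFit(
        n_matched=len(matched_obs),
        offset=float(offset),
        slope=float(slope),
        residuals_pre=res_pre,
        residuals_post=tuple(post),
    )


def _nearest(
    mz: np.ndarray, inten: np.ndarray, target: float, tol_ppm: float
) -> tuple[int | None, float, bool]:
    """Nearest peak to ``target`` within ``tol_ppm``.

    Returns (index or None, signed ppm error, ambiguous flag).  A match is
    ambiguous when a second peak also lies within tolerance with an
    intensity within a factor of two of the chosen one.
    """
    tol_da = target * tol_ppm * 1e-6
    lo = int(np.searchsorted(mz, target - tol_da))
    hi = int(np.searchsorted(mz, target + tol_da))
    if hi == lo:
        return None, np.nan, False
    cand = np.arange(lo, hi)
    best = cand[np.argmin(np.abs(mz[cand] - target))]
    ppm = (mz[best] - target) / target * 1e6
    ambiguous = False
    for j in cand:
        if j == best:
            continue
        hi_int = max(inten[j], inten[best])
        lo_int = min(inten[j], inten[best])
        if lo_int > 0 and hi_int / lo_int <= 2.0:
            ambiguous = True
    return int(best), float(ppm), ambiguous


def match_pairs(
    peaks: pd.DataFrame,
    library: TheoreticalLibrary,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Match every library glycan's light/heavy pair to observed peaks.

    For each entry the nearest peak within ``tol_ppm`` of the light and of
    the heavy m/z is taken; the light/heavy intensity ratio is formed only
    for status ``ok``.  Statuses record missing channels and ambiguous
    matches (a competing peak within tolerance and within 2x intensity, or
    one observed peak claimed by two library entries).
    """
    mz = peaks["mz"].to_numpy()
    inten = peaks["intensity"].to_numpy()
    rows = []
    used: dict[int, list[int]] = {}
    for k, entry in enumerate(library):
        li, l_ppm, l_amb = _nearest(mz, inten, entry.light_mz, tol_ppm)
        hi_, h_ppm, h_amb = _nearest(mz, inten, entry.heavy_mz, tol_ppm)
        if li is None:
            status = LIGHT_MISSING
        elif hi_ is None:
            status = HEAVY_MISSING
        elif l_amb or h_amb:
            status = AMBIGUOUS
        else:
            status = OK
        light_int = inten[li] if li is not None else np.nan
        heavy_int = inten[hi_] if hi_ is not None else np.nan
        ratio = light_int / heavy_int if status == OK else np.nan
        rows.append(
            {
                "glycan": entry.name,
                "status": status,
                "ratio": ratio,
                "light_intensity": light_int,
                "heavy_intensity": heavy_int,
                "light_ppm": l_ppm,
                "heavy_ppm": h_ppm,
            }
        )
        for idx in (li, hi_):
            if idx is not None:
                used.setdefault(idx, []).append(k)

    out = pd.DataFrame(rows)
    # one observed peak must never serve two library entries silently
    for idx, entries in used.items():
        if len(entries) > 1:
            out.loc[entries, "status"] = AMBIGUOUS
            out.loc[entries, "ratio"] = np.nan
    return out


def aggregate_replicates(pair_tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Average light/heavy ratios over replicate spots of one sample.

    Only ``ok`` replicates contribute.  Returns one row per glycan with the
    arithmetic mean ratio, the technical CV (sample sd / mean, NaN when
    fewer than two replicates), and the replicate count; a glycan with no
    usable replicate gets a missing ratio.
    """
    frames = list(pair_tables)
    if not frames:
        raise ValueError("no replicate tables supplied")
    stacked = pd.concat(frames, ignore_index=True)
    ok = stacked[stacked["status"] == OK]
    glycans = frames[0]["glycan"]
    grouped = ok.groupby("glycan")["ratio"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.size()
    out = pd.DataFrame(
        {
            "ratio": mean.reindex(glycans),
            "technical_cv": (sd / mean).reindex(glycans),
            "n_replicates": n.reindex(glycans).fillna(0).astype(int),
        }
    ).reset_index()
    return out


def process_spot(
    peaks: pd.DataFrame,
    library: TheoreticalLibrary,
    calibrants: Sequence[str | float],
    snr_threshold: float = 3.0,
    snr_exclude_da: float = 0.5,
    calib_tol: float = 0.3,
    match_tol_ppm: float = 10.0,
) -> tuple[pd.DataFrame, CalibrationFit]:
    """Full single-spot chain: S/N filter, recalibration, pair matching."""
    peaks = estimate_snr(peaks, library, exclude_da=snr_exclude_da)
    peaks = snr_filter(peaks, snr_threshold)
    peaks, fit = recalibrate(peaks, calibrants, tol=calib_tol)
    pairs = match_pairs(peaks, library, tol_ppm=match_tol_ppm)
    return pairs, fit


def process_peaklists(
    peaklists: Mapping[tuple[str, int], pd.DataFrame],
    library: TheoreticalLibrary,
    calibrants: Sequence[str | float],
    snr_threshold: float = 3.0,
    snr_exclude_da: float = 0.5,
    calib_tol: float = 0.3,
    match_tol_ppm: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a dict of (sample_id, replicate) -> peak list.

    Returns ``(aggregates, calibration_report)``: per-sample mean ratios in
    long form (sample_id, glycan, ratio, technical_cv, n_replicates) and
    one calibration row per spot.
    """
    by_sample: dict[str, list[pd.DataFrame]] = {}
    calib_rows = []
    for (sid, rep), peaks in peaklists.items():
        pairs, fit = process_spot(
            peaks, library, calibrants,
            snr_threshold=snr_threshold,
            snr_exclude_da=snr_exclude_da,
            calib_tol=calib_tol,
            match_tol_ppm=match_tol_ppm,
        )
        by_sample.setdefault(sid, []).append(pairs)
        calib_rows.append(
            {
                "sample_id": sid,
                "replicate": rep,
                "n_calibrants": fit.n_matched,
                "offset": fit.offset,
                "slope": fit.slope,
                "identity": fit.identity,
                "max_abs_residual": max(
                    (abs(r) for r in fit.residuals_post), default=np.nan
                ),
            }
        )
    agg_frames = []
    for sid, tables in by_sample.items():
        agg = aggregate_replicates(tables)
        agg.insert(0, "sample_id", sid)
        agg_frames.append(agg)
    aggregates = pd.concat(agg_frames, ignore_index=True)
    return aggregates, pd.DataFrame(calib_rows)


def process_dataset_dir(
    input_dir: str | Path,
    library: TheoreticalLibrary,
    calibrants: Sequence[str | float],
    window: tuple[float, float] = MZ_WINDOW,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """File-based variant: read ``manifest.tsv`` and the spot files.

    Returns (aggregates, calibration report, manifest).
    """
    input_dir = Path(input_dir)
    manifest_path = input_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    peaklists = {
        (row["sample_id"], int(row["replicate"])): read_peaklist(
            input_dir / row["file"], window=window
        )
        for _, row in manifest.iterrows()
    }
    aggregates, calib = process_peaklists(peaklists, library, calibrants, **kwargs)
    return aggregates, calib, manifest
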