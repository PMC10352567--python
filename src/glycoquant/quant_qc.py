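"""Panel-level quality control and assembly of the quantitation matrix.

Two QC layers are applied before any group statistics: a reproducibility
filter that retains only glycans whose light/heavy ratio has a coefficient
of variation below 25% over repeated measurements of a pooled reference
sample, and per-stratum Tukey fencing (1.5 x IQR) that masks outlying
sample values without deleting them from raw storage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RETAINED = "retained"
HIGH_CV = "cv_above_threshold"
ZERO_MEAN = "zero_mean"
TOO_FEW = "insufficient_replicates"


def cv_filter(
    repro: pd.DataFrame, threshold: float = 0.25
) -> pd.DataFrame:
    """Reproducibility filter: retain glycans with CV strictly below threshold.

    ``repro`` holds repeated measurements of one pooled sample, one row per
    repeat and one column per glycan.  CV is the sample (n-1) standard
    deviation divided by the mean.  Glycans with a zero mean or fewer than
    two non-missing repeats are dropped with distinct reason codes.

    Returns one row per glycan: mean, sd, cv, retained flag, reason.
    """
    if threshold <= 0:
        raise ValueError("CV threshold must be positive")
    rows = []
    for glycan in repro.columns:
        vals = repro[glycan].dropna().to_numpy(float)
        if len(vals) < 2:
            rows.append((glycan, np.nan, np.nan, np.nan, False, TOO_FEW))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if mean == 0:
            rows.append((glycan, mean, sd, np.nan, False, ZERO_MEAN))
            continue
        cv = sd / mean
        keep = cv < threshold
        rows.append((glycan, mean, sd, cv, keep, RETAINED if keep else HIGH_CV))
    out = pd.DataFrame(
        rows, columns=["glycan", "mean", "sd", "cv", "retained", "reason"]
    )
    logger.info(
        "CV filter at %.0f%%: %d of %d glycans retained",
        threshold * 100, int(out["retained"].sum()), len(out),
    )
    return out


def iqr_outliers(
    values: Sequence[float] | np.ndarray, k: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey fencing on one stratum's values.

    Quartiles use linear interpolation between order statistics (position
    ``(n - 1) * p + 1``); values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are
    flagged.  Strata with fewer than four non-missing values pass through
    unchanged (logged).  Returns ``(kept values, removed indices)`` with
    indices into the input array; missing values are never flagged.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        logger.info("IQR fencing skipped: only %d values", int(finite.sum()))
        return arr[finite], np.array([], dtype=int)
    q1, q3 = np.percentile(arr[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    removed = np.where(finite & ((arr < lo) | (arr > hi)))[0]
    kept = arr[finite & (arr >= lo) & (arr <= hi)]
    return kept, removed


def flag_outliers(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    by: Sequence[str] = ("group", "week"),
    k: float = 1.5,
) -> pd.DataFrame:
    """Tukey-fence each glycan within each stratum of ``by``.

    ``values`` is samples x glycans; ``meta`` is indexed like ``values``
    and carries the stratification keys.  Returns a boolean mask (True =
    outlier) of the same shape.  Fencing is single-pass, so removing the
    flagged cells cannot change which cells are flagged.
    """
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    for _, idx in meta.groupby(list(by)).groups.items():
        block = values.loc[idx]
        for glycan in values.columns:
            _, removed = iqr_outliers(block[glycan].to_numpy(), k=k)
            if len(removed):
                mask.loc[block.index[removed], glycan] = True
    n = int(mask.to_numpy().sum())
    if n:
        logger.info("flagged %d outlying cells by %s", n, tuple(by))
    return mask


@dataclass
class QuantTable:
    """Samples x glycans matrix of mean light/heavy ratios with QC state.

    ``values`` keeps every measured cell; ``mask`` (True = outlier) is a
    parallel boolean table and outlier-flagged cells are excluded from all
    downstream statistics via :meth:`masked_values`.  ``meta`` carries the
    stratification keys (mouse, group, sex, week) indexed by sample, and
    ``qc`` the per-glycan reproducibility report.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    meta: pd.DataFrame
    qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not (
            self.values.columns.equals(self.mask.columns)
        ):
            raise ValueError("values and mask must be aligned")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the sample index")
        arr = self.values.to_numpy(float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("ratios must be >= 0")

    @property
    def glycans(self) -> list[str]:
        return list(self.values.columns)

    def masked_values(self) -> pd.DataFrame:
        """Ratios with outlier-flagged cells set to NaN."""
        return self.values.mask(self.mask)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(out / "quant.tsv", sep="\t", float_format="%.9g")
        self.mask.to_csv(out / "quant_mask.tsv", sep="\t")
        self.meta.to_csv(out / "meta.tsv", sep="\t")
        if self.qc is not None:
            self.qc.to_csv(out / "qc_report.tsv", sep="\t", index=False,
                           float_format="%.6g")

    @classmethod
    def read(cls, out_dir: str | Path) -> "QuantTable":
        out = Path(out_dir)
        values = pd.read_csv(out / "quant.tsv", sep="\t", index_col=0).astype(float)
        mask = pd.read_csv(out / "quant_mask.tsv", sep="\t", index_col=0)
        mask = mask.astype(bool)
        meta = pd.read_csv(out / "meta.tsv", sep="\t", index_col=0)
        qc_path = out / "qc_report.tsv"
        qc = pd.read_csv(qc_path, sep="\t") if qc_path.exists() else None
        return cls(values=values, mask=mask, meta=meta, qc=qc)


def assemble_quant_table(
    aggregates: pd.DataFrame,
    manifest: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    iqr_k: float = 1.5,
    strata: Sequence[str] = ("group", "week"),
) -> QuantTable:
    """Pivot per-sample aggregates into the final quantitation matrix.

    ``aggregates`` is long form (sample_id, glycan, ratio, ...); the
    manifest supplies sample metadata (pooled reference rows, group
    ``POOL``, are excluded from the matrix).  When a QC report is given,
    only retained glycans become columns.  Outliers are then fenced per
    glycan within each stratum and recorded in the mask.  A sample present
    in one input but not the other raises an error naming the orphans.
    """
    meta = (
        manifest[manifest["group"] != "POOL"]
        [["sample_id", "mouse_id", "group", "sex", "week"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .sort_index()
    )
    orphans = sorted(set(aggregates["sample_id"]) - set(manifest["sample_id"]))
    if orphans:
        raise ValueError(f"samples in aggregates but not in manifest: {orphans}")
    agg = aggregates[aggregates["sample_id"].isin(meta.index)]
    missing = sorted(set(meta.index) - set(agg["sample_id"]))
    if missing:
        raise ValueError(f"samples in manifest but not in aggregates: {missing}")

    values = agg.pivot(index="sample_id", columns="glycan", values="ratio")
    values = values.loc[meta.index]
    if qc is not None:
        retained = [g for g in qc[qc["retained"]]["glycan"] if g in values.columns]
        values = values[retained]
    values.columns.name = None

    mask = flag_outliers(values, meta, by=strata, k=iqr_k)
    logger.info(
        "quant table: %d samples x %d glycans, %d cells flagged",
        values.shape[0], values.shape[1], int(mask.to_numpy().sum()),
    )
    return QuantTable(values=values, mask=mask, meta=meta, qc=qc)
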