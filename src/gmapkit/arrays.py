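"""Microarray read-out pipeline for pooled barcode screens.

Raw per-feature intensities pass through GC-matched background subtraction,
replicate-median summarization per barcode, log2 transform and pairwise
cyclic-loess normalization across arrays.  Normalized per-barcode signals
are thresholded against the background distribution (mean + z*SD of log2
background signal), converted to log2 ratios against a reference array, and
summarized per dilution subpool (count/median/KDE mode/IQR).  A
cross-hybridization rate quantifies off-pool features with signal above the
detection threshold.

Processing order: background correction on features first, then replicate
median, then log2, then cyclic loess across arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ThresholdPolicy",
    "RatioSet",
    "gcbg_correct",
    "summarize_replicates",
    "cyclic_loess_normalize",
    "background_threshold",
    "detection_call",
    "log2_ratios",
    "subpool_distribution",
    "cross_hyb_rate",
    "cross_hyb_percent",
    "round_percent",
]

FEATURE_COLUMNS = [
    "feature_id",
    "class_id",
    "barcode_id",
    "replicate_index",
    "gc_count",
    "intensity",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Background-threshold multiplier: threshold = mean + z * SD."""

    z: float = 1.96

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be >= 0")


@dataclass
class RatioSet:
    """Per-barcode log2(sample/reference) values annotated by subpool."""

    ratios: pd.DataFrame  # columns: barcode_id, log2_ratio, subpool_label
    sample_id: str = "sample"
    reference_id: str = "reference"
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratios["log2_ratio"]).all():
            raise ValueError("log2 ratios must be finite")


def round_percent(value: float, decimals: int = 2) -> float:
    """Half-even rounding for reported percentages.

    Trailing zeros drop naturally from the float representation, so
    0.4983 -> 0.5 while 0.2840 -> 0.28.
    """
    return float(np.round(value, decimals))


def _check_feature_table(table: pd.DataFrame) -> None:
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")


def gcbg_correct(
    table: pd.DataFrame, background_class: str = "GCBG", floor: float = 1.0
) -> pd.DataFrame:
    """Subtract the GC-matched background median from each feature intensity.

    For every non-background feature, the median intensity of background
    probes with the same GC count is subtracted; results are floored at
    ``floor`` and background rows are dropped.  A GC bin absent from the
    background probes falls back to the nearest available GC count.
    """
    _check_feature_table(table)
    bg = table[table["class_id"] == background_class]
    if bg.empty:
        raise ValueError(
            f"no background features of class {background_class!r} in table"
        )
    fg = table[table["class_id"] != background_class].copy()
    medians = bg.groupby("gc_count")["intensity"].median()
    bins = medians.index.to_numpy(dtype=float)

    def lookup(gc: float) -> float:
        if gc in medians.index:
            return float(medians.loc[gc])
        nearest = bins[np.argmin(np.abs(bins - gc))]
        return float(medians.loc[nearest])

    sub = fg["gc_count"].map(lookup)
    fg["intensity"] = np.maximum(fg["intensity"] - sub, floor)
    return fg


def summarize_replicates(table: pd.DataFrame) -> pd.Series:
    """Median intensity across replicate features, per barcode."""
    with_bc = table[table["barcode_id"].astype(str) != ""]
    out = with_bc.groupby("barcode_id")["intensity"].median()
    out.name = "signal"
    return out


def cyclic_loess_normalize(
    arrays: Mapping[str, pd.Series],
    span: float = 0.4,
    max_cycles: int = 3,
    tol: float = 1e-3,
) -> dict[str, pd.Series]:
    """Pairwise cyclic-loess normalization of log2 per-barcode signals.

    For every pair of arrays a smooth (local-linear) curve is fitted to the
    MA plot (M = log2 a - log2 b, A = mean of the two log2 signals) and half
    of the fitted trend is removed from each array, so the pairwise total
    log2 signal per barcode is conserved.  Cycling stops when the largest
    absolute adjustment of a cycle drops below ``tol``.

    Inputs are linear-scale signals (must be > 0); outputs are log2 scale.
    """
    names = list(arrays)
    if len(names) < 2:
        raise ValueError("need at least two arrays")
    common = arrays[names[0]].index
    for name in names[1:]:
        common = common.intersection(arrays[name].index)
    logs: dict[str, np.ndarray] = {}
    for name in names:
        vals = arrays[name].loc[common].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError(f"array {name!r} has non-positive signals; floor first")
        logs[name] = np.log2(vals)

    for _ in range(max_cycles):
        max_adjust = 0.0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = logs[names[i]], logs[names[j]]
                m = a - b
                av = 0.5 * (a + b)
                fit = lowess(m, av, frac=span, return_sorted=False)
                a -= fit / 2.0
                b += fit / 2.0
                max_adjust = max(max_adjust, float(np.max(np.abs(fit / 2.0))))
        if max_adjust < tol:
            break
    return {
        name: pd.Series(logs[name], index=common, name=name) for name in names
    }


def background_threshold(
    log2_background_signals: Iterable[float],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> float:
    """Detection threshold: mean + z * sample SD of log2 background signal."""
    vals = np.asarray(list(log2_background_signals), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two background values")
    return float(vals.mean() + policy.z * vals.std(ddof=1))


def detection_call(
    signals: pd.Series, threshold: float
) -> tuple[pd.Index, float]:
    """Barcodes whose log2 signal meets the threshold, and the retained fraction."""
    if len(signals) == 0:
        raise ValueError("empty signal table")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    retained = signals.index[signals >= threshold]
    return retained, len(retained) / len(signals)


def log2_ratios(
    sample: pd.Series,
    reference: pd.Series,
    subpool_annotation: Mapping[str, str] | pd.Series,
    sample_id: str = "sample",
    reference_id: str = "reference",
    center: Optional[str] = None,
) -> RatioSet:
    """Per-barcode log2 difference (sample - reference) with subpool labels.

    Both inputs are log2-scale per-barcode signals.  Barcodes missing from
    either table are excluded and recorded in the drop log.  ``center`` may
    be ``None`` (raw differences), ``"median"`` (subtract the overall median
    ratio — median-ratio centering, appropriate when the undiluted bulk is
    the majority), or a subpool label whose median is taken as the zero
    point.
    """
    ann = pd.Series(subpool_annotation)
    shared = sample.index.intersection(reference.index)
    dropped = sorted(
        set(sample.index.symmetric_difference(reference.index)).union(
            set(shared) - set(ann.index)
        )
    )
    shared = shared.intersection(ann.index)
    ratio = (sample.loc[shared] - reference.loc[shared]).astype(float)
    labels = ann.loc[shared]
    if center is not None:
        if center == "median":
            ratio = ratio - ratio.median()
        else:
            in_pool = ratio[labels == center]
            if in_pool.empty:
                raise ValueError(f"no barcodes with subpool label {center!r}")
            ratio = ratio - in_pool.median()
    df = pd.DataFrame(
        {
            "barcode_id": shared,
            "log2_ratio": ratio.to_numpy(),
            "subpool_label": labels.to_numpy(),
        }
    )
    return RatioSet(df, sample_id, reference_id, dropped)


def subpool_distribution(
    ratios: RatioSet,
    bandwidth: float | str = "scott",
    min_members: int = 10,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Per-subpool summary: count, median, KDE-mode, IQR.

    The mode is the argmax of a Gaussian-kernel density evaluated on a fixed
    grid with step ``grid_step`` spanning the data (padded by 1 log2 unit).
    Subpools below ``min_members`` get a median-only summary with
    ``mode_flagged=True``.
    """
    rows = []
    for label, grp in ratios.ratios.groupby("subpool_label"):
        vals = grp["log2_ratio"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        row = {
            "subpool_label": label,
            "count": len(vals),
            "median": med,
            "iqr": q3 - q1,
            "mode": np.nan,
            "mode_flagged": False,
        }
        if len(vals) < min_members:
            row["mode_flagged"] = True
        elif np.ptp(vals) == 0.0:
            row["mode"] = vals[0]
        else:
            kde = stats.gaussian_kde(vals, bw_method=bandwidth)
            grid = np.arange(vals.min() - 1.0, vals.max() + 1.0 + grid_step, grid_step)
            row["mode"] = float(grid[np.argmax(kde(grid))])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subpool_label")


def cross_hyb_percent(n_significant: int, n_assessed: int) -> float:
    """Cross-hybridization percentage from raw counts, rounded half-even to 2 dp."""
    if n_assessed <= 0:
        raise ValueError("n_assessed must be positive")
    return round_percent(100.0 * n_significant / n_assessed)


def cross_hyb_rate(
    signals: pd.Series,
    off_pool_barcodes: Iterable[str],
    threshold: float,
    exclusion_set: Iterable[str] = (),
) -> tuple[int, int, float]:
    """Fraction of off-pool barcode features with signal above threshold.

    Features with known sequence identity to in-pool barcodes are removed
    via ``exclusion_set`` before assessment.  Returns
    ``(n_significant, n_assessed, percent)`` with the percentage rounded
    half-even to two decimals.
    """
    assessed = set(off_pool_barcodes) - set(exclusion_set)
    if not assessed:
        raise ValueError("no off-pool barcodes left to assess")
    n_assessed = len(assessed)
    present = signals.loc[signals.index.intersection(list(assessed))]
    n_significant = int((present >= threshold).sum())
    return n_significant, n_assessed, cross_hyb_percent(n_significant, n_assessed)
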