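"""ROI segmentation, error statistics, and summary tables.

Estimation errors are reported in percentage points (pp) of saturation,
as signed errors (estimate - truth) and their absolutes, summarized by
mean, quartiles Q1/Q2/Q3, IQR, and the 90th percentile.  Quantiles use
linear interpolation between order statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoiSpec",
    "ErrorSummary",
    "roi_threshold_segmentation",
    "summarize_errors",
    "report_table",
    "parse_table",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI in mm plus the segmentation threshold fraction.

    The transversal-scan protocol uses 3.75 mm x 3.3 mm ROIs keeping the
    brightest 15% of pixels; the longitudinal protocol uses
    7.5 mm x 1.5 mm ROIs keeping the brightest 50%.
    """

    x_mm: float
    z_mm: float
    width_mm: float
    height_mm: float
    fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("threshold fraction must be in (0, 1]")
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI extent must be positive")


def roi_threshold_segmentation(mean_signal: np.ndarray, roi: RoiSpec,
                               pitch_mm: float) -> np.ndarray:
    """Indices of the brightest ``ceil(fraction * N)`` pixels inside the ROI.

    Returns flat indices into *mean_signal*.  Ties are broken by stable
    row-major pixel order, so a constant image yields the first pixels
    in row-major order.
    """
    sig = np.asarray(mean_signal, dtype=float)
    nz, nx = sig.shape
    ix0 = int(round(roi.x_mm / pitch_mm))
    iz0 = int(round(roi.z_mm / pitch_mm))
    ix1 = int(round((roi.x_mm + roi.width_mm) / pitch_mm))
    iz1 = int(round((roi.z_mm + roi.height_mm) / pitch_mm))
    if not (0 <= ix0 < ix1 <= nx and 0 <= iz0 < iz1 <= nz):
        raise ValueError("ROI outside image bounds")
    sub = sig[iz0:iz1, ix0:ix1]
    n_roi = sub.size
    if n_roi == 0:
        raise ValueError("empty ROI")
    n_keep = int(np.ceil(roi.fraction * n_roi))
    flat = sub.ravel()
    # stable sort descending: negate values, mergesort keeps row-major ties
    order = np.argsort(-flat, kind="stable")[:n_keep]
    iz, ix = np.unravel_index(order, sub.shape)
    return np.ravel_multi_index((iz + iz0, ix + ix0), sig.shape)


@dataclass(frozen=True)
class ErrorSummary:
    """Descriptive statistics of estimation errors, in percentage points."""

    n: int
    mean: float
    q1: float
    q2: float
    q3: float
    p90: float
    abs_mean: float
    abs_q1: float
    abs_q2: float
    abs_q3: float
    abs_p90: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def abs_iqr(self) -> float:
        return self.abs_q3 - self.abs_q1


def summarize_errors(estimates: np.ndarray, truths: np.ndarray) -> ErrorSummary:
    """Summarize signed and absolute saturation errors in pp.

    NaN estimates (degenerate unmixing) are excluded from the summary.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    ok = ~np.isnan(est)
    if not ok.any():
        raise ValueError("no valid estimates to summarize")
    delta = (est[ok] - tru[ok]) * 100.0
    adelta = np.abs(delta)
    q = np.percentile(delta, [25, 50, 75, 90])
    aq = np.percentile(adelta, [25, 50, 75, 90])
    return ErrorSummary(
        n=int(delta.size),
        mean=float(delta.mean()), q1=float(q[0]), q2=float(q[1]),
        q3=float(q[2]), p90=float(q[3]),
        abs_mean=float(adelta.mean()), abs_q1=float(aq[0]), abs_q2=float(aq[1]),
        abs_q3=float(aq[2]), abs_p90=float(aq[3]))


_COLUMNS = ["model", "mode", "set", "n",
            "mean", "Q1", "Q2", "Q3",
            "abs_mean", "abs_Q1", "abs_Q2", "abs_Q3", "abs_P90"]


def report_table(summaries: dict) -> pd.DataFrame:
    """Assemble summaries keyed by (model, mode, test set) into a table
    with one row per estimator and signed / absolute error blocks."""
    rows = []
    for (model, mode, test_set), s in summaries.items():
        rows.append([model, mode, test_set, s.n,
                     s.mean, s.q1, s.q2, s.q3,
                     s.abs_mean, s.abs_q1, s.abs_q2, s.abs_q3, s.abs_p90])
    return pd.DataFrame(rows, columns=_COLUMNS)


def table_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.10g")


def parse_table(text: str) -> pd.DataFrame:
    """Inverse of ``table_to_tsv``."""
    return pd.read_csv(io.StringIO(text), sep="\t")
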