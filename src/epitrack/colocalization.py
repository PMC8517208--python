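"""Manders overlap coefficients M1/M2 with manual thresholds.

For two registered single-channel images A and B with thresholds t_A, t_B:

    M1 = sum_{A_i > t_A} A_i * [B_i > t_B]  /  sum_{A_i > t_A} A_i
    M2 = sum_{B_i > t_B} B_i * [A_i > t_A]  /  sum_{B_i > t_B} B_i

i.e. the fraction of each channel's supra-threshold integrated intensity that
lies on pixels where the other channel is above its own threshold (the
threshold-Manders convention of the standard ImageJ colocalization plugin; a
total-intensity denominator mode is available behind a flag).  Thresholds are
manual configuration inputs; no automatic estimation is attempted.

Convention for the trafficking study: channel A is the bait (EpCAM-YFP),
channel B the marker (mCherry-Rab or lysotracker), so M2 is the fraction of
marker signal overlapping the bait.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImagePair", "MandersResult", "manders_coefficients",
           "read_image_pair", "compare_conditions"]


@dataclass
class ImagePair:
    """Two registered single-channel intensity images plus manual thresholds."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    threshold_a: float = 0.0
    threshold_b: float = 0.0
    mask: np.ndarray | None = None

    def validate(self) -> None:
        a, b = np.asarray(self.channel_a), np.asarray(self.channel_b)
        if a.shape != b.shape:
            raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if self.threshold_a < 0 or self.threshold_b < 0:
            raise ValueError("thresholds must be >= 0")
        if self.mask is not None and np.asarray(self.mask).shape != a.shape:
            raise ValueError("mask shape must match the channels")


@dataclass
class MandersResult:
    M1: float
    M2: float
    n_above_a: int
    n_above_b: int


def manders_coefficients(pair: ImagePair, *,
                         total_denominator: bool = False) -> MandersResult:
    """Compute M1/M2; raises naming the channel when a denominator is zero."""
    pair.validate()
    a = np.asarray(pair.channel_a, dtype=float)
    b = np.asarray(pair.channel_b, dtype=float)
    if pair.mask is not None:
        keep = np.asarray(pair.mask).astype(bool)
        a, b = a[keep], b[keep]
    above_a = a > pair.threshold_a
    above_b = b > pair.threshold_b

    denom_a = a.sum() if total_denominator else a[above_a].sum()
    denom_b = b.sum() if total_denominator else b[above_b].sum()
    if denom_a <= 0:
        raise ValueError("no supra-threshold signal in channel A "
                         "(M1 denominator is zero)")
    if denom_b <= 0:
        raise ValueError("no supra-threshold signal in channel B "
                         "(M2 denominator is zero)")
    m1 = a[above_a & above_b].sum() / denom_a
    m2 = b[above_b & above_a].sum() / denom_b
    return MandersResult(float(m1), float(m2),
                         int(above_a.sum()), int(above_b.sum()))


def read_image_pair(path_a: str | Path, path_b: str | Path,
                    threshold_a: float = 0.0, threshold_b: float = 0.0,
                    mask_path: str | Path | None = None) -> ImagePair:
    """Load a TIFF pair (8/16-bit single-channel) into an :class:`ImagePair`."""
    import tifffile

    mask = tifffile.imread(mask_path) > 0 if mask_path else None
    return ImagePair(tifffile.imread(path_a), tifffile.imread(path_b),
                     threshold_a, threshold_b, mask)


def compare_conditions(results_by_condition: dict,
                       *, coefficient: str = "M2") -> pd.DataFrame:
    """Summarize per-condition coefficients and report pairwise differences.

    ``results_by_condition`` maps condition name to a list of
    :class:`MandersResult` (one per imaged area).  Returns a summary frame
    (condition, mean, sd, n); pairwise Welch t-tests between conditions are
    attached in ``attrs['comparisons']`` and are descriptive only.  With < 2
    areas in a condition the summary row is kept but no test involves it.
    """
    rows = {}
    for cond, results in results_by_condition.items():
        vals = np.array([getattr(r, coefficient) for r in results], dtype=float)
        rows[cond] = vals
    summary = pd.DataFrame(
        [(c, v.mean() if v.size else np.nan,
          v.std(ddof=1) if v.size > 1 else np.nan, v.size)
         for c, v in rows.items()],
        columns=["condition", "mean", "sd", "n"],
    )
    comparisons = []
    conds = list(rows)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1:]:
            v1, v2 = rows[c1], rows[c2]
            if v1.size < 2 or v2.size < 2:
                comparisons.append((c1, c2, np.nan, np.nan,
                                    "insufficient areas for a test"))
                continue
            t, p = stats.ttest_ind(v1, v2, equal_var=False)
            direction = ("increased" if v2.mean() > v1.mean()
                         else "decreased" if v2.mean() < v1.mean() else "equal")
            comparisons.append((c1, c2, float(t), float(p), direction))
    summary.attrs["comparisons"] = pd.DataFrame(
        comparisons, columns=["condition_1", "condition_2", "t", "p",
                              "direction_2_vs_1"])
    return summary
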