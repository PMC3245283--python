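"""Differential-methylation calling on fixed 500 bp windows.

Each full-size window is scored with a two-sided Fisher's exact test on the
2x2 table ``[[count_A, lib_A - count_A], [count_B, lib_B - count_B]]`` and
reported as a DMR when it passes the triple filter with strict inequalities:
max(rpm) > rpm_min, rpm ratio > ratio_min, p < p_max. The rpm ratio is
``max(rpm_A, rpm_B) / min(rpm_A, rpm_B)`` and is infinite when the smaller
rpm is zero — infinite ratios pass the ratio filter.

The upstream experiment delegated p-values to capture-analysis software
without stating a model; this package deliberately defines the test as
Fisher's exact — exact, assumption-light and reproducible. No multiple-
testing correction gates the calls (the filter uses the raw p), but a
Benjamini-Hochberg FDR column is emitted for information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval
from .simulate import DIRECTION_A, DIRECTION_B


@dataclass
class DMRFilterConfig:
    """The published filter: 500 bp windows, rpm > 20, ratio > 20, p < 0.001."""

    window_size: int = 500
    rpm_min: float = 20.0
    ratio_min: float = 20.0
    p_max: float = 0.001

    def validate(self) -> None:
        for name in ("window_size", "rpm_min", "ratio_min", "p_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def window_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher's exact p for one window against the library totals."""
    if count_a < 0 or count_b < 0:
        raise ValueError("negative read count")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be > 0")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("window count exceeds library size")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(sps.fisher_exact(table, alternative="two-sided").pvalue)


def rpm_ratio(rpm_a: float, rpm_b: float) -> float:
    """max/min rpm; ``inf`` when the smaller is zero, ``nan`` for 0/0."""
    lo, hi = min(rpm_a, rpm_b), max(rpm_a, rpm_b)
    if hi == 0.0:
        return math.nan
    if lo == 0.0:
        return math.inf
    return hi / lo


def score_windows(
    stats: pd.DataFrame,
    lib_a: int,
    lib_b: int,
    window_size: int = 500,
) -> pd.DataFrame:
    """Attach ratio, Fisher p and BH-FDR to every full-size window.

    Partial terminal tiles are excluded up front (published DMRs are all
    exactly one window long).
    """
    full = stats[(stats["end"] - stats["start"]) == window_size].copy()
    full["ratio"] = [
        rpm_ratio(a, b) for a, b in zip(full["rpm_A"], full["rpm_B"])
    ]
    full["p_value"] = [
        window_test(int(a), int(b), lib_a, lib_b)
        for a, b in zip(full["count_A"], full["count_B"])
    ]
    full["fdr"] = _bh_fdr(full["p_value"].to_numpy())
    full["direction"] = np.where(
        full["rpm_A"] >= full["rpm_B"], DIRECTION_A, DIRECTION_B
    )
    return full.reset_index(drop=True)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_dmrs(
    stats: pd.DataFrame,
    config: DMRFilterConfig,
    lib_a: int,
    lib_b: int,
) -> pd.DataFrame:
    """Score windows and keep exactly those passing the triple filter.

    Returns a frame with chrom, start, end, count/rpm pairs, ratio, p_value,
    fdr and direction (``A_hyper``/``B_hyper``: side of the larger rpm; the
    ratio filter forbids ties among passing windows). Adjacent passing
    windows are reported separately, not merged.
    """
    config.validate()
    scored = score_windows(stats, lib_a, lib_b, config.window_size)
    if len(scored) == 0:
        return scored
    max_rpm = np.maximum(scored["rpm_A"], scored["rpm_B"])
    ratio = scored["ratio"].to_numpy(dtype=float)
    passing = (
        (max_rpm > config.rpm_min)
        & (ratio > config.ratio_min)  # inf passes; nan (0/0) fails
        & (scored["p_value"] < config.p_max)
    )
    return scored[passing].reset_index(drop=True)


def recover_truth(
    dmr_records: pd.DataFrame, truth: pd.DataFrame
) -> tuple[float, float, bool]:
    """(sensitivity, precision, defined) of called DMRs against planted truth.

    Sensitivity: fraction of planted DMR regions overlapped by >= 1 called
    window. Precision: fraction of called windows overlapping a planted DMR
    region. Vacuous cases (no planted DMRs / no calls) report 1.0 with
    ``defined=False``.
    """
    planted = truth[truth["is_dmr"]]
    calls = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in dmr_records.itertuples(index=False)
    ] if len(dmr_records) else []

    defined = True
    if len(planted) == 0:
        sensitivity = 1.0
        defined = False
    else:
        hit = 0
        for region in planted.itertuples(index=False):
            riv = GenomicInterval(region.chrom, region.start, region.end)
            if any(riv.overlaps(c) for c in calls):
                hit += 1
        sensitivity = hit / len(planted)

    if not calls:
        precision = 1.0
        defined = False
    else:
        regions = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in planted.itertuples(index=False)
        ]
        good = sum(1 for c in calls if any(c.overlaps(r) for r in regions))
        precision = good / len(calls)
    return sensitivity, precision, defined
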