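"""Recursive change-point segmentation of probe profiles and gain/loss calling.

The segmenter is a top-down binary splitter per chromosome: at each step it
chooses the breakpoint maximizing the two-sample Welch t statistic between the
left and right flanks, accepting the split when the two-sided p-value is below
the split threshold and both children carry at least the minimum marker count.
Flank variances are floored at a robust per-chromosome noise estimate so that
maximum-statistic selection cannot exploit flukishly small flank variances.
A bottom-up merge pass then collapses adjacent segments that fail either the
p-value criterion or the signal-to-noise criterion (|mean difference| divided
by the probe-count-weighted pooled standard deviation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    CNACall,
    Direction,
    GenomicInterval,
    ProbeProfile,
    Segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "ConcordanceReport",
    "segment_profile",
    "call_segments",
    "call_profile",
    "profile_concordance",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Stringency parameters for segmentation and calling.

    Defaults: 10 consecutive markers, split p-value cut-off 0.001,
    signal-to-noise cut-off 0.3, linear-ratio call thresholds 1.15 (gain)
    and 0.85 (loss) against a diploid baseline of 1.0.
    """

    min_markers: int = 10
    split_p_threshold: float = 0.001
    snr_threshold: float = 0.3
    gain_ratio: float = 1.15
    loss_ratio: float = 0.85

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if not 0.0 < self.split_p_threshold < 1.0:
            raise ValueError("split_p_threshold must be in (0, 1)")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")
        if not 0.0 < self.loss_ratio < 1.0 < self.gain_ratio:
            raise ValueError("require 0 < loss_ratio < 1 < gain_ratio")


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between two profiles on a shared probe grid."""

    r_squared: float
    mean_abs_dev_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.mean_abs_dev_log2 < 0:
            raise ValueError("negative mean absolute deviation")


# ---------------------------------------------------------------------------
# Welch statistics (vectorized over candidate breakpoints)
# ---------------------------------------------------------------------------

def _welch_from_moments(
    n1: np.ndarray, m1: np.ndarray, v1: np.ndarray,
    n2: np.ndarray, m2: np.ndarray, v2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and two-sided p from per-flank counts, means, variances.

    Zero pooled standard error with unequal means yields t = inf, p = 0;
    with equal means t = 0, p = 1 (degenerate noiseless data must still
    split on a real step and never split on a constant).
    """
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    # float-cancellation guard: mean differences and variances far below the
    # data scale are treated as exactly zero so constant data never splits
    scale = np.maximum(1.0, np.maximum(np.abs(m1), np.abs(m2)))
    diff = np.where(np.abs(diff) < 1e-9 * scale, 0.0, diff)
    se2 = np.where(se2 < (1e-9 * scale) ** 2, 0.0, se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff != 0, np.inf, 0.0))
        num = se2 ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = np.where(den > 0, num / den, n1 + n2 - 2)
    df = np.maximum(df, 1.0)
    finite = np.isfinite(t)
    p = np.empty_like(np.asarray(t, dtype=float))
    p[~finite] = 0.0
    p[finite] = 2.0 * stats.t.sf(np.abs(np.asarray(t, dtype=float)[finite]), np.asarray(df)[finite])
    return t, p


def _prefix_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.concatenate([[0.0], np.cumsum(x)]), np.concatenate([[0.0], np.cumsum(x * x)])


def _robust_noise_var(x: np.ndarray) -> float:
    """Noise variance from median absolute successive differences.

    Robust to segment structure (level shifts affect only boundary
    differences); zero for noiseless data so degenerate fixtures keep their
    exact-arithmetic behaviour.
    """
    if len(x) < 2:
        return 0.0
    mad = float(np.median(np.abs(np.diff(x))))
    return (mad / (np.sqrt(2.0) * 0.6745)) ** 2


def _flank_moments(
    csum: np.ndarray, csq: np.ndarray, lo: int, hi: int, ks: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Moments of x[lo:k] and x[k:hi] for each candidate breakpoint k."""
    n1 = (ks - lo).astype(float)
    n2 = (hi - ks).astype(float)
    s1 = csum[ks] - csum[lo]
    s2 = csum[hi] - csum[ks]
    q1 = csq[ks] - csq[lo]
    q2 = csq[hi] - csq[ks]
    m1, m2 = s1 / n1, s2 / n2
    # unbiased variance; clamp tiny negatives from float cancellation
    v1 = np.maximum((q1 - n1 * m1 * m1) / np.maximum(n1 - 1, 1), 0.0)
    v2 = np.maximum((q2 - n2 * m2 * m2) / np.maximum(n2 - 1, 1), 0.0)
    return (n1, m1, v1), (n2, m2, v2)


def _best_split(
    csum: np.ndarray, csq: np.ndarray, lo: int, hi: int, params: SegmentationParams,
    var_floor: float = 0.0,
) -> tuple[int, float] | None:
    """Best breakpoint k in (lo, hi) with both flanks >= min flank size.

    Returns (k, p-value) for the leftmost maximal-|t| breakpoint, or None if
    no admissible breakpoint exists. Flank variances are floored at the
    chromosome's robust noise variance so that selection of the maximal t
    cannot combine with a flukishly small flank variance.
    """
    min_flank = max(params.min_markers, 3)
    k_lo, k_hi = lo + min_flank, hi - min_flank
    if k_lo > k_hi:
        return None
    ks = np.arange(k_lo, k_hi + 1)
    (n1, m1, v1), (n2, m2, v2) = _flank_moments(csum, csq, lo, hi, ks)
    v1 = np.maximum(v1, var_floor)
    v2 = np.maximum(v2, var_floor)
    t, p = _welch_from_moments(n1, m1, v1, n2, m2, v2)
    abs_t = np.abs(t)
    best = int(np.argmax(abs_t))  # argmax is leftmost on ties
    return int(ks[best]), float(p[best])


def _split_recursive(
    csum: np.ndarray, csq: np.ndarray, lo: int, hi: int, params: SegmentationParams,
    out: list[tuple[int, int]], var_floor: float,
) -> None:
    found = _best_split(csum, csq, lo, hi, params, var_floor)
    if found is not None:
        k, p = found
        if p < params.split_p_threshold:
            _split_recursive(csum, csq, lo, k, params, out, var_floor)
            _split_recursive(csum, csq, k, hi, params, out, var_floor)
            return
    out.append((lo, hi))


def _pair_stats(
    x: np.ndarray, a: tuple[int, int], b: tuple[int, int], var_floor: float = 0.0
) -> tuple[float, float]:
    """(p-value, SNR) for adjacent index ranges a, b of values x."""
    xa, xb = x[a[0]: a[1]], x[b[0]: b[1]]
    na, nb = len(xa), len(xb)
    ma, mb = float(xa.mean()), float(xb.mean())
    va = max(float(xa.var(ddof=1)) if na > 1 else 0.0, var_floor)
    vb = max(float(xb.var(ddof=1)) if nb > 1 else 0.0, var_floor)
    _, p = _welch_from_moments(
        np.array([float(na)]), np.array([ma]), np.array([va]),
        np.array([float(nb)]), np.array([mb]), np.array([vb]),
    )
    pooled_var = (na * va + nb * vb) / (na + nb)
    delta = abs(ma - mb)
    scale = max(1.0, abs(ma), abs(mb))
    if delta < 1e-9 * scale:
        delta = 0.0
    if pooled_var < (1e-9 * scale) ** 2:
        pooled_var = 0.0
    if pooled_var > 0:
        snr = delta / math.sqrt(pooled_var)
    else:
        snr = math.inf if delta > 0 else 0.0
    return float(p[0]), snr


def _merge_pass(
    x: np.ndarray, ranges: list[tuple[int, int]], params: SegmentationParams,
    var_floor: float = 0.0,
) -> list[tuple[int, int]]:
    """Collapse adjacent segments failing the p-value or SNR criterion.

    The p criterion is applied to the scan-corrected p-value (raw p times the
    chromosome probe count): split boundaries are chosen as the maximum
    statistic over all candidate positions, so the raw pairwise p is
    anti-conservative by roughly that multiplicity. Repeatedly merges the
    failing pair with the largest p-value (leftmost on ties) until every
    adjacent pair satisfies both criteria.
    """
    ranges = list(ranges)
    scan_multiplicity = max(len(x), 1)
    while len(ranges) > 1:
        worst_i, worst_p = -1, -1.0
        for i in range(len(ranges) - 1):
            p, snr = _pair_stats(x, ranges[i], ranges[i + 1], var_floor)
            p = min(1.0, p * scan_multiplicity)
            if p >= params.split_p_threshold or snr < params.snr_threshold:
                if p > worst_p:
                    worst_i, worst_p = i, p
        if worst_i < 0:
            break
        a, b = ranges[worst_i], ranges[worst_i + 1]
        ranges[worst_i: worst_i + 2] = [(a[0], b[1])]
    return ranges


def segment_profile(profile: ProbeProfile, params: SegmentationParams | None = None) -> list[Segment]:
    """Partition each chromosome's probes into segments.

    Chromosomes with fewer than ``min_markers`` probes yield one unsplit
    segment. Segment intervals span from the first member probe position to
    one past the last (probes are length-1 points).
    """
    if params is None:
        params = SegmentationParams()
    if len(profile) == 0:
        raise ValueError("empty profile")
    segments: list[Segment] = []
    for chrom, (pos, vals) in profile.by_chromosome().items():
        csum, csq = _prefix_moments(vals)
        var_floor = _robust_noise_var(vals)
        ranges: list[tuple[int, int]] = []
        _split_recursive(csum, csq, 0, len(vals), params, ranges, var_floor)
        ranges.sort()
        ranges = _merge_pass(vals, ranges, params, var_floor)
        for lo, hi in ranges:
            seg_vals = vals[lo:hi]
            segments.append(
                Segment(
                    interval=GenomicInterval(chrom, int(pos[lo]), int(pos[hi - 1]) + 1),
                    mean_log2=float(seg_vals.mean()),
                    n_markers=hi - lo,
                    sd_log2=float(seg_vals.std(ddof=1)) if hi - lo > 1 else 0.0,
                )
            )
        logger.debug("%s %s: %d segment(s)", profile.sample_id, chrom, len(ranges))
    return segments


def call_segments(
    segments: list[Segment], params: SegmentationParams | None = None
) -> list[CNACall]:
    """Assign gain/loss/neutral by comparing 2**mean_log2 to the thresholds."""
    if params is None:
        params = SegmentationParams()
    calls: list[CNACall] = []
    for seg in segments:
        ratio = 2.0 ** seg.mean_log2
        if ratio > params.gain_ratio:
            direction = Direction.GAIN
        elif ratio < params.loss_ratio:
            direction = Direction.LOSS
        else:
            direction = Direction.NEUTRAL
        calls.append(CNACall(segment=seg, direction=direction))
    return calls


def call_profile(
    profile: ProbeProfile, params: SegmentationParams | None = None
) -> list[CNACall]:
    """Segment a profile and call every segment (convenience composition)."""
    return call_segments(segment_profile(profile, params), params)


def profile_concordance(a: ProbeProfile, b: ProbeProfile) -> ConcordanceReport:
    """Squared Pearson correlation and mean |Δlog2| over a shared probe grid."""
    if not a.same_grid(b):
        raise ValueError("profiles do not share an identical probe grid")
    if len(a) < 2:
        raise ValueError("need at least 2 shared probes for concordance")
    if np.ptp(a.log2) == 0 or np.ptp(b.log2) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    r = float(np.corrcoef(a.log2, b.log2)[0, 1])
    return ConcordanceReport(
        r_squared=min(r * r, 1.0),
        mean_abs_dev_log2=float(np.mean(np.abs(a.log2 - b.log2))),
        n_probes=len(a),
    )
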