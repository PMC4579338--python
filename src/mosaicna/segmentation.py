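"""Changepoint segmentation of LRR and mirrored-BAF probe series.

The segmentation is recursive binary splitting: within a region, the split
maximising the absolute two-sample z statistic of the child means (pooled
within-child variance) is accepted when its two-sided normal p-value falls
below ``alpha`` (default 5e-9) and both children keep at least
``min_probes`` probes; accepted children are split recursively.  Breaks are
additionally forced at chromosome boundaries and wherever adjacent probes
are further apart than ``max_gap``.  The procedure is fully deterministic
(leftmost maximal split wins ties) and is equivalent to a naive exhaustive
re-evaluation of every candidate split at every level, which the test suite
checks on small series.

Copy-number evidence (LRR, all probes) and allelic-imbalance evidence
(mirrored BAF, probes heterozygous in the matched control) are segmented
separately and their breakpoints pooled per chromosome before per-segment
statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import FormatError, ProbeSeries

__all__ = [
    "SegmentationSettings",
    "informative_probes",
    "mirrored_baf",
    "segment_series",
    "build_segments",
]


@dataclass(frozen=True)
class SegmentationSettings:
    """Split-acceptance and segment-definition thresholds.

    ``alpha`` is the two-sided significance needed to accept a split;
    ``het_imbalance`` is the BAF bound below which a heterozygous probe
    cluster counts as imbalanced (stored on the mirrored scale as
    ``1 - het_imbalance`` by consumers); ``hom_freq``/``hom_value`` define
    runs of homozygosity (fraction of informative probes pushed to the
    homozygous rails).
    """

    alpha: float = 5.0e-9
    min_probes: int = 10
    max_gap: int = 1_000_000  # bp; larger inter-probe gaps force a break
    hom_freq: float = 0.85
    hom_value: float = 0.95
    het_imbalance: float = 0.46

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if not 0.5 < self.hom_value <= 1.0:
            raise ValueError("hom_value must be in (0.5, 1]")
        if not 0.0 < self.het_imbalance < 0.5:
            raise ValueError("het_imbalance must be in (0, 0.5)")

    @property
    def mirrored_imbalance_bound(self) -> float:
        """het_imbalance on the mirrored-BAF scale (0.46 -> 0.54)."""
        return 1.0 - self.het_imbalance


def mirrored_baf(baf):
    """Fold BAF around 0.5: ``0.5 + |baf - 0.5|`` (phase is unobserved)."""
    arr = np.asarray(baf, dtype=float)
    valid = ~np.isnan(arr)
    if ((arr[valid] < 0) | (arr[valid] > 1)).any():
        raise ValueError("BAF outside [0, 1]")
    out = 0.5 + np.abs(arr - 0.5)
    return float(out) if np.isscalar(baf) else out


def informative_probes(control: ProbeSeries, test: ProbeSeries) -> np.ndarray:
    """Indices of probes heterozygous (AB) in the matched control sample."""
    control.same_grid(test)
    return np.flatnonzero(control.probes["gtype"].to_numpy() == "AB")


# ---------------------------------------------------------------------------
# recursive binary splitting

# mean differences at or below this are treated as identical: split
# evidence cannot be smaller than float rounding of the input signal
MEAN_TOL = 1e-9


def _best_split(cs, css, lo, hi, min_probes):
    """Leftmost split index maximising |z| in [lo, hi); (index, |z|) or None."""
    n = hi - lo
    if n < 2 * min_probes:
        return None
    idx = np.arange(lo + min_probes, hi - min_probes + 1)
    n_l = (idx - lo).astype(float)
    n_r = (hi - idx).astype(float)
    sum_l = cs[idx] - cs[lo]
    sum_r = cs[hi] - cs[idx]
    m_l = sum_l / n_l
    m_r = sum_r / n_r
    ss_l = (css[idx] - css[lo]) - n_l * m_l**2
    ss_r = (css[hi] - css[idx]) - n_r * m_r**2
    var = (ss_l + ss_r) / (n - 2)
    diff = m_l - m_r
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(diff) / np.sqrt(np.maximum(var, 0.0) * (1.0 / n_l + 1.0 / n_r))
    z = np.where(np.isnan(z) | (np.abs(diff) <= MEAN_TOL), 0.0, z)
    k = int(np.argmax(z))  # argmax returns the first (leftmost) maximum
    return int(idx[k]), float(z[k])


def _split_block(values: np.ndarray, lo: int, hi: int, settings) -> list[int]:
    """All accepted changepoints inside [lo, hi), by recursive splitting."""
    cs = np.concatenate(([0.0], np.cumsum(values)))
    css = np.concatenate(([0.0], np.cumsum(values.astype(float) ** 2)))
    out: list[int] = []
    stack = [(lo, hi)]
    while stack:
        a, b = stack.pop()
        best = _best_split(cs, css, a, b, settings.min_probes)
        if best is None:
            continue
        i, z = best
        p = math.erfc(z / math.sqrt(2.0)) if math.isfinite(z) else 0.0
        if p < settings.alpha:
            out.append(i)
            stack.append((i, b))
            stack.append((a, i))
    return sorted(out)


def segment_series(
    values,
    positions=None,
    settings: SegmentationSettings = SegmentationSettings(),
) -> list[int]:
    """Changepoint indices of a numeric series (break *before* each index).

    Includes breaks forced at inter-probe gaps larger than ``max_gap`` when
    ``positions`` are given.  Deterministic; an empty or constant series
    yields no changepoints.
    """
    breaks, _forced = _segment_with_forced(values, positions, settings)
    return breaks


def _segment_with_forced(values, positions, settings):
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return [], set()
    forced: set[int] = set()
    if positions is not None:
        positions = np.asarray(positions)
        gaps = np.flatnonzero(np.diff(positions) > settings.max_gap) + 1
        forced = set(int(g) for g in gaps)
    block_edges = [0] + sorted(forced) + [n]
    breaks: list[int] = sorted(forced)
    for a, b in zip(block_edges, block_edges[1:]):
        breaks.extend(_split_block(values, a, b, settings))
    return sorted(set(breaks)), forced


# ---------------------------------------------------------------------------
# joint segment construction

SEGMENT_COLUMNS = [
    "chrom", "i0", "i1", "start", "end", "n_probes", "mean_lrr",
    "n_informative", "mean_mbaf", "sd_b", "mean_b2", "ctrl_mean_b",
    "ctrl_sd_b", "ctrl_mean_b2", "hom_fraction", "left_forced",
]


def _thin_breaks(breaks, forced, lo, hi, min_probes):
    """Drop accepted breaks that would leave a child below min_probes.

    Pooling LRR- and BAF-derived breakpoints can put two breaks a few
    probes apart at the same physical boundary; the leftmost wins.  Forced
    (gap) breaks are physical and always kept.
    """
    kept: list[int] = []
    last = lo
    ordered = sorted(set(breaks))
    for i, b in enumerate(ordered):
        nxt_forced = next((x for x in ordered[i + 1:] if x in forced), hi)
        if b in forced:
            kept.append(b)
            last = b
        elif b - last >= min_probes and nxt_forced - b >= min_probes:
            kept.append(b)
            last = b
    return kept


def build_segments(
    control: ProbeSeries,
    test: ProbeSeries,
    settings: SegmentationSettings = SegmentationSettings(),
) -> pd.DataFrame:
    """Segment a test sample against its matched control.

    LRR changepoints (all probes) and mirrored-BAF changepoints (control-het
    probes only) are pooled per chromosome; per-segment statistics are
    computed between consecutive pooled breaks.  Returned segments tile
    every chromosome without overlap.

    Columns include the test segment's mean LRR, the informative-probe
    mirrored-BAF mean (``mean_mbaf``), the second moments of the folded
    deviation ``b = |BAF - 0.5|`` for test and control (used by the caller
    for the moment estimate of the BAF split), the homozygous fraction of
    informative probes, and whether the segment's left break was a forced
    gap (``left_forced``).
    """
    control.same_grid(test)
    pos = test.probes["pos"].to_numpy()
    lrr = test.probes["lrr"].to_numpy()
    t_baf = test.probes["baf"].to_numpy()
    c_baf = control.probes["baf"].to_numpy()
    info = (control.probes["gtype"].to_numpy() == "AB") & ~np.isnan(t_baf)
    b_test = np.abs(t_baf - 0.5)
    b_ctrl = np.abs(c_baf - 0.5)
    hom_hi = settings.hom_value
    is_hom = (t_baf >= hom_hi) | (t_baf <= 1.0 - hom_hi)

    rows = []
    for chrom, s, e in test.chrom_slices():
        lrr_breaks, lrr_forced = _segment_with_forced(
            lrr[s:e], pos[s:e], settings
        )
        gi = np.flatnonzero(info[s:e]) + s  # global indices of informative probes
        if gi.size:
            baf_breaks_local, _ = _segment_with_forced(
                b_test[gi], pos[gi], settings
            )
            baf_breaks = [int(gi[j] - s) for j in baf_breaks_local if j < gi.size]
        else:
            baf_breaks = []
        forced = {int(f) for f in lrr_forced}
        pooled = _thin_breaks(
            set(lrr_breaks) | set(baf_breaks), forced, 0, e - s, settings.min_probes
        )
        edges = [0] + pooled + [e - s]
        prev_forced = False
        for a, b in zip(edges, edges[1:]):
            ga, gb = s + a, s + b
            seg_info = info[ga:gb]
            n_inf = int(seg_info.sum())
            bt = b_test[ga:gb][seg_info]
            bc = b_ctrl[ga:gb][seg_info]
            mean_b = float(bt.mean()) if n_inf else np.nan
            mean_b2 = float((bt**2).mean()) if n_inf else np.nan
            sd_b = (
                float(np.sqrt(max(mean_b2 - mean_b**2, 0.0))) if n_inf else np.nan
            )
            cb_mean = float(bc.mean()) if n_inf else np.nan
            cb2 = float((bc**2).mean()) if n_inf else np.nan
            cb_sd = (
                float(np.sqrt(max(cb2 - cb_mean**2, 0.0))) if n_inf else np.nan
            )
            rows.append(
                {
                    "chrom": chrom,
                    "i0": ga,
                    "i1": gb,
                    "start": int(pos[ga]),
                    "end": int(pos[gb - 1]),
                    "n_probes": gb - ga,
                    "mean_lrr": float(np.nanmean(lrr[ga:gb])),
                    "n_informative": n_inf,
                    "mean_mbaf": 0.5 + mean_b if n_inf else np.nan,
                    "sd_b": sd_b,
                    "mean_b2": mean_b2,
                    "ctrl_mean_b": cb_mean,
                    "ctrl_sd_b": cb_sd,
                    "ctrl_mean_b2": cb2,
                    "hom_fraction": (
                        float(is_hom[ga:gb][seg_info].mean()) if n_inf else np.nan
                    ),
                    "left_forced": prev_forced,
                }
            )
            prev_forced = b in forced
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
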