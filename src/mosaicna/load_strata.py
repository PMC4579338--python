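"""Per-sample aberration load and histology-correlated stratification.

The *aberration load* of a sample is the summed size (Mb) of its scored
aberrations, computed after merging overlapping same-class intervals so the
result is invariant to call order and to splitting a call into adjacent
pieces.  Samples are stratified as

* ``LOW``         — total load strictly below 105.6 Mb (the low-load bound
  associated with a predisposition signature),
* ``TUMOR_LIKE``  — aberrant fraction of the genome strictly above 39 %
  (profiles consistent with tumor cells),
* ``INTERMEDIATE`` otherwise.

The genome denominator defaults to 3300 Mb so that a 1288-Mb load sits at
the 39 % boundary; chromosome X is excluded by default (all-female cohort)
and can be included with ``include_x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mosaic_model import AberrationClass

__all__ = ["LoadSettings", "LoadSummary", "total_load", "cohort_load", "type_proportions"]

STRATA = ("LOW", "INTERMEDIATE", "TUMOR_LIKE")


@dataclass(frozen=True)
class LoadSettings:
    low_threshold_mb: float = 105.6
    tumor_fraction: float = 0.39
    genome_mb: float = 3300.0
    include_x: bool = False


@dataclass(frozen=True)
class LoadSummary:
    sample_id: str
    load_mb: dict  # class name -> Mb
    total_mb: float
    genome_fraction: float
    stratum: str
    settings: LoadSettings


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals (overlapping or abutting)."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def total_load(
    calls: pd.DataFrame, settings: LoadSettings = LoadSettings()
) -> LoadSummary:
    """Aberration load of one sample's calls, with stratum label.

    Overlapping same-class calls are merged before summing.  All calls must
    belong to one sample.  Strata honor strict inequalities at both
    boundaries (a total of exactly 105.6 Mb is not LOW; a genome fraction
    of exactly 0.39 is not TUMOR_LIKE).
    """
    samples = set(calls["sample"]) if len(calls) else set()
    if len(samples) > 1:
        raise ValueError(f"calls from multiple samples: {sorted(samples)}")
    sample_id = samples.pop() if samples else ""

    df = calls
    if len(df) and not settings.include_x:
        df = df[~df["chrom"].isin(["X", "Y"])]

    load_mb = {cls.value: 0.0 for cls in AberrationClass}
    for cls in AberrationClass:
        sub = df[df["class"] == cls.value] if len(df) else df
        if len(sub) == 0:
            continue
        bp = 0
        for chrom in sub["chrom"].unique():
            ints = list(
                zip(
                    sub.loc[sub["chrom"] == chrom, "start"],
                    sub.loc[sub["chrom"] == chrom, "end"],
                )
            )
            bp += sum(e - s + 1 for s, e in merge_intervals(ints))
        load_mb[cls.value] = bp / 1e6

    total = sum(load_mb.values())
    fraction = total / settings.genome_mb
    if total < settings.low_threshold_mb:
        stratum = "LOW"
    elif fraction > settings.tumor_fraction:
        stratum = "TUMOR_LIKE"
    else:
        stratum = "INTERMEDIATE"
    return LoadSummary(sample_id, load_mb, total, fraction, stratum, settings)


def cohort_load(
    calls: pd.DataFrame, settings: LoadSettings = LoadSettings()
) -> pd.DataFrame:
    """Per-sample LoadSummary table for a cohort call set."""
    rows = []
    for (subject, sample), grp in calls.groupby(["subject", "sample"], sort=True):
        s = total_load(grp, settings)
        rows.append(
            {
                "subject": subject,
                "sample": sample,
                "gain_mb": s.load_mb["GAIN"],
                "del_mb": s.load_mb["DEL"],
                "cnnloh_mb": s.load_mb["CNNLOH"],
                "total_mb": s.total_mb,
                "genome_fraction": s.genome_fraction,
                "stratum": s.stratum,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "sample", "gain_mb", "del_mb", "cnnloh_mb",
            "total_mb", "genome_fraction", "stratum",
        ],
    )


def type_proportions(calls: pd.DataFrame) -> dict[str, float]:
    """Per-class fractions of aberration count (they sum to 1)."""
    if len(calls) == 0:
        raise ValueError("type_proportions of an empty call set")
    counts = calls["class"].value_counts()
    n = counts.sum()
    return {cls.value: float(counts.get(cls.value, 0)) / n for cls in AberrationClass}
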