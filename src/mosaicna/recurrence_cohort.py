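"""Cross-subject recurrence analysis and cohort statistics.

Recurrence peaks follow the minimal-common-region convention: pool one
class's calls across the cohort (each subject contributing at most once per
base, via the union of its intervals), build the per-base subject-count
step function, and report each local-maximum plateau — the smallest overlap
of the calls covering the most frequently affected locus — with its
frequency over a cohort denominator (by convention the number of subjects
carrying at least one scored aberration).

Also here: receptor-gene gain co-occurrence over a bundled six-gene set
(ERBB2, EGFR, FGFR1, IGF1R, LIFR, NGFR), margin-to-tumor propagation
matching, the sampled-vs-aberrant-margin correlation, and the
distance-versus-load regression.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import read_gene_bed
from .calling import reciprocal_overlap

__all__ = [
    "RecurrencePeak",
    "default_gene_set",
    "frequency_track",
    "find_peaks",
    "recurrence_peaks",
    "receptor_cooccurrence",
    "propagation_report",
    "sampling_vs_aberrant",
    "distance_vs_load",
]

TRACK_COLUMNS = ["chrom", "start", "end", "count", "units"]
PEAK_COLUMNS = ["chrom", "start", "end", "n_units", "frequency", "units"]


@dataclass(frozen=True)
class RecurrencePeak:
    """Minimal-overlap recurrent region for one aberration class."""

    chrom: str
    start: int
    end: int
    n_units: int
    frequency: float
    units: tuple[str, ...]  # contributing subject (or sample) ids


def default_gene_set() -> pd.DataFrame:
    """Bundled GRCh37 receptor-gene intervals (1-based inclusive)."""
    ref = importlib.resources.files("mosaicna") / "data" / "receptor_genes_grch37.bed"
    with importlib.resources.as_file(ref) as path:
        return read_gene_bed(path)


# ---------------------------------------------------------------------------
# frequency track and peaks

def _unit_unions(calls: pd.DataFrame, by: str) -> dict[str, dict[str, list]]:
    """chrom -> unit id -> union of that unit's intervals (sorted)."""
    from .load_strata import merge_intervals

    out: dict[str, dict[str, list]] = {}
    for (chrom, unit), grp in calls.groupby(["chrom", by]):
        ints = merge_intervals(list(zip(grp["start"], grp["end"])))
        out.setdefault(chrom, {})[unit] = ints
    return out


def frequency_track(
    calls: pd.DataFrame, cls: str | None = None, by: str = "subject"
) -> pd.DataFrame:
    """Per-base unit-count step function over the cohort's calls.

    ``by`` chooses the counting unit: ``subject`` (default, each subject
    counts once per base however many of its samples are affected) or
    ``sample``.  Returns constant-count runs with the contributing unit
    ids; zero-count gaps are omitted.
    """
    df = calls
    if cls is not None:
        df = df[df["class"] == str(cls)]
    rows = []
    for chrom, per_unit in sorted(_unit_unions(df, by).items()):
        events: dict[int, list[tuple[int, str]]] = {}
        for unit, ints in per_unit.items():
            for s, e in ints:
                events.setdefault(s, []).append((1, unit))
                events.setdefault(e + 1, []).append((-1, unit))
        active: set[str] = set()
        coords = sorted(events)
        for c, nxt in zip(coords, coords[1:] + [None]):
            for sign, unit in events[c]:
                (active.add if sign > 0 else active.discard)(unit)
            if nxt is None or not active:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": c,
                    "end": nxt - 1,
                    "count": len(active),
                    "units": tuple(sorted(active)),
                }
            )
    track = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # merge abutting runs with identical contributing sets
    merged: list[dict] = []
    for row in track.to_dict("records"):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == row["chrom"]
            and prev["end"] + 1 == row["start"]
            and prev["units"] == row["units"]
        ):
            prev["end"] = row["end"]
        else:
            merged.append(row)
    return pd.DataFrame(merged, columns=TRACK_COLUMNS)


def find_peaks(track: pd.DataFrame, denominator: int | None = None) -> list[RecurrencePeak]:
    """Local-maximum plateaus of a frequency track.

    A plateau is a maximal run of contiguous equal-count atoms; it is a
    peak when its count exceeds both neighbors (zero at chromosome ends and
    across gaps).  Adjacent equal-count plateaus separated by lower troughs
    are distinct peaks.  Where the contributing set changes inside a
    winning plateau, one peak per constant-set atom is reported so that
    every peak is contained in every contributing unit's call.
    """
    if len(track) == 0:
        return []
    peaks: list[RecurrencePeak] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        atoms = grp.sort_values("start").to_dict("records")
        # group contiguous atoms into equal-count plateaus
        plateaus: list[list[dict]] = []
        for atom in atoms:
            prev = plateaus[-1] if plateaus else None
            if (
                prev is not None
                and prev[-1]["end"] + 1 == atom["start"]
                and prev[-1]["count"] == atom["count"]
            ):
                prev.append(atom)
            else:
                plateaus.append([atom])
        for i, plat in enumerate(plateaus):
            count = plat[0]["count"]
            left = (
                plateaus[i - 1][-1]["count"]
                if i > 0 and plateaus[i - 1][-1]["end"] + 1 == plat[0]["start"]
                else 0
            )
            right = (
                plateaus[i + 1][0]["count"]
                if i + 1 < len(plateaus)
                and plat[-1]["end"] + 1 == plateaus[i + 1][0]["start"]
                else 0
            )
            if count > left and count > right:
                for atom in plat:
                    freq = count / denominator if denominator else np.nan
                    peaks.append(
                        RecurrencePeak(
                            chrom, atom["start"], atom["end"], count, freq,
                            atom["units"],
                        )
                    )
    return peaks


def recurrence_peaks(
    calls: pd.DataFrame,
    cls: str,
    denominator: int | None = None,
    by: str = "subject",
) -> pd.DataFrame:
    """Peak table for one class; denominator defaults to the number of
    units carrying at least one call of any class (the size-defined-
    aberration convention)."""
    if denominator is None:
        denominator = calls[by].nunique()
    track = frequency_track(calls, cls, by)
    peaks = find_peaks(track, denominator or None)
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "n_units": p.n_units,
                "frequency": p.frequency,
                "units": ",".join(p.units),
            }
            for p in peaks
        ],
        columns=PEAK_COLUMNS,
    )


# ---------------------------------------------------------------------------
# receptor-gene co-occurrence

def receptor_cooccurrence(
    calls: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    subjects: list[str] | None = None,
):
    """Per-subject gain status over a receptor gene set.

    A gene counts as gained in a subject when any of the subject's GAIN
    calls overlaps its interval by at least 1 bp.  Returns
    ``(matrix, combination_counts, cumulative_fraction)``: a boolean
    subject-by-gene DataFrame, counts of each observed non-empty gene
    combination, and the fraction of subjects with at least one gained
    gene (denominator: ``subjects`` when given, else subjects in
    ``calls``).
    """
    if genes is None:
        genes = default_gene_set()
    if len(genes) == 0:
        raise ValueError("empty gene set")
    gains = calls[calls["class"] == "GAIN"]
    if subjects is None:
        subjects = sorted(calls["subject"].unique())
    matrix = pd.DataFrame(False, index=list(subjects), columns=list(genes["gene"]))
    for _, g in genes.iterrows():
        sub = gains[
            (gains["chrom"] == g["chrom"])
            & (gains["start"] <= g["end"])
            & (gains["end"] >= g["start"])
        ]
        for subj in sub["subject"].unique():
            if subj in matrix.index:
                matrix.loc[subj, g["gene"]] = True
    combos: dict[tuple[str, ...], int] = {}
    for _, row in matrix.iterrows():
        gained = tuple(sorted(matrix.columns[row.to_numpy()]))
        if gained:
            combos[gained] = combos.get(gained, 0) + 1
    cumulative = float(matrix.any(axis=1).mean()) if len(matrix) else 0.0
    return matrix, combos, cumulative


# ---------------------------------------------------------------------------
# UM -> PT propagation

def propagation_report(
    um_calls: pd.DataFrame,
    pt_calls: pd.DataFrame,
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Match each margin call against the same subject's tumor calls.

    A UM call is PROPAGATED when a same-class PT call of the same subject
    overlaps it reciprocally by at least the threshold; the best (largest-
    overlap) match supplies the tumor-side fraction, and ``delta_f`` is
    f(PT) - f(UM).
    """
    rows = []
    for _, um in um_calls.iterrows():
        cand = pt_calls[
            (pt_calls["subject"] == um["subject"])
            & (pt_calls["class"] == um["class"])
            & (pt_calls["chrom"] == um["chrom"])
        ]
        best_ro, best = 0.0, None
        for _, pt in cand.iterrows():
            ro = reciprocal_overlap(um["start"], um["end"], pt["start"], pt["end"])
            if ro >= min_reciprocal_overlap and ro > best_ro:
                best_ro, best = ro, pt
        rows.append(
            {
                "subject": um["subject"],
                "sample": um["sample"],
                "chrom": um["chrom"],
                "start": um["start"],
                "end": um["end"],
                "class": um["class"],
                "status": "PROPAGATED" if best is not None else "NOT_PROPAGATED",
                "f_um": um["est_fraction"],
                "f_pt": best["est_fraction"] if best is not None else np.nan,
                "delta_f": (
                    best["est_fraction"] - um["est_fraction"]
                    if best is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "sample", "chrom", "start", "end", "class",
            "status", "f_um", "f_pt", "delta_f",
        ],
    )


# ---------------------------------------------------------------------------
# cohort statistics

def sampling_vs_aberrant(records: pd.DataFrame):
    """Correlation between margins sampled and margins found aberrant.

    ``records`` has one row per subject with columns ``n_sampled`` and
    ``n_aberrant``.  Subjects are grouped by sampling count; the Pearson r
    between the sampling count and the group mean of aberrant counts is
    returned along with the group-mean table.  At least three distinct
    sampling counts are required; a degenerate correlation (zero variance
    of the group means) is reported as NaN, not 0.
    """
    groups = (
        records.groupby("n_sampled")["n_aberrant"].agg(["mean", "count"]).reset_index()
    )
    if len(groups) < 3:
        raise ValueError("need at least 3 distinct sampling counts")
    x = groups["n_sampled"].to_numpy(dtype=float)
    y = groups["mean"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        return groups, float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return groups, r


def distance_vs_load(records: pd.DataFrame):
    """OLS of aberration load (Mb) on edge-to-edge distance to tumor (cm).

    Margins with tumor cells at the sampling site (``tumor_at_site`` truthy)
    enter at distance 0; for multifocal subjects the supplied distance is
    expected to be to the closest tumor.  Returns ``(table, fit)`` where
    ``fit`` carries slope, intercept and R^2.  Degenerate distance variance
    is an error.
    """
    df = records.copy()
    x = df["distance_cm"].to_numpy(dtype=float)
    if "tumor_at_site" in df.columns:
        x = np.where(df["tumor_at_site"].fillna(False).astype(bool), 0.0, x)
    y = df["load_mb"].to_numpy(dtype=float)
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate distance variance")
    res = stats.linregress(x, y)
    fit = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }
    df["distance_used_cm"] = x
    return df, fit
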