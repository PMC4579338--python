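"""Aberration calling: classify segments, estimate cell fractions, and
apply the paired control-subtraction scoring rule.

A segment is a candidate aberration when its heterozygous probes show
allelic imbalance, decided by either of two rules: (a) the mean mirrored
BAF exceeds the imbalance bound (het-imbalance threshold 0.46, i.e. a
mirrored mean above 0.54), or (b) the segment's mean folded deviation
``b = |BAF - 0.5|`` sits significantly above the matched control's at the
same probes (one-sided paired z, default z >= 5).  Folded noisy BAF has a
null mean above 0.5 (approximately ``sd * sqrt(2/pi)``), so testing
against the literal 0.5 would flag every clean segment; comparing test
against control over the identical probe set cancels that bias exactly
without needing a noise model.  Rule (b) admits large low-fraction events
whose mean split is small but precisely measured.

Imbalanced segments are classified by mean LRR: GAIN above +0.05, DEL
below -0.05, CNNLOH in the neutral band.  Segments without imbalance but
with >= 85 % of informative probes pushed to the homozygous rails and
neutral LRR are scored CNNLOH (constitutional-LOH run) and flagged.

The BAF split is estimated by second moments, ``delta^2 = E[b^2]_test -
E[b^2]_control`` over the same probes, which is unbiased under symmetric
noise (the folded mean is not); the cell fraction follows from the exact
inverse formulas in :mod:`mosaicna.mosaic_model`.

Scoring is paired: candidates are also produced for the control sample
against itself, and any test candidate matching a control candidate (same
class, reciprocal overlap >= 0.5) is removed — only changes absent from
blood/skin are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import (
    CALL_COLUMNS,
    CALL_EXTRA_COLUMNS,
    Manifest,
    ProbeSeries,
    empty_calls,
    logger,
)
from .mosaic_model import (
    AberrationClass,
    estimate_fraction,
    lrr_implied_fraction,
)
from .qc import QCSettings, qc_sample
from .segmentation import SegmentationSettings, build_segments

__all__ = [
    "CallingSettings",
    "segment_imbalanced",
    "classify_segment",
    "call_sample",
    "call_cohort",
    "reciprocal_overlap",
]


@dataclass(frozen=True)
class CallingSettings:
    """Thresholds mapping segment statistics to aberration calls."""

    lrr_gain_min: float = 0.05
    lrr_del_max: float = -0.05
    imbalance_z_min: float = 5.0
    min_informative_probes: int = 10
    reciprocal_overlap_for_control_match: float = 0.5
    lrr_response: float = 1.0  # platform attenuation factor c
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)

    def __post_init__(self) -> None:
        if not self.lrr_del_max < 0.0 < self.lrr_gain_min:
            raise ValueError("need lrr_del_max < 0 < lrr_gain_min")


def _imbalance_z(seg) -> float:
    """Paired z of the folded deviation b = |BAF - 0.5|, test vs control.

    Both samples are measured at the same control-het probes, so the
    folded-noise null mean cancels exactly and no baseline model is needed.
    """
    n = seg["n_informative"]
    if n == 0:
        return 0.0
    se = np.sqrt((seg["sd_b"] ** 2 + seg["ctrl_sd_b"] ** 2) / n)
    diff = (seg["mean_mbaf"] - 0.5) - seg["ctrl_mean_b"]
    if se == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return float(diff / se)


def segment_imbalanced(seg, settings: CallingSettings) -> tuple[bool, str]:
    """Allelic-imbalance decision for one segment row; (decision, flag).

    Rule (a): mean mirrored BAF above the mirrored het-imbalance bound
    (0.54 for the default 0.46 threshold).  Rule (b): paired test-vs-
    control z of the folded deviation at least ``imbalance_z_min``.
    Segments with fewer than ``min_informative_probes`` control-het probes
    are never imbalanced and carry an ``uninformative`` flag.
    """
    if seg["n_informative"] < settings.min_informative_probes:
        return False, "uninformative"
    if seg["mean_mbaf"] > settings.segmentation.mirrored_imbalance_bound:
        return True, ""
    z = _imbalance_z(seg)
    return (z >= settings.imbalance_z_min), ""


def classify_segment(seg, settings: CallingSettings):
    """Classify one segment row; returns (class-or-None, flags, z)."""
    z = _imbalance_z(seg)
    imb, flag = segment_imbalanced(seg, settings)
    flags = [flag] if flag else []
    if imb:
        if seg["mean_lrr"] >= settings.lrr_gain_min:
            return AberrationClass.GAIN, flags, z
        if seg["mean_lrr"] <= settings.lrr_del_max:
            return AberrationClass.DEL, flags, z
        return AberrationClass.CNNLOH, flags, z
    # run-of-homozygosity special case: hets vanished without a split signal
    if (
        seg["n_informative"] >= settings.min_informative_probes
        and seg["hom_fraction"] >= settings.segmentation.hom_freq
        and settings.lrr_del_max < seg["mean_lrr"] < settings.lrr_gain_min
    ):
        return AberrationClass.CNNLOH, flags + ["hom-run"], z
    return None, flags, z


def _merge_candidate_segments(segs: pd.DataFrame, classified) -> list[dict]:
    """Merge adjacent same-class segments separated only by forced gaps."""
    merged: list[dict] = []
    for idx, (cls, flags, z) in classified:
        seg = segs.loc[idx]
        if cls is None:
            merged.append(None)
            continue
        row = {
            "chrom": seg["chrom"],
            "i0": int(seg["i0"]),
            "i1": int(seg["i1"]),
            "start": int(seg["start"]),
            "end": int(seg["end"]),
            "cls": cls,
            "flags": list(flags),
            "n_probes": int(seg["n_probes"]),
            "n_informative": int(seg["n_informative"]),
            "lrr_sum": seg["mean_lrr"] * seg["n_probes"],
            "b_sum": (seg["mean_mbaf"] - 0.5) * seg["n_informative"]
            if seg["n_informative"]
            else 0.0,
            "b2_sum": seg["mean_b2"] * seg["n_informative"]
            if seg["n_informative"]
            else 0.0,
            "cb2_sum": seg["ctrl_mean_b2"] * seg["n_informative"]
            if seg["n_informative"]
            else 0.0,
            "z": z,
            "left_forced": bool(seg["left_forced"]),
        }
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["cls"] == cls
            and prev["chrom"] == row["chrom"]
            and prev["i1"] == row["i0"]
            and row["left_forced"]
        ):
            prev["i1"] = row["i1"]
            prev["end"] = row["end"]
            prev["n_probes"] += row["n_probes"]
            prev["n_informative"] += row["n_informative"]
            for k in ("lrr_sum", "b_sum", "b2_sum", "cb2_sum"):
                prev[k] += row[k]
            prev["z"] = max(prev["z"], row["z"])
            prev["flags"] = sorted(set(prev["flags"]) | set(row["flags"]))
        else:
            merged.append(row)
    return [m for m in merged if m is not None]


def _candidates(
    control: ProbeSeries, test: ProbeSeries, settings: CallingSettings
) -> list[dict]:
    segs = build_segments(control, test, settings.segmentation)
    classified = [
        (idx, classify_segment(segs.loc[idx], settings)) for idx in segs.index
    ]
    cands = _merge_candidate_segments(segs, classified)
    _refine_candidates(cands, control, test, settings)
    return cands


# matched-filter window for boundary refinement, in probes (LRR) and in
# informative probes (folded BAF)
_REFINE_WINDOW = 150


def _edge_scan(series: np.ndarray, k: int, lo: int, hi: int, sign: float) -> int:
    """Re-localize a boundary near index k by a matched-filter edge scan.

    Scans candidate splits j in a window around ``k`` (bounded by
    [lo, hi]) and returns the j maximising the signed difference of means
    over flanking windows — ``sign`` +1 when the event lies right of the
    boundary, -1 when left.  Leftmost maximum wins.
    """
    w = _REFINE_WINDOW
    j_lo, j_hi = max(lo + 1, k - w), min(hi - 1, k + w)
    if j_hi <= j_lo:
        return k
    cs = np.concatenate(([0.0], np.cumsum(series)))
    js = np.arange(j_lo, j_hi + 1)
    left_lo = np.maximum(js - w, lo)
    right_hi = np.minimum(js + w, hi)
    mean_left = (cs[js] - cs[left_lo]) / (js - left_lo)
    mean_right = (cs[right_hi] - cs[js]) / (right_hi - js)
    score = sign * (mean_right - mean_left)
    return int(js[int(np.argmax(score))])


def _refine_candidates(
    cands: list[dict], control: ProbeSeries, test: ProbeSeries, settings
) -> None:
    """Sharpen candidate boundaries and refresh their statistics in place.

    Pooled LRR/BAF changepoints can disagree by tens of probes at one
    physical boundary; with the class known, the informative signal (LRR
    for GAIN/DEL, folded BAF at control-het probes for CNNLOH) re-localizes
    each edge within a fixed window.
    """
    if not cands:
        return
    pos = test.probes["pos"].to_numpy()
    lrr = test.probes["lrr"].to_numpy()
    t_baf = test.probes["baf"].to_numpy()
    c_baf = control.probes["baf"].to_numpy()
    info = (control.probes["gtype"].to_numpy() == "AB") & ~np.isnan(t_baf)
    b_test = np.abs(t_baf - 0.5)
    b_ctrl = np.abs(c_baf - 0.5)
    bounds = {chrom: (s, e) for chrom, s, e in test.chrom_slices()}
    gi_by_chrom = {
        chrom: np.flatnonzero(info[s:e]) + s for chrom, (s, e) in bounds.items()
    }
    min_probes = settings.segmentation.min_probes

    for cand in cands:
        c_lo, c_hi = bounds[cand["chrom"]]
        i0, i1 = cand["i0"], cand["i1"]
        if cand["cls"] is AberrationClass.CNNLOH:
            gi = gi_by_chrom[cand["chrom"]]
            if gi.size == 0:
                continue
            series = b_test[gi]
            k0 = int(np.searchsorted(gi, i0))
            k1 = int(np.searchsorted(gi, i1))
            lo = int(np.searchsorted(gi, c_lo))
            hi = int(np.searchsorted(gi, c_hi))
            j0 = _edge_scan(series, k0, lo, hi, +1.0)
            j1 = _edge_scan(series, k1, lo, hi, -1.0)
            if j1 - j0 >= 2:
                i0 = int(gi[j0])
                i1 = int(gi[j1 - 1]) + 1
        else:
            i0 = _edge_scan(lrr, i0, c_lo, c_hi, float(cand["cls"].copy_delta))
            i1 = _edge_scan(lrr, i1, c_lo, c_hi, -float(cand["cls"].copy_delta))
        if i1 - i0 < min_probes:
            continue
        seg_info = info[i0:i1]
        bt = b_test[i0:i1][seg_info]
        bc = b_ctrl[i0:i1][seg_info]
        cand.update(
            i0=i0,
            i1=i1,
            start=int(pos[i0]),
            end=int(pos[i1 - 1]),
            n_probes=i1 - i0,
            n_informative=int(seg_info.sum()),
            lrr_sum=float(lrr[i0:i1].sum()),
            b_sum=float(bt.sum()),
            b2_sum=float((bt**2).sum()),
            cb2_sum=float((bc**2).sum()),
        )


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals, in [0, 1]."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def _cand_to_call(cand, subject: str, sample: str, settings: CallingSettings) -> dict:
    n_inf = cand["n_informative"]
    if n_inf > 0:
        mean_b2 = cand["b2_sum"] / n_inf
        ctrl_b2 = cand["cb2_sum"] / n_inf
        delta = float(np.sqrt(max(mean_b2 - ctrl_b2, 0.0)))
    else:
        delta = 0.0
    delta = min(delta, 0.5)
    est = estimate_fraction(cand["cls"], delta)
    flags = list(cand["flags"])
    if est.clipped:
        flags.append("clipped")
    z = cand["z"]
    if (
        np.isfinite(z)
        and z < 2 * settings.imbalance_z_min
        or cand["n_probes"] < 20
    ):
        flags.append("low-confidence")
    mean_lrr = cand["lrr_sum"] / cand["n_probes"]
    return {
        "subject": subject,
        "sample": sample,
        "chrom": cand["chrom"],
        "start": cand["start"],
        "end": cand["end"],
        "class": cand["cls"].value,
        "n_probes": cand["n_probes"],
        "size_bp": cand["end"] - cand["start"] + 1,
        "mean_lrr": mean_lrr,
        "baf_split": delta,
        "est_fraction": est.fraction,
        "flags": ";".join(sorted(set(flags))),
        "lrr_fraction": lrr_implied_fraction(
            cand["cls"], mean_lrr, settings.lrr_response
        ),
        "imbalance_z": z,
        "n_informative": n_inf,
    }


def call_sample(
    control: ProbeSeries,
    test: ProbeSeries,
    settings: CallingSettings = CallingSettings(),
    subject: str = "NA",
) -> pd.DataFrame:
    """Score somatic aberrations in a test sample against its paired control.

    Candidates are produced independently for the test sample and for the
    control (against itself); test candidates that match a control
    candidate — same class, reciprocal overlap at least 0.5 — are removed,
    so germline CNVs and shared artifacts are never scored.  Calling a
    control against itself therefore yields zero calls.
    """
    test_cands = _candidates(control, test, settings)
    if test.sample_id == control.sample_id or test.probes is control.probes:
        ctrl_cands = test_cands
    else:
        ctrl_cands = _candidates(control, control, settings)

    min_ro = settings.reciprocal_overlap_for_control_match
    rows = []
    for cand in test_cands:
        germline = any(
            c["cls"] == cand["cls"]
            and c["chrom"] == cand["chrom"]
            and reciprocal_overlap(
                cand["start"], cand["end"], c["start"], c["end"]
            )
            >= min_ro
            for c in ctrl_cands
        )
        if germline:
            continue
        rows.append(_cand_to_call(cand, subject, test.sample_id, settings))
    if not rows:
        return empty_calls()
    return pd.DataFrame(rows, columns=CALL_COLUMNS + CALL_EXTRA_COLUMNS)


def call_cohort(
    manifest: Manifest,
    series,
    settings: CallingSettings = CallingSettings(),
    qc_settings: QCSettings = QCSettings(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call every UM and PT sample against its subject's control.

    ``series`` is a mapping ``sample_id -> ProbeSeries`` or a callable
    loading one by id.  Samples failing QC are excluded (logged); subjects
    whose control fails QC or is absent are skipped with a warning.

    Returns (cohort call table, QC report table).
    """
    get = series if callable(series) else series.__getitem__

    qc_rows = []
    call_frames = []
    for subject in manifest.subjects():
        controls = manifest.samples_for(subject, "CONTROL")
        tests = manifest.samples_for(subject, "UM") + manifest.samples_for(
            subject, "PT"
        )
        if not controls:
            if tests:
                logger.warning("subject %s has no control sample; skipped", subject)
            continue
        try:
            control = get(controls[0])
        except (KeyError, OSError) as exc:
            raise FileNotFoundError(
                f"cannot load control sample {controls[0]} for subject {subject}"
            ) from exc
        ctrl_qc = qc_sample(control, qc_settings)
        qc_rows.append(ctrl_qc)
        if not ctrl_qc.passed:
            logger.warning(
                "control %s fails QC; subject %s skipped", controls[0], subject
            )
            continue
        for sample_id in tests:
            try:
                test = get(sample_id)
            except (KeyError, OSError) as exc:
                raise FileNotFoundError(
                    f"cannot load sample {sample_id} for subject {subject}"
                ) from exc
            rep = qc_sample(test, qc_settings)
            qc_rows.append(rep)
            if not rep.passed:
                logger.warning("sample %s fails QC; excluded", sample_id)
                continue
            call_frames.append(call_sample(control, test, settings, subject))

    calls = (
        pd.concat([f for f in call_frames], ignore_index=True)
        if call_frames
        else empty_calls()
    )
    qc_table = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "call_rate": r.call_rate,
                "lrr_dev": r.lrr_dev,
                "pass": r.passed,
            }
            for r in qc_rows
        ]
    )
    return calls, qc_table
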