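"""Classification, paired control subtraction, and cohort calling."""

import numpy as np
import pandas as pd
import pytest

from mosaicna import (
    CallingSettings,
    CohortSimConfig,
    NoiseModel,
    call_cohort,
    call_sample,
    reciprocal_overlap,
    simulate_cohort,
    small_genome,
)
from mosaicna.calling import classify_segment, segment_imbalanced
from mosaicna.mosaic_model import AberrationClass
from mosaicna.qc import QCSettings
from mosaicna.synthetic_cohort import NOISELESS, SimAberrationSpec


def _seg(**kw):
    base = dict(
        chrom="1", i0=0, i1=200, start=1, end=200_000, n_probes=200,
        mean_lrr=0.0, n_informative=200, mean_mbaf=0.52, sd_b=0.018,
        mean_b2=0.0, ctrl_mean_b=0.02, ctrl_sd_b=0.018, ctrl_mean_b2=0.0,
        hom_fraction=0.0, left_forced=False,
    )
    base.update(kw)
    return pd.Series(base)


SETTINGS = CallingSettings()


def test_imbalance_via_mirrored_mean_threshold():
    seg = _seg(mean_mbaf=0.55, n_informative=200)
    assert segment_imbalanced(seg, SETTINGS) == (True, "")


def test_balanced_segment_is_not_imbalanced():
    seg = _seg(mean_mbaf=0.5, ctrl_mean_b=0.0, sd_b=0.0, ctrl_sd_b=0.0)
    assert segment_imbalanced(seg, SETTINGS)[0] is False


def test_large_low_fraction_segment_detected_by_z():
    # 50-Mb CNNLOH at f=0.05 in 12500 probes: small mean split, tiny SE
    seg = _seg(
        n_informative=12_500, mean_mbaf=0.5 + 0.0318, ctrl_mean_b=0.0239,
        sd_b=0.018, ctrl_sd_b=0.018,
    )
    assert segment_imbalanced(seg, SETTINGS) == (True, "")


def test_uninformative_segment_flagged():
    seg = _seg(n_informative=5, mean_mbaf=0.9)
    assert segment_imbalanced(seg, SETTINGS) == (False, "uninformative")


@pytest.mark.parametrize(
    "mean_lrr,expected",
    [(-0.3, AberrationClass.DEL), (0.0, AberrationClass.CNNLOH), (0.3, AberrationClass.GAIN)],
)
def test_classification_by_lrr_band(mean_lrr, expected):
    seg = _seg(mean_mbaf=0.6, mean_lrr=mean_lrr)
    cls, flags, _ = classify_segment(seg, SETTINGS)
    assert cls is expected


def test_homozygosity_run_is_cnnloh_with_flag():
    seg = _seg(
        mean_mbaf=0.52, ctrl_mean_b=0.02, sd_b=0.018, ctrl_sd_b=0.018,
        hom_fraction=0.9, mean_lrr=0.0,
    )
    cls, flags, _ = classify_segment(seg, SETTINGS)
    assert cls is AberrationClass.CNNLOH
    assert "hom-run" in flags


def test_reciprocal_overlap_basics():
    assert reciprocal_overlap(1, 100, 1, 100) == 1.0
    assert reciprocal_overlap(1, 100, 200, 300) == 0.0
    assert reciprocal_overlap(1, 100, 51, 150) == pytest.approx(0.5)


GENOME = small_genome(n_chroms=2, chrom_mb=120.0)
GRID = GENOME.probe_grid()


def test_control_vs_self_yields_zero_calls(paired_factory):
    ctrl, _ = paired_factory(GENOME, GRID, [], seed=31)
    calls = call_sample(ctrl, ctrl, SETTINGS, "S")
    assert len(calls) == 0


def test_shared_germline_duplication_is_not_scored(paired_factory):
    germ = SimAberrationSpec("1", 30_000_001, 50_000_000, "GAIN", 1.0, germline=True)
    ctrl, test = paired_factory(
        GENOME, GRID, [germ], seed=32, control_specs=[germ]
    )
    calls = call_sample(ctrl, test, SETTINGS, "S")
    assert len(calls) == 0


def test_somatic_deletion_called_with_fraction_recovery(paired_factory):
    spec = SimAberrationSpec("1", 40_000_001, 70_000_000, "DEL", 0.3)
    ctrl, test = paired_factory(GENOME, GRID, [spec], seed=33)
    calls = call_sample(ctrl, test, SETTINGS, "S")
    assert len(calls) == 1
    call = calls.iloc[0]
    assert call["class"] == "DEL"
    assert reciprocal_overlap(call["start"], call["end"], spec.start, spec.end) > 0.9
    assert abs(call["est_fraction"] - 0.3) < 0.03
    assert abs(call["lrr_fraction"] - 0.3) < 0.1  # LRR consistency column


def test_event_split_by_forced_gap_is_merged(paired_factory):
    """A deletion spanning a large probe-free gap comes back as one call."""
    genome = small_genome(n_chroms=1, chrom_mb=60.0)
    grid = genome.probe_grid()
    gap = (grid["pos"] < 30_000_000) | (grid["pos"] > 32_000_000)
    grid = grid[gap].reset_index(drop=True)
    spec = SimAberrationSpec("1", 20_000_001, 45_000_000, "DEL", 0.5)
    ctrl, test = paired_factory(genome, grid, [spec], seed=34)
    calls = call_sample(ctrl, test, SETTINGS, "S")
    dels = calls[calls["class"] == "DEL"]
    assert len(dels) == 1
    call = dels.iloc[0]
    assert call["start"] < 30_000_000 < 45_000_000 <= call["end"] + 5 * 4000


def _cohort_cfg(**kw):
    base = dict(
        n_subjects=3,
        genome=small_genome(n_chroms=2, chrom_mb=100.0),
        seed=35,
        um_range=(1, 2),
        pt_range=(1, 1),
        p_aberrant_um=1.0,
        aberrations_per_um=0.0,
        size_mb_range=(15.0, 40.0),
        fraction_range=(0.25, 0.7),
        propagation_prob=1.0,
    )
    base.update(kw)
    return CohortSimConfig(**base)


def test_cohort_calls_recover_truth_and_propagation():
    res = simulate_cohort(_cohort_cfg())
    # events span a large share of this reduced genome, so use the
    # derivative noise estimator, which global copy structure cannot inflate
    calls, qc_table = call_cohort(
        res.manifest, res.series, qc_settings=QCSettings(dev_method="diff")
    )
    assert (qc_table["pass"]).all()
    truth = res.truth[~res.truth["germline"]]
    # every simulated event is recovered in its own sample with the right class
    recovered = 0
    for _, ev in truth.iterrows():
        sub = calls[(calls["sample"] == ev["sample"]) & (calls["class"] == ev["class"])]
        hit = any(
            reciprocal_overlap(c["start"], c["end"], ev["start"], ev["end"]) >= 0.5
            for _, c in sub.iterrows()
        )
        recovered += hit
    assert recovered == len(truth)
    # no spurious calls beyond the truth set
    for _, c in calls.iterrows():
        sub = truth[truth["sample"] == c["sample"]]
        assert any(
            reciprocal_overlap(c["start"], c["end"], ev["start"], ev["end"]) >= 0.5
            for _, ev in sub.iterrows()
        )
    # propagated tumor events carry a higher estimated fraction
    roles = res.manifest.table.set_index("sample")["role"]
    calls = calls.assign(role=roles.loc[calls["sample"]].to_numpy())
    um = calls[calls["role"] == "UM"]
    pt = calls[calls["role"] == "PT"]
    checked = 0
    for _, u in um.iterrows():
        for _, p in pt.iterrows():
            if (
                p["subject"] == u["subject"]
                and p["class"] == u["class"]
                and reciprocal_overlap(u["start"], u["end"], p["start"], p["end"]) >= 0.5
            ):
                assert p["est_fraction"] > u["est_fraction"]
                checked += 1
    assert checked > 0


def test_subject_without_control_is_skipped():
    from mosaicna.array_io import FormatError, Manifest

    res = simulate_cohort(_cohort_cfg(n_subjects=1))
    table = res.manifest.table.copy()
    victim = table["subject"].iloc[0]
    # a UM subject without control is invalid outright
    no_ctrl = table[~((table["subject"] == victim) & (table["role"] == "CONTROL"))]
    with pytest.raises(FormatError, match="no CONTROL"):
        Manifest(no_ctrl)
    # a PT-only subject without control is legal but skipped by the caller
    pt_only = Manifest(no_ctrl[no_ctrl["role"] == "PT"])
    calls, qc_table = call_cohort(pt_only, res.series)
    assert len(calls) == 0 and len(qc_table) == 0


def test_control_failing_qc_drops_whole_subject():
    res = simulate_cohort(_cohort_cfg(n_subjects=1))
    control_id = res.manifest.samples_for("S001", "CONTROL")[0]
    noisy = res.series[control_id]
    rng = np.random.default_rng(0)
    noisy.probes["lrr"] = rng.normal(0, 0.5, len(noisy))
    calls, qc_table = call_cohort(res.manifest, res.series)
    assert len(calls) == 0
    assert not qc_table.loc[qc_table["sample"] == control_id, "pass"].iloc[0]
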