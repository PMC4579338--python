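"""Recurrence peaks, receptor co-occurrence, propagation, cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from mosaicna import (
    default_gene_set,
    distance_vs_load,
    find_peaks,
    frequency_track,
    propagation_report,
    receptor_cooccurrence,
    recurrence_peaks,
    sampling_vs_aberrant,
)

from _oracles import oracle_peaks


def _calls(rows):
    out = []
    for subject, sample, chrom, start, end, cls in rows:
        out.append(
            {
                "subject": subject,
                "sample": sample,
                "chrom": chrom,
                "start": start,
                "end": end,
                "class": cls,
                "n_probes": 10,
                "size_bp": end - start + 1,
                "mean_lrr": 0.1,
                "baf_split": 0.05,
                "est_fraction": 0.2,
                "flags": "",
            }
        )
    return pd.DataFrame(out)


def test_single_call_track():
    track = frequency_track(_calls([("A", "A_UM1", "1", 100, 200, "GAIN")]), "GAIN")
    assert len(track) == 1
    row = track.iloc[0]
    assert (row["start"], row["end"], row["count"]) == (100, 200, 1)


def test_overlap_counts_subjects_once_per_base():
    calls = _calls(
        [
            ("A", "A_UM1", "1", 100, 300, "GAIN"),
            ("B", "B_UM1", "1", 200, 400, "GAIN"),
            ("A", "A_UM2", "1", 150, 250, "GAIN"),  # same subject: no extra count
        ]
    )
    track = frequency_track(calls, "GAIN")
    two = track[track["count"] == 2]
    assert len(two) == 1
    assert (two.iloc[0]["start"], two.iloc[0]["end"]) == (200, 300)
    assert track["count"].max() == 2


def test_duplicating_calls_never_changes_frequencies():
    calls = _calls(
        [
            ("A", "A_UM1", "1", 100, 300, "DEL"),
            ("B", "B_UM1", "1", 250, 500, "DEL"),
        ]
    )
    doubled = pd.concat([calls, calls], ignore_index=True)
    pd.testing.assert_frame_equal(
        frequency_track(calls, "DEL"), frequency_track(doubled, "DEL")
    )


def test_minimal_common_region_peak():
    calls = _calls(
        [
            ("A", "A_UM1", "1", 10_000_000, 30_000_000, "GAIN"),
            ("B", "B_UM1", "1", 20_000_000, 40_000_000, "GAIN"),
            ("C", "C_UM1", "1", 25_000_000, 35_000_000, "GAIN"),
        ]
    )
    peaks = find_peaks(frequency_track(calls, "GAIN"), denominator=3)
    assert len(peaks) == 1
    p = peaks[0]
    assert (p.start, p.end, p.n_units) == (25_000_000, 30_000_000, 3)
    assert p.frequency == pytest.approx(1.0)
    assert p.units == ("A", "B", "C")


def test_disjoint_calls_each_form_a_peak():
    calls = _calls(
        [
            ("A", "A_UM1", "1", 100, 200, "GAIN"),
            ("B", "B_UM1", "1", 500, 600, "GAIN"),
            ("C", "C_UM1", "2", 100, 300, "GAIN"),
        ]
    )
    peaks = find_peaks(frequency_track(calls, "GAIN"), denominator=3)
    assert len(peaks) == 3
    assert all(p.n_units == 1 for p in peaks)


def test_cohort_frequency_convention():
    # a peak hit by 36 of 93 size-defined subjects
    calls = _calls(
        [(f"S{i}", f"S{i}_UM1", "17", 1000, 2000, "GAIN") for i in range(36)]
    )
    peaks = find_peaks(frequency_track(calls, "GAIN"), denominator=93)
    assert peaks[0].frequency == pytest.approx(0.387, abs=5e-4)


def test_peaks_match_per_base_oracle():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n_subjects = int(rng.integers(1, 11))
        rows = []
        intervals = {}
        for s in range(n_subjects):
            subject = f"S{s}"
            ints = []
            for _ in range(int(rng.integers(1, 4))):
                start = int(rng.integers(1, 90_000))
                end = start + int(rng.integers(1, 10_000))
                rows.append((subject, f"{subject}_UM1", "1", start, end, "GAIN"))
                ints.append((start, end))
            from mosaicna.load_strata import merge_intervals

            intervals[subject] = merge_intervals(ints)
        got = find_peaks(frequency_track(_calls(rows), "GAIN"), denominator=None)
        expected = oracle_peaks(intervals, length=101_000)
        assert len(got) == len(expected)
        for g, (s, e, c, members) in zip(
            sorted(got, key=lambda p: p.start), sorted(expected)
        ):
            assert (g.start, g.end, g.n_units) == (s, e, c)
            assert frozenset(g.units) == members


def test_peak_contained_in_every_contributing_call():
    rng = np.random.default_rng(17)
    rows = []
    for s in range(6):
        for _ in range(2):
            start = int(rng.integers(1, 50_000))
            end = start + int(rng.integers(1, 30_000))
            rows.append((f"S{s}", f"S{s}_UM1", "1", start, end, "DEL"))
    from mosaicna.load_strata import merge_intervals

    calls = _calls(rows)
    for p in find_peaks(frequency_track(calls, "DEL")):
        for unit in p.units:
            sub = calls[calls["subject"] == unit]
            covering = merge_intervals(list(zip(sub["start"], sub["end"])))
            assert any(s <= p.start and e >= p.end for s, e in covering)


def test_receptor_cooccurrence_combination_counting():
    genes = default_gene_set()
    erbb2 = genes[genes["gene"] == "ERBB2"].iloc[0]
    # one call spanning ERBB2 and NGFR on 17q counts the combination once
    calls = _calls([("A", "A_UM1", "17", 37_000_000, 48_000_000, "GAIN")])
    matrix, combos, cumulative = receptor_cooccurrence(calls, genes)
    assert matrix.loc["A", "ERBB2"] and matrix.loc["A", "NGFR"]
    assert combos == {("ERBB2", "NGFR"): 1}
    assert cumulative == 1.0
    # 1-bp overlap suffices
    edge = _calls([("B", "B_UM1", "17", int(erbb2["end"]), int(erbb2["end"]) + 10, "GAIN")])
    m2, _, _ = receptor_cooccurrence(edge, genes)
    assert m2.loc["B", "ERBB2"]


def test_receptor_cumulative_fraction():
    rows = [("S0", "S0_UM1", "7", 55_100_000, 55_200_000, "GAIN")]  # EGFR
    rows += [(f"S{i}", f"S{i}_UM1", "3", 1000, 2000, "GAIN") for i in range(1, 10)]
    matrix, _, cumulative = receptor_cooccurrence(_calls(rows))
    assert cumulative == pytest.approx(0.1)
    none = _calls([("A", "A_UM1", "1", 1, 10, "DEL")])
    _, combos, cumulative = receptor_cooccurrence(none)
    assert combos == {} and cumulative == 0.0
    with pytest.raises(ValueError):
        receptor_cooccurrence(none, genes=default_gene_set().iloc[0:0])


def test_propagation_matching():
    um = _calls([("A", "A_UM1", "1", 1_000_000, 2_000_000, "GAIN"),
                 ("A", "A_UM1", "2", 1_000_000, 2_000_000, "DEL")])
    um.loc[:, "est_fraction"] = 0.2
    pt = _calls([("A", "A_PT1", "1", 1_100_000, 2_100_000, "GAIN")])
    pt.loc[:, "est_fraction"] = 0.7
    report = propagation_report(um, pt)
    gain = report[report["class"] == "GAIN"].iloc[0]
    assert gain["status"] == "PROPAGATED"
    assert gain["delta_f"] == pytest.approx(0.5)
    dele = report[report["class"] == "DEL"].iloc[0]
    assert dele["status"] == "NOT_PROPAGATED"


def test_sampling_vs_aberrant_statistics():
    linear = pd.DataFrame({"n_sampled": [1, 2, 3, 4], "n_aberrant": [0, 1, 2, 3]})
    groups, r = sampling_vs_aberrant(linear)
    assert r == pytest.approx(1.0)
    flat = pd.DataFrame({"n_sampled": [1, 2, 3], "n_aberrant": [1, 1, 1]})
    _, r = sampling_vs_aberrant(flat)
    assert np.isnan(r)
    with pytest.raises(ValueError):
        sampling_vs_aberrant(pd.DataFrame({"n_sampled": [1, 2], "n_aberrant": [0, 1]}))


def test_distance_vs_load_regression():
    collinear = pd.DataFrame(
        {"distance_cm": [1.0, 2.0, 3.0, 4.0], "load_mb": [10.0, 20.0, 30.0, 40.0]}
    )
    _, fit = distance_vs_load(collinear)
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(10.0)
    flagged = pd.DataFrame(
        {
            "distance_cm": [5.0, 2.0, 3.0],
            "load_mb": [1.0, 2.0, 3.0],
            "tumor_at_site": [True, False, False],
        }
    )
    table, _ = distance_vs_load(flagged)
    assert table["distance_used_cm"].iloc[0] == 0.0
    degenerate = pd.DataFrame({"distance_cm": [1.0, 1.0, 1.0], "load_mb": [1, 2, 3]})
    with pytest.raises(ValueError, match="degenerate"):
        distance_vs_load(degenerate)


def test_recurrence_peaks_default_denominator():
    calls = _calls(
        [
            ("A", "A_UM1", "1", 100, 200, "GAIN"),
            ("B", "B_UM1", "1", 150, 250, "GAIN"),
            ("C", "C_UM1", "2", 100, 200, "DEL"),
        ]
    )
    peaks = recurrence_peaks(calls, "GAIN")  # denominator = 3 subjects with calls
    top = peaks.sort_values("n_units", ascending=False).iloc[0]
    assert top["n_units"] == 2
    assert top["frequency"] == pytest.approx(2 / 3)
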