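"""Unit and property tests of the copy-number engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lessel import cna, synthdata
from lessel.cna import (
    BinCounts,
    CnaProfile,
    GenomeBins,
    Segment,
    call_malignant,
    call_states,
    cna_burden,
    concordance_score,
    count_in_bins,
    gc_normalize,
    make_bins,
    mapd,
    segment_cbs,
    to_ratios,
)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,width,expected", [
    (1_000_000, 500_000, [(0, 500_000), (500_000, 1_000_000)]),
    # remainder under half a width merges into the last bin
    (1_200_000, 500_000, [(0, 500_000), (500_000, 1_200_000)]),
    # remainder of at least half a width becomes its own bin
    (1_800_000, 500_000, [(0, 500_000), (500_000, 1_000_000),
                          (1_000_000, 1_500_000), (1_500_000, 1_800_000)]),
    (300_000, 500_000, [(0, 300_000)]),
])
def test_make_bins_layout(length, width, expected):
    bins = make_bins({"1": length}, width)
    got = list(zip(bins.start, bins.end))
    assert got == expected


def test_make_bins_rejects_bad_width():
    with pytest.raises(ValueError):
        make_bins({"1": 1000}, 0)


def test_count_in_bins_half_open_membership_and_conservation():
    bins = make_bins({"1": 1_000_000}, 500_000)
    positions = [("1", 0), ("1", 499_999), ("1", 500_000), ("1", 999_999)]
    counts = count_in_bins(positions, bins)
    # a position at a bin start belongs to that bin, not the previous one
    assert counts.counts.tolist() == [2, 2]
    assert counts.total() == 4


def test_count_in_bins_skips_unknown_chromosome():
    bins = make_bins({"1": 1_000_000}, 500_000)
    counts = count_in_bins([("1", 10), ("7", 10)], bins)
    assert counts.total() == 1


def test_count_in_bins_matches_interval_scan_oracle(rng):
    """Binned counting agrees with a brute-force interval scan."""
    bins = make_bins({"1": 2_000_000, "2": 1_300_000}, 400_000)
    chroms = rng.choice(["1", "2"], size=300)
    lengths = {"1": 2_000_000, "2": 1_300_000}
    pos = [(c, int(rng.integers(lengths[c]))) for c in chroms]
    got = count_in_bins(pos, bins).counts
    oracle = np.zeros(len(bins), dtype=int)
    for c, p in pos:
        for i in range(len(bins)):
            if bins.chrom[i] == c and bins.start[i] <= p < bins.end[i]:
                oracle[i] += 1
    assert np.array_equal(got, oracle)


# ---------------------------------------------------------------------------
# GC normalization and ratios
# ---------------------------------------------------------------------------

def test_gc_normalize_identity_on_flat_trend(small_bins, rng):
    # GC-independent counts: the correction is the identity within 1%
    flat = np.full(len(small_bins), 200.0)
    assert np.allclose(gc_normalize(flat, small_bins), flat, rtol=0.01)
    # with Poisson noise the fitted trend may chase noise but stays small
    noisy = BinCounts("c", rng.poisson(200, len(small_bins)))
    corrected = gc_normalize(noisy, small_bins)
    assert abs(corrected / noisy.counts - 1).mean() < 0.03


def test_gc_normalize_flattens_pure_quadratic(small_bins):
    gc = small_bins.gc
    raw = 200.0 * (0.5 + 2.0 * gc - 1.5 * gc ** 2)
    corrected = gc_normalize(raw, small_bins)
    assert np.all(np.abs(corrected / corrected.mean() - 1) < 0.02)


def test_gc_normalize_preserves_mean(small_bins, rng):
    raw = rng.poisson(100 * (1 + small_bins.gc), len(small_bins)).astype(float)
    corrected = gc_normalize(raw, small_bins)
    assert corrected.mean() == pytest.approx(raw.mean(), rel=1e-6)


def test_gc_normalize_rejects_sparse_input(small_bins):
    counts = np.zeros(len(small_bins))
    counts[:10] = 5
    with pytest.raises(ValueError):
        gc_normalize(counts, small_bins)


def test_to_ratios_arithmetic():
    bins = make_bins({"1": 1_500_000}, 500_000)
    track = to_ratios(np.array([10.0, 20.0, 30.0]), bins)
    assert track.ratios.tolist() == [0.5, 1.0, 1.5]


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.1, max_value=100), min_size=3, max_size=40))
def test_to_ratios_mean_is_one(values):
    bins = make_bins({"1": 500_000 * len(values)}, 500_000)
    track = to_ratios(np.array(values), bins)
    assert track.ratios.mean() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# MAPD
# ---------------------------------------------------------------------------

def test_mapd_hand_computed_values():
    assert mapd(np.ones(10)) == 0.0
    assert mapd(np.array([1.0, 1.2, 0.8])) == pytest.approx(0.3)


def test_mapd_excludes_cross_chromosome_pairs():
    chrom = np.array(["1", "1", "2", "2"])
    # the 5.0 jump sits on the chromosome boundary and must not count
    assert mapd(np.array([1.0, 1.0, 6.0, 6.0]), chrom) == 0.0


def test_mapd_qc_boundary():
    track = cna.RatioTrack("c", np.ones(3), mapd=0.46)
    assert not track.qc_pass
    assert cna.RatioTrack("c", np.ones(3), mapd=0.45).qc_pass


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(min_value=-5, max_value=5))
def test_mapd_shift_invariant(shift):
    base = np.array([1.0, 1.3, 0.9, 1.1, 0.7])
    assert mapd(base + shift) == pytest.approx(mapd(base), abs=1e-12)


def test_mapd_single_bin_errors():
    with pytest.raises(ValueError):
        mapd(np.array([1.0]))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_cbs_flat_noiseless_single_segment(small_bins):
    ratios = np.ones(len(small_bins))
    profile = segment_cbs(ratios, small_bins, seed=1)
    per_chrom = {}
    for s in profile.segments:
        per_chrom[s.chrom] = per_chrom.get(s.chrom, 0) + 1
    assert all(v == 1 for v in per_chrom.values())


def test_cbs_noiseless_step_breakpoint_exact():
    bins = make_bins({"1": 50_000_000}, 500_000)  # 100 bins
    ratios = np.ones(100)
    ratios[50:] = 1.5
    profile = segment_cbs(ratios, bins, seed=1)
    boundaries = sorted({s.start_bin for s in profile.segments})
    assert boundaries == [0, 50]


def test_cbs_translation_invariance():
    """Identical chromosomes segment identically."""
    bins = make_bins({"1": 30_000_000, "2": 30_000_000}, 500_000)
    rng = np.random.default_rng(3)
    one = 1.0 + 0.1 * rng.normal(size=60)
    one[20:45] *= 1.5
    ratios = np.concatenate([one, one])
    profile = segment_cbs(ratios, bins, seed=5)
    by_chrom = {c: [] for c in ("1", "2")}
    for s in profile.segments:
        by_chrom[s.chrom].append((s.start_bin % 60, s.end_bin - s.start_bin,
                                  round(s.mean_log2, 10)))
    assert by_chrom["1"] == by_chrom["2"]


# ---------------------------------------------------------------------------
# states and burden
# ---------------------------------------------------------------------------

def _profile(segment_specs, cell_id="c", mapd_val=0.2):
    segs = tuple(Segment(*spec) for spec in segment_specs)
    return CnaProfile(cell_id, segs, mapd_val)


def test_call_states_all_neutral_zero_burden():
    p = _profile([("1", 0, 10, 0, 5_000_000, 0.0),
                  ("2", 10, 20, 0, 5_000_000, 0.0)])
    out = call_states(p)
    assert all(s.state == "neutral" for s in out.segments)
    assert out.burden == 0.0


def test_call_states_single_copy_gain_called():
    p = _profile([("1", 0, 50, 0, 25_000_000, 0.0),
                  ("1", 50, 60, 25_000_000, 30_000_000, np.log2(1.5))])
    out = call_states(p)
    assert out.segments[1].state == "gain"
    assert out.segments[0].state == "neutral"


def test_call_states_threshold_sweep_matches_relabel_oracle(rng):
    means = rng.normal(0, 0.4, 30)
    p = _profile([("1", i, i + 1, i * 10 ** 6, (i + 1) * 10 ** 6, m)
                  for i, m in enumerate(means)])
    for thr in (0.1, 0.25, 0.5):
        out = call_states(p, gain=thr, loss=-thr, center=False)
        oracle = ["gain" if m >= thr else ("loss" if m <= -thr else "neutral")
                  for m in means]
        assert [s.state for s in out.segments] == oracle


def test_burden_hand_computed():
    # two 100 Mb autosomes, one 50 Mb gain -> 25%
    p = _profile([
        ("1", 0, 100, 0, 50_000_000, 0.58, "gain"),
        ("1", 100, 200, 50_000_000, 100_000_000, 0.0, "neutral"),
        ("2", 200, 400, 0, 100_000_000, 0.0, "neutral"),
    ])
    assert cna_burden(p) == pytest.approx(25.0)


def test_burden_extremes_and_sex_exclusion():
    all_gain = _profile([("1", 0, 10, 0, 10 ** 7, 0.6, "gain"),
                         ("X", 10, 20, 0, 10 ** 7, 0.6, "gain")])
    assert cna_burden(all_gain) == pytest.approx(100.0)
    none = _profile([("1", 0, 10, 0, 10 ** 7, 0.0, "neutral")])
    assert cna_burden(none) == 0.0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _random_profile(rng, n_bins=100, cell_id="c"):
    """A random segmented profile with a handful of alterations."""
    edges = np.sort(rng.choice(np.arange(5, n_bins - 5), 4, replace=False))
    edges = [0, *edges.tolist(), n_bins]
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        state = rng.choice(["neutral", "gain", "loss"], p=[0.5, 0.25, 0.25])
        mean = {"neutral": 0.0, "gain": 0.58, "loss": -1.0}[state] + rng.normal(0, 0.05)
        segs.append(Segment("1", a, b, a * 10 ** 6, b * 10 ** 6, mean, state))
    return CnaProfile(cell_id, tuple(segs), 0.2)


def test_concordance_identical_and_mirror():
    p = _profile([("1", 0, 50, 0, 25 * 10 ** 6, 0.0, "neutral"),
                  ("1", 50, 100, 25 * 10 ** 6, 50 * 10 ** 6, 0.58, "gain")])
    mirror = _profile([("1", 0, 50, 0, 25 * 10 ** 6, 0.0, "neutral"),
                       ("1", 50, 100, 25 * 10 ** 6, 50 * 10 ** 6, -0.58, "loss")])
    assert concordance_score(p, p, 100) == pytest.approx(1.0)
    assert concordance_score(p, mirror, 100) == pytest.approx(-1.0)


def test_concordance_flat_profile_not_eligible():
    flat = _profile([("1", 0, 100, 0, 50 * 10 ** 6, 0.0, "neutral")])
    cna_p = _profile([("1", 0, 100, 0, 50 * 10 ** 6, 0.6, "gain")])
    assert concordance_score(flat, cna_p, 100) is None
    assert concordance_score(flat, flat, 100) is None


def test_concordance_random_profiles_center_on_zero(rng):
    scores = []
    for k in range(300):
        a = _random_profile(rng, cell_id=f"a{k}")
        b = _random_profile(rng, cell_id=f"b{k}")
        s = concordance_score(a, b, 100)
        if s is not None:
            scores.append(s)
    assert abs(np.mean(scores)) < 0.1


def test_call_malignant_rules(rng):
    clone_events = [("1", 0, 40, 0, 20 * 10 ** 6, 0.0, "neutral"),
                    ("1", 40, 80, 20 * 10 ** 6, 40 * 10 ** 6, 0.58, "gain"),
                    ("1", 80, 100, 40 * 10 ** 6, 50 * 10 ** 6, 0.0, "neutral")]
    clones = [_profile(clone_events, cell_id=f"t{i}") for i in range(3)]
    flats = [_profile([("1", 0, 100, 0, 50 * 10 ** 6, 0.0, "neutral")],
                      cell_id=f"n{i}") for i in range(3)]
    res = call_malignant(clones + flats, 100)
    assert res.malignant_ids == {"t0", "t1", "t2"}
    # all flat -> nothing called
    res2 = call_malignant(flats + [_profile([("1", 0, 100, 0, 50 * 10 ** 6,
                                              0.0, "neutral")], "n9")], 100)
    assert res2.malignant_ids == frozenset()
    # a lone CNA-bearing cell cannot form a clone of two
    res3 = call_malignant([clones[0]] + flats, 100)
    assert res3.malignant_ids == frozenset()


def test_call_malignant_matrix_symmetric_unit_diagonal():
    clone_events = [("1", 0, 50, 0, 25 * 10 ** 6, 0.58, "gain"),
                    ("1", 50, 100, 25 * 10 ** 6, 50 * 10 ** 6, 0.0, "neutral")]
    profiles = [_profile(clone_events, cell_id=f"t{i}") for i in range(3)]
    res = call_malignant(profiles, 100)
    assert np.allclose(res.scores, res.scores.T, equal_nan=True)
    assert np.allclose(np.diag(res.scores), 1.0)


# ---------------------------------------------------------------------------
# report round-trips
# ---------------------------------------------------------------------------

def test_bins_and_counts_tsv_roundtrip(tmp_path, small_bins, rng):
    path = tmp_path / "bins.tsv"
    small_bins.to_tsv(path)
    loaded = GenomeBins.from_tsv(path)
    pd.testing.assert_frame_equal(loaded.table, small_bins.table)
    counts = BinCounts("cell7", rng.poisson(50, len(small_bins)))
    cpath = tmp_path / "cell7.tsv"
    counts.to_tsv(cpath, small_bins)
    loaded_counts = BinCounts.from_tsv(cpath)
    assert loaded_counts.cell_id == "cell7"
    assert np.array_equal(loaded_counts.counts, counts.counts)
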