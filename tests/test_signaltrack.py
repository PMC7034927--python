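import numpy as np
import pytest

from chefind._stats import significance_tier
from chefind.genome import BedInterval, TranscriptModel
from chefind.signaltrack import (
    PeakSet,
    SignalTrack,
    body_profile,
    compare_groups_at_tss,
    group_by_mark,
    signal_vs_input,
    tss_profile,
)


def tmodel(id, start, end, strand="+", chrom="c"):
    return TranscriptModel(id=id, chrom=chrom, start=start, end=end, strand=strand)


# ---------------------------------------------------------------------------
# signal vs input


def test_ratio_identity_and_doubling():
    base = {"c": np.full(100, 5.0)}
    t1 = SignalTrack(base)
    assert np.allclose(signal_vs_input(t1, t1).data["c"], 1.0)
    t2 = SignalTrack({"c": base["c"] * 2})
    small_pc = signal_vs_input(t2, t1, pseudocount=1e-9)
    assert np.allclose(small_pc.data["c"], 2.0)


def test_ratio_matches_elementwise_oracle(rng):
    a = SignalTrack({"c": rng.random(200) * 3})
    b = SignalTrack({"c": rng.random(200) * 3})
    r = signal_vs_input(a, b, pseudocount=1.0)
    assert np.allclose(r.data["c"], (a.data["c"] + 1) / (b.data["c"] + 1))


def test_ratio_rejects_mismatched_chromosomes():
    a = SignalTrack({"c1": np.ones(10)})
    b = SignalTrack({"c2": np.ones(10)})
    with pytest.raises(ValueError):
        signal_vs_input(a, b)


def test_bedgraph_round_trip(tmp_path, rng):
    vals = np.round(rng.random(500) * 4, 3)
    vals[rng.random(500) < 0.3] = 0.0
    track = SignalTrack({"c": vals})
    p = tmp_path / "t.bedgraph"
    track.to_bedgraph(p)
    back = SignalTrack.from_bedgraph(p, {"c": 500})
    assert np.allclose(back.data["c"], vals)


def test_bigwig_reader_round_trip(tmp_path, rng):
    pyBigWig = pytest.importorskip("pyBigWig")
    vals = np.round(rng.random(300) * 2, 3)
    p = str(tmp_path / "t.bw")
    bw = pyBigWig.open(p, "w")
    bw.addHeader([("c", 300)])
    bw.addEntries("c", 0, values=list(vals), span=1, step=1)
    bw.close()
    track = SignalTrack.from_bigwig(p)
    assert np.allclose(track.data["c"], vals, atol=1e-6)


# ---------------------------------------------------------------------------
# TSS profiles


def test_tss_profile_constant_track_is_flat():
    track = SignalTrack({"c": np.full(10000, 3.0)})
    prof = tss_profile(track, [tmodel("a", 3000, 4000), tmodel("b", 6000, 6400, "-")])
    assert np.allclose(prof.mean_ratio, 3.0)
    assert prof.n_transcripts == 2


def test_tss_profile_impulse_hits_center_bin():
    data = np.zeros(20000)
    ts = [tmodel(f"x{i}", s, s + 500) for i, s in enumerate((2000, 9000, 15000))]
    for t in ts:
        data[t.tss] = 1.0
    prof = tss_profile(SignalTrack({"c": data}), ts)
    nonzero = np.flatnonzero(prof.mean_ratio)
    assert list(nonzero) == [len(prof.bins) // 2]


def test_tss_profile_out_of_bounds_dropped():
    track = SignalTrack({"c": np.ones(5000)})
    prof = tss_profile(track, [tmodel("edge", 100, 600), tmodel("ok", 3000, 3500)])
    assert prof.n_transcripts == 1
    assert prof.n_dropped == 1


def test_tss_profile_linearity(rng):
    a = SignalTrack({"c": rng.random(10000)})
    b = SignalTrack({"c": rng.random(10000)})
    summed = SignalTrack({"c": a.data["c"] + b.data["c"]})
    ts = [tmodel(f"t{i}", 2000 + 1500 * i, 2600 + 1500 * i,
                 "+" if i % 2 else "-") for i in range(4)]
    pa = tss_profile(a, ts)
    pb = tss_profile(b, ts)
    ps = tss_profile(summed, ts)
    assert np.allclose(ps.mean_ratio, pa.mean_ratio + pb.mean_ratio)


def test_tss_profile_strand_reflection_is_exact(rng):
    """Mirroring the genome (track reversed, transcripts coordinate-mirrored
    with strands flipped) leaves every profile unchanged."""
    L = 12000
    sig = rng.random(L)
    fwd = SignalTrack({"c": sig})
    rev = SignalTrack({"c": sig[::-1].copy()})
    plus = [tmodel(f"p{i}", s, s + 700) for i, s in enumerate((1500, 4200, 7000))]
    mirrored = [
        tmodel(f"m{i}", L - (t.end), L - t.start, "-") for i, t in enumerate(plus)
    ]
    pf = tss_profile(fwd, plus)
    pr = tss_profile(rev, mirrored)
    assert np.array_equal(pf.mean_ratio, pr.mean_ratio)


# ---------------------------------------------------------------------------
# body profiles


def test_body_profile_constant_is_flat():
    track = SignalTrack({"c": np.full(20000, 2.0)})
    prof = body_profile(track, [tmodel("a", 5000, 8000)])
    assert np.allclose(prof.mean_ratio, 2.0)


def test_body_profile_flanks_separate_from_body():
    data = np.zeros(20000)
    t = tmodel("a", 5000, 8000)
    data[t.start:t.end] = 1.0
    prof = body_profile(SignalTrack({"c": data}), [t], n_bins=100, flank=1000,
                        flank_bins=10)
    assert np.allclose(prof.mean_ratio[:10], 0.0)
    assert np.allclose(prof.mean_ratio[-10:], 0.0)
    assert np.allclose(prof.mean_ratio[10:110], 1.0)


def test_body_profile_scaling_invariance():
    """Two transcripts of different lengths with the same per-scaled-position
    signal produce identical body profiles."""
    n_bins = 50
    shape = np.repeat(np.arange(n_bins, dtype=float), 20)  # len 1000
    data = np.zeros(30000)
    t1 = tmodel("a", 2000, 3000)
    t2 = tmodel("b", 10000, 12000)
    data[t1.start:t1.end] = shape
    data[t2.start:t2.end] = np.repeat(np.arange(n_bins, dtype=float), 40)
    track = SignalTrack({"c": data})
    p1 = body_profile(track, [t1], n_bins=n_bins, flank=0)
    p2 = body_profile(track, [t2], n_bins=n_bins, flank=0)
    assert np.allclose(p1.mean_ratio, p2.mean_ratio)


def test_body_profile_drops_short_transcripts():
    track = SignalTrack({"c": np.ones(10000)})
    prof = body_profile(track, [tmodel("short", 5000, 5050),
                                tmodel("ok", 2000, 3000)], n_bins=100)
    assert prof.n_transcripts == 1
    assert prof.n_dropped == 1


# ---------------------------------------------------------------------------
# high/low mark grouping


def peakset(*ivs):
    return PeakSet([BedInterval("c", s, e) for s, e in ivs], mark="m")


def test_group_by_mark_examples():
    ts = [tmodel("in", 1000, 2000), tmodel("far", 20000, 21000)]
    groups = group_by_mark(ts, peakset((1500, 1600), (26000, 26200)),
                          proximity=1000)
    assert [t.id for t in groups["high"]] == ["in"]   # peak inside body
    assert [t.id for t in groups["low"]] == ["far"]   # nearest peak 5 kb away


def test_group_by_mark_zero_proximity_equals_span_overlap():
    ts = [tmodel("a", 1000, 2000), tmodel("b", 3000, 4000)]
    pk = peakset((2000, 2500))  # adjacent to a, half-open: no overlap
    groups = group_by_mark(ts, pk, proximity=0)
    assert not groups["high"]
    pk2 = peakset((1999, 2500))
    groups2 = group_by_mark(ts, pk2, proximity=0)
    assert [t.id for t in groups2["high"]] == ["a"]


def test_group_by_mark_matches_brute_force(rng):
    ts = [tmodel(f"t{i}", int(s), int(s) + 500)
          for i, s in enumerate(rng.integers(1000, 90000, size=60))]
    peaks = [(int(s), int(s) + 200) for s in rng.integers(0, 95000, size=40)]
    pk = peakset(*peaks)
    prox = 800
    groups = group_by_mark(ts, pk, proximity=prox)
    high_ids = {t.id for t in groups["high"]}
    for t in ts:
        expected = any(ps < t.end + prox and pe > t.start - prox
                       for ps, pe in peaks)
        assert (t.id in high_ids) == expected


def test_group_by_mark_rejects_empty_peaks():
    with pytest.raises(ValueError):
        group_by_mark([tmodel("a", 0, 10)], PeakSet([], "m"))


# ---------------------------------------------------------------------------
# group comparison and tiers


@pytest.mark.parametrize(
    "p,tier",
    [
        (0.5, "NS"), (0.06, "NS"),
        (0.02, "ns*"),   # the legend's unnamed gap between 0.01 and 0.05
        (0.009, "*"), (1e-12, "**"), (1e-17, "****"),
    ],
)
def test_significance_tiers(p, tier):
    assert significance_tier(p) == tier


def test_identical_groups_not_significant():
    track = SignalTrack({"c": np.ones(20000) * 2})
    ts = [tmodel(f"t{i}", 2000 + 1500 * i, 2500 + 1500 * i) for i in range(6)]
    comp = compare_groups_at_tss(track, ts, ts)
    assert comp.pvalue == pytest.approx(1.0)
    assert comp.tier == "NS"


def test_planted_shift_detected(rng):
    data = np.ones(200000)
    ga, gb = [], []
    for i in range(50):
        s = 2000 + 3900 * i
        t = tmodel(f"a{i}", s, s + 500)
        data[s - 1000: s + 1000] += 2.0  # group A shifted by +2 ratio units
        ga.append(t)
        gb.append(tmodel(f"b{i}", s + 2000, s + 2400))
    track = SignalTrack({"c": data + rng.normal(0, 0.05, size=len(data)).clip(-0.5)})
    comp = compare_groups_at_tss(track, ga, gb)
    assert comp.tier in ("*", "**", "****")


def test_compare_groups_requires_minimum_size():
    track = SignalTrack({"c": np.ones(10000)})
    ts = [tmodel(f"t{i}", 2000 + 1500 * i, 2500 + 1500 * i) for i in range(4)]
    with pytest.raises(ValueError):
        compare_groups_at_tss(track, ts, ts)
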